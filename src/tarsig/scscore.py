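"""Single-cell composite scoring of the TAR signature.

Implements the single-cell half of the pipeline: per-cell QC filtering,
library-size log normalization, marker-based annotation of precomputed
clusters, the keratinocyte-preferential gene filter, the per-cell
composite ("TAR11") score, percentile-based stratification of cells, and
the stress-keratin association summary (Kruskal-Wallis across strata
plus a median-trend flag).

Cells live in an :class:`anndata.AnnData` (cells x genes) whose ``obs``
carries ``cluster``, ``n_features``, ``total_counts`` and ``mito_frac``.
Clustering itself is an input, never recomputed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "AD_QC",
    "CellQCThresholds",
    "HS_QC",
    "PSOR_QC",
    "QC_PRESETS",
    "DEFAULT_MARKER_RULES",
    "SignatureDef",
    "TAR11",
    "TAR11_GENES",
    "annotate_clusters",
    "composite_score",
    "kc_preferential_filter",
    "normalize_log",
    "qc_filter",
    "stratify",
    "stratum_association",
]

#: The 11-gene keratinocyte-preferential TAR signature (human symbols).
TAR11_GENES: tuple[str, ...] = (
    "ANGPTL4", "IFITM1", "IFI16", "PHLDA2", "KLK1", "PDPN",
    "AKR1B10", "ACAT2", "TUBB6", "OAS1", "HRH2",
)

#: Marker rules used to annotate clusters with cell types.
DEFAULT_MARKER_RULES: dict[str, tuple[str, ...]] = {
    "KC": ("KRT10", "KRT15", "KRT2"),
    "Mel": ("PMEL",),
    "TC": ("CD3D",),
    "Myeloid": ("LYZ",),
}


@dataclass(frozen=True)
class SignatureDef:
    """An ordered list of human gene symbols scored as one composite."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature gene symbols must be unique")


TAR11 = SignatureDef(name="TAR11", genes=TAR11_GENES)


@dataclass(frozen=True)
class CellQCThresholds:
    """Strict-inequality per-cell QC bounds; ``None`` disables a bound."""

    min_features: int = 500
    max_features: int | None = None
    max_counts: int | None = None
    max_mito: float = 0.15

    def __post_init__(self) -> None:
        if self.max_features is not None and self.min_features >= self.max_features:
            raise ValueError("min_features must be < max_features")


PSOR_QC = CellQCThresholds(min_features=500, max_features=7500, max_mito=0.15)
HS_QC = CellQCThresholds(min_features=500, max_counts=50_000, max_mito=0.15)
AD_QC = HS_QC

QC_PRESETS: dict[str, CellQCThresholds] = {"psor": PSOR_QC, "hs": HS_QC, "ad": AD_QC}


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)


def qc_filter(
    adata: ad.AnnData, thresholds: CellQCThresholds = PSOR_QC
) -> tuple[ad.AnnData, dict[str, int]]:
    """Retain cells satisfying every applicable strict inequality.

    Returns the filtered AnnData plus the number of cells removed by
    each criterion (a cell can count against several).
    """
    obs = adata.obs
    for col in ("n_features", "total_counts", "mito_frac"):
        if col not in obs.columns:
            raise ValueError(f"cell metadata lacks required column {col!r}")
    keep = obs["n_features"] > thresholds.min_features
    removed = {"min_features": int((~keep).sum())}
    if thresholds.max_features is not None:
        ok = obs["n_features"] < thresholds.max_features
        removed["max_features"] = int((~ok).sum())
        keep &= ok
    if thresholds.max_counts is not None:
        ok = obs["total_counts"] < thresholds.max_counts
        removed["max_counts"] = int((~ok).sum())
        keep &= ok
    ok = obs["mito_frac"] < thresholds.max_mito
    removed["max_mito"] = int((~ok).sum())
    keep &= ok
    if adata.n_obs > 0 and not keep.any():
        raise ValueError("QC removed every cell; check thresholds and units")
    return adata[keep.to_numpy()].copy(), removed


def normalize_log(adata: ad.AnnData, scale: float = 10_000.0) -> pd.DataFrame:
    """Library-size normalized, natural-log transformed expression.

    value = ln(1 + count / total_counts * scale); a zero count maps
    exactly to 0, so the normalized vector of a cell is invariant to
    uniform depth scaling.
    """
    counts = _dense(adata.X).astype(float)
    totals = counts.sum(axis=1)
    if adata.n_obs and (totals <= 0).any():
        raise ValueError("cells with zero total counts present; QC should remove them")
    out = np.log1p(counts / totals[:, None] * scale)
    return pd.DataFrame(out, index=adata.obs_names, columns=adata.var_names)


def annotate_clusters(
    logexpr: pd.DataFrame,
    cluster_labels: pd.Series,
    marker_rules: dict[str, tuple[str, ...]] | None = None,
    min_z: float = 1.0,
) -> dict[str, str]:
    """Assign each cluster the cell type whose markers are most enriched.

    Per-cluster mean expression is z-scored across clusters gene-wise;
    each cluster receives the cell type with the highest mean marker
    z-score, or ``"Other"`` if no rule reaches ``min_z``. Marker genes
    absent from the matrix are skipped with a warning; a rule with no
    present markers is dropped.
    """
    marker_rules = marker_rules or DEFAULT_MARKER_RULES
    labels = cluster_labels.loc[logexpr.index]
    if labels.index.duplicated().any():
        raise ValueError("duplicate cell ids in cluster labels")
    cluster_means = logexpr.groupby(labels.to_numpy()).mean()
    mu = cluster_means.mean(axis=0)
    sd = cluster_means.std(axis=0, ddof=0).replace(0.0, np.nan)
    z = (cluster_means - mu) / sd

    usable: dict[str, list[str]] = {}
    for cell_type, markers in marker_rules.items():
        present = [g for g in markers if g in logexpr.columns]
        missing = sorted(set(markers) - set(present))
        if missing:
            warnings.warn(
                f"marker genes missing for {cell_type}: {missing}", stacklevel=2
            )
        if present:
            usable[cell_type] = present
        else:
            warnings.warn(f"rule for {cell_type} skipped: no markers present",
                          stacklevel=2)

    annotation: dict[str, str] = {}
    for cluster in cluster_means.index:
        best_type, best_score = "Other", -np.inf
        for cell_type, markers in usable.items():
            vals = z.loc[cluster, markers].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]  # genes flat across clusters carry no signal
            if vals.size == 0:
                continue
            score = float(vals.mean())
            if score > best_score:
                best_type, best_score = cell_type, score
        annotation[str(cluster)] = best_type if best_score >= min_z else "Other"
    return annotation


def kc_preferential_filter(
    logexpr: pd.DataFrame,
    cluster_labels: pd.Series,
    annotation: dict[str, str],
    genes: set[str],
) -> set[str]:
    """Keep genes with strictly higher mean expression in keratinocytes
    than in myeloid-lineage cells (means over all cells of each type)."""
    labels = cluster_labels.loc[logexpr.index].astype(str)
    cell_types = labels.map(annotation)
    missing = [t for t in ("KC", "Myeloid") if not (cell_types == t).any()]
    if missing:
        raise ValueError(f"annotation contains no cells of type: {missing}")
    present = sorted(g for g in genes if g in logexpr.columns)
    kc_mean = logexpr.loc[(cell_types == "KC").to_numpy(), present].mean(axis=0)
    mye_mean = logexpr.loc[(cell_types == "Myeloid").to_numpy(), present].mean(axis=0)
    return set(kc_mean.index[(kc_mean > mye_mean).to_numpy()])


def composite_score(logexpr: pd.DataFrame, sig: SignatureDef) -> pd.Series:
    """Per-cell arithmetic mean of log-normalized signature expression.

    Signature genes missing from the matrix are dropped with a warning
    (the score is taken over the intersection); if none are present the
    call fails.
    """
    present = [g for g in sig.genes if g in logexpr.columns]
    missing = [g for g in sig.genes if g not in logexpr.columns]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in the matrix")
    if missing:
        warnings.warn(
            f"signature {sig.name}: {len(missing)} gene(s) absent and dropped: "
            f"{missing}", stacklevel=2,
        )
    return logexpr[present].mean(axis=1).rename(f"{sig.name}_score")


def _nearest_rank(sorted_scores: np.ndarray, pct: float) -> float:
    """Nearest-rank empirical percentile: value at rank ceil(p/100 * N)."""
    n = sorted_scores.size
    rank = max(1, math.ceil(pct / 100.0 * n))
    return float(sorted_scores[rank - 1])


def stratify(
    scores: pd.Series, high_pct: float = 95.0, med_pct: float = 75.0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Split cells into high / medium / low strata by score percentiles.

    Cutoffs are nearest-rank percentiles of the score distribution;
    cells strictly above the high cutoff are ``high``, cells strictly
    above the medium cutoff (and at most the high cutoff) are
    ``medium``, the rest ``low``. Ties at a cutoff fall to the lower
    stratum, so with all-equal scores every cell is ``low``.
    """
    if high_pct <= med_pct:
        raise ValueError("high_pct must be > med_pct")
    if len(scores) == 0:
        raise ValueError("at least one cell is required")
    srt = np.sort(scores.to_numpy(dtype=float))
    q_high = _nearest_rank(srt, high_pct)
    q_med = _nearest_rank(srt, med_pct)
    stratum = np.where(
        scores > q_high, "high", np.where(scores > q_med, "medium", "low")
    )
    table = pd.DataFrame({"score": scores, "stratum": stratum}, index=scores.index)
    cutoffs = {"high_pct": float(high_pct), "med_pct": float(med_pct),
               "q_high": q_high, "q_med": q_med}
    return table, cutoffs


def stratum_association(
    logexpr: pd.DataFrame, strata: pd.Series, gene: str
) -> dict:
    """Association of one gene's expression with the score strata.

    Reports per-stratum n/mean/median, the Kruskal-Wallis H and p-value
    across non-empty strata, and a monotone-trend flag
    (median_high >= median_medium >= median_low, computed over the
    strata that are present; ties count as monotone).
    """
    if gene not in logexpr.columns:
        raise ValueError(f"gene {gene!r} absent from the expression matrix")
    strata = strata.loc[logexpr.index]
    values = logexpr[gene]
    groups = {
        s: values[(strata == s).to_numpy()].to_numpy()
        for s in ("high", "medium", "low")
        if (strata == s).any()
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty strata")
    arrays = list(groups.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        # every observation tied: no rank information
        h_stat, p_value = 0.0, 1.0
    else:
        h_stat, p_value = stats.kruskal(*arrays)
    per_stratum = {
        s: {"n": int(v.size), "mean": float(v.mean()), "median": float(np.median(v))}
        for s, v in groups.items()
    }
    medians = [per_stratum[s]["median"] for s in ("high", "medium", "low") if s in per_stratum]
    trend = all(a >= b for a, b in zip(medians, medians[1:]))
    return {
        "gene": gene,
        "strata": per_stratum,
        "kruskal_h": float(h_stat),
        "p_value": float(p_value),
        "monotone_trend": bool(trend),
    }
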