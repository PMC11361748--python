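"""Bulk RNA-seq differential expression engine.

Self-contained reimplementation of the standard bulk workflow used to
derive treatment-response gene sets from a two-genotype x two-treatment
design: low-expression filtering, TMM (trimmed mean of M-values)
compositional normalization, log2 counts-per-million, per-gene moderated
two-sample contrasts with empirical-Bayes variance shrinkage, and
Benjamini-Hochberg FDR adjustment.

The moderated engine is deliberately simpler than a precision-weighted
(voom-style) fit: downstream signature derivation consumes only the
log fold change and the adjusted p-value, and those are produced here by
a pooled-variance t statistic shrunk toward a common prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "BulkCountMatrix",
    "ContrastSpec",
    "NormFactors",
    "bh_adjust",
    "filter_low_expression",
    "log_cpm",
    "moderated_de",
    "tmm_factors",
]

DESIGN_COLUMNS = ("genotype", "treatment", "replicate")


@dataclass
class BulkCountMatrix:
    """Integer gene x sample count matrix plus its factorial sample design.

    Parameters
    ----------
    counts:
        Genes as rows, samples as columns. Non-negative integers.
    design:
        One row per sample (index = sample id) with at least the columns
        ``genotype``, ``treatment`` and ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("counts must be finite")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integer-valued")
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValueError(f"design table lacks columns: {missing}")
        uncovered = self.counts.columns.difference(self.design.index)
        if len(uncovered):
            raise ValueError(f"samples missing from design: {list(uncovered)[:5]}")
        # align design row order to the count columns
        self.design = self.design.loc[self.counts.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def group_sizes(self) -> pd.Series:
        """Number of replicates in each (genotype, treatment) design cell."""
        return self.design.groupby(["genotype", "treatment"], observed=True).size()


@dataclass(frozen=True)
class ContrastSpec:
    """A within-genotype treatment-versus-vehicle contrast.

    Direction convention: ``treatment`` over ``reference`` — positive log
    fold changes mean higher expression under the treatment.
    """

    name: str
    genotype: str
    treatment: str = "TPA"
    reference: str = "vehicle"


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors, geometric mean constrained to 1."""

    factors: pd.Series
    reference_sample: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        log_gm = np.log(self.factors.to_numpy()).mean()
        if abs(log_gm) > 1e-9:
            raise ValueError("TMM factors must have geometric mean 1")

    def effective_library_sizes(self, m: BulkCountMatrix) -> pd.Series:
        return m.library_sizes() * self.factors


def filter_low_expression(
    m: BulkCountMatrix, min_count: int = 10, min_total: int = 15
) -> BulkCountMatrix:
    """Drop genes too weakly expressed to support inference.

    A gene is kept iff it has ``count >= min_count`` in at least *g*
    samples, where *g* is the size of the smallest (genotype, treatment)
    design cell, AND its total count across all samples is at least
    ``min_total``.
    """
    if min_count < 0 or min_total < 0:
        raise ValueError("min_count and min_total must be >= 0")
    g = int(m.group_sizes().min())
    counts = m.counts
    keep = ((counts >= min_count).sum(axis=1) >= g) & (counts.sum(axis=1) >= min_total)
    if not keep.any():
        warnings.warn("all genes removed by the expression filter", stacklevel=2)
    return BulkCountMatrix(counts=counts.loc[keep].copy(), design=m.design.copy())


def _quantile_fraction(counts: np.ndarray, lib: np.ndarray, p: float = 75.0) -> np.ndarray:
    """Per-sample p-th percentile of counts expressed as a library fraction."""
    return np.percentile(counts, p, axis=0) / lib


def _tmm_one_sample(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Doubly trimmed, precision-weighted mean of M-values for one sample.

    Returns the scaling factor on the linear scale (2**f). Genes must be
    positive in both the sample and the reference to contribute.
    """
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        warnings.warn("sample shares no positive genes with the reference; factor set to 1",
                      stacklevel=3)
        return 1.0
    obs = obs[ok].astype(float)
    ref = ref[ok].astype(float)
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    # asymptotic binomial variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    m: BulkCountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormFactors:
    """TMM normalization factors (weighted trimmed mean of M-values).

    The reference sample is the one whose 75th-percentile count fraction
    is closest to the mean of that quantity across samples. For every
    sample, M (log2 expression ratio vs reference) and A (mean log2
    abundance) are computed over genes positive in both; M is trimmed by
    ``trim_m`` and A by ``trim_a`` from each tail; the factor is the
    precision-weighted mean of the surviving M values, exponentiated.
    Factors are rescaled to geometric mean 1.
    """
    if m.counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    counts = m.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have positive library size")
    q = _quantile_fraction(counts, lib)
    ref_idx = int(np.argmin(np.abs(q - q.mean())))
    ref = counts[:, ref_idx]
    n_ref = lib[ref_idx]
    raw = np.ones(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == ref_idx:
            continue
        raw[k] = _tmm_one_sample(counts[:, k], ref, lib[k], n_ref, trim_m, trim_a)
    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormFactors(
        factors=pd.Series(factors, index=m.counts.columns, name="tmm_factor"),
        reference_sample=str(m.counts.columns[ref_idx]),
    )


def log_cpm(
    m: BulkCountMatrix, f: NormFactors | None = None, prior: float = 0.5
) -> pd.DataFrame:
    """log2 counts per million on effective library sizes.

    value = log2( (count + prior) / (libsize * factor + 2 * prior) * 1e6 )
    """
    lib = m.library_sizes().to_numpy(dtype=float)
    factors = np.ones_like(lib) if f is None else f.factors.loc[m.sample_ids].to_numpy()
    eff = lib * factors
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    values = m.counts.to_numpy(dtype=float)
    out = np.log2((values + prior) / (eff + 2.0 * prior) * 1e6)
    return pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min_{j >= i} p_(j) * n / j over the ascending sort, clipped at
    1, returned in the original order.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.isnan(arr).any():
        raise ValueError("NaN p-values are not allowed")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = arr.size
    if n == 0:
        return arr.copy()
    order = np.argsort(arr, kind="mergesort")
    scaled = arr[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_log_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior df d0, prior variance s0^2).

    Works on z = log(s^2): under the scaled-F model, E[z] and Var[z] have
    closed forms in digamma/trigamma; the trigamma equation is inverted
    numerically. Genes with zero sample variance are excluded from the
    fit. A non-finite moment estimate (under-dispersed variances) falls
    back to d0 = 10 with a warning.
    """
    pos = s2[s2 > 0]
    if pos.size < 2:
        warnings.warn("too few positive gene variances; using prior df d0=10", stacklevel=3)
        s0_sq = float(np.mean(s2)) if s2.size else 1.0
        return 10.0, max(s0_sq, 1e-12)
    z = np.log(pos)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df_resid / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
    else:
        d0 = np.inf
    if not np.isfinite(d0):
        warnings.warn(
            "moment estimate of the prior df is non-finite; falling back to d0=10",
            stacklevel=3,
        )
        d0 = 10.0
    s0_sq = float(np.exp(
        e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    ))
    return d0, s0_sq


def moderated_de(
    logcpm: pd.DataFrame,
    design: pd.DataFrame,
    contrast: ContrastSpec,
    prior_df: float | None = None,
    fold_change_only: bool = False,
) -> pd.DataFrame:
    """Per-gene moderated two-sample contrast on log-CPM values.

    For each gene the log fold change is the mean difference between the
    two design cells of the contrast; the pooled residual variance s_g^2
    (d_g = n1 + n2 - 2 df) is shrunk toward a common prior,
    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g), with (d0, s0^2)
    estimated by method of moments on log s_g^2. The moderated t is
    logFC / (s~_g sqrt(1/n1 + 1/n2)) on d0 + d_g df, with two-sided
    p-values and a BH-adjusted column appended.

    Parameters
    ----------
    prior_df:
        Override the estimated prior df d0. ``prior_df=0`` gives the
        ordinary pooled-variance two-sample t test.
    fold_change_only:
        Allow design cells with a single replicate; the statistic and
        p-value columns are then NaN.

    Returns a DataFrame indexed by gene with columns
    ``log_fc, t, p_value, adj_p_value, mean_logcpm``.
    """
    design = design.loc[logcpm.columns]
    in_treat = (design["genotype"] == contrast.genotype) & (
        design["treatment"] == contrast.treatment
    )
    in_ref = (design["genotype"] == contrast.genotype) & (
        design["treatment"] == contrast.reference
    )
    n1, n2 = int(in_treat.sum()), int(in_ref.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(
            f"contrast {contrast.name!r}: empty design cell "
            f"({contrast.genotype}/{contrast.treatment}: {n1}, "
            f"{contrast.genotype}/{contrast.reference}: {n2})"
        )
    x1 = logcpm.loc[:, in_treat.to_numpy()].to_numpy()
    x2 = logcpm.loc[:, in_ref.to_numpy()].to_numpy()
    log_fc = x1.mean(axis=1) - x2.mean(axis=1)
    mean_logcpm = np.concatenate([x1, x2], axis=1).mean(axis=1)

    if min(n1, n2) < 2:
        if not fold_change_only:
            raise ValueError(
                f"contrast {contrast.name!r} has a design cell with <2 replicates; "
                "pass fold_change_only=True for a fold-change-only table"
            )
        nan = np.full(log_fc.shape, np.nan)
        return pd.DataFrame(
            {"log_fc": log_fc, "t": nan, "p_value": nan,
             "adj_p_value": nan, "mean_logcpm": mean_logcpm},
            index=logcpm.index,
        )

    df_resid = float(n1 + n2 - 2)
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = (ss1 + ss2) / df_resid

    if prior_df is None:
        d0, s0_sq = _fit_log_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0

    if d0 > 0:
        s2_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    else:
        s2_tilde = s2
        df_total = df_resid

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log_fc / se, 0.0)
    t = np.where((se == 0) & (log_fc == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {"log_fc": log_fc, "t": t, "p_value": p,
         "adj_p_value": bh_adjust(p), "mean_logcpm": mean_logcpm},
        index=logcpm.index,
    )
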