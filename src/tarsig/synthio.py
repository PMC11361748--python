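"""Synthetic data with planted truth for every pipeline stage.

Three generators:

* negative-binomial bulk counts over a two-genotype x two-treatment
  factorial design, with gene classes whose treatment response depends
  on genotype (the structure the DE + partition stages must recover);
* single-cell counts with marker-defined clusters, a keratinocyte
  subpopulation of "stressed" cells whose signature-gene activity
  co-varies with the stress keratins KRT6A/KRT17, and deliberate
  QC-failing cells;
* many-to-many mouse-to-human homolog tables.

All generators are deterministic under their integer seed. Bulk counts
follow the standard RNA-seq parameterization: mean mu, dispersion phi,
variance mu + phi mu^2 (phi = 0 degenerates to Poisson). Library-size
factors are drawn log-uniformly and applied multiplicatively to the
means so that compositional normalization has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .bulkde import BulkCountMatrix

__all__ = [
    "BulkSimParams",
    "ClusterSpec",
    "SCSimParams",
    "SignatureSpec",
    "SynthTruth",
    "generate_bulk_counts",
    "generate_homolog_table",
    "generate_sc_counts",
]

GENE_CLASSES = ("wt_only_up", "shared_up", "ko_only_up", "down")
STRESS_KERATINS = ("KRT6A", "KRT17")


@dataclass(frozen=True)
class SynthTruth:
    """Planted ground truth accompanying a simulated data set."""

    gene_class: dict[str, str] = field(default_factory=dict)
    cell_activity: dict[str, float] = field(default_factory=dict)
    planted_signature: tuple[str, ...] = ()

    def genes_of_class(self, cls: str) -> set[str]:
        return {g for g, c in self.gene_class.items() if c == cls}

    def to_dict(self) -> dict:
        return {
            "gene_class": dict(self.gene_class),
            "cell_activity": dict(self.cell_activity),
            "planted_signature": list(self.planted_signature),
        }


@dataclass(frozen=True)
class BulkSimParams:
    """Parameters of the factorial bulk count simulation.

    ``n_per_class`` may be a single count (used for each planted class)
    or a mapping over ``wt_only_up / shared_up / ko_only_up / down``.
    Effect multipliers are linear fold changes applied to the gene mean
    under treatment in the designated genotype(s): wt_only in WT only,
    ko_only in KO only, shared in both; the ``down`` class is reduced in
    WT only (the mirror of wt_only_up). Remaining genes are null.
    """

    n_genes: int = 2000
    n_reps: int = 3
    baseline_log_mu: float = 4.0
    baseline_log_sigma: float = 1.0
    dispersion: float = 0.1
    effect_wt_only: float = 16.0
    effect_shared: float = 16.0
    effect_ko_only: float = 16.0
    effect_down: float = 1.0 / 16.0
    n_per_class: int | dict[str, int] = 100
    libsize_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def class_sizes(self) -> dict[str, int]:
        if isinstance(self.n_per_class, dict):
            unknown = set(self.n_per_class) - set(GENE_CLASSES)
            if unknown:
                raise ValueError(f"unknown gene classes: {sorted(unknown)}")
            return {c: int(self.n_per_class.get(c, 0)) for c in GENE_CLASSES}
        return {c: int(self.n_per_class) for c in GENE_CLASSES}

    def validate(self) -> None:
        for name in ("effect_wt_only", "effect_shared", "effect_ko_only", "effect_down"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_reps < 1 or self.n_genes < 1:
            raise ValueError("n_genes and n_reps must be >= 1")
        if not (0 < self.libsize_range[0] <= self.libsize_range[1]):
            raise ValueError("libsize_range must be positive and ordered")
        total = sum(self.class_sizes().values())
        if total > self.n_genes:
            raise ValueError(
                f"planted class sizes sum to {total} which exceeds n_genes="
                f"{self.n_genes}"
            )


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, phi) with Var = mu + phi mu^2; phi=0 is Poisson."""
    if phi == 0:
        return rng.poisson(mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_bulk_counts(params: BulkSimParams) -> tuple[BulkCountMatrix, SynthTruth]:
    """Simulate a genotype x treatment bulk count matrix with planted classes."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    sizes = params.class_sizes()

    gene_ids = [f"Gene{i + 1:05d}" for i in range(params.n_genes)]
    gene_class: dict[str, str] = {}
    cursor = 0
    for cls in GENE_CLASSES:
        for _ in range(sizes[cls]):
            gene_class[gene_ids[cursor]] = cls
            cursor += 1
    for g in gene_ids[cursor:]:
        gene_class[g] = "null"

    mu = rng.lognormal(params.baseline_log_mu, params.baseline_log_sigma,
                       size=params.n_genes)

    design_rows = []
    for genotype in ("WT", "KO"):
        for treatment in ("vehicle", "TPA"):
            for rep in range(1, params.n_reps + 1):
                design_rows.append(
                    (f"{genotype}_{treatment}_r{rep}", genotype, treatment, rep)
                )
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "genotype", "treatment", "replicate"]
    ).set_index("sample_id")

    lo, hi = params.libsize_range
    libfac = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(design)))

    effect = {
        "wt_only_up": {"WT": params.effect_wt_only, "KO": 1.0},
        "shared_up": {"WT": params.effect_shared, "KO": params.effect_shared},
        "ko_only_up": {"WT": 1.0, "KO": params.effect_ko_only},
        "down": {"WT": params.effect_down, "KO": 1.0},
        "null": {"WT": 1.0, "KO": 1.0},
    }
    classes = np.array([gene_class[g] for g in gene_ids])

    counts = np.empty((params.n_genes, len(design)), dtype=np.int64)
    for j, (sample, row) in enumerate(design.iterrows()):
        mult = np.ones(params.n_genes)
        if row["treatment"] == "TPA":
            mult = np.array([effect[c][row["genotype"]] for c in classes])
        mean = mu * mult * libfac[j]
        counts[:, j] = _nb_draws(rng, mean, params.dispersion)

    matrix = BulkCountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=design.index),
        design=design,
    )
    return matrix, SynthTruth(gene_class=gene_class)


@dataclass(frozen=True)
class ClusterSpec:
    """One precomputed cluster: its cells, type and planted markers."""

    name: str
    cell_type: str  # KC, Myeloid, TC, Mel or Other
    n_cells: int
    marker_genes: tuple[str, ...]
    marker_fold: float = 8.0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"cluster {self.name!r} needs n_cells >= 1")
        if self.marker_fold <= 0:
            raise ValueError("marker_fold must be > 0")


@dataclass(frozen=True)
class SignatureSpec:
    """Planted signature activity in the keratinocyte compartment.

    A ``stressed_fraction`` of KC cells is flagged stressed and assigned
    a latent activity in [0.6, 1]; the remaining KC cells get a low
    activity in [0, 0.3] and non-KC cells activity 0. Signature-gene
    means scale as ``activity_fold ** activity``; stress-keratin
    (KRT6A/KRT17) means in stressed cells are additionally multiplied by
    ``coupling_fold``, emulating the empirical co-expression of the
    signature with the stress keratins without asserting a mechanism.
    Signature genes get a fixed relative baseline of ``baseline_weight``
    (in units of the median background gene), reflecting genes expressed
    at solid levels in keratinocytes rather than at the detection floor.
    """

    genes: tuple[str, ...]
    stressed_fraction: float = 0.2
    activity_fold: float = 8.0
    coupling_fold: float = 8.0
    baseline_weight: float = 5.0

    def validate(self) -> None:
        if not (0.0 <= self.stressed_fraction <= 1.0):
            raise ValueError("stressed_fraction must lie in [0, 1]")
        if self.activity_fold <= 0 or self.coupling_fold <= 0:
            raise ValueError("folds must be > 0")
        if self.baseline_weight <= 0:
            raise ValueError("baseline_weight must be > 0")


DEFAULT_CLUSTERS: tuple[ClusterSpec, ...] = (
    ClusterSpec("c0", "KC", 800, ("KRT10", "KRT15", "KRT2")),
    ClusterSpec("c1", "Myeloid", 400, ("LYZ",)),
    ClusterSpec("c2", "TC", 400, ("CD3D",)),
    ClusterSpec("c3", "Mel", 400, ("PMEL",)),
)


@dataclass(frozen=True)
class SCSimParams:
    """Parameters of the single-cell count simulation."""

    cluster_spec: tuple[ClusterSpec, ...] = DEFAULT_CLUSTERS
    signature_spec: SignatureSpec = SignatureSpec(
        genes=("ANGPTL4", "IFITM1", "IFI16", "PHLDA2", "KLK1", "PDPN",
               "AKR1B10", "ACAT2", "TUBB6", "OAS1", "HRH2")
    )
    n_background_genes: int = 1500
    depth: float = 5000.0
    dispersion: float = 0.1
    mito_fraction_range: tuple[float, float] = (0.0, 0.10)
    qc_fail_fraction: float = 0.05
    gene_universe: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        self.signature_spec.validate()
        for c in self.cluster_spec:
            c.validate()
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not (0.0 <= self.qc_fail_fraction <= 1.0):
            raise ValueError("qc_fail_fraction must lie in [0, 1]")
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("mito_fraction_range must lie in [0, 1] and be ordered")


def _sc_gene_universe(params: SCSimParams) -> list[str]:
    if params.gene_universe is not None:
        universe = list(dict.fromkeys(params.gene_universe))
        missing = [g for g in params.signature_spec.genes if g not in universe]
        if missing:
            raise ValueError(f"signature genes absent from gene universe: {missing}")
        return universe
    genes: list[str] = [f"BG{i + 1:04d}" for i in range(params.n_background_genes)]
    for spec in params.cluster_spec:
        genes.extend(spec.marker_genes)
    genes.extend(STRESS_KERATINS)
    genes.extend(params.signature_spec.genes)
    return list(dict.fromkeys(genes))


def generate_sc_counts(params: SCSimParams) -> tuple[ad.AnnData, SynthTruth]:
    """Simulate clustered single-cell counts with a planted stressed
    keratinocyte subpopulation.

    Returns an AnnData (cells x genes) whose ``obs`` records the true
    cluster, cell type, stressed flag, latent activity, mito fraction
    and the computed n_features / total_counts, plus the matching truth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    genes = _sc_gene_universe(params)
    gene_index = {g: i for i, g in enumerate(genes)}
    sig = params.signature_spec

    base = rng.lognormal(0.0, 0.8, size=len(genes))
    base[[gene_index[g] for g in sig.genes]] = sig.baseline_weight
    marker_mult = {
        spec.name: np.array(
            [spec.marker_fold if g in spec.marker_genes else 1.0 for g in genes]
        )
        for spec in params.cluster_spec
    }
    sig_idx = np.array([gene_index[g] for g in sig.genes])
    keratin_idx = np.array([gene_index[g] for g in STRESS_KERATINS if g in gene_index])

    rows, cell_ids, obs_rows = [], [], []
    cell_activity: dict[str, float] = {}
    counter = 0
    for spec in params.cluster_spec:
        for _ in range(spec.n_cells):
            counter += 1
            cid = f"cell{counter:05d}"
            stressed = False
            if spec.cell_type == "KC":
                stressed = bool(rng.random() < sig.stressed_fraction)
                activity = rng.uniform(0.6, 1.0) if stressed else rng.uniform(0.0, 0.3)
            else:
                activity = 0.0
            weights = base * marker_mult[spec.name]
            weights = weights.copy()
            weights[sig_idx] *= sig.activity_fold**activity
            if stressed and keratin_idx.size:
                weights[keratin_idx] *= sig.coupling_fold
            probs = weights / weights.sum()
            depth = rng.lognormal(np.log(params.depth), 0.3)
            mean = depth * probs
            if params.dispersion > 0:
                mean = mean * rng.gamma(
                    1.0 / params.dispersion, params.dispersion, size=mean.size
                )
            row = rng.poisson(mean)
            mito = rng.uniform(*params.mito_fraction_range)
            rows.append(row)
            cell_ids.append(cid)
            obs_rows.append(
                {"cluster": spec.name, "cell_type": spec.cell_type,
                 "stressed": stressed, "activity": activity, "mito_frac": mito}
            )
            cell_activity[cid] = float(activity)

    counts = np.vstack(rows)
    obs = pd.DataFrame(obs_rows, index=cell_ids)

    # deliberately QC-failing cells: half get a high mito fraction, half a
    # collapsed library so they fall below the feature floor
    n_cells = counts.shape[0]
    n_fail = int(round(params.qc_fail_fraction * n_cells))
    if n_fail:
        fail_idx = rng.choice(n_cells, size=n_fail, replace=False)
        half = n_fail // 2
        obs.iloc[fail_idx[:half], obs.columns.get_loc("mito_frac")] = rng.uniform(
            0.2, 0.5, size=half
        )
        for i in fail_idx[half:]:
            keep = rng.random(counts.shape[1]) < 0.02
            counts[i] = counts[i] * keep

    obs["n_features"] = (counts > 0).sum(axis=1)
    obs["total_counts"] = counts.sum(axis=1)
    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=genes))
    truth = SynthTruth(cell_activity=cell_activity, planted_signature=tuple(sig.genes))
    return adata, truth


def generate_homolog_table(
    n_mouse: int,
    p_unmapped: float = 0.2,
    p_one_to_many: float = 0.1,
    seed: int = 0,
    mouse_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Two-column mouse-to-human homolog table with controlled gaps.

    Each mouse gene is unmapped with probability ``p_unmapped``;
    otherwise it maps to its upper-cased symbol, and with probability
    ``p_one_to_many`` it additionally maps to a paralog (suffix ``L2``),
    giving a many-to-many structure on the human side.
    """
    for name, p in (("p_unmapped", p_unmapped), ("p_one_to_many", p_one_to_many)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if mouse_genes is None:
        mouse_genes = [f"Gene{i + 1:05d}" for i in range(n_mouse)]
    elif len(mouse_genes) != n_mouse:
        raise ValueError("len(mouse_genes) must equal n_mouse")
    rows = []
    for g in mouse_genes:
        if rng.random() < p_unmapped:
            continue
        rows.append((g, g.upper()))
        if rng.random() < p_one_to_many:
            rows.append((g, f"{g.upper()}L2"))
    return pd.DataFrame(rows, columns=["mouse_symbol", "human_symbol"])
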