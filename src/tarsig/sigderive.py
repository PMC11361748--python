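"""Genotype-dependent gene-set derivation and cross-species mapping.

Turns two genotype-specific differential-expression tables (wild type
and knockout, each treatment vs vehicle) into the knockout-dependent
gene partition — genes called up in WT only, in KO only, or in both —
and maps a mouse gene set to human symbols through a two-column
homology table, with a mapping report mirroring how such counts are
reported (n input, n with at least one homolog, n unique human genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GenePartition",
    "MappingReport",
    "call_regulated",
    "load_homolog_table",
    "map_homologs",
    "partition_by_genotype",
]


@dataclass(frozen=True)
class GenePartition:
    """Disjoint sets from two marginal DE calls over one gene universe."""

    wt_only_up: frozenset[str]
    ko_only_up: frozenset[str]
    shared_up: frozenset[str]
    wt_only_down: frozenset[str] = frozenset()
    ko_only_down: frozenset[str] = frozenset()
    shared_down: frozenset[str] = frozenset()
    fc_threshold: float = 8.0
    adjp_threshold: float = 0.01

    def counts(self) -> dict[str, int]:
        return {
            "wt_only_up": len(self.wt_only_up),
            "ko_only_up": len(self.ko_only_up),
            "shared_up": len(self.shared_up),
            "wt_only_down": len(self.wt_only_down),
            "ko_only_down": len(self.ko_only_down),
            "shared_down": len(self.shared_down),
        }

    def to_dict(self) -> dict:
        d: dict = {k: sorted(getattr(self, k)) for k in (
            "wt_only_up", "ko_only_up", "shared_up",
            "wt_only_down", "ko_only_down", "shared_down")}
        d["thresholds"] = {"fc": self.fc_threshold, "adj_p": self.adjp_threshold}
        d["counts"] = self.counts()
        return d


@dataclass(frozen=True)
class MappingReport:
    n_input: int
    n_mapped: int
    n_unique_human: int
    unmapped: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_mapped": self.n_mapped,
            "n_unique_human": self.n_unique_human,
            "unmapped": list(self.unmapped),
        }


def call_regulated(
    de: pd.DataFrame,
    fc_threshold: float = 8.0,
    adjp_threshold: float = 0.01,
    direction: str = "up",
) -> set[str]:
    """Genes passing the linear fold-change and FDR cutoffs.

    ``up``: 2**log_fc strictly greater than ``fc_threshold`` and adjusted
    p strictly below ``adjp_threshold``; ``down`` mirrors the rule with
    2**(-log_fc). A linear fold change of exactly the threshold is
    excluded (strict inequality).
    """
    if fc_threshold <= 0 or adjp_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if de.empty:
        return set()
    lin_fc = 2.0 ** de["log_fc"] if direction == "up" else 2.0 ** (-de["log_fc"])
    mask = (lin_fc > fc_threshold) & (de["adj_p_value"] < adjp_threshold)
    return set(de.index[mask])


def partition_by_genotype(
    up_wt: set[str],
    up_ko: set[str],
    down_wt: set[str] | None = None,
    down_ko: set[str] | None = None,
    fc_threshold: float = 8.0,
    adjp_threshold: float = 0.01,
) -> GenePartition:
    """Venn partition of the two genotypes' regulated-gene calls."""
    down_wt = down_wt or set()
    down_ko = down_ko or set()
    return GenePartition(
        wt_only_up=frozenset(up_wt - up_ko),
        ko_only_up=frozenset(up_ko - up_wt),
        shared_up=frozenset(up_wt & up_ko),
        wt_only_down=frozenset(down_wt - down_ko),
        ko_only_down=frozenset(down_ko - down_wt),
        shared_down=frozenset(down_wt & down_ko),
        fc_threshold=fc_threshold,
        adjp_threshold=adjp_threshold,
    )


def load_homolog_table(path) -> pd.DataFrame:
    """Read and validate a two-column (mouse, human) homology TSV.

    The first two columns are used regardless of header names; symbols
    are whitespace-stripped and compared case-sensitively. Empty symbols
    and exact duplicate rows are rejected with the offending line
    numbers.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ValueError("homolog table needs two columns (mouse, human)")
    table = table.iloc[:, :2].copy()
    table.columns = ["mouse_symbol", "human_symbol"]
    return validate_homolog_table(table)


def validate_homolog_table(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    for col in ("mouse_symbol", "human_symbol"):
        table[col] = table[col].astype(str).str.strip()
    bad = table.index[
        (table["mouse_symbol"] == "") | (table["human_symbol"] == "")
        | table["mouse_symbol"].isin(("nan", "None"))
        | table["human_symbol"].isin(("nan", "None"))
    ]
    if len(bad):
        raise ValueError(f"empty symbols in homolog table rows: {list(bad[:10])}")
    dup = table.index[table.duplicated()]
    if len(dup):
        raise ValueError(f"exact duplicate homolog rows: {list(dup[:10])}")
    return table


def map_homologs(
    genes: set[str], table: pd.DataFrame
) -> tuple[set[str], MappingReport]:
    """Union of human homologs of a mouse gene set, with a report.

    Many-to-many tables are supported: a mouse gene with several human
    homologs contributes all of them, and the human output is
    deduplicated. ``n_mapped`` counts input genes with at least one
    homolog; ``n_unique_human`` the distinct human symbols emitted.
    """
    table = validate_homolog_table(table)
    genes = {str(g).strip() for g in genes}
    hit = table[table["mouse_symbol"].isin(genes)]
    human = set(hit["human_symbol"])
    mapped = set(hit["mouse_symbol"])
    unmapped = tuple(sorted(genes - mapped))
    report = MappingReport(
        n_input=len(genes),
        n_mapped=len(mapped),
        n_unique_human=len(human),
        unmapped=unmapped,
    )
    return human, report
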