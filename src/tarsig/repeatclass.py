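"""Single- versus repeated-stimulation response classification.

Signature genes are classified by comparing their bulk fold changes
after a single irritant application with those after a repeated
(double) application:

* ``double_only`` — significant after the double treatment but not after
  the single one (or not detected in the single-treatment data set);
* ``greater_after_double`` — significant after both, with the double
  fold change at least ``ratio_threshold`` times the single one;
* ``similar`` — significant after both with a smaller ratio;
* ``single_dominant`` — significant only after the single treatment;
* ``undetected`` — significant after neither.

The union of the first two categories is the "repeat-associated" set —
genes tied to the skin's response to repeated inflammatory stress.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FoldChangeRecord",
    "RepeatClassification",
    "TAR11_MOUSE_HOMOLOGS",
    "classify_repeat_response",
    "load_fold_change_table",
    "load_tar11_fold_changes",
]

#: Human TAR11 symbol -> mouse homolog assayed in the bulk data sets.
TAR11_MOUSE_HOMOLOGS: dict[str, str] = {
    "ANGPTL4": "Angptl4",
    "IFITM1": "Ifitm1",
    "IFI16": "Ifi209",
    "PHLDA2": "Phlda2",
    "KLK1": "Klk1",
    "PDPN": "Pdpn",
    "AKR1B10": "Akr1b8",
    "ACAT2": "Acat2",
    "TUBB6": "Tubb6",
    "OAS1": "Oas1a",
    "HRH2": "Hrh2",
}

CATEGORIES = (
    "double_only", "greater_after_double", "similar", "single_dominant", "undetected",
)


@dataclass(frozen=True)
class FoldChangeRecord:
    """Linear fold changes and significance flags for one gene.

    ``fc_single`` is ``None`` when the gene was not detected in the
    single-treatment data set; detected fold changes must be positive.
    """

    gene: str
    fc_single: float | None
    sig_single: bool
    fc_double: float | None
    sig_double: bool

    def __post_init__(self) -> None:
        for name, fc in (("fc_single", self.fc_single), ("fc_double", self.fc_double)):
            if fc is not None and fc <= 0:
                raise ValueError(f"{self.gene}: {name} must be > 0 when detected")


@dataclass(frozen=True)
class RepeatClassification:
    categories: dict[str, str]
    ratio_threshold: float

    @property
    def repeat_associated(self) -> set[str]:
        return {
            g for g, c in self.categories.items()
            if c in ("double_only", "greater_after_double")
        }

    def to_dict(self) -> dict:
        return {
            "ratio_threshold": self.ratio_threshold,
            "categories": dict(self.categories),
            "repeat_associated": sorted(self.repeat_associated),
        }


def classify_repeat_response(
    records: list[FoldChangeRecord], ratio_threshold: float = 2.0
) -> RepeatClassification:
    """Classify every record into exactly one response category.

    A gene not detected after the single treatment is treated as not
    significant there, so it lands in ``double_only`` when the double
    response is significant. A fold-change ratio exactly at the
    threshold counts as ``greater_after_double`` (>=).
    """
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be > 0")
    seen: set[str] = set()
    categories: dict[str, str] = {}
    for rec in records:
        if rec.gene in seen:
            raise ValueError(f"duplicate gene row: {rec.gene!r}")
        seen.add(rec.gene)
        sig_single = rec.sig_single and rec.fc_single is not None
        if rec.sig_double and not sig_single:
            cat = "double_only"
        elif rec.sig_double and sig_single:
            assert rec.fc_double is not None and rec.fc_single is not None
            ratio = rec.fc_double / rec.fc_single
            cat = "greater_after_double" if ratio >= ratio_threshold else "similar"
        elif sig_single and not rec.sig_double:
            cat = "single_dominant"
        else:
            cat = "undetected"
        categories[rec.gene] = cat
    return RepeatClassification(categories=categories, ratio_threshold=ratio_threshold)


def load_fold_change_table(path_or_buffer) -> list[FoldChangeRecord]:
    """Read a fold-change TSV (gene, fc_single, sig_single, fc_double,
    sig_double; "NA" marks an undetected fold change)."""
    table = pd.read_csv(path_or_buffer, sep="\t", na_values=["NA"])
    required = {"gene", "fc_single", "sig_single", "fc_double", "sig_double"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"fold-change table lacks columns: {sorted(missing)}")

    def _bool(x) -> bool:
        if isinstance(x, str):
            return x.strip().lower() in ("true", "1", "yes")
        return bool(x)

    records = []
    for _, row in table.iterrows():
        records.append(
            FoldChangeRecord(
                gene=str(row["gene"]).strip(),
                fc_single=None if pd.isna(row["fc_single"]) else float(row["fc_single"]),
                sig_single=_bool(row["sig_single"]),
                fc_double=None if pd.isna(row["fc_double"]) else float(row["fc_double"]),
                sig_double=_bool(row["sig_double"]),
            )
        )
    return records


def load_tar11_fold_changes() -> list[FoldChangeRecord]:
    """Bundled single- vs double-treatment fold changes for the 11 mouse
    homologs of the TAR11 signature.

    Synthetic transcription: the qualitative pattern per gene (which
    responses were significant, and whether the double response was
    notably greater) follows the published description; the numeric
    fold-change magnitudes are invented placeholders consistent with
    that pattern.
    """
    path = resources.files("tarsig.data").joinpath(
        "tar11_single_vs_double_synthetic.tsv"
    )
    with path.open("r") as fh:
        return load_fold_change_table(fh)
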