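import numpy as np
import pandas as pd
import pytest

import tarsig
from tarsig import scscore


def make_design(n_reps: int = 3) -> pd.DataFrame:
    rows = []
    for genotype in ("WT", "KO"):
        for treatment in ("vehicle", "TPA"):
            for rep in range(1, n_reps + 1):
                rows.append((f"{genotype}_{treatment}_r{rep}", genotype, treatment, rep))
    return pd.DataFrame(
        rows, columns=["sample_id", "genotype", "treatment", "replicate"]
    ).set_index("sample_id")


@pytest.fixture(scope="session")
def recovery_sim():
    """One bulk simulation at the planted-recovery settings."""
    params = tarsig.BulkSimParams(seed=11)
    return tarsig.generate_bulk_counts(params)


@pytest.fixture(scope="session")
def sc_sim():
    """One single-cell simulation at default (planted-signature) settings."""
    return tarsig.generate_sc_counts(tarsig.SCSimParams(seed=11))


@pytest.fixture(scope="session")
def sc_scored(sc_sim):
    """QC-filtered, normalized expression plus composite scores for sc_sim."""
    adata, truth = sc_sim
    filtered, _ = scscore.qc_filter(adata, scscore.PSOR_QC)
    logexpr = scscore.normalize_log(filtered)
    scores = scscore.composite_score(logexpr, scscore.TAR11)
    return filtered, logexpr, scores, truth
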