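import numpy as np
import pandas as pd
import pytest

from mei import (
    MatchedCounts,
    default_cohort_config,
    gene_model_from_exons,
    simulate_counts,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200924)


@pytest.fixture()
def three_exon_gene():
    # merged exons [99,300) and [399,500); one intron [300,399)
    return gene_model_from_exons(
        "GENE1", "chr1", "+", [(99, 200), (149, 300), (399, 500)]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """240-gene cohort, 8 vs 8, with all four truth classes and spike-ins."""
    cfg = default_cohort_config(
        seed=42, n_control=8, n_case=8, n_genes=240, scale_log_sd=0.1
    )
    return simulate_counts(cfg)


def toy_matched(exon_rows: dict, intron_rows: dict, samples=None) -> MatchedCounts:
    genes = list(exon_rows)
    samples = samples or [f"s{i}" for i in range(len(next(iter(exon_rows.values()))))]
    exon = pd.DataFrame.from_dict(exon_rows, orient="index", columns=samples)
    intron = pd.DataFrame.from_dict(intron_rows, orient="index", columns=samples)
    return MatchedCounts(exon=exon.loc[genes], intron=intron.loc[genes])
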