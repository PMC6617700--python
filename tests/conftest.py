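"""Shared fixtures: the bundled VAMP2-like fixture and session-scoped
synthetic datasets (generated once, reused across test modules)."""

from __future__ import annotations

import warnings
from importlib import resources

import pytest

from codonshift import (
    CohortSpec,
    GenomeSpec,
    composition_table,
    generate_cds_set,
    generate_cohort,
    parse_cds,
)

# synthetic-data warnings (gene-universe mismatches etc.) are not under test
warnings.filterwarnings("ignore", message=".*composition genes absent.*")


@pytest.fixture(scope="session")
def vamp2_path(tmp_path_factory):
    ref = resources.files("codonshift") / "data" / "vamp2_synthetic.fa"
    with resources.as_file(ref) as p:
        out = tmp_path_factory.mktemp("data") / "vamp2_synthetic.fa"
        out.write_bytes(p.read_bytes())
    return out


@pytest.fixture(scope="session")
def vamp2_seq(vamp2_path):
    return parse_cds(str(vamp2_path)).records[0]


@pytest.fixture(scope="session")
def small_genome():
    """400-gene genome for cheap unit tests."""
    seqs, truth = generate_cds_set(GenomeSpec(n_genes=400, seed=11))
    return seqs, truth


@pytest.fixture(scope="session")
def small_comp(small_genome):
    seqs, _ = small_genome
    return composition_table(seqs)


@pytest.fixture(scope="session")
def default_genome():
    """Genome at the generator's default study conditions."""
    seqs, truth = generate_cds_set(GenomeSpec(seed=1))
    return seqs, truth


@pytest.fixture(scope="session")
def default_comp(default_genome):
    seqs, _ = default_genome
    return composition_table(seqs)


@pytest.fixture(scope="session")
def strong_cohort(default_genome):
    """Strong-effect control/disease cohort on the default genome."""
    _, truth = default_genome
    abundance, cohort_truth = generate_cohort(truth, CohortSpec(seed=2))
    return abundance, cohort_truth
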