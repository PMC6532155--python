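import numpy as np
import pytest

from snppanel import (
    CandidateSnp,
    DesignConfig,
    GenomeLayout,
    Group,
    Priority,
    SimConfig,
    SnpLocus,
    design_panel,
    make_design_fixture,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_genome():
    return GenomeLayout((("1", 500_000), ("2", 300_000)))


@pytest.fixture
def design_config():
    return DesignConfig()


def make_snp(chrom="1", pos=100, group=Group.GWAS, priority=Priority.P1, **kw):
    locus = SnpLocus(chrom, pos, "A", "G", f"{chrom}_{pos}")
    return CandidateSnp(locus=locus, group=group, priority=priority, **kw)


@pytest.fixture
def fixture_panel():
    """A designed panel on the default synthetic fixture."""
    cfg = SimConfig(seed=11)
    genome, candidates, snpdb = make_design_fixture(cfg)
    panel, ledgers = design_panel(genome, candidates + snpdb)
    return panel, ledgers
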