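import numpy as np
import pytest

from ampseq import (
    FamilyConfig,
    LocusSpec,
    SnpSite,
    attach_linkers,
    curate_panel,
    design_primer_pair,
    make_template,
    simulate_family,
    simulate_gbs_stack,
)
from ampseq.haploblock import LdRecord


@pytest.fixture(scope="session")
def family_truth():
    """A 100-progeny pseudo-testcross family with one quantitative locus."""
    positions = list(np.linspace(50_000, 1_950_000, 12).astype(int))
    cfg = FamilyConfig(
        n_progeny=100,
        marker_positions=positions,
        loci=[LocusSpec(pos=1_000_000, qtl_r2=0.54)],
        seed=3,
    )
    return simulate_family(cfg)


def build_panel(truth, seed_offset: int = 0):
    """Design a curated panel over the truth's marker sites from simulated
    error-free GBS stacks."""
    pairs = []
    for site in truth.genotypes.sites:
        stack = simulate_gbs_stack(
            site, {site.ref_allele: 12, site.alt_allele: 10}, seed=site.pos + seed_offset
        )
        tpl = make_template(site, stack.reads, ld=LdRecord(site, 1.0, 1e-40, 100))
        pairs.append(attach_linkers(design_primer_pair(tpl)))
    return curate_panel(pairs, trait="sim")


@pytest.fixture(scope="session")
def sim_panel(family_truth):
    return build_panel(family_truth)


@pytest.fixture
def toy_site():
    return SnpSite("chr2", 5_186_869, "G", "T")
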