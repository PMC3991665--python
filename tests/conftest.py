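"""Shared fixtures: one moderately sized simulated experiment per session.

The simulation plants 8 miRNA hairpins (half entered in the known
reference), 2 decoy loci per ncRNA/gene class, 2% contaminants per
cleaning class and two planted fold changes, at 12,000 reads per
library — small enough to run in seconds, large enough that every
pipeline stage has work to do.
"""

import pytest

from mirseed import annotation, cleaning
from mirseed.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def sim():
    config = SimulationConfig(
        n_planted_mirnas=8,
        n_decoy_loci=2,
        read_depth=12_000,
        seed=11,
        de_spec={"mir-0": 4.0, "mir-1": 0.25},
    )
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def cleaned(sim):
    """(survivors, report) per library for the session simulation."""
    cfg = sim.config
    ctrl = cleaning.clean_reads(sim.reads_control, cfg.adapter_5p, cfg.adapter_3p)
    trt = cleaning.clean_reads(sim.reads_treatment, cfg.adapter_5p, cfg.adapter_3p)
    return {"control": ctrl, "treatment": trt}


@pytest.fixture(scope="session")
def tags(cleaned):
    return cleaning.collapse_unique(cleaned["control"][0], cleaned["treatment"][0])


@pytest.fixture(scope="session")
def annotated(sim, tags):
    """(records, hits, high_copy) for the session simulation."""
    return annotation.annotate(
        tags,
        sim.genome,
        mature_ref=sim.mature_ref,
        ncrna_refs=sim.ncrna_refs,
        gene_features=sim.gene_features,
    )
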