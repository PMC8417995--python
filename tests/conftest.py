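import pytest

from lncscape import simulate as sim
from lncscape.pipeline import run_annotation, run_identification
from lncscape.types import TranscriptModel

SIM_SEED = 1


@pytest.fixture(scope="session")
def simulation():
    """Default-condition simulation shared across closure tests."""
    return sim.simulate(seed=SIM_SEED)


@pytest.fixture(scope="session")
def identification(simulation):
    res = simulation
    return run_identification(
        res.assembly.transcripts,
        res.reference,
        res.genome,
        res.expression,
        res.assembly.organelle_bed,
        res.assembly.ncrna_bed,
        res.assembly.sim_hits,
        res.assembly.domain_hits,
        seed=SIM_SEED,
        canonical_id=lambda tid: tid.split("|")[0],
    )


@pytest.fixture(scope="session")
def lnc_models(simulation):
    """TranscriptModels of the planted true lncRNAs, keyed by base id."""
    geoms = {}
    for t in simulation.assembly.transcripts:
        base = t.transcript_id.split("|")[0]
        geoms.setdefault(
            base, TranscriptModel(base, base, t.chrom, t.strand, t.exons)
        )
    return [geoms[b] for b in sorted(simulation.truth.expected_lncrnas())]


@pytest.fixture(scope="session")
def annotation(simulation, lnc_models):
    return run_annotation(
        lnc_models,
        simulation.reference,
        simulation.expression,
        simulation.go_annotation,
        seed=SIM_SEED,
    )
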