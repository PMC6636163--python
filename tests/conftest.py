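import warnings

import pytest
from hypothesis import HealthCheck, settings

import teretain as tr
from teretain.gene_orthology import build_proteome

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=DeprecationWarning)


SMALL_SIM = tr.SimulationConfig(
    seed=7,
    n_scaffolds=2,
    scaffold_length=150_000,
    n_genes=24,
    n_ancestral_tes=120,
    n_new_insertions=8,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated genome pair with truth table."""
    ancestor, library = tr.simulate_ancestor(SMALL_SIM)
    genome_a, genome_b, truth = tr.evolve_pair(ancestor, library, SMALL_SIM)
    return {
        "config": SMALL_SIM,
        "ancestor": ancestor,
        "library": library,
        "genome_a": genome_a,
        "genome_b": genome_b,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_pairwise(small_sim):
    """Gene orthology map + both-direction TE orthology calls for small_sim."""
    m = tr.rbh_ortholog_map(
        build_proteome(small_sim["genome_a"]), build_proteome(small_sim["genome_b"])
    )
    result = tr.run_pairwise(small_sim["genome_a"], small_sim["genome_b"], m)
    return {"map": m, "result": result, **small_sim}
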