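import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import crossmut as cm

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def default_filters() -> cm.FilterConfig:
    return cm.FilterConfig()


@pytest.fixture(scope="session")
def small_experiment() -> cm.Experiment:
    """A compact six-line experiment with elevated background density so every
    stage has material to work on at test scale (~250 kb assembly)."""
    config = cm.SimulationConfig(
        seed=42,
        n_contigs=30,
        contig_length_median=6000,
        contig_length_sigma=0.5,
        causal_length=8000,
        n_mutants=6,
        background_density=1 / 40_000,
        coverage_lambda=30.0,
    )
    return cm.simulate(config)


@pytest.fixture(scope="session")
def small_experiment_dir(tmp_path_factory) -> tuple:
    """The same kind of experiment written to disk, plus contaminant and
    artifact scenarios, for pipeline/CLI tests."""
    config = cm.SimulationConfig(
        seed=99,
        n_contigs=25,
        contig_length_median=8000,
        contig_length_sigma=0.4,
        causal_length=6000,
        n_mutants=5,
        background_density=1 / 100_000,
        contaminant=True,
        artifact_contig=True,
    )
    out = tmp_path_factory.mktemp("experiment")
    cm.simulate_experiment(config, out)
    return config, out


def random_callsets(rng: np.random.Generator, n_mutants: int, contig_ids,
                    max_calls: int = 30) -> list:
    """Random call sets over the given contigs (shared positions likely)."""
    callsets = []
    for m in range(n_mutants):
        mutant_id = f"m{m}"
        n_calls = int(rng.integers(0, max_calls))
        seen = set()
        calls = []
        for _ in range(n_calls):
            cid = contig_ids[int(rng.integers(len(contig_ids)))]
            pos = int(rng.integers(1, 50))
            if (cid, pos) in seen:
                continue
            seen.add((cid, pos))
            ref, alt = ("G", "A") if rng.random() < 0.5 else ("C", "T")
            calls.append(cm.SnvCall(mutant_id, cid, pos, ref, alt, 1.0, 30, True))
        calls.sort(key=lambda s: (s.contig_id, s.position))
        callsets.append(cm.MutantCallSet(mutant_id, calls, 100_000))
    return callsets
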