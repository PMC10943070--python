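import numpy as np
import pandas as pd
import pytest

from desmoprox.quant_io import IntensityMatrix, filter_contaminants, median_center
from desmoprox.scoring import ScoringParams, score_experiment
from desmoprox.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """One study-scale synthetic experiment (shared; treat as read-only)."""
    return simulate_experiment(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def scored_experiment(default_experiment):
    """The same experiment preprocessed and scored end to end."""
    matrix, design, truth = default_experiment
    matrix = median_center(filter_contaminants(matrix))
    scores = score_experiment(matrix, design, ScoringParams())
    return scores, design, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240210)


def random_scores(rng, n_preys=40, baits=("Dsc2a", "PG-N", "PG-C", "Pkp2a"),
                  conditions=("ca_dependent", "hyper_adhesive"), p_sig=0.25):
    """Random scored-interaction table: every prey present in every dataset,
    significance drawn i.i.d.; preys with no significant call occur naturally."""
    rows = []
    for prey in [f"P{i:03d}" for i in range(n_preys)]:
        for bait in baits:
            for condition in conditions:
                sig = rng.random() < p_sig
                bfdr = rng.uniform(0.0, 0.05) if sig else rng.uniform(0.051, 1.0)
                rows.append(
                    dict(bait=bait, condition=condition, prey=prey,
                         avg_p=1.0 - bfdr, bfdr=bfdr,
                         log2fc=rng.normal(2.0, 1.0), significant=sig)
                )
    return pd.DataFrame(rows)


def toy_matrix(values, proteins=None, samples=None, provenance="raw"):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"prot{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return IntensityMatrix(pd.DataFrame(values, index=proteins, columns=samples), provenance)
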