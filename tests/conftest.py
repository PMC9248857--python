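import numpy as np
import pandas as pd
import pytest

from organsort.pipeline import PipelineConfig, run_all
from organsort.quantio import quant_table_from_frame
from organsort.synthetic_data import GeneratorConfig, simulate_experiment

ORGS = ("PM", "ER", "Endosome", "Lysosome", "Golgi", "Mito")


def make_quant_frame(values: dict[str, np.ndarray]) -> pd.DataFrame:
    """Toy quantification frame: protein_id -> 36-entry array ordered by
    (organelle, condition, replicate)."""
    cols = [
        f"{o}_{c}_R{r}" for o in ORGS for c in ("parental", "KO") for r in (1, 2, 3)
    ]
    rows = []
    for pid, arr in values.items():
        rows.append([pid] + list(np.asarray(arr, dtype=float)))
    return pd.DataFrame(rows, columns=["protein_id"] + cols)


def profile_to_entries(profile, scale=1000.0, jitter=None, rng=None):
    """Expand a 6-organelle profile into 36 entries (2 conditions x 3 reps)."""
    profile = np.asarray(profile, dtype=float)
    out = []
    for o in range(6):
        for _c in range(2):
            for _r in range(3):
                v = profile[o] * scale
                if jitter is not None:
                    v *= float(np.exp(rng.normal(0.0, jitter)))
                out.append(v)
    return np.array(out)


@pytest.fixture(scope="session")
def small_experiment():
    """Mid-sized simulated experiment shared across module tests."""
    return simulate_experiment(GeneratorConfig(n_proteins=800, seed=11))


@pytest.fixture(scope="session")
def small_quant(small_experiment):
    return quant_table_from_frame(small_experiment.quant)


@pytest.fixture(scope="session")
def small_pipeline_runs():
    """Two end-to-end pipeline runs with one config (determinism checks)."""
    def run_once():
        cfg = PipelineConfig(
            seed=5,
            simulate=GeneratorConfig(n_proteins=500, seed=5),
            grid_preset="coarse",
            kmax=22,
        )
        return run_all(cfg)

    return run_once(), run_once()
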