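import numpy as np
import pytest

from iggfc.panel import build_panel
from iggfc.simulate import CohortConfig, RunConfig, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return build_panel()


@pytest.fixture(scope="session")
def clean_truth(panel):
    """Small cohort without batch effects or run distortions."""
    cfg = CohortConfig(n_individuals=4, n_families=2, batch_sd=0.0,
                       calib_offset_sd=0.0, rt_shift_sd=0.0, seed=11)
    cohort, truth = simulate_cohort(cfg, panel)
    return cohort, truth


@pytest.fixture(scope="session")
def noiseless_run(panel, clean_truth):
    from iggfc.simulate import simulate_run
    _, truth = clean_truth
    return truth, simulate_run(truth, "S00000", panel, RunConfig().noiseless())


def random_feasible_traits(rng, subclass="IgG1"):
    """Draw one feasible trait-target vector (percent scale)."""
    f = rng.uniform(60, 99.5) if subclass != "IgG4" else None
    cap = (f if f is not None else 100.0)
    b = rng.uniform(1, min(30, cap - 10))
    gal = rng.uniform(1, cap - b - 1)
    sia = rng.uniform(0, min(gal, (cap - b) / 2 - 0.5))
    t = {"bisection": b, "galactosylation": gal, "sialylation": max(sia, 0.0)}
    if f is not None:
        t["fucosylation"] = f
    return t
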