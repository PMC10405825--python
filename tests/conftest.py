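import numpy as np
import pytest

from enmpipe.geodata import EnvStack, Grid, OccurrenceSet, clean_occurrences
from enmpipe import synthetic


def make_grid(values, x_min=0.0, y_min=0.0, cell_size=1.0, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    return Grid(values.shape[0], values.shape[1], x_min, y_min, cell_size,
                nodata, values)


@pytest.fixture
def small_grid():
    return make_grid([[1.0, 2.0], [3.0, np.nan]])


@pytest.fixture(scope="session")
def study_system():
    """Synthetic stack + logistic truth + cleaned occurrences, session-wide.

    Low-prevalence truth (intercept -6) driven by two of four uncorrelated
    variables, so the maxent family contains the generating density.
    """
    cfg = synthetic.SyntheticConfig(
        n_rows=60, n_cols=60, n_vars=4, target_correlation=np.eye(4),
        true_coefficients={"bio01": 1.5, "bio02": -1.0}, intercept=-6.0,
        n_presences=300, noise_fraction=0.0, seed=11)
    stack = synthetic.make_env_stack(cfg)
    truth = synthetic.true_suitability(stack, cfg.true_coefficients, cfg.intercept)
    occ_raw = synthetic.sample_occurrences(truth, cfg.n_presences, seed=12)
    occ = clean_occurrences(occ_raw, stack.grid)
    return {"config": cfg, "stack": stack, "truth": truth,
            "occ_raw": occ_raw, "occ": occ}
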