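import numpy as np
import pytest

import dnjquant as dq
from dnjquant import ipls, validation


def noiseless_max_absorbance() -> float:
    """Peak absorbance of the default mixture with all noise terms off,
    used to express noise levels as a fraction of the signal."""
    cfg = dq.SimulationConfig(
        n_products=5, noise_sd=0.0, baseline_amplitude=0.0, scatter_sd=0.0, seed=0
    )
    return float(dq.generate_dataset(cfg).absorbance.max())


@pytest.fixture(scope="session")
def recovery_run():
    """Full pipeline on the parameter-recovery dataset: 60 products in
    triplicate on the 750-4000 cm^-1 grid, additive noise at 0.5% of the
    maximum mixture absorbance, forward iPLS selection.

    Shared session-wide because the forward search is the expensive part
    of the suite.
    """
    noise = 0.005 * noiseless_max_absorbance()
    cfg = dq.SimulationConfig(n_products=60, noise_sd=noise, seed=123)
    ds = dq.generate_dataset(cfg)
    prep = dq.preprocess_pipeline(ds)
    split = dq.kennard_stone(prep.X, dq.default_n_cal(prep.n_samples), ids=prep.sample_ids)
    cal = prep.select(split.calibration_ids)
    test = prep.select(split.test_ids)
    selection, model, history = ipls.forward_ipls(cal.X, cal.y, prep.wavenumbers)
    report = validation.evaluate(model, cal.X, cal.y, test.X, test.y)
    return {
        "dataset": ds,
        "prep": prep,
        "split": split,
        "cal": cal,
        "test": test,
        "selection": selection,
        "model": model,
        "history": history,
        "report": report,
    }
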