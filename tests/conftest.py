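import numpy as np
import pytest

from woundkit.chart import ChartSpec, render_chart


@pytest.fixture(scope="session")
def spec():
    return ChartSpec()


@pytest.fixture(scope="session")
def chart10(spec):
    """Default chart rendered at 10 px/mm with exact ground truth."""
    return render_chart(spec, 10.0)


@pytest.fixture(scope="session")
def gray10(chart10):
    img, _ = chart10
    return img.astype(float) @ np.array([0.299, 0.587, 0.114])


@pytest.fixture(scope="session")
def recovery_run():
    """One scaled-down segmentation recovery run shared by the training
    tests and the model-recovery acceptance check (training is the
    expensive step; the recipe is fixed, so sharing changes nothing)."""
    from woundkit.experiments import run_recovery
    return run_recovery(seed=0, n_scenes=16, epochs=15)


@pytest.fixture(scope="session")
def converged_run():
    """A longer run of the same recipe for properties that presume a
    well-converged model (flip augmentation consistency)."""
    from woundkit.experiments import run_recovery
    return run_recovery(seed=0, n_scenes=16, epochs=40)
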