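import numpy as np
import pytest

import optircb


@pytest.fixture(scope="session")
def default_model():
    """Absorption model trained on the default 640-phantom set.

    Session-scoped: the default fit (10,000 gradient-descent iterations,
    5-fold CV, one polynomial per detector position) is shared by every
    test that needs a realistic trained model.
    """
    phantoms = optircb.generate_phantom_dataset(seed=1)
    return optircb.fit_polynomial_model(phantoms)


@pytest.fixture(scope="session")
def heldout_phantoms():
    """Phantom set disjoint (by seed) from the training set."""
    return optircb.generate_phantom_dataset(n_phantoms=200, seed=99)


@pytest.fixture()
def geometry():
    return optircb.ProbeGeometry()


def make_curve(values, *, side="healthy", eled=1, patient=0, slice_id=0, treatment=0):
    return optircb.AbsorptionCurve(
        values=np.asarray(values, dtype=float),
        patient_id=patient,
        side=side,
        slice_id=slice_id,
        treatment_id=treatment,
        eled=eled,
    )
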