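import numpy as np
import pandas as pd
import pytest

from deltarad.core import SUBTYPES
from deltarad.features import all_feature_names
from deltarad.phantom import PhantomParams, generate_lesion


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, texture-free phantom parameters (closed-form checks)."""
    return PhantomParams(
        seed=11,
        noise_sd=0.0,
        texture_amplitude=0.0,
        background_texture_amplitude=0.0,
        scale_jitter=0.0,
    )


@pytest.fixture(scope="session")
def textured_lesion():
    """A realistic textured non-responder lesion shared across tests."""
    return generate_lesion(PhantomParams(seed=5), "no-pCR")


@pytest.fixture(scope="session")
def responder_lesion():
    return generate_lesion(PhantomParams(seed=6), "pCR")


def make_feature_table(
    n=60, n_pcr=20, n_signal=6, effect=1.5, seed=0, with_split=False
) -> pd.DataFrame:
    """Synthetic cohort table: 255 canonical columns, a few informative."""
    rng = np.random.default_rng(seed)
    names = all_feature_names()
    X = rng.standard_normal((n, len(names)))
    labels = np.array(["pCR"] * n_pcr + ["no-pCR"] * (n - n_pcr))
    rng.shuffle(labels)
    X[:, :n_signal] += effect * (labels == "pCR").astype(float)[:, None]
    df = pd.DataFrame(X, columns=names)
    df["label"] = labels
    df["subtype"] = rng.choice(SUBTYPES, n)
    if with_split:
        from deltarad.modeling import split_cohort

        df = split_cohort(df, seed=seed)
    return df


@pytest.fixture(scope="session")
def signal_table():
    """Cohort with a clearly separable class signal on six features."""
    return make_feature_table(n=60, n_pcr=20, effect=2.5, seed=1, with_split=True)
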