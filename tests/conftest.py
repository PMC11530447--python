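import numpy as np
import pytest

from audsync.synth import AudienceSpec, generate_audience


@pytest.fixture(scope="session")
def small_audience():
    """8 + 8 subjects, 600 s, moderate shared loading (seeded)."""
    spec = AudienceSpec(
        n_subjects_per_group=8,
        duration_s=600,
        shared_loading=0.6,
        modality_loading=0.6,
        ar_coef=0.5,
        noise_sd=1.0,
        seed=7,
    )
    return generate_audience(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def naive_windowed_pearson(x, y, w):
    """Brute-force sliding-window Pearson, the independent oracle."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.empty(len(x) - w + 1)
    for t in range(len(out)):
        xw, yw = x[t : t + w], y[t : t + w]
        if np.var(xw) == 0 or np.var(yw) == 0:
            out[t] = np.nan
        else:
            out[t] = np.corrcoef(xw, yw)[0, 1]
    return out
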