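"""Shared fixtures: small phantom cohorts reused across test modules.

All fixtures are deterministic (fixed seeds) and sized so the whole
suite runs on one CPU in minutes; image side 256 keeps eight-level
decomposition valid for every basis while being ~16x cheaper than the
full 1024 canvas.
"""

import numpy as np
import pandas as pd
import pytest

import wfc
from wfc.pipeline import phantom_feature_table


@pytest.fixture(scope="session")
def small_images():
    """24 regularized phantoms at 256 px, half abnormal."""
    imgs = wfc.generate_dataset(
        24, prevalence=0.5, seed=5, template=wfc.PhantomSpec(image_size=256)
    )
    return [wfc.regularize(m, target_spacing=200.0, size=256) for m in imgs]


@pytest.fixture(scope="session")
def small_table(small_images):
    """Feature table of the small cohort for the haar and db2 bases."""
    return wfc.extract_table(small_images, bases=["haar", "db2"])


@pytest.fixture(scope="session")
def toy_gaussian_table():
    """Synthetic 40-image feature table with one informative feature.

    Ten columns named as haar skew/kurt features; only 'haar:S-d2'
    separates the classes (gap >> spread), the rest are noise.
    """
    rng = np.random.default_rng(7)
    n = 40
    labels = ["calc_benign" if i < 20 else "normal" for i in range(n)]
    ids = [wfc.FeatureId("haar", "S", m, l) for m in ("a", "h", "v", "d") for l in (1, 2)]
    ids += [wfc.FeatureId("haar", "K", "a", 1), wfc.FeatureId("haar", "K", "d", 2)]
    data = {f.encode(): rng.standard_normal(n) for f in ids}
    sep = np.where(np.arange(n) < 20, 10.0, 0.0) + 0.1 * rng.standard_normal(n)
    data["haar:S-d2"] = sep
    df = pd.DataFrame(data)
    df["image_id"] = [f"img{i}" for i in range(n)]
    df["label"] = labels
    return df


@pytest.fixture(scope="session")
def study_table():
    """The phantom cohort for network-level evaluation: 300 images at the
    full 1024 canvas, one third abnormal, features for every basis used by
    the stock four-tap and sequential networks."""
    bases = ["haar", "db2", "db8", "bior2.2", "bior3.7", "bior5.5", "bior6.8"]
    return phantom_feature_table(
        n=300, prevalence=0.33, seed=0, bases=bases,
        template=wfc.PhantomSpec(image_size=1024),
    )
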