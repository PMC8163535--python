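"""Shared test helpers."""

import numpy as np
import pandas as pd
from sklearn.datasets import make_blobs

from hippopix.dataset import LabelledSet, split
from hippopix.features import FEATURE_COLUMNS


def blob_split(seed=0, n=2000, sep=6.0):
    """Linearly separable 2-blob dataset lifted into the 14-D feature table.

    Two Gaussian blobs ``sep`` standard deviations apart in a 2-D latent
    space are mixed into all 14 feature columns (plus a little independent
    noise), emulating the strong correlations of real pixel features:
    every column is informative, but the intrinsic dimension stays low.
    """
    rng = np.random.default_rng(seed)
    centres = np.array([[-sep / 2, -sep / 2], [sep / 2, sep / 2]]) / np.sqrt(2)
    X2, y = make_blobs(n_samples=n, centers=centres, cluster_std=1.0, random_state=seed)
    mixing = np.random.default_rng(7).normal(size=(2, 14))
    X = X2 @ mixing + rng.normal(size=(n, 14)) * 0.05
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    df["label"] = y
    df["x"] = np.arange(n)
    df["y"] = 0
    df["source"] = "blob"
    return split(LabelledSet(df), seed=seed)
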