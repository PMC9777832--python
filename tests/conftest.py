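import numpy as np
import pandas as pd
import pytest

from entrochan import (EntropyParams, FeatureTable, SynthConfig,
                       epoch_segments, extract_features, generate_subject)


@pytest.fixture(scope="session")
def small_synth():
    """One default-profile synthetic subject, its feature table and truth."""
    cfg = SynthConfig(n_subjects=1, seed=12)
    rec, ann, gt = generate_subject(cfg, 0)
    table = extract_features(epoch_segments(rec, ann))
    return {"cfg": cfg, "rec": rec, "ann": ann, "gt": gt, "table": table}


def make_table(x, labels, channels=None) -> FeatureTable:
    """Wrap a plain feature matrix as a FeatureTable (2 columns/channel)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n_ch = x.shape[1] // 2
    if x.shape[1] % 2:  # pad an odd column count with zeros
        x = np.hstack([x, np.zeros((len(x), 1))])
        n_ch += 1
    if channels is None:
        channels = [f"ch{i}" for i in range(n_ch)]
    cols = [f"{c}:{k}" for c in channels for k in ("ApEn", "SampEn")]
    return FeatureTable(pd.DataFrame(x, columns=cols), np.asarray(labels, dtype=object))


@pytest.fixture
def gaussian_clusters():
    """Two well-separated Gaussian clusters (4 sigma apart), n=200."""
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 1.0, size=(100, 4))
    b = rng.normal(4.0, 1.0, size=(100, 4))
    x = np.vstack([a, b])
    labels = np.array(["A"] * 100 + ["B"] * 100, dtype=object)
    perm = rng.permutation(200)
    return make_table(x[perm], labels[perm])
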