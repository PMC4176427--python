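import dataclasses
import math

import numpy as np
import pytest

from methylqc import io as mio
from methylqc import summarize as msum
from methylqc import synthetic_data as msim


def oracle_quantiles(values, probs):
    """Independent sort-and-interpolate quantile oracle (h = (n-1)p + 1)."""
    x = sorted(float(v) for v in values)
    n = len(x)
    out = []
    for p in probs:
        h = (n - 1) * p
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        out.append(x[lo] + (h - lo) * (x[hi] - x[lo]))
    return np.array(out)


@pytest.fixture(scope="session")
def clean_small_dataset():
    return msim.generate_dataset(msim.preset("clean_small"))


@pytest.fixture(scope="session")
def clean_small_summary(clean_small_dataset):
    d = clean_small_dataset
    return msum.summarize_raw(d.signals, d.manifest, d.controls, d.phenotypes)


@pytest.fixture(scope="session")
def fig4_dataset():
    return msim.generate_dataset(msim.preset("fig4_sex"))


@pytest.fixture(scope="session")
def fig4_summary(fig4_dataset):
    d = fig4_dataset
    return msum.summarize_raw(d.signals, d.manifest, d.controls, d.phenotypes)


@pytest.fixture(scope="session")
def fig2_dataset():
    return msim.generate_dataset(msim.preset("fig2_batch"))


@pytest.fixture(scope="session")
def fig2_summary(fig2_dataset):
    d = fig2_dataset
    return msum.summarize_raw(d.signals, d.manifest, d.controls, d.phenotypes)


@pytest.fixture(scope="session")
def low_quality_dataset():
    """20 samples, 3 of them dimmed to 15% intensity, no batch effect."""
    params = dataclasses.replace(
        msim.preset("fig2_batch"),
        batch_labels=None,
        batch_shift_beta=0.0,
        batch_probe_fraction=0.0,
        n_low_quality=3,
        seed=7,
    )
    return msim.generate_dataset(params)


@pytest.fixture()
def summary_archive(clean_small_summary, tmp_path):
    path = tmp_path / "summary.zip"
    mio.write_summary(clean_small_summary, path)
    return path
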