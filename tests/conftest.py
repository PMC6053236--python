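import numpy as np
import pytest

from mirvar.io_plates import CtMeasurement, DropletCount, SampleMeta
from mirvar.synthetic_data import SyntheticConfig


@pytest.fixture
def study_config():
    return SyntheticConfig.preset("study", seed=123)


@pytest.fixture
def zero_config():
    return SyntheticConfig.preset("zero_noise", seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(99)


def make_meta(**kw) -> SampleMeta:
    base = dict(
        sample_id="s1", subject_id="p1", material="PPP", protocol="dual",
        experiment_id="exp", run_day=1, rt_replicate=1, pcr_replicate=1,
    )
    base.update(kw)
    return SampleMeta(**base)


def make_ct(ct=25.0, assay="miR-92a", platform="qPCR", **meta_kw) -> CtMeasurement:
    return CtMeasurement(meta=make_meta(**meta_kw), assay=assay,
                         platform=platform, ct=ct)


def make_droplets(k=5000, n=16000, assay="miR-92a", vol=0.85, **meta_kw) -> DropletCount:
    return DropletCount(meta=make_meta(**meta_kw), assay=assay, positives=k,
                        total_droplets=n, droplet_volume_nl=vol)
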