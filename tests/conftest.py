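import numpy as np
import pytest

import seizlite as sz


@pytest.fixture(scope="session")
def short_records():
    """Cheap 512-sample records with the published 200/352/106 class mix."""
    specs = {
        lab: sz.SyntheticSpec(
            **{**sz.default_spec(lab).__dict__, "record_length": 512}
        )
        for lab in sz.ClassLabel
    }
    return sz.generate_dataset(
        {sz.ClassLabel.NORMAL: 200, sz.ClassLabel.INTERICTAL: 352, sz.ClassLabel.ICTAL: 106},
        seed=11,
        specs=specs,
    )


@pytest.fixture(scope="session")
def tiny_records():
    """A handful of full-length records for segmentation tests."""
    return sz.generate_dataset(
        {sz.ClassLabel.NORMAL: 3, sz.ClassLabel.INTERICTAL: 5, sz.ClassLabel.ICTAL: 2},
        seed=7,
    )


@pytest.fixture(scope="session")
def edf_fixture(tmp_path_factory):
    channels, _ = sz.make_multichannel_fixture(
        n_channels=2, duration_s=10.0, fs_hz=256.0, seed=3
    )
    path = tmp_path_factory.mktemp("edf") / "fixture.edf"
    edf_path, ann_path = sz.write_minimal_edf(channels, 256.0, [(2.0, 4.0)], path)
    return {"channels": channels, "edf": edf_path, "annotations": ann_path}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
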