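import numpy as np
import pytest

from raddecomp.phantom import PhantomSpec, build_dataset


@pytest.fixture(scope="session")
def toy_spec() -> PhantomSpec:
    """Small 4-channel phantom spec (1 bone, 2 muscles, background)."""
    return PhantomSpec(
        grid_shape=(32, 32, 32), spacing=(4.0, 4.0, 4.0),
        n_bones=1, n_muscles=2, asymmetry_factor=0.85, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_manifest(tmp_path_factory):
    """4-case rendered dataset shared by training/evaluation tests."""
    out = tmp_path_factory.mktemp("tiny_dataset")
    specs = [
        PhantomSpec(
            grid_shape=(32, 32, 32), spacing=(4.0, 4.0, 4.0),
            n_bones=1, n_muscles=2, asymmetry_factor=0.85, seed=40 + i,
        )
        for i in range(4)
    ]
    return build_dataset(
        specs, out, splits={"train": 0.75, "test": 0.25}, seed=9,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
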