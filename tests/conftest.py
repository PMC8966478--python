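import numpy as np
import pytest

from neurocf import nn
from neurocf.data import LabeledDataset, SynthConfig, generate_synthetic_dataset
from neurocf.gan import Discriminator, GanConfig, Generator


@pytest.fixture()
def tiny_cfg() -> SynthConfig:
    return SynthConfig(H=16, W=16, K=3, n_per_class=5, seed=0)


@pytest.fixture()
def tiny_ds(tiny_cfg) -> LabeledDataset:
    return generate_synthetic_dataset(tiny_cfg)


@pytest.fixture()
def tiny_gan_cfg() -> GanConfig:
    return GanConfig(input_shape=(16, 16), K=3, base_channels=2, seed=0)


@pytest.fixture()
def tiny_gen(tiny_ds, tiny_gan_cfg) -> Generator:
    return Generator(tiny_gan_cfg, tiny_ds.mask)


@pytest.fixture()
def tiny_disc(tiny_gan_cfg) -> Discriminator:
    return Discriminator(tiny_gan_cfg)


class IdentityGenerator:
    """Stub generator returning its input unchanged (any target class)."""

    def __init__(self, mask: np.ndarray, K: int = 3):
        self.mask = np.asarray(mask, dtype=bool)
        self.cfg = GanConfig(input_shape=self.mask.shape, K=K)

    def __call__(self, x: nn.Tensor, targets) -> nn.Tensor:
        return x


class ConstantShiftGenerator:
    """Stub generator adding a constant delta inside the mask each pass."""

    def __init__(self, mask: np.ndarray, delta: float, K: int = 3):
        self.mask = np.asarray(mask, dtype=bool)
        self.delta = delta
        self.cfg = GanConfig(input_shape=self.mask.shape, K=K)

    def __call__(self, x: nn.Tensor, targets) -> nn.Tensor:
        return x + nn.Tensor(self.delta * self.mask.astype(np.float64))


@pytest.fixture()
def identity_gen(tiny_ds):
    return IdentityGenerator(tiny_ds.mask, K=tiny_ds.n_classes)


@pytest.fixture(scope="session")
def study():
    """One seeded desk-scale end-to-end run shared by the acceptance suite."""
    from neurocf.pipeline import run_study

    return run_study(seed=2, verbose=False)
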