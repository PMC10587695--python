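import numpy as np
import pytest

from polstain.phantom import PhantomParams, generate_scene, scene_to_brightfield, scene_to_stokes
from polstain.polarimetry import linear_polarizer, retarder
from polstain.preprocess import encode_stokes
from polstain.translator import DiscriminatorSpec, GeneratorSpec, TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_physical_mueller(rng: np.random.Generator) -> np.ndarray:
    """A random physical Mueller matrix: product of an isotropic attenuation,
    a partial diattenuator, a retarder and a partial depolarizer."""
    tau = rng.uniform(0.3, 1.0)
    ret = retarder(rng.uniform(0, np.pi), rng.uniform(0, np.pi))
    w = rng.uniform(0.0, 1.0)  # diattenuation strength
    diat = w * linear_polarizer(rng.uniform(0, np.pi)) + (1 - w) * np.eye(4)
    p = rng.uniform(0.2, 1.0)
    depol = np.diag([1.0, p, p, p])
    return tau * (depol @ ret @ diat)


def random_physical_stokes(rng: np.random.Generator) -> np.ndarray:
    """A random physical Stokes vector with DoP <= 1."""
    s0 = rng.uniform(0.1, 2.0)
    v = rng.normal(size=3)
    v *= rng.uniform(0, 1) / np.linalg.norm(v)
    return np.concatenate([[s0], s0 * v])


# --- toy-scale translator conditions (network width and batch size are the
# package's CPU-scale defaults; dataset geometry matches the phantom's) ---

TOY_PATCH = 64
TOY_BASE_WIDTH = 8
TOY_DISC_WIDTHS = (8, 16, 32, 64, 1)


def toy_train_config(seed: int, epochs: int = 10, gan_mode: str = "log") -> TrainConfig:
    return TrainConfig(
        epochs=epochs, flat_epochs=epochs // 2, batch_size=2, gan_mode=gan_mode, seed=seed
    )


def toy_gen_spec(in_channels: int = 3) -> GeneratorSpec:
    return GeneratorSpec(in_channels=in_channels, out_channels=3, base_width=TOY_BASE_WIDTH)


def toy_disc_spec() -> DiscriminatorSpec:
    return DiscriminatorSpec(widths=TOY_DISC_WIDTHS)


def toy_scene_params(size: int = TOY_PATCH) -> PhantomParams:
    return PhantomParams(size=(size, size), n_nuclei=8, n_fibers=3)


def phantom_arrays(n_scenes: int, sop: str = "LIN45", palette: str = "HE", seed: int = 0,
                   size: int = TOY_PATCH):
    """Co-registered (encoded Stokes, bright-field in [-1,1]) arrays for
    n_scenes toy phantom scenes."""
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, n_scenes)
    xs, ys = [], []
    params = toy_scene_params(size)
    for s in seeds:
        scene = generate_scene(params, int(s))
        _, stokes = scene_to_stokes(scene, sop)
        xs.append(encode_stokes(stokes).data)
        ys.append(scene_to_brightfield(scene, palette) / 127.5 - 1.0)
    return np.stack(xs).astype(np.float32), np.stack(ys).astype(np.float32)
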