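"""Seeded synthetic tissue scenes with known polarimetric and stain ground
truth.

A scene is a parametric arrangement of cell nuclei (ellipses) and fibrous
stroma (smooth curves) on a transparent background.  From one geometry the
module renders every co-registered modality the pipeline consumes:

* a per-pixel Mueller map — nuclei absorb and depolarize, fibers carry
  linear retardance oriented along their tangent;
* raw eight-channel DoFP intensities and the reconstructed Stokes image
  under any chosen illumination state (via :mod:`polstain.dofp`);
* bright-field renderings in H&E or IHC (Ki-67 / TTF-1) stain palettes
  through Beer–Lambert absorbance compositing.

All randomness flows from one integer seed, so a dataset is reproducible
across platforms.  This is a statistical stand-in for clinical slides, not
a histology texture model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import dofp
from .polarimetry import NAMED_STATES
from .preprocess import encode_stokes

__all__ = [
    "Nucleus",
    "Fiber",
    "PhantomParams",
    "PhantomScene",
    "OpticalProperties",
    "PALETTES",
    "generate_scene",
    "rasterize_optics",
    "scene_to_mueller",
    "scene_to_stokes",
    "scene_to_brightfield",
    "DatasetConfig",
    "make_dataset",
]


@dataclass(frozen=True)
class Nucleus:
    center: tuple[float, float]  # (row, col), pixels
    semi_axes: tuple[float, float]
    orientation: float  # radians
    positive: bool  # IHC marker positivity


@dataclass(frozen=True)
class Fiber:
    points: tuple  # ((row, col), ...) polyline through the fiber core
    width: float  # pixels
    retardance: float  # peak retardance at the core, radians


@dataclass(frozen=True)
class PhantomParams:
    """Scene statistics.  Defaults give a sparse epithelial-like field:
    ~25 nuclei of 3-7 px radius and 6 wavy stromal fibers on a 128 px
    canvas, with 30% IHC-positive nuclei."""

    size: tuple[int, int] = (128, 128)
    n_nuclei: int = 25
    n_fibers: int = 6
    nucleus_radius: tuple[float, float] = (3.0, 7.0)
    nucleus_eccentricity: float = 0.6  # min minor/major axis ratio
    positive_fraction: float = 0.3
    fiber_width: tuple[float, float] = (1.5, 3.5)
    fiber_retardance: tuple[float, float] = (0.5, 1.5)  # radians at core
    nucleus_tau: float = 0.55  # transmittance inside nuclei
    nucleus_depol: float = 0.6  # residual DoP factor inside nuclei
    background_tau: float = 0.96
    max_overlap_fraction: float = 0.25
    max_place_retries: int = 200

    def __post_init__(self) -> None:
        if min(self.size) < 64:
            raise ValueError("scene must be at least 64 px on a side")
        if self.n_nuclei < 0 or self.n_fibers < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class PhantomScene:
    params: PhantomParams
    nuclei: list[Nucleus]
    fibers: list[Fiber]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": asdict(self.params),
                "nuclei": [asdict(n) for n in self.nuclei],
                "fibers": [asdict(f) for f in self.fibers],
                "seed": self.seed,
            },
            sort_keys=True,
        )


@dataclass
class OpticalProperties:
    """Per-pixel optical maps: linear retardance ``delta`` (radians), slow
    axis ``phi`` (radians), isotropic transmittance ``tau`` in (0, 1] and
    residual polarization factor ``p`` in [0, 1] (1 = no depolarization)."""

    delta: np.ndarray
    phi: np.ndarray
    tau: np.ndarray
    p: np.ndarray
    nucleus_mask: np.ndarray
    positive_mask: np.ndarray
    fiber_density: np.ndarray


def generate_scene(params: PhantomParams | None = None, seed: int = 0) -> PhantomScene:
    """Randomly place nuclei and fibers; identical (params, seed) pairs give
    identical scenes.

    Nuclei are rejected if they overlap an existing nucleus center-to-center
    closer than ``(1 - max_overlap_fraction)`` of the summed radii; if a
    nucleus cannot be placed within ``max_place_retries`` attempts the
    packing is infeasible and an error is raised.
    """
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    h, w = params.size
    nuclei: list[Nucleus] = []
    margin = params.nucleus_radius[1]
    for _ in range(params.n_nuclei):
        for attempt in range(params.max_place_retries):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            a = rng.uniform(*params.nucleus_radius)
            b = a * rng.uniform(params.nucleus_eccentricity, 1.0)
            ok = all(
                np.hypot(r - n.center[0], c - n.center[1])
                >= (1.0 - params.max_overlap_fraction) * (max(a, b) + max(n.semi_axes))
                for n in nuclei
            )
            if ok:
                nuclei.append(
                    Nucleus(
                        (r, c),
                        (a, b),
                        float(rng.uniform(0, np.pi)),
                        bool(rng.random() < params.positive_fraction),
                    )
                )
                break
        else:
            raise RuntimeError(
                f"could not place nucleus {len(nuclei) + 1}/{params.n_nuclei} "
                f"after {params.max_place_retries} retries: packing infeasible"
            )
    fibers: list[Fiber] = []
    for _ in range(params.n_fibers):
        r = rng.uniform(0, h)
        c = rng.uniform(0, w)
        ang = rng.uniform(0, 2 * np.pi)
        pts = [(r, c)]
        n_steps = int(1.5 * max(h, w) / 3)
        for _ in range(n_steps):
            ang += rng.normal(0.0, 0.15)
            r += 3.0 * np.sin(ang)
            c += 3.0 * np.cos(ang)
            if not (0 <= r < h and 0 <= c < w):
                break
            pts.append((r, c))
        if len(pts) >= 3:
            fibers.append(
                Fiber(
                    tuple(pts),
                    float(rng.uniform(*params.fiber_width)),
                    float(rng.uniform(*params.fiber_retardance)),
                )
            )
    return PhantomScene(params, nuclei, fibers, seed)


def rasterize_optics(scene: PhantomScene, scale: float = 1.0) -> OpticalProperties:
    """Render the per-pixel optical maps at a given magnification.

    ``scale > 1`` emulates a higher-magnification objective: the same
    physical structures subtend proportionally more pixels around the scene
    center, on a canvas of the same pixel count.
    """
    p = scene.params
    h, w = p.size
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    if scale != 1.0:  # zoom about the scene center
        rows = rows / scale + (h / 2) * (1 - 1 / scale)
        cols = cols / scale + (w / 2) * (1 - 1 / scale)
    phi = np.zeros((h, w))
    tau = np.full((h, w), p.background_tau)
    pol = np.ones((h, w))
    fiber_density = np.zeros((h, w))
    fiber_ret = np.zeros((h, w))
    for f in scene.fibers:
        pts = np.asarray(f.points)
        tangents = np.gradient(pts, axis=0)
        sigma = f.width * scale
        for (r, c), (tr, tc) in zip(pts, tangents):
            rr = (r - rows) * scale
            cc = (c - cols) * scale
            stamp = np.exp(-(rr * rr + cc * cc) / (2 * sigma * sigma))
            stronger = stamp > fiber_density
            ang = np.arctan2(tr, tc) % np.pi
            phi = np.where(stronger, ang, phi)
            fiber_ret = np.where(stronger, f.retardance, fiber_ret)
            fiber_density = np.where(stronger, stamp, fiber_density)
    delta = fiber_density * fiber_ret
    nucleus_mask = np.zeros((h, w), dtype=bool)
    positive_mask = np.zeros((h, w), dtype=bool)
    for nuc in scene.nuclei:
        (r0, c0), (a, b) = nuc.center, nuc.semi_axes
        co, si = np.cos(nuc.orientation), np.sin(nuc.orientation)
        dr, dc = rows - r0, cols - c0
        u = (co * dc + si * dr) / a
        v = (-si * dc + co * dr) / b
        inside = u * u + v * v <= 1.0
        nucleus_mask |= inside
        if nuc.positive:
            positive_mask |= inside
    tau = np.where(nucleus_mask, p.nucleus_tau, tau)
    pol = np.where(nucleus_mask, p.nucleus_depol, pol)
    # nuclei dominate optically where they overlap fibers
    delta = np.where(nucleus_mask, 0.0, delta)
    return OpticalProperties(delta, phi, tau, pol, nucleus_mask, positive_mask, fiber_density)


def _retarder_maps(delta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-pixel linear-retarder Mueller matrices, shape (H, W, 4, 4).

    Closed form of R(-phi) @ M0(delta) @ R(phi) with the library's sign
    convention (see :func:`polstain.polarimetry.retarder`)."""
    c2, s2 = np.cos(2 * phi), np.sin(2 * phi)
    cd, sd = np.cos(delta), np.sin(delta)
    h, w = delta.shape
    m = np.zeros((h, w, 4, 4))
    m[..., 0, 0] = 1.0
    m[..., 1, 1] = c2**2 + s2**2 * cd
    m[..., 1, 2] = c2 * s2 * (1 - cd)
    m[..., 1, 3] = -s2 * sd
    m[..., 2, 1] = c2 * s2 * (1 - cd)
    m[..., 2, 2] = s2**2 + c2**2 * cd
    m[..., 2, 3] = c2 * sd
    m[..., 3, 1] = s2 * sd
    m[..., 3, 2] = -c2 * sd
    m[..., 3, 3] = cd
    return m


def scene_to_mueller(scene: PhantomScene, scale: float = 1.0) -> np.ndarray:
    """Forward physics: per-pixel Mueller map, shape (H, W, 16) row-major.

    Each pixel is an isotropic attenuation ``tau`` times a partial
    depolarizer ``diag(1, p, p, p)`` times a linear retarder
    ``(delta, phi)``; background pixels reduce to ``tau_bg * identity``.
    """
    opt = rasterize_optics(scene, scale)
    ret = _retarder_maps(opt.delta, opt.phi)
    depol = np.stack([np.ones_like(opt.p), opt.p, opt.p, opt.p], axis=-1)  # (H, W, 4)
    m = ret * depol[..., :, None]  # row scaling = diag(1,p,p,p) @ ret
    m = m * opt.tau[..., None, None]
    h, w = opt.delta.shape
    return m.reshape(h, w, 16)


def scene_to_stokes(
    scene: PhantomScene,
    sop: str = "LIN45",
    instrument: dofp.InstrumentMatrix | None = None,
    scale: float = 1.0,
    noise: str | None = None,
    noise_level: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Simulate a snapshot acquisition under one illumination SOP.

    Propagates the named illumination state through the scene's Mueller
    map, forward-models the eight DoFP intensities and reconstructs the
    Stokes image — the exact chain a real snapshot measurement follows.

    Returns
    -------
    (intensities, stokes) : (H, W, 8) and (H, W, 4) arrays.
    """
    if sop not in NAMED_STATES:
        raise KeyError(f"unknown SOP {sop!r}; choose from {sorted(NAMED_STATES)}")
    instrument = instrument or dofp.build_instrument_matrix()
    mm = scene_to_mueller(scene, scale)
    h, w = mm.shape[:2]
    s_in = NAMED_STATES[sop].stokes
    s_out = np.einsum("hwij,j->hwi", mm.reshape(h, w, 4, 4), s_in)
    intens = dofp.simulate_intensities(instrument, s_out, noise, noise_level, rng)
    stokes = dofp.reconstruct_stokes(instrument, intens)
    return intens, stokes


#: Beer-Lambert extinction (optical density at full component density) per
#: RGB channel for each stain palette.  Values are documented constants
#: chosen to mimic the qualitative look of each stain, not fits to real
#: absorbance spectra.
PALETTES: dict[str, dict[str, tuple[float, float, float]]] = {
    "HE": {  # hematoxylin nuclei (blue-purple) + eosin stroma (pink)
        "nucleus": (1.10, 0.90, 0.30),
        "positive_nucleus": (1.10, 0.90, 0.30),  # H&E ignores positivity
        "fiber": (0.12, 0.55, 0.25),
        "background": (0.02, 0.04, 0.02),
    },
    "KI67": {  # DAB-brown positive nuclei on hematoxylin counterstain
        "nucleus": (0.85, 0.65, 0.20),
        "positive_nucleus": (0.35, 0.80, 1.25),
        "fiber": (0.08, 0.12, 0.10),
        "background": (0.02, 0.02, 0.02),
    },
    "TTF1": {  # DAB with a slightly warmer hue and fainter stroma
        "nucleus": (0.80, 0.60, 0.25),
        "positive_nucleus": (0.30, 0.70, 1.10),
        "fiber": (0.05, 0.08, 0.07),
        "background": (0.015, 0.02, 0.015),
    },
}


def scene_to_brightfield(scene: PhantomScene, palette: str = "HE", scale: float = 1.0) -> np.ndarray:
    """Render the stained bright-field view of a scene, uint8 RGB.

    Component densities (nuclei, fibers, background) multiply palette
    extinction coefficients and composite through Beer-Lambert attenuation
    ``I = 255 * exp(-sum OD)``; an empty scene renders uniform white.
    """
    if palette not in PALETTES:
        raise KeyError(f"unknown palette {palette!r}; choose from {sorted(PALETTES)}")
    pal = PALETTES[palette]
    opt = rasterize_optics(scene, scale)
    h, w = opt.tau.shape
    od = np.zeros((h, w, 3))
    neg = opt.nucleus_mask & ~opt.positive_mask
    od += neg[..., None] * np.asarray(pal["nucleus"])
    od += opt.positive_mask[..., None] * np.asarray(pal["positive_nucleus"])
    fiber = np.clip(opt.fiber_density, 0, 1) * (~opt.nucleus_mask)
    od += fiber[..., None] * np.asarray(pal["fiber"])
    od += np.asarray(pal["background"]) * (~opt.nucleus_mask[..., None])
    return np.clip(np.rint(255.0 * np.exp(-od)), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Dataset rendering


@dataclass(frozen=True)
class DatasetConfig:
    out_dir: str
    n_scenes: int = 10
    train_fraction: float = 0.8
    palette: str = "HE"
    sop: str = "LIN45"
    paired: bool = True
    scene_params: PhantomParams = field(default_factory=PhantomParams)
    magnifications: tuple[float, ...] = (1.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_scenes < 2:
            raise ValueError("need at least 2 scenes to split")


def make_dataset(config: DatasetConfig) -> dict:
    """Render a full on-disk dataset of co-registered modalities.

    Per scene and magnification: raw intensity stack, Stokes image, Mueller
    stack (multipage TIFF) and bright-field rendering (PNG).  Scenes are
    split into train/test by scene id, emulating a subject-level split.  In
    unpaired mode the training manifest lists the polarimetric and
    bright-field files in independently shuffled order, withholding the
    geometric pairing; the test manifest always keeps pairs aligned for
    evaluation.

    Returns the manifest (also written to ``manifest.json``).
    """
    from . import io as pio  # local import to keep module import light

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=config.n_scenes)
    n_train = int(round(config.train_fraction * config.n_scenes))
    n_train = min(max(n_train, 1), config.n_scenes - 1)
    instrument = dofp.build_instrument_matrix()
    entries = []
    for sid, sseed in enumerate(scene_seeds):
        scene = generate_scene(config.scene_params, int(sseed))
        for mag in config.magnifications:
            tag = f"scene{sid:04d}_mag{mag:g}"
            mm = scene_to_mueller(scene, mag)
            intens, stokes_img = scene_to_stokes(scene, config.sop, instrument, mag)
            bf = scene_to_brightfield(scene, config.palette, mag)
            enc = encode_stokes(stokes_img)
            files = {
                "mueller": f"{tag}_mm.tiff",
                "intensities": f"{tag}_dofp.tiff",
                "stokes": f"{tag}_stokes.tiff",
                "stokes_encoded": f"{tag}_enc.tiff",
                "brightfield": f"{tag}_bf.png",
            }
            pio.write_stack(out / files["mueller"], mm, {"kind": "mueller", "order": "m11..m44"})
            pio.write_stack(
                out / files["intensities"], intens,
                {"kind": "dofp_intensities", "sop": config.sop},
            )
            pio.write_stack(out / files["stokes"], stokes_img, {"kind": "stokes", "sop": config.sop})
            pio.write_stack(out / files["stokes_encoded"], enc.data, {"kind": "encoded_stokes"})
            pio.write_png(out / files["brightfield"], bf)
            entries.append({"scene": sid, "magnification": mag, "split": "train" if sid < n_train else "test", **files})
    train = [e for e in entries if e["split"] == "train"]
    test = [e for e in entries if e["split"] == "test"]
    manifest = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "scene_params"},
            "scene_params": asdict(config.scene_params),
        },
        "paired": config.paired,
        "test": test,
    }
    if config.paired:
        manifest["train"] = train
    else:
        # withhold pairing: independent shuffles of the two modality lists
        pol = [e["stokes_encoded"] for e in train]
        bf = [e["brightfield"] for e in train]
        manifest["train_polarimetric"] = list(rng.permutation(pol))
        manifest["train_brightfield"] = list(rng.permutation(bf))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
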