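"""Synthetic flock generator: phenotypes and rendered dorsal/lateral images.

The generator emulates a commercial ewe flock whose live weight is a
truncated normal (defaults: mean 62.4 kg, SD 8.7 kg on [48.0, 88.5] kg) and
whose CT-derived fat mass is a truncated lognormal sharing a latent Gaussian
factor with live weight.  Carcass weight is a dressing fraction of live
weight plus noise, bone mass a fixed fraction of carcass, and lean mass the
remainder, so the component masses sum to carcass weight exactly.

Images are deliberately schematic rather than photorealistic: a two-lobed
body silhouette (thoracic and rump lobes) whose half-width is an affine
function of live weight and fat mass, a red reference marker bar, and
additive background/fleece noise.  The fat-mass slope is modulated by the
animal's size category so fat mass is NOT decodable from the image alone —
the tabular covariates carry the missing context, which is what makes the
multimodal fusion architectures the right tool on this data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import optimize
from scipy.stats import truncnorm

__all__ = [
    "FlockCalibration",
    "AnimalPhenotype",
    "RenderConfig",
    "ImageSample",
    "sample_flock",
    "derive_tabular",
    "render_animal",
    "body_pixel_mask",
    "write_flock_csv",
    "read_flock_csv",
    "save_image",
    "load_image",
]

SIZE_CATEGORIES = ("small", "medium", "large")
VIEWS = ("dorsal", "lateral")


class ValidationError(ValueError):
    """A domain object violated one of its invariants."""


@dataclass(frozen=True)
class FlockCalibration:
    """Population parameters of the simulated flock (all masses in kg)."""

    lw_mean: float = 62.4
    lw_sd: float = 8.7
    lw_min: float = 48.0
    lw_max: float = 88.5
    fm_logmean: float = float(np.log(5.5))
    fm_logsd: float = 0.55
    fm_min: float = 0.88
    fm_max: float = 17.64
    fm_lw_corr: float = 0.6
    dressing_fraction: float = 0.44
    bone_fraction: float = 0.18
    fm_cap_fraction: float = 0.55
    cw_noise_sd: float = 0.5

    def __post_init__(self):
        if not (self.lw_min < self.lw_mean < self.lw_max):
            raise ValidationError("need lw_min < lw_mean < lw_max")
        if not self.fm_min < self.fm_max:
            raise ValidationError("need fm_min < fm_max")
        if not 0.0 < self.dressing_fraction < 1.0:
            raise ValidationError("dressing_fraction must be in (0, 1)")
        if not 0.0 < self.bone_fraction < 1.0:
            raise ValidationError("bone_fraction must be in (0, 1)")
        if self.bone_fraction + self.fm_cap_fraction >= 1.0:
            raise ValidationError("bone_fraction + fm_cap_fraction must be < 1")
        if not -1.0 <= self.fm_lw_corr <= 1.0:
            raise ValidationError("fm_lw_corr must be in [-1, 1]")
        if self.lw_sd <= 0:
            raise ValidationError("lw_sd must be positive")

    def latent_normal_params(self) -> tuple[float, float]:
        """Latent (mu0, sigma0) whose truncation to [lw_min, lw_max] has the
        requested mean and SD.

        Truncation shrinks the SD of the parent normal, so sampling directly
        from N(lw_mean, lw_sd) and rejecting would undershoot the target SD.
        We instead solve the two truncated-moment equations for the parent
        parameters; this is the generator's truncation correction.
        """
        target = np.array([self.lw_mean, self.lw_sd])

        def residual(p):
            mu0, sig0 = p
            sig0 = abs(sig0)
            a = (self.lw_min - mu0) / sig0
            b = (self.lw_max - mu0) / sig0
            m, v = truncnorm.stats(a, b, loc=mu0, scale=sig0, moments="mv")
            return [m - target[0], np.sqrt(v) - target[1]]

        sol = optimize.fsolve(residual, x0=[self.lw_mean, self.lw_sd], full_output=False)
        mu0, sig0 = float(sol[0]), float(abs(sol[1]))
        if np.max(np.abs(residual([mu0, sig0]))) > 1e-6:
            raise ValidationError(
                "no latent normal reproduces the requested truncated moments"
            )
        return mu0, sig0


@dataclass(frozen=True)
class AnimalPhenotype:
    animal_id: str
    live_weight: float
    carcass_weight: float
    fat_mass: float
    lean_mass: float
    bone_mass: float
    bcs: float | None = None
    size_category: str | None = None


@dataclass(frozen=True)
class RenderConfig:
    """Geometry of the schematic renders.

    ``width_coeffs`` maps view -> (intercept, lw_slope, fm_slope), all in
    pixels (slopes in px/kg); ``size_modulation`` scales the fm_slope per
    size category so fat mass only decodes jointly with the tabular record.
    """

    image_size: int = 64
    marker_length: int = 10  # stands for the 40 cm reference marker
    background_noise_sd: float = 0.02
    texture_noise_sd: float = 0.03
    width_coeffs: dict = field(
        default_factory=lambda: {
            "dorsal": (-8.0, 0.28, 0.12),
            "lateral": (-6.0, 0.24, 0.10),
        }
    )
    size_modulation: dict = field(
        default_factory=lambda: {"small": 0.5, "medium": 1.0, "large": 1.5}
    )
    background_level: float = 0.25
    body_level: float = 0.85

    def __post_init__(self):
        if self.image_size < 32:
            raise ValidationError("image_size must be >= 32")
        if self.marker_length >= self.image_size:
            raise ValidationError("marker_length must fit inside the frame")


@dataclass(frozen=True)
class ImageSample:
    animal_id: str
    view: str
    augtag: str
    pixels: np.ndarray  # (H, W, 3) float in [0, 1]

    def __post_init__(self):
        if self.view not in VIEWS:
            raise ValidationError(f"unknown view {self.view!r}")

    @property
    def filename(self) -> str:
        return f"{self.animal_id}_{self.view}_{self.augtag}.png"


def _animal_rng(seed: int, animal_id: str, *extra: int) -> np.random.Generator:
    # one stream per (seed, animal) so flocks are order-independent
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(animal_id.encode("utf-8")), *extra]
    )


def sample_flock(
    n: int, seed: int, calib: FlockCalibration | None = None
) -> list[AnimalPhenotype]:
    """Draw `n` phenotypically coherent animals, deterministic in (n, seed, calib).

    The live-weight latent is rejection-sampled against its own bounds (so
    the marginal is exactly the truncated normal the calibration targets);
    the fat-mass latent is then drawn conditionally on it, correlation
    ``fm_lw_corr``, and rejection-sampled against the fat-mass bounds.
    Rejection rather than clipping avoids probability atoms at the bounds.
    Fat mass is additionally capped at ``fm_cap_fraction * carcass_weight``
    so lean mass is always positive.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    calib = calib or FlockCalibration()
    mu0, sig0 = calib.latent_normal_params()
    rho = calib.fm_lw_corr
    width = len(str(max(n, 1)))

    animals: list[AnimalPhenotype] = []
    for i in range(n):
        animal_id = f"ewe_{i:0{width}d}"
        rng = _animal_rng(seed, animal_id)
        while True:
            z1 = rng.standard_normal()
            lw = mu0 + sig0 * z1
            if calib.lw_min <= lw <= calib.lw_max:
                break
        while True:
            z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal()
            fm = float(np.exp(calib.fm_logmean + calib.fm_logsd * z2))
            if calib.fm_min <= fm <= calib.fm_max:
                break
        while True:
            cw = calib.dressing_fraction * lw + calib.cw_noise_sd * rng.standard_normal()
            if 0.0 < cw < lw:
                break
        fm = min(fm, calib.fm_cap_fraction * cw)
        bone = calib.bone_fraction * cw
        lean = cw - fm - bone
        animals.append(
            AnimalPhenotype(
                animal_id=animal_id,
                live_weight=float(lw),
                carcass_weight=float(cw),
                fat_mass=float(fm),
                lean_mass=float(lean),
                bone_mass=float(bone),
            )
        )
    if len(animals) >= 3:
        animals = [
            replace(ph, bcs=b, size_category=s)
            for ph, (b, s) in zip(animals, _tabular_for_flock(animals))
        ]
    return animals


def _tabular_for_flock(flock: list[AnimalPhenotype]) -> list[tuple[float, str]]:
    n = len(flock)
    # BCS from the rank-quantile of the fat ratio; ties broken by animal_id
    ratio_order = sorted(
        range(n), key=lambda i: (flock[i].fat_mass / flock[i].carcass_weight, flock[i].animal_id)
    )
    bcs = [0.0] * n
    for rank, i in enumerate(ratio_order):
        q = rank / (n - 1) if n > 1 else 0.0
        bcs[i] = float(np.clip(np.round((1.0 + 4.0 * q) * 2.0) / 2.0, 1.0, 5.0))
    # size category from live-weight tertiles
    lw_order = sorted(range(n), key=lambda i: (flock[i].live_weight, flock[i].animal_id))
    cut = n // 3
    size = [""] * n
    for rank, i in enumerate(lw_order):
        if rank < cut:
            size[i] = "small"
        elif rank >= n - cut:
            size[i] = "large"
        else:
            size[i] = "medium"
    return list(zip(bcs, size))


def derive_tabular(
    ph: AnimalPhenotype, flock: list[AnimalPhenotype]
) -> tuple[float, str]:
    """Body-condition score and size category of `ph` within its flock."""
    if len(flock) < 3:
        raise ValidationError("tertiles undefined for flocks smaller than 3")
    ids = [a.animal_id for a in flock]
    if ph.animal_id not in ids:
        raise ValidationError(f"{ph.animal_id} not in flock")
    tab = _tabular_for_flock(flock)
    return tab[ids.index(ph.animal_id)]


def _half_width(ph: AnimalPhenotype, view: str, cfg: RenderConfig) -> float:
    intercept, lw_slope, fm_slope = cfg.width_coeffs[view]
    mod = cfg.size_modulation[ph.size_category or "medium"]
    return intercept + lw_slope * ph.live_weight + fm_slope * mod * ph.fat_mass


def _body_mask(ph: AnimalPhenotype, view: str, cfg: RenderConfig) -> np.ndarray:
    s = cfg.image_size
    w = _half_width(ph, view, cfg)
    if w <= 0:
        raise ValidationError("phenotype renders with non-positive body width")
    if w >= s / 2 - max(3, round(0.1 * s)):
        raise ValidationError("phenotype outside calibration range: body overflows frame")
    cols = np.arange(s)
    margin = int(round(0.11 * s))
    length = s - 2 * margin
    t = (cols - margin) / max(length - 1, 1)
    inside = (t >= 0.0) & (t <= 1.0)
    # two-lobed silhouette: thoracic lobe (anterior) and rump lobe (posterior)
    lobes = np.maximum(
        np.exp(-(((t - 0.32) / 0.20) ** 2)), np.exp(-(((t - 0.72) / 0.17) ** 2))
    )
    profile = np.where(inside, w * (0.55 + 0.45 * lobes), 0.0)
    rows = np.arange(s)
    return np.abs(rows[:, None] - (s - 1) / 2.0) <= profile[None, :]


def body_pixel_mask(ph: AnimalPhenotype, view: str, cfg: RenderConfig | None = None) -> np.ndarray:
    """Boolean (H, W) mask of body pixels for a zero-noise render."""
    return _body_mask(ph, view, cfg or RenderConfig())


def render_animal(
    ph: AnimalPhenotype,
    view: str,
    cfg: RenderConfig | None = None,
    seed: int = 0,
) -> ImageSample:
    """Render one view of one animal; deterministic given the arguments."""
    if view not in VIEWS:
        raise ValidationError(f"unknown view {view!r}")
    cfg = cfg or RenderConfig()
    s = cfg.image_size
    rng = _animal_rng(seed, ph.animal_id, VIEWS.index(view))
    mask = _body_mask(ph, view, cfg)

    img = np.full((s, s, 3), cfg.background_level)
    if cfg.background_noise_sd > 0:
        img += cfg.background_noise_sd * rng.standard_normal((s, s, 3))
    body = np.full((s, s, 3), cfg.body_level)
    if cfg.texture_noise_sd > 0:
        body += cfg.texture_noise_sd * rng.standard_normal((s, s, 3))
    img = np.where(mask[:, :, None], body, img)

    # reference marker: a pure-red bar in the bottom-left corner
    row = s - 5
    img[row, 3 : 3 + cfg.marker_length] = (1.0, 0.0, 0.0)
    return ImageSample(
        animal_id=ph.animal_id,
        view=view,
        augtag="original",
        pixels=np.clip(img, 0.0, 1.0),
    )


# -- flock / image IO -------------------------------------------------------

_FLOCK_COLUMNS = [
    "animal_id", "live_weight", "carcass_weight", "fat_mass", "lean_mass",
    "bone_mass", "bcs", "size_category",
]


def write_flock_csv(flock: list[AnimalPhenotype], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(a, c) for c in _FLOCK_COLUMNS} for a in flock])
    df.to_csv(path, index=False)


def read_flock_csv(path: str | Path) -> list[AnimalPhenotype]:
    df = pd.read_csv(path)
    if df["animal_id"].duplicated().any():
        dup = df.loc[df["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise ValidationError(f"duplicated animal row: {dup}")
    return [
        AnimalPhenotype(
            animal_id=str(r.animal_id),
            live_weight=float(r.live_weight),
            carcass_weight=float(r.carcass_weight),
            fat_mass=float(r.fat_mass),
            lean_mass=float(r.lean_mass),
            bone_mass=float(r.bone_mass),
            bcs=float(r.bcs),
            size_category=str(r.size_category),
        )
        for r in df.itertuples()
    ]


def save_image(sample: ImageSample, directory: str | Path) -> Path:
    path = Path(directory) / sample.filename
    arr = np.clip(np.round(sample.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)
    return path


def load_image(path: str | Path) -> ImageSample:
    stem = Path(path).stem
    animal_id, view, augtag = stem.rsplit("_", 2)
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0
    return ImageSample(animal_id=animal_id, view=view, augtag=augtag, pixels=arr)
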