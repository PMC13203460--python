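"""Dataset assembly with strict animal-level partitioning.

All of the splitting here operates on animal identifiers, never on images:
every image of an individual lands in exactly one partition or fold, which
is the leakage-control discipline required when multiple correlated views
(and augmented copies) of the same animal exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .synth import ImageSample, ValidationError

__all__ = [
    "SplitManifest",
    "FoldManifest",
    "AugSuite",
    "LeakReport",
    "partition_animals",
    "assign_folds",
    "augment_training_images",
    "apply_augmentation",
    "verify_no_leakage",
    "write_split_csv",
    "read_split_csv",
    "write_folds_csv",
    "read_folds_csv",
]

PARTITIONS = ("train", "val", "test")


@dataclass(frozen=True)
class SplitManifest:
    assignment: dict  # animal_id -> "train" | "val" | "test"
    ratios: tuple
    seed: int

    def animals(self, partition: str) -> list[str]:
        return sorted(a for a, p in self.assignment.items() if p == partition)

    def counts(self) -> tuple[int, int, int]:
        return tuple(len(self.animals(p)) for p in PARTITIONS)


@dataclass(frozen=True)
class FoldManifest:
    assignment: dict  # animal_id -> fold index
    k: int

    def fold(self, index: int) -> list[str]:
        return sorted(a for a, f in self.assignment.items() if f == index)


@dataclass(frozen=True)
class AugSuite:
    """Augmentation parameters: stochastic knobs plus the deterministic
    5-variant materialization suite (original, horizontal flip, +/- rotation,
    brightness increase)."""

    flip_prob: float = 0.5
    rotation_deg: float = 8.0
    brightness_delta: float = 0.2
    fixed_variants: tuple = ("original", "hflip", "rot+", "rot-", "bright+")

    def __post_init__(self):
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValidationError("flip_prob must be a probability")


@dataclass(frozen=True)
class LeakReport:
    cross_partition: list = field(default_factory=list)  # animal ids
    augmentation_leaks: list = field(default_factory=list)  # image filenames

    @property
    def n_violations(self) -> int:
        return len(self.cross_partition) + len(self.augmentation_leaks)

    @property
    def clean(self) -> bool:
        return self.n_violations == 0


def partition_animals(
    ids: list[str], ratios: tuple = (0.70, 0.15, 0.15), seed: int = 42
) -> SplitManifest:
    """Shuffle animals deterministically and cut train/val/test.

    Counts follow floor(train) / ceil(val) / remainder; with 156 animals at
    70/15/15 this yields 109/24/23.
    """
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate animal ids")
    n = len(ids)
    if n < 3:
        raise ValidationError("need at least 3 animals to split")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValidationError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.ceil(ratios[1] * n))
    if n_train + n_val > n:
        raise ValidationError("degenerate ratios leave no animals for test")
    assignment = {}
    for i, a in enumerate(order):
        if i < n_train:
            assignment[a] = "train"
        elif i < n_train + n_val:
            assignment[a] = "val"
        else:
            assignment[a] = "test"
    return SplitManifest(assignment=assignment, ratios=tuple(ratios), seed=seed)


def assign_folds(ids: list[str], k: int, seed: int = 42) -> FoldManifest:
    """Deterministic shuffle then round-robin; fold sizes differ by <= 1."""
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate animal ids")
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > len(ids):
        raise ValidationError("k may not exceed the number of animals")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    return FoldManifest(assignment={a: i % k for i, a in enumerate(order)}, k=k)


def _border_fill(img: np.ndarray) -> float:
    border = np.concatenate([img[0].ravel(), img[-1].ravel(), img[:, 0].ravel(), img[:, -1].ravel()])
    return float(np.median(border))


def apply_augmentation(sample: ImageSample, variant: str, suite: AugSuite) -> ImageSample:
    """One deterministic variant of one image; rotation corners are filled
    with the (median) background colour, brightness is multiplicative."""
    img = sample.pixels
    if variant == "original":
        out = img
    elif variant == "hflip":
        out = img[:, ::-1]
    elif variant in ("rot+", "rot-"):
        angle = suite.rotation_deg if variant == "rot+" else -suite.rotation_deg
        out = ndimage.rotate(
            img, angle, axes=(1, 0), reshape=False, order=1,
            mode="constant", cval=_border_fill(img),
        )
    elif variant == "bright+":
        out = img * (1.0 + suite.brightness_delta)
    elif variant == "bright-":
        out = img * (1.0 - suite.brightness_delta)
    else:
        raise ValidationError(f"unknown augmentation variant {variant!r}")
    return replace(sample, augtag=variant, pixels=np.clip(np.ascontiguousarray(out), 0.0, 1.0))


def augment_training_images(
    samples: list[ImageSample], suite: AugSuite | None = None
) -> list[ImageSample]:
    """Materialize the fixed variant suite: |fixed_variants| images per input."""
    suite = suite or AugSuite()
    for s in samples:
        if s.augtag != "original":
            raise ValidationError(
                f"refusing to augment already-augmented image {s.filename}"
            )
    return [apply_augmentation(s, v, suite) for s in samples for v in suite.fixed_variants]


def stochastic_augment(
    sample: ImageSample, suite: AugSuite, rng: np.random.Generator
) -> ImageSample:
    """On-the-fly training-time augmentation: random flip, rotation in
    [-rotation_deg, +rotation_deg], brightness factor in 1 +/- delta."""
    img = sample.pixels
    if rng.random() < suite.flip_prob:
        img = img[:, ::-1]
    angle = rng.uniform(-suite.rotation_deg, suite.rotation_deg)
    img = ndimage.rotate(
        img, angle, axes=(1, 0), reshape=False, order=1,
        mode="constant", cval=_border_fill(img),
    )
    img = img * (1.0 + rng.uniform(-suite.brightness_delta, suite.brightness_delta))
    return replace(sample, augtag="stochastic", pixels=np.clip(np.ascontiguousarray(img), 0.0, 1.0))


def verify_no_leakage(
    split: SplitManifest,
    images: list[tuple[ImageSample, str]],
) -> LeakReport:
    """Check an assembled image set against its split manifest.

    ``images`` pairs each image with the partition it was placed in.  Flags
    (a) any animal whose images span more than one partition or contradict
    the manifest, and (b) any augmented image outside the training set.
    """
    seen: dict[str, set] = {}
    aug_leaks = []
    for sample, partition in images:
        if sample.animal_id not in split.assignment:
            raise ValidationError(f"unknown animal {sample.animal_id!r}")
        seen.setdefault(sample.animal_id, set()).add(partition)
        if sample.augtag != "original" and partition != "train":
            aug_leaks.append(sample.filename)
    cross = sorted(
        a for a, parts in seen.items()
        if len(parts) > 1 or next(iter(parts)) != split.assignment[a]
    )
    return LeakReport(cross_partition=cross, augmentation_leaks=sorted(aug_leaks))


# -- manifest round trips ---------------------------------------------------

def write_split_csv(manifest: SplitManifest, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(manifest.assignment.items()), columns=["animal_id", "partition"]
    )
    df.attrs = {}
    header = f"# ratios={','.join(str(r) for r in manifest.ratios)} seed={manifest.seed}\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_split_csv(path: str | Path) -> SplitManifest:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("# ratios="):
            raise ValidationError(f"{path}: line 1: missing split header")
        meta = dict(part.split("=") for part in header[2:].split())
        df = pd.read_csv(fh)
    _check_manifest_frame(df, path)
    return SplitManifest(
        assignment=dict(zip(df.animal_id.astype(str), df.partition)),
        ratios=tuple(float(r) for r in meta["ratios"].split(",")),
        seed=int(meta["seed"]),
    )


def write_folds_csv(manifest: FoldManifest, path: str | Path) -> None:
    df = pd.DataFrame(sorted(manifest.assignment.items()), columns=["animal_id", "fold"])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# k={manifest.k}\n")
        df.to_csv(fh, index=False)


def read_folds_csv(path: str | Path) -> FoldManifest:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("# k="):
            raise ValidationError(f"{path}: line 1: missing fold header")
        df = pd.read_csv(fh)
    _check_manifest_frame(df, path)
    return FoldManifest(
        assignment=dict(zip(df.animal_id.astype(str), df.fold.astype(int))),
        k=int(header.strip().split("=")[1]),
    )


def _check_manifest_frame(df: pd.DataFrame, path) -> None:
    dup = df.animal_id.duplicated()
    if dup.any():
        # +3: header comment, column row, 1-based
        line = int(np.flatnonzero(dup.values)[0]) + 3
        raise ValidationError(f"{path}: line {line}: duplicated animal row")


# -- array assembly ---------------------------------------------------------

@dataclass(frozen=True)
class ArrayDataset:
    """Paired-view arrays ready for the fusion models.

    dorsal/lateral: (N, 3, H, W) channel-normalized images; tabular:
    (N, 4) scaled BCS + size one-hot; y: (N, 4) targets in kg.  One row per
    (animal, augmentation-variant) pair; the two views share the variant.
    """

    dorsal: np.ndarray
    lateral: np.ndarray
    tabular: np.ndarray
    y: np.ndarray
    animal_ids: tuple
    augtags: tuple

    def __len__(self) -> int:
        return len(self.animal_ids)

    def subset(self, animals) -> "ArrayDataset":
        wanted = set(animals)
        idx = [i for i, a in enumerate(self.animal_ids) if a in wanted]
        return ArrayDataset(
            dorsal=self.dorsal[idx], lateral=self.lateral[idx],
            tabular=self.tabular[idx], y=self.y[idx],
            animal_ids=tuple(self.animal_ids[i] for i in idx),
            augtags=tuple(self.augtags[i] for i in idx),
        )


def normalize_image(pixels: np.ndarray, mean=None, sd=None) -> np.ndarray:
    """(H, W, 3) in [0,1] -> channel-normalized (3, H, W)."""
    from .models import IMAGENET_MEAN, IMAGENET_SD

    mean = IMAGENET_MEAN if mean is None else np.asarray(mean)
    sd = IMAGENET_SD if sd is None else np.asarray(sd)
    return ((pixels - mean) / sd).transpose(2, 0, 1)


def build_arrays(flock, render_config=None, seed: int = 0, animals=None,
                 augment: AugSuite | None = None) -> ArrayDataset:
    """Render and assemble a flock (or a subset) into model-ready arrays.

    With `augment` set, each animal contributes one row per fixed variant
    (the two views receive the same variant); otherwise one original row.
    """
    from .models import encode_tabular_raw
    from .synth import RenderConfig, render_animal

    cfg = render_config or RenderConfig()
    wanted = None if animals is None else set(animals)
    dorsal, lateral, tabular, y, ids, tags = [], [], [], [], [], []
    for ph in flock:
        if wanted is not None and ph.animal_id not in wanted:
            continue
        d = render_animal(ph, "dorsal", cfg, seed)
        l = render_animal(ph, "lateral", cfg, seed)
        variants = augment.fixed_variants if augment else ("original",)
        for v in variants:
            dv = apply_augmentation(d, v, augment) if augment else d
            lv = apply_augmentation(l, v, augment) if augment else l
            dorsal.append(normalize_image(dv.pixels))
            lateral.append(normalize_image(lv.pixels))
            tabular.append(encode_tabular_raw(ph.bcs, ph.size_category))
            y.append([ph.live_weight, ph.carcass_weight, ph.fat_mass, ph.lean_mass])
            ids.append(ph.animal_id)
            tags.append(v)
    return ArrayDataset(
        dorsal=np.asarray(dorsal), lateral=np.asarray(lateral),
        tabular=np.asarray(tabular), y=np.asarray(y),
        animal_ids=tuple(ids), augtags=tuple(tags),
    )
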