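"""Patch containers, file I/O and batch sampling.

The unit flowing through every network is an :class:`RGBPatch`: an
H x W x 3 float array with an explicit value-range tag. The canonical
in-memory range is signed [-1, 1] (matching the generators' tanh
output); byte [0, 255] and unit [0, 1] exist only at I/O boundaries.
Grayscale input is rejected rather than broadcast — the whole premise
of color-style transfer is three-channel input.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

PATCH_EXTENSIONS = (".png", ".tif", ".tiff")


class RangeTag(str, enum.Enum):
    UNIT = "unit"      # [0, 1]
    SIGNED = "signed"  # [-1, 1]
    BYTE = "byte"      # [0, 255]


_BOUNDS = {RangeTag.UNIT: (0.0, 1.0), RangeTag.SIGNED: (-1.0, 1.0), RangeTag.BYTE: (0.0, 255.0)}


class Domain(str, enum.Enum):
    A = "A"
    B = "B"


class Split(str, enum.Enum):
    CLASSIFIER_PRETRAIN = "pretrain"
    CYCLEGAN_TRAIN = "train"
    TEST = "test"


@dataclasses.dataclass
class RGBPatch:
    pixels: np.ndarray  # H x W x 3 float64
    range_tag: RangeTag = RangeTag.SIGNED
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"patch must be HxWx3 RGB, got shape {self.pixels.shape} "
                f"(grayscale input is rejected, not broadcast)")
        lo, hi = _BOUNDS[self.range_tag]
        if self.pixels.min() < lo - 1e-9 or self.pixels.max() > hi + 1e-9:
            raise ValueError(
                f"pixel values [{self.pixels.min():.4g}, {self.pixels.max():.4g}] "
                f"outside declared range '{self.range_tag.value}' ({lo}, {hi})")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def to_range(self, tag: RangeTag) -> "RGBPatch":
        if tag == self.range_tag:
            return RGBPatch(self.pixels.copy(), tag, self.source_id)
        unit = _to_unit(self.pixels, self.range_tag)
        return RGBPatch(_from_unit(unit, tag), tag, self.source_id)


def _to_unit(px: np.ndarray, tag: RangeTag) -> np.ndarray:
    if tag == RangeTag.UNIT:
        return px
    if tag == RangeTag.SIGNED:
        return (px + 1.0) / 2.0
    return px / 255.0


def _from_unit(px: np.ndarray, tag: RangeTag) -> np.ndarray:
    if tag == RangeTag.UNIT:
        return px
    if tag == RangeTag.SIGNED:
        return px * 2.0 - 1.0
    return px * 255.0


@dataclasses.dataclass
class DomainDataset:
    patches: list[RGBPatch]
    domain: Domain
    split: Split = Split.CYCLEGAN_TRAIN

    def __post_init__(self):
        if self.patches:
            tag = self.patches[0].range_tag
            shape = self.patches[0].shape
            for p in self.patches:
                if p.range_tag != tag:
                    raise ValueError("mixed range tags within a dataset")
                if p.shape != shape:
                    raise ValueError("mixed patch shapes within a dataset")

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def __getitem__(self, i: int) -> RGBPatch:
        return self.patches[i]

    def as_array(self) -> np.ndarray:
        """Stack into an NCHW array (network layout)."""
        return np.stack([p.pixels.transpose(2, 0, 1) for p in self.patches])


def read_patch(path, range_tag: RangeTag = RangeTag.SIGNED) -> RGBPatch:
    path = Path(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        raise ValueError(f"{path.name}: grayscale images are not supported")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]  # drop alpha
    if arr.dtype == np.uint16:
        byte = arr.astype(np.float64) / 257.0
    else:
        byte = arr.astype(np.float64)
    patch = RGBPatch(byte, RangeTag.BYTE, source_id=path.stem)
    return patch.to_range(range_tag)


def write_patch(path, patch: RGBPatch) -> None:
    """Write as 8-bit PNG/TIFF; byte round-trips are lossless."""
    byte = patch.to_range(RangeTag.BYTE).pixels
    iio.imwrite(Path(path), np.clip(np.rint(byte), 0, 255).astype(np.uint8))


def load_domain_dataset(dir_path, domain: Domain | str,
                        range_tag: RangeTag | str = RangeTag.SIGNED,
                        split: Split | str = Split.CYCLEGAN_TRAIN,
                        min_size: int = 16, divisor: int = 1) -> DomainDataset:
    """Load every PNG/TIFF patch in a directory, lexicographic by filename.

    ``divisor`` is the generator's ``2**depth``; patch sides must be
    divisible by it (and be at least ``min_size``), enforced at load time.
    """
    dir_path = Path(dir_path)
    domain = Domain(domain)
    range_tag = RangeTag(range_tag)
    split = Split(split)
    files = sorted(p for p in dir_path.iterdir()
                   if p.suffix.lower() in PATCH_EXTENSIONS) if dir_path.is_dir() else []
    if not files:
        raise FileNotFoundError(f"no patches (PNG/TIFF) found in {dir_path}")
    patches = [read_patch(f, range_tag) for f in files]
    shapes = {p.shape for p in patches}
    if len(shapes) > 1:
        ref = patches[0].shape
        offenders = [p.source_id for p in patches if p.shape != ref]
        raise ValueError(f"mixed patch sizes in {dir_path}: expected {ref}, "
                         f"offenders: {offenders}")
    H, W, _ = patches[0].shape
    if H < min_size or W < min_size:
        raise ValueError(f"patches {H}x{W} smaller than minimum {min_size}")
    if H % divisor or W % divisor:
        raise ValueError(f"patch sides {H}x{W} not divisible by {divisor}")
    return DomainDataset(patches, domain, split)


def save_domain_dataset(dir_path, ds: DomainDataset) -> None:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    width = len(str(max(len(ds) - 1, 1)))
    for i, patch in enumerate(ds):
        name = patch.source_id or f"patch_{i:0{width}d}"
        write_patch(dir_path / f"{name}.png", patch)


def sample_batch(ds: DomainDataset, n: int, seed: int) -> list[RGBPatch]:
    """Seeded batch: without replacement when n <= |ds|, with otherwise."""
    if n < 1:
        raise ValueError("batch size must be >= 1")
    if len(ds) == 0:
        raise ValueError("cannot sample from an empty dataset")
    rng = np.random.default_rng(seed)
    replace = n > len(ds)
    idx = rng.choice(len(ds), size=n, replace=replace)
    return [ds[int(i)] for i in idx]


def patches_to_batch(patches: Sequence[RGBPatch]) -> np.ndarray:
    return np.stack([p.pixels.transpose(2, 0, 1) for p in patches])


def batch_to_patches(batch: np.ndarray, range_tag: RangeTag = RangeTag.SIGNED,
                     source_ids: Iterable[str] | None = None) -> list[RGBPatch]:
    ids = list(source_ids) if source_ids is not None else [""] * len(batch)
    return [RGBPatch(img.transpose(1, 2, 0), range_tag, sid)
            for img, sid in zip(batch, ids)]
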