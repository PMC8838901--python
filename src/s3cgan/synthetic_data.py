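"""Two-style synthetic histology fixtures.

Generates patch collections that share tissue-like structure statistics
(elliptical nuclei scattered over a smooth stromal texture) but are
rendered under two distinct color styles, emulating the two-lab /
two-scanner situation stain-transfer methods are built for. Rendering
follows Beer-Lambert optics: each of the two density maps (nuclear,
stromal) attenuates RGB light exponentially through a per-style stain
matrix,

    RGB = background * exp(-(S^T . densities)) + noise,

so the two styles differ in the *direction* of their stain vectors, not
merely in brightness — per-channel mean matching cannot align them,
which leaves the generative model something nontrivial to learn.

The same structure rendered under both styles forms a ground-truth pair
for SSIM/PSNR evaluation, and each structure carries a binary density
label (many nuclei vs few) standing in for tumor/non-tumor annotation
in downstream-classifier experiments.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_data import Domain, DomainDataset, RangeTag, RGBPatch, Split

DEFAULT_NUCLEI_RANGE = (2, 14)


@dataclasses.dataclass
class StyleSpec:
    """Maps (nuclear, stromal) densities to an RGB rendering."""
    stain_matrix: np.ndarray   # 2 x 3: rows = per-stain RGB attenuation
    background_tint: np.ndarray  # 3-vector, unit range
    noise_sd: float = 0.01
    name: str = "style"

    def __post_init__(self):
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=np.float64)
        self.background_tint = np.asarray(self.background_tint, dtype=np.float64)
        if self.stain_matrix.shape != (2, 3):
            raise ValueError("stain_matrix must be 2x3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_styles() -> tuple[StyleSpec, StyleSpec]:
    """The two shipped styles: an H&E-like pair with rotated stain vectors.

    Style A: blue-purple nuclei on a pink stroma under a warm white
    background; style B: the same tissue chemistry as seen through a
    different scanner/reagent combination — nuclei darker and more
    cyan, stroma more orange, background cooler.
    """
    style_a = StyleSpec(
        stain_matrix=np.array([[0.85, 0.95, 0.25],    # nuclear: absorbs R,G -> blue-violet
                               [0.10, 0.55, 0.25]]),  # stromal: absorbs G -> pink
        background_tint=np.array([0.98, 0.96, 0.95]),
        noise_sd=0.01, name="style_A")
    style_b = StyleSpec(
        stain_matrix=np.array([[0.30, 0.75, 0.95],    # nuclear: absorbs G,B -> warm dark
                               [0.45, 0.30, 0.05]]),  # stromal: absorbs R -> teal-ish
        background_tint=np.array([0.90, 0.94, 0.99]),
        noise_sd=0.01, name="style_B")
    return style_a, style_b


@dataclasses.dataclass
class StructureField:
    nuclear_density: np.ndarray  # H x W in [0, 1]
    stromal_density: np.ndarray  # H x W in [0, 1]
    n_nuclei: int
    label: int  # 1 = high-density ("tumor-like")
    structure_id: str = ""


@dataclasses.dataclass
class PairedFixture:
    """One structure rendered under both styles — evaluation ground truth."""
    structure: StructureField
    patch_a: RGBPatch
    patch_b: RGBPatch
    label: int


def sample_structure(size: int, nuclei_range: tuple[int, int] = DEFAULT_NUCLEI_RANGE,
                     seed: int = 0, label_threshold: int | None = None) -> StructureField:
    """Random ellipse field plus smooth stromal texture, all in [0, 1]."""
    if size < 32:
        raise ValueError("structure size must be >= 32")
    lo, hi = nuclei_range
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid nuclei_range {nuclei_range}")
    if label_threshold is None:
        label_threshold = (lo + hi) // 2  # median of the range
    rng = np.random.default_rng(seed)
    n_nuclei = int(rng.integers(lo, hi + 1))

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    nuclear = np.zeros((size, size))
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(2, size - 2, size=2)
        a = rng.uniform(size * 0.03, size * 0.09)  # semi-axes
        b = rng.uniform(size * 0.03, size * 0.09)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        r2 = (u / a) ** 2 + (v / b) ** 2
        nuclear += np.clip(1.2 - r2, 0.0, 1.0)
    nuclear = np.clip(nuclear, 0.0, 1.0)

    stroma = rng.normal(size=(size, size))
    stroma = gaussian_filter(stroma, sigma=size / 12.0, mode="wrap")
    lo_s, hi_s = stroma.min(), stroma.max()
    stroma = (stroma - lo_s) / (hi_s - lo_s + 1e-12) * 0.6 + 0.15

    return StructureField(nuclear_density=nuclear, stromal_density=stroma,
                          n_nuclei=n_nuclei, label=int(n_nuclei > label_threshold),
                          structure_id=f"s{seed}")


def render(structure: StructureField, style: StyleSpec, seed: int = 0,
           range_tag: RangeTag = RangeTag.SIGNED) -> RGBPatch:
    """Beer-Lambert rendering of a structure under one style."""
    densities = np.stack([structure.nuclear_density, structure.stromal_density], axis=-1)
    od = densities @ style.stain_matrix  # H x W x 3 optical density
    rgb = style.background_tint[None, None, :] * np.exp(-od)
    if style.noise_sd > 0:
        rng = np.random.default_rng(seed)
        rgb = rgb + rng.normal(0.0, style.noise_sd, size=rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)
    patch = RGBPatch(rgb, RangeTag.UNIT,
                     source_id=f"{structure.structure_id}_{style.name}")
    return patch.to_range(range_tag)


def make_fixture_set(n_per_domain: int = 200, size: int = 64, seed: int = 0,
                     n_paired: int = 20, n_pretrain: int | None = None,
                     nuclei_range: tuple[int, int] = DEFAULT_NUCLEI_RANGE,
                     styles: tuple[StyleSpec, StyleSpec] | None = None) -> dict:
    """Build the full two-domain fixture suite.

    The adversarial-training domains A and B use *disjoint* structure
    sets (the data is unpaired, as cycle-consistent training assumes);
    the classifier-pretraining split is disjoint from both; the paired
    test set is built from further held-out structures rendered under
    both styles.

    Returns a dict with keys ``ds_a``, ``ds_b`` (training splits),
    ``pre_a``, ``pre_b`` (classifier pretraining splits) and
    ``paired_test`` (list of :class:`PairedFixture`).
    """
    if n_per_domain < 2:
        raise ValueError("need at least 2 patches per domain")
    if n_pretrain is None:
        n_pretrain = n_per_domain
    style_a, style_b = styles or default_styles()
    base = np.random.default_rng(seed).integers(0, 2 ** 31 - 1)

    def build(count: int, style: StyleSpec, block: int, split: Split,
              domain: Domain) -> DomainDataset:
        patches = []
        for i in range(count):
            s = int((base + block * 1_000_003 + i) % (2 ** 31 - 1))
            struct = sample_structure(size, nuclei_range, seed=s)
            patches.append(render(struct, style, seed=s + 17))
        return DomainDataset(patches, domain, split)

    ds_a = build(n_per_domain, style_a, 0, Split.CYCLEGAN_TRAIN, Domain.A)
    ds_b = build(n_per_domain, style_b, 1, Split.CYCLEGAN_TRAIN, Domain.B)
    pre_a = build(n_pretrain, style_a, 2, Split.CLASSIFIER_PRETRAIN, Domain.A)
    pre_b = build(n_pretrain, style_b, 3, Split.CLASSIFIER_PRETRAIN, Domain.B)

    paired = []
    for i in range(n_paired):
        s = int((base + 4 * 1_000_003 + i) % (2 ** 31 - 1))
        struct = sample_structure(size, nuclei_range, seed=s)
        pa = render(struct, style_a, seed=s + 29)
        pb = render(struct, style_b, seed=s + 31)
        paired.append(PairedFixture(struct, pa, pb, struct.label))

    return {"ds_a": ds_a, "ds_b": ds_b, "pre_a": pre_a, "pre_b": pre_b,
            "paired_test": paired, "styles": (style_a, style_b)}


def make_labeled_set(n: int, size: int, style: StyleSpec, seed: int,
                     nuclei_range: tuple[int, int] = DEFAULT_NUCLEI_RANGE) -> tuple[DomainDataset, np.ndarray]:
    """Patches of one style plus binary density labels (downstream protocol)."""
    rng = np.random.default_rng(seed)
    patches, labels = [], []
    for i in range(n):
        s = int(rng.integers(0, 2 ** 31 - 1))
        struct = sample_structure(size, nuclei_range, seed=s)
        patches.append(render(struct, style, seed=s + 13))
        labels.append(struct.label)
    domain = Domain.A if "A" in style.name else Domain.B
    return DomainDataset(patches, domain, Split.TEST), np.asarray(labels, dtype=int)
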