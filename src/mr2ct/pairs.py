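"""Pointwise MRI-CT intensity pairs, phantom templates, and patch datasets.

Registered MRI/CT volumes are never fed to the conversion network directly:
residual registration error (breathing, organ distortion) would corrupt the
training signal.  Instead, per axial slice and tissue class, voxels inside
the class mask are sorted by MRI intensity and a fixed number of
(MRI intensity, CT HU) pairs is read off at evenly spaced rank positions —
25 per slice for lung and fat, 50 for soft tissue, always including the
class minimum and maximum.  The soft-tissue pairs are split at the median
into low- and high-intensity halves, giving four groups: lung, soft-low,
soft-high, fat.

Each group is laid out as a *phantom template pair*: a block grid where
block b is constant at pair b's MRI intensity in the input image and at its
CT HU in the label image.  Random 32x32 crops of the input template, paired
with the centered 18x18 crops of the label template, form the network's
training substrate.  Any layout satisfying the pixel-wise invariant — every
pixel's (MRI, CT) value is one of the extracted pairs — trains the same
pointwise mapping, so the block geometry is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import AIR_LUNG, FAT, SOFT_TISSUE, TissueLabelMap, Volume

#: per-slice pair counts: 25 lung, 50 soft tissue, 25 fat
DEFAULT_COUNTS = {AIR_LUNG: 25, SOFT_TISSUE: 50, FAT: 25}

#: axial slices used for training / validation pair extraction (1-based
#: slice numbers 2,4,6,8 and 20 as printed -> 0-based internally)
DEFAULT_TRAINING_SLICES = [1, 3, 5, 7]
DEFAULT_VALIDATION_SLICES = [19]

TEMPLATE_KINDS = ("lung", "soft_low", "soft_high", "fat")


@dataclass
class IntensityPairSet:
    """Sorted (MRI a.u., CT HU) pairs tagged by tissue class and slice."""

    pairs: pd.DataFrame        # columns mri_au, ct_hu, tissue, slice
    role: str = "training"

    def __post_init__(self) -> None:
        required = {"mri_au", "ct_hu", "tissue", "slice"}
        if not required.issubset(self.pairs.columns):
            raise ValueError(f"pair table must have columns {sorted(required)}")

    def __len__(self) -> int:
        return len(self.pairs)

    def subset(self, tissue: int | None = None,
               slice_index: int | None = None) -> "IntensityPairSet":
        df = self.pairs
        if tissue is not None:
            df = df[df.tissue == tissue]
        if slice_index is not None:
            df = df[df["slice"] == slice_index]
        return IntensityPairSet(df.reset_index(drop=True), role=self.role)

    def to_csv(self, path) -> None:
        df = self.pairs.copy()
        df["role"] = self.role
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IntensityPairSet":
        df = pd.read_csv(path)
        role = df["role"].iloc[0] if "role" in df and len(df) else "training"
        return cls(df.drop(columns=["role"], errors="ignore"), role=str(role))


@dataclass
class PhantomTemplatePair:
    """Paired constant-block MRI/CT template images for one tissue group."""

    mri_image: np.ndarray
    ct_image: np.ndarray
    template_kind: str
    region_map: np.ndarray     # block index per pixel

    def __post_init__(self) -> None:
        if self.mri_image.shape != self.ct_image.shape:
            raise ValueError("template images must share a shape")
        if self.template_kind not in TEMPLATE_KINDS:
            raise ValueError(f"template_kind must be one of {TEMPLATE_KINDS}")


@dataclass
class PairedPatchSet:
    """N 32x32 input patches with centered 18x18 label patches."""

    inputs: np.ndarray         # (N, 32, 32)
    labels: np.ndarray         # (N, 18, 18)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inputs.ndim != 3 or self.labels.ndim != 3:
            raise ValueError("patch arrays must be (N, H, W)")
        if len(self.inputs) != len(self.labels) or len(self.inputs) == 0:
            raise ValueError("inputs and labels must be equal-length and non-empty")

    def __len__(self) -> int:
        return len(self.inputs)


def _even_rank_positions(m: int, n: int) -> np.ndarray:
    """n rank positions floor(j*(M-1)/(n-1)) evenly covering 0..M-1.

    Truncation keeps the positions deterministic and pins j=0 / j=n-1 to
    the exact minimum and maximum ranks.
    """
    if n == 1:
        return np.array([0])
    j = np.arange(n)
    return (j * (m - 1) // (n - 1)).astype(int)


def extract_pairs(mri: Volume, ct_registered: Volume, labels: TissueLabelMap,
                  slices: list[int] | None = None,
                  counts: dict[int, int] | None = None,
                  role: str = "training") -> IntensityPairSet:
    """Pick rank-evenly-spaced (MRI, CT) pairs per slice and tissue class.

    Voxels in each (slice, tissue) mask are sorted ascending by MRI
    intensity (ties broken by scan order); pairs are read at rank positions
    round(j*(M-1)/(n-1)), which always includes the minimum and maximum.  A
    mask with fewer than n voxels contributes all of them with a warning.
    """
    if mri.shape != ct_registered.shape or mri.shape != labels.shape:
        raise ValueError("MRI, CT and labels must share a grid")
    slices = DEFAULT_TRAINING_SLICES if slices is None else list(slices)
    counts = dict(DEFAULT_COUNTS if counts is None else counts)
    if any(s < 0 or s >= mri.n_slices for s in slices):
        raise ValueError(f"slice index out of range for {mri.n_slices} slices")

    rows = []
    for s in slices:
        for tissue, n in counts.items():
            mask = labels.labels[s] == tissue
            m = int(mask.sum())
            if m == 0:
                warnings.warn(f"empty tissue {tissue} mask on slice {s}; skipped")
                continue
            mri_vals = mri.data[s][mask]
            ct_vals = ct_registered.data[s][mask]
            order = np.argsort(mri_vals, kind="stable")   # ties: scan order
            if m < n:
                warnings.warn(f"tissue {tissue} slice {s}: only {m} voxels "
                              f"for {n} requested pairs; taking all")
                sel = order
            else:
                sel = order[_even_rank_positions(m, n)]
            for i in sel:
                rows.append((float(mri_vals[i]), float(ct_vals[i]), tissue, s))
    df = pd.DataFrame(rows, columns=["mri_au", "ct_hu", "tissue", "slice"])
    df = df.sort_values(["slice", "tissue", "mri_au"], kind="stable")
    return IntensityPairSet(df.reset_index(drop=True), role=role)


def split_soft_tissue(pairs: IntensityPairSet) -> tuple[IntensityPairSet,
                                                        IntensityPairSet]:
    """Split soft-tissue pairs per slice at the median rank into low/high.

    Odd counts put the extra pair in the low half.  The split is by rank,
    not value, so duplicate intensities still split evenly.
    """
    soft = pairs.pairs[pairs.pairs.tissue == SOFT_TISSUE]
    if soft.empty:
        raise ValueError("no soft-tissue pairs to split")
    low_parts, high_parts = [], []
    for s, grp in soft.groupby("slice"):
        grp = grp.sort_values("mri_au", kind="stable")
        n_low = (len(grp) + 1) // 2
        low_parts.append(grp.iloc[:n_low])
        high_parts.append(grp.iloc[n_low:])
    low = pd.concat(low_parts).reset_index(drop=True)
    high = pd.concat(high_parts).reset_index(drop=True)
    return (IntensityPairSet(low, role=pairs.role),
            IntensityPairSet(high, role=pairs.role))


@dataclass
class TemplateLayout:
    """Square block-grid geometry for phantom templates."""

    block_px: int = 40

    def __post_init__(self) -> None:
        if self.block_px < 34:
            raise ValueError("blocks must be >= 34 px so a 32x32 crop plus the "
                             "7-px label offset fits inside one block")


def build_template_pair(pairs: IntensityPairSet, kind: str,
                        layout: TemplateLayout | None = None) -> PhantomTemplatePair:
    """Lay pairs out as a square grid of constant blocks (sorted row-major).

    Surplus grid cells (when the pair count is not a perfect square) are
    filled by cycling through the pairs again.
    """
    layout = layout or TemplateLayout()
    df = pairs.pairs.sort_values("mri_au", kind="stable").reset_index(drop=True)
    n = len(df)
    if n < 1:
        raise ValueError("need at least one pair")
    grid = int(np.ceil(np.sqrt(n)))
    size = grid * layout.block_px
    mri_img = np.empty((size, size))
    ct_img = np.empty((size, size))
    region = np.empty((size, size), dtype=np.int32)
    b = layout.block_px
    for cell in range(grid * grid):
        i = cell % n
        r, c = divmod(cell, grid)
        sl = (slice(r * b, (r + 1) * b), slice(c * b, (c + 1) * b))
        mri_img[sl] = df.mri_au.iloc[i]
        ct_img[sl] = df.ct_hu.iloc[i]
        region[sl] = cell
    return PhantomTemplatePair(mri_image=mri_img, ct_image=ct_img,
                               template_kind=kind, region_map=region)


def build_all_templates(pairs: IntensityPairSet,
                        layout: TemplateLayout | None = None
                        ) -> list[PhantomTemplatePair]:
    """The four standard templates: lung, soft-low, soft-high, fat."""
    soft_low, soft_high = split_soft_tissue(pairs)
    groups = [
        (pairs.subset(tissue=AIR_LUNG), "lung"),
        (soft_low, "soft_low"),
        (soft_high, "soft_high"),
        (pairs.subset(tissue=FAT), "fat"),
    ]
    return [build_template_pair(g, kind, layout) for g, kind in groups]


PATCH_IN = 32
PATCH_OUT = 18
PATCH_OFFSET = (PATCH_IN - PATCH_OUT) // 2      # 7 px on each side


def crop_patches(templates: list[PhantomTemplatePair] | PhantomTemplatePair,
                 n_per_template: int, seed: int = 0) -> PairedPatchSet:
    """Uniform random 32x32 crops with centered 18x18 labels (seeded)."""
    if isinstance(templates, PhantomTemplatePair):
        templates = [templates]
    rng = np.random.default_rng(seed)
    inputs, labs = [], []
    for tp in templates:
        h, w = tp.mri_image.shape
        if h < PATCH_IN or w < PATCH_IN:
            raise ValueError(f"template {tp.template_kind} smaller than "
                             f"{PATCH_IN}x{PATCH_IN}")
        rs = rng.integers(0, h - PATCH_IN + 1, size=n_per_template)
        cs = rng.integers(0, w - PATCH_IN + 1, size=n_per_template)
        for r, c in zip(rs, cs):
            inputs.append(tp.mri_image[r:r + PATCH_IN, c:c + PATCH_IN])
            labs.append(tp.ct_image[r + PATCH_OFFSET:r + PATCH_OFFSET + PATCH_OUT,
                                    c + PATCH_OFFSET:c + PATCH_OFFSET + PATCH_OUT])
    return PairedPatchSet(inputs=np.stack(inputs), labels=np.stack(labs),
                          seed=seed)
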