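"""Digital torso phantoms with known ground truth.

Generates paired MRI/CT volumes whose axial geometry mimics torso anatomy —
an elliptical body with a subcutaneous fat ring, soft-tissue interior, and
air cavities (two lungs for the chest preset, a bowel-gas pocket for the
abdomen preset) — together with the exact tissue label map, the smooth
multiplicative bias field applied to the MRI, and the clean (bias- and
noise-free) MRI.  Every quantity the normalization and synthesis pipeline
estimates therefore has a known truth to compare against.

The two presets reproduce the intensity regimes of a 0.35 T torso
acquisition (chest) and a 1.5 T diagnostic acquisition (abdomen): abdomen
MRI levels are roughly twice the chest levels, which exercises the
inter-scanner harmonization property of the shading-map normalization.
Ellipse radii drift slowly (±5 %) across slices so per-slice statistics are
non-trivial.

No MR physics is simulated — tissue classes are piecewise-constant levels
with a multiplicative bias and additive noise.  See docs/methods.md for
what this does and does not validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import AIR_LUNG, FAT, SOFT_TISSUE, Modality, TissueLabelMap, Volume

#: MRI tissue levels (a.u.) emulating the uncorrected per-tissue means of a
#: 0.35 T chest scan and a 1.5 T abdominal scan.
CHEST_MRI_LEVELS = {AIR_LUNG: 26.0, SOFT_TISSUE: 125.0, FAT: 297.0}
ABDOMEN_MRI_LEVELS = {AIR_LUNG: 65.0, SOFT_TISSUE: 298.0, FAT: 533.0}

#: CT tissue levels (HU) matching real-CT per-tissue means for the torso.
CHEST_HU_LEVELS = {AIR_LUNG: -800.0, SOFT_TISSUE: 35.0, FAT: -108.0}
ABDOMEN_HU_LEVELS = {AIR_LUNG: -822.0, SOFT_TISSUE: 32.0, FAT: -86.0}


@dataclass
class BiasSpec:
    """Multiplicative bias-field description.

    kind:
        "gaussian_blobs" — 1 + sum of signed Gaussian bumps, renormalized;
        "linear_ramp"    — spans [1-amplitude, 1+amplitude] along one axis;
        "none"           — all-ones field.
    amplitude:
        Peak deviation from 1; must stay in [0, 1) so the field is positive.
    length_scale:
        Bump s.d. in pixels; should be much larger than the smoothing width
        of the shading-map estimator for the field to be recoverable.
    """

    kind: str = "gaussian_blobs"
    amplitude: float = 0.3
    length_scale: float = 40.0
    n_blobs: int = 4
    axis: int = 2            # ramp axis for linear_ramp

    def __post_init__(self) -> None:
        if self.kind not in {"gaussian_blobs", "linear_ramp", "none"}:
            raise ValueError(f"unknown bias kind {self.kind!r}")
        if not 0 <= self.amplitude < 1:
            raise ValueError("amplitude must be in [0, 1)")


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (24, 256, 256)
    spacing: tuple[float, float, float] = (3.0, 1.5, 1.5)
    preset: str = "chest"
    tissue_mri_levels: dict[int, float] | None = None
    tissue_hu_levels: dict[int, float] | None = None
    bias: BiasSpec = field(default_factory=BiasSpec)
    noise_sd: float = 5.0
    noise_kind: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in {"chest", "abdomen"}:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.tissue_mri_levels is None:
            self.tissue_mri_levels = dict(
                CHEST_MRI_LEVELS if self.preset == "chest" else ABDOMEN_MRI_LEVELS)
        if self.tissue_hu_levels is None:
            self.tissue_hu_levels = dict(
                CHEST_HU_LEVELS if self.preset == "chest" else ABDOMEN_HU_LEVELS)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PhantomTruth:
    """A phantom plus everything the pipeline would have to estimate."""

    mri: Volume
    ct: Volume
    labels: TissueLabelMap
    bias_field: Volume
    clean_mri: Volume
    config: PhantomConfig


def _ellipse_mask(rows: int, cols: int, center: tuple[float, float],
                  radii: tuple[float, float]) -> np.ndarray:
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    return ((r - center[0]) / radii[0]) ** 2 + ((c - center[1]) / radii[1]) ** 2 <= 1.0


def _slice_labels(rows: int, cols: int, preset: str, wobble: float) -> np.ndarray:
    """One axial slice of tissue labels; wobble scales all radii (±5 %)."""
    cy, cx = rows / 2.0, cols / 2.0
    body_ry = 0.38 * rows * wobble
    body_rx = 0.44 * cols * wobble
    if min(body_ry, body_rx) < 8:
        raise ValueError("grid too small for torso geometry")
    if 2 * body_ry > rows or 2 * body_rx > cols:
        raise ValueError("body larger than grid")

    labels = np.zeros((rows, cols), dtype=np.int32)        # exterior air
    body = _ellipse_mask(rows, cols, (cy, cx), (body_ry, body_rx))
    inner = _ellipse_mask(rows, cols, (cy, cx), (0.90 * body_ry, 0.90 * body_rx))
    labels[body] = FAT                                      # outer 10 % ring
    labels[inner] = SOFT_TISSUE

    if preset == "chest":
        for sign in (-1, 1):
            lung = _ellipse_mask(
                rows, cols,
                (cy - 0.05 * body_ry, cx + sign * 0.45 * body_rx),
                (0.50 * body_ry, 0.30 * body_rx))
            labels[lung & inner] = AIR_LUNG
    else:  # abdomen: small bowel-gas pocket
        gas = _ellipse_mask(rows, cols,
                            (cy + 0.30 * body_ry, cx - 0.25 * body_rx),
                            (0.12 * body_ry, 0.15 * body_rx))
        labels[gas & inner] = AIR_LUNG
    return labels


def make_bias_field(shape: tuple[int, int, int], spec: BiasSpec,
                    seed: int = 0) -> Volume:
    """Strictly positive smooth field with spatial mean renormalized to 1."""
    ns, nr, nc = shape
    if spec.kind == "none" or spec.amplitude == 0:
        return Volume(np.ones(shape), modality=Modality.MAP, units="ratio")

    if spec.kind == "linear_ramp":
        ramp = np.linspace(1 - spec.amplitude, 1 + spec.amplitude, shape[spec.axis])
        idx = [None, None, None]
        idx[spec.axis] = slice(None)
        fld = np.ones(shape) * ramp[tuple(idx)]
    else:  # gaussian_blobs
        rng = np.random.default_rng(seed)
        r = np.arange(nr)[:, None]
        c = np.arange(nc)[None, :]
        bumps_2d = np.zeros((nr, nc))
        for i in range(spec.n_blobs):
            center = rng.uniform([0.2 * nr, 0.2 * nc], [0.8 * nr, 0.8 * nc])
            s = spec.length_scale * rng.uniform(0.8, 1.25)
            a = spec.amplitude * rng.uniform(0.5, 1.0) * (-1 if i % 2 else 1)
            bumps_2d += a * np.exp(-((r - center[0]) ** 2 + (c - center[1]) ** 2)
                                   / (2 * s * s))
        # peak-normalize so the field deviation is exactly ±amplitude
        peak = np.abs(bumps_2d).max()
        if peak > 0:
            bumps_2d *= spec.amplitude / max(peak, spec.amplitude)
        # slow longitudinal modulation keeps slices distinct but smooth
        z_mod = 1.0 + 0.1 * np.sin(np.linspace(0, np.pi, ns))
        fld = 1.0 + z_mod[:, None, None] * bumps_2d[None, :, :]

    fld /= fld.mean()
    if np.any(fld <= 0):
        raise ValueError("bias field not strictly positive; reduce amplitude")
    assert abs(fld.mean() - 1.0) < 1e-3
    return Volume(fld, modality=Modality.MAP, units="ratio")


def add_noise(vol: Volume, sd: float, kind: str = "gaussian",
              seed: int = 0) -> Volume:
    """Seeded additive Gaussian or Rician noise.

    Rician noise models magnitude MRI: two independent Gaussian channels of
    the given sd, so a zero-signal background acquires mean sd*sqrt(pi/2).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return vol.copy_with(vol.data.copy())
    rng = np.random.default_rng(seed)
    if kind == "gaussian":
        noisy = vol.data + rng.normal(0.0, sd, vol.shape)
    elif kind == "rician":
        n1 = rng.normal(0.0, sd, vol.shape)
        n2 = rng.normal(0.0, sd, vol.shape)
        noisy = np.sqrt((vol.data + n1) ** 2 + n2**2)
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    return vol.copy_with(noisy)


def make_torso_phantom(cfg: PhantomConfig | None = None) -> PhantomTruth:
    """Build a paired MRI/CT torso phantom with full ground truth."""
    cfg = cfg or PhantomConfig()
    ns, nr, nc = cfg.shape
    rng = np.random.default_rng(cfg.seed)
    phase = rng.uniform(0, 2 * np.pi)

    labels = np.empty(cfg.shape, dtype=np.int32)
    for s in range(ns):
        # slow ±5 % breathing-like drift of the outline across slices
        wobble = 1.0 + (0.05 * np.sin(2 * np.pi * s / max(ns, 2) + phase)
                        if ns > 1 else 0.0)
        labels[s] = _slice_labels(nr, nc, cfg.preset, wobble)
    label_map = TissueLabelMap(labels=labels, spacing=cfg.spacing)

    mri_table = np.array([cfg.tissue_mri_levels[i] for i in (0, 1, 2)])
    hu_table = np.array([cfg.tissue_hu_levels[i] for i in (0, 1, 2)])
    clean = Volume(mri_table[labels], spacing=cfg.spacing,
                   modality=Modality.MRI, units="a.u.")
    ct = Volume(hu_table[labels], spacing=cfg.spacing,
                modality=Modality.CT, units="HU")

    bias = make_bias_field(cfg.shape, cfg.bias, seed=cfg.seed + 1)
    bias = Volume(bias.data, spacing=cfg.spacing, modality=Modality.MAP,
                  units="ratio")
    biased = clean.copy_with(clean.data * bias.data)
    mri = add_noise(biased, cfg.noise_sd, kind=cfg.noise_kind,
                    seed=cfg.seed + 2)
    return PhantomTruth(mri=mri, ct=ct, labels=label_map, bias_field=bias,
                        clean_mri=clean, config=cfg)


def save_phantom(truth: PhantomTruth, out_dir: str | Path) -> dict:
    """Write mri/ct/labels/bias/clean as NIfTI plus a JSON truth manifest."""
    import json

    from .volume import write_labels, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in [("mri", truth.mri), ("ct", truth.ct),
                      ("bias", truth.bias_field), ("clean_mri", truth.clean_mri)]:
        p = out / f"{name}.nii.gz"
        write_volume(vol, p)
        paths[name] = str(p)
    p = out / "labels.nii.gz"
    write_labels(truth.labels, p)
    paths["labels"] = str(p)
    cfg = truth.config
    manifest = {
        "preset": cfg.preset,
        "shape": list(cfg.shape),
        "spacing": list(cfg.spacing),
        "tissue_mri_levels": {str(k): v for k, v in cfg.tissue_mri_levels.items()},
        "tissue_hu_levels": {str(k): v for k, v in cfg.tissue_hu_levels.items()},
        "bias": {"kind": cfg.bias.kind, "amplitude": cfg.bias.amplitude,
                 "length_scale": cfg.bias.length_scale},
        "noise_sd": cfg.noise_sd,
        "noise_kind": cfg.noise_kind,
        "seed": cfg.seed,
        "files": paths,
    }
    (out / "truth.json").write_text(json.dumps(manifest, indent=2))
    return manifest
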