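"""Synthetic 3-D phantom cohorts with a planted atrophy signal.

The generator emulates the statistical structure the classifier assumes in
real T1 data: each phantom is Gaussian background noise plus a handful of
class-independent "redundant" ellipsoids plus two bilateral hippocampus-like
ellipsoids whose radius shrinks by ``atrophy_fraction`` in the disease class.
Morphological metric vectors are unit-variance Gaussians whose class means
differ by ``morph_effect`` (in SD units), mimicking z-scored tissue volumes.

Every sample is drawn from its own seed substream keyed by
``(seed, label, index)``, so cohorts are bitwise reproducible and
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import SampleRecord, Volume, normalize_and_clip, crop_patch, save_volume

#: Metric column names written by :func:`save_cohort` for the default
#: 3-dimensional morph vector (gray matter, white matter, CSF volumes).
DEFAULT_MORPH_COLUMNS = ("gmv", "wmv", "csf")

# Default class-mean shift of the (z-scored) tissue volumes for AD vs NC, in
# SD units: gray matter down, white matter mildly down, CSF up (ex vacuo).
DEFAULT_MORPH_EFFECT = (-1.5, -0.8, 1.2)


@dataclass
class PhantomConfig:
    """Study conditions for a phantom cohort.

    ``signal_radius_nc`` is the hippocampal ellipsoid radius (voxels) in the
    NC class; the AD radius is ``signal_radius_nc * (1 - atrophy_fraction)``.
    """

    shape: tuple[int, int, int] = (80, 100, 80)
    n_per_class: int = 100
    signal_radius_nc: float = 8.0
    atrophy_fraction: float = 0.3
    noise_sd: float = 0.5
    n_redundant_blobs: int = 6
    morph_dim: int = 3
    morph_effect: tuple[float, ...] = DEFAULT_MORPH_EFFECT
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if np.isscalar(self.morph_effect):
            self.morph_effect = (float(self.morph_effect),) * self.morph_dim
        self.morph_effect = tuple(float(e) for e in self.morph_effect)
        if len(self.morph_effect) != self.morph_dim:
            raise ValueError(
                f"morph_effect length {len(self.morph_effect)} != morph_dim {self.morph_dim}")
        if not 0 <= self.atrophy_fraction < 1:
            raise ValueError("atrophy_fraction must lie in [0, 1)")
        if self.signal_radius_nc * (1 - self.atrophy_fraction) < 1:
            raise ValueError("atrophied signal radius would fall below one voxel")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def morph_columns(self) -> list[str]:
        if self.morph_dim == len(DEFAULT_MORPH_COLUMNS):
            return list(DEFAULT_MORPH_COLUMNS)
        return [f"m{i + 1}" for i in range(self.morph_dim)]


def _sample_rng(cfg: PhantomConfig, label: int, index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(int(label), int(index)))
    return np.random.default_rng(ss)


def ellipsoid_mask(shape: tuple[int, int, int], center: tuple[float, float, float],
                   semiaxes: tuple[float, float, float]) -> np.ndarray:
    """Boolean mask of the analytic ellipsoid on the voxel grid."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def _hippocampus_centers(shape) -> list[tuple[float, float, float]]:
    d, h, w = shape
    return [(0.35 * d, 0.45 * h, 0.5 * w), (0.65 * d, 0.45 * h, 0.5 * w)]


def make_raw_phantom(cfg: PhantomConfig, label: int, index: int):
    """Raw (un-normalized) phantom volume plus morph vector and subject id."""
    if label not in (0, 1):
        raise ValueError("label must be 0 (NC) or 1 (AD)")
    if not 0 <= index < cfg.n_per_class:
        raise ValueError(f"index {index} out of range for n_per_class={cfg.n_per_class}")
    rng = _sample_rng(cfg, label, index)
    data = rng.normal(0.0, cfg.noise_sd, size=cfg.shape)

    # class-independent redundant structure: random bright ellipsoids
    lo = np.array([0.15 * s for s in cfg.shape])
    hi = np.array([0.85 * s for s in cfg.shape])
    rmin, rmax = 0.05 * min(cfg.shape), 0.10 * min(cfg.shape)
    for _ in range(cfg.n_redundant_blobs):
        center = rng.uniform(lo, hi)
        radii = rng.uniform(rmin, rmax, size=3)
        data[ellipsoid_mask(cfg.shape, center, radii)] += 1.0

    # bilateral hippocampal signal: radius shrinks with atrophy in AD
    r = cfg.signal_radius_nc * (1.0 - cfg.atrophy_fraction if label == 1 else 1.0)
    for center in _hippocampus_centers(cfg.shape):
        data[ellipsoid_mask(cfg.shape, center, (r, 1.25 * r, 0.8 * r))] += 1.2

    morph = rng.normal(label * np.asarray(cfg.morph_effect, dtype=float), 1.0)
    subject_id = f"sub-{'ad' if label else 'nc'}{index:04d}"
    return Volume(data), morph, subject_id


def make_phantom(cfg: PhantomConfig, label: int, index: int) -> SampleRecord:
    """One training-ready record: normalized/clipped patch + morph + label."""
    vol, morph, sid = make_raw_phantom(cfg, label, index)
    vol = normalize_and_clip(vol)
    patch = crop_patch(vol, (0, 0, 0), vol.shape)
    return SampleRecord(patch=patch, morph=morph, label=label, subject_id=sid)


def make_cohort(cfg: PhantomConfig) -> list[SampleRecord]:
    """A balanced cohort of ``2 * n_per_class`` records (NC then AD pairs)."""
    if cfg.n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    records = []
    for index in range(cfg.n_per_class):
        for label in (0, 1):
            records.append(make_phantom(cfg, label, index))
    return records


def save_cohort(cfg: PhantomConfig, out_dir) -> Path:
    """Write raw NIfTI volumes plus the label/metric CSV ``cohort.csv``.

    Raw (pre-normalization) intensities are written so that reloading through
    :func:`varcnn.volume_io.load_cohort` reproduces the preprocessing path
    used on real data.  Returns the table path.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    cols = cfg.morph_columns()
    for index in range(cfg.n_per_class):
        for label in (0, 1):
            vol, morph, sid = make_raw_phantom(cfg, label, index)
            save_volume(vol, img_dir / f"{sid}.nii.gz")
            rows.append({"subject_id": sid, "label": label,
                         **{c: v for c, v in zip(cols, morph)}})
    table_path = out_dir / "cohort.csv"
    pd.DataFrame(rows, columns=["subject_id", "label", *cols]).to_csv(table_path, index=False)
    return table_path
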