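"""Raw-cube preprocessing: reflectance calibration, spectral-angle-mapper
background removal, edge-trimmed plot ROIs and non-repetitive pixel sampling.

The output of this stage is a ``SampleSet``: for every plot, ``n`` distinct
rice pixels with their full-resolution spectra, ready for band aggregation
and vegetation-index computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .field_sim import (
    RICE,
    CalibrationFrames,
    FieldMap,
    HypercubeScene,
    Spectrum,
)

__all__ = [
    "ReferenceSpectraLibrary",
    "PixelMask",
    "CalibrationError",
    "EmptyROIError",
    "SamplingError",
    "calibrate_reflectance",
    "spectral_angle",
    "sam_classify",
    "select_plot_rois",
    "sample_pixels",
    "band_columns",
    "spectra_matrix",
]

#: mask label codes (match field_sim ground-truth coding)
BACKGROUND = 0
MASK_RICE = 1

DEFAULT_EDGE_MARGIN_PX = 2
DEFAULT_N_SAMPLES = 300


class CalibrationError(ValueError):
    """Calibration frames are degenerate (white equals dark somewhere)."""


class EmptyROIError(ValueError):
    """A plot ROI is empty after edge trimming / background masking."""


class SamplingError(ValueError):
    """A plot has fewer eligible pixels than the requested sample count."""


@dataclass
class ReferenceSpectraLibrary:
    """Mean rice and soil spectra used as SAM references.

    In the field workflow these come from hand-labelled pure ROIs; here they
    can also be built directly from simulator ground truth.
    """

    rice_mean: Spectrum
    soil_mean: Spectrum

    def __post_init__(self) -> None:
        if self.rice_mean.n_bands != self.soil_mean.n_bands:
            raise ValueError("reference spectra must share a band count")
        for name, spec in (("rice", self.rice_mean), ("soil", self.soil_mean)):
            if not np.any(spec.values):
                raise ValueError(f"{name} reference spectrum is all zeros")

    @classmethod
    def from_truth(cls, scene: HypercubeScene) -> "ReferenceSpectraLibrary":
        """Average the ground-truth rice and soil pixels of a scene."""
        rice_px = scene.truth_labels == RICE
        soil_px = ~rice_px
        if not rice_px.any() or not soil_px.any():
            raise ValueError("scene lacks rice or soil pixels")
        wl = scene.wavelengths_nm
        return cls(
            Spectrum(scene.cube[rice_px].mean(axis=0), wl),
            Spectrum(scene.cube[soil_px].mean(axis=0), wl),
        )


@dataclass
class PixelMask:
    """2-D rice/background label grid aligned with a source cube."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.labels = labels.astype(np.int16)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def is_rice(self) -> np.ndarray:
        return self.labels == MASK_RICE

    def to_ascii(self, path: str | Path) -> None:
        np.savetxt(path, self.labels, fmt="%d")

    @classmethod
    def from_ascii(cls, path: str | Path) -> "PixelMask":
        return cls(np.loadtxt(path, dtype=np.int16, ndmin=2))


def calibrate_reflectance(
    raw: np.ndarray, frames: CalibrationFrames, clip: bool = True
) -> np.ndarray:
    """Convert raw counts to reflectance against the white/dark references.

    ``reflectance = panel_reflectance * (raw - dark) / (white - dark)``,
    evaluated per band (frames broadcast along the spatial axes).  With
    ``clip`` the result is bounded to [0, 1]: values above the white panel
    are sensor saturation, values below dark are noise.
    """
    raw = np.asarray(raw, dtype=float)
    gain = frames.white_frame - frames.dark_frame
    if np.any(gain == 0):
        raise CalibrationError("white frame equals dark frame at some band")
    if raw.shape[-1] != frames.white_frame.shape[0]:
        raise ValueError(
            f"raw band count {raw.shape[-1]} does not match frames "
            f"({frames.white_frame.shape[0]})"
        )
    refl = frames.panel_reflectance * (raw - frames.dark_frame) / gain
    if not np.all(np.isfinite(refl)):
        raise CalibrationError("non-finite reflectance after calibration")
    if clip:
        refl = np.clip(refl, 0.0, 1.0)
    return refl


def spectral_angle(x: np.ndarray | Spectrum, r: np.ndarray | Spectrum) -> float:
    """Angle in radians between two spectra: ``arccos(<x,r> / (|x||r|))``.

    Scale-invariant, so insensitive to illumination differences; lies in
    [0, pi].
    """
    xv = x.values if isinstance(x, Spectrum) else np.asarray(x, float)
    rv = r.values if isinstance(r, Spectrum) else np.asarray(r, float)
    if xv.shape != rv.shape:
        raise ValueError(f"length mismatch: {xv.shape} vs {rv.shape}")
    nx = np.linalg.norm(xv)
    nr = np.linalg.norm(rv)
    if nx == 0.0 or nr == 0.0:
        raise ValueError("spectral angle undefined for a zero spectrum")
    cos = np.clip(np.dot(xv, rv) / (nx * nr), -1.0, 1.0)
    return float(np.arccos(cos))


def _angles_to_reference(flat: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Angles of each row of ``flat`` to ``ref``; zero rows map to pi/2."""
    norms = np.linalg.norm(flat, axis=1)
    ref_norm = np.linalg.norm(ref)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = (flat @ ref) / (norms * ref_norm)
    cos = np.where(norms == 0, 0.0, cos)
    return np.arccos(np.clip(cos, -1.0, 1.0))


def sam_classify(
    cube: np.ndarray | HypercubeScene, library: ReferenceSpectraLibrary
) -> PixelMask:
    """Label every pixel rice or background by its nearer reference angle.

    A pixel is background iff its angle to the soil mean is smaller than
    (or equal to -- ties are conservative) its angle to the rice mean.
    """
    arr = cube.cube if isinstance(cube, HypercubeScene) else np.asarray(cube, float)
    if arr.ndim != 3:
        raise ValueError("cube must be rows x cols x bands")
    if arr.shape[2] != library.rice_mean.n_bands:
        raise ValueError(
            f"cube has {arr.shape[2]} bands, library has "
            f"{library.rice_mean.n_bands}"
        )
    flat = arr.reshape(-1, arr.shape[2])
    a_rice = _angles_to_reference(flat, library.rice_mean.values)
    a_soil = _angles_to_reference(flat, library.soil_mean.values)
    labels = np.where(a_soil <= a_rice, BACKGROUND, MASK_RICE)
    return PixelMask(labels.reshape(arr.shape[:2]))


def select_plot_rois(
    mask: PixelMask,
    fieldmap: FieldMap,
    margin_px: int = DEFAULT_EDGE_MARGIN_PX,
) -> dict[int, np.ndarray]:
    """Per-plot ROI masks: plot rectangle shrunk by ``margin_px`` on every
    side, intersected with rice-labelled pixels.

    Edge trimming removes the influence of adjacent plots.  Rectangle
    bounds are half-open, pixel coordinates 0-based (row, col).
    """
    if margin_px < 0:
        raise ValueError("margin_px must be >= 0")
    rice = mask.is_rice()
    rois: dict[int, np.ndarray] = {}
    for rec in fieldmap.plots.itertuples():
        r0 = rec.px_row0 + margin_px
        c0 = rec.px_col0 + margin_px
        r1 = rec.px_row0 + rec.px_rows - margin_px
        c1 = rec.px_col0 + rec.px_cols - margin_px
        roi = np.zeros(mask.shape, dtype=bool)
        if r1 > r0 and c1 > c0:
            roi[r0:r1, c0:c1] = rice[r0:r1, c0:c1]
        if not roi.any():
            raise EmptyROIError(
                f"plot {rec.plot_id} (line {rec.line_id}, rep "
                f"{rec.replicate}): ROI empty with margin {margin_px}"
            )
        rois[int(rec.plot_id)] = roi
    return rois


def band_columns(n_bands: int) -> list[str]:
    return [f"band_{i:03d}" for i in range(n_bands)]


def spectra_matrix(samples: pd.DataFrame) -> np.ndarray:
    """Extract the (n_samples, n_bands) spectra block of a SampleSet."""
    cols = [c for c in samples.columns if c.startswith("band_")]
    return samples[cols].to_numpy(dtype=float)


def sample_pixels(
    rois: dict[int, np.ndarray],
    cube: np.ndarray | HypercubeScene,
    fieldmap: FieldMap,
    n: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n`` distinct pixels per plot, uniformly without replacement.

    Eligible pixels are ROI members with no zero-valued band: zeros are
    removed background or degenerate readings.  Deterministic given ``seed``.
    Returns a SampleSet DataFrame: plot_id, px_row, px_col, line_id,
    replicate, band_000..band_NNN.

    Raises :class:`SamplingError`, reporting the deficit, when a plot has
    fewer than ``n`` eligible pixels.
    """
    arr = cube.cube if isinstance(cube, HypercubeScene) else np.asarray(cube, float)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    meta = fieldmap.plots.set_index("plot_id")
    frames = []
    for plot_id in sorted(rois):
        roi = rois[plot_id]
        rr, cc = np.nonzero(roi)
        nonzero = np.all(arr[rr, cc, :] != 0.0, axis=1)
        rr, cc = rr[nonzero], cc[nonzero]
        if rr.size < n:
            raise SamplingError(
                f"plot {plot_id}: requested {n} pixels but only {rr.size} "
                f"eligible (deficit {n - rr.size})"
            )
        pick = rng.choice(rr.size, size=n, replace=False)
        spectra = arr[rr[pick], cc[pick], :]
        rec = meta.loc[plot_id]
        df = pd.DataFrame(spectra, columns=band_columns(arr.shape[2]))
        df.insert(0, "plot_id", plot_id)
        df.insert(1, "px_row", rr[pick])
        df.insert(2, "px_col", cc[pick])
        df.insert(3, "line_id", rec["line_id"])
        df.insert(4, "replicate", int(rec["replicate"]))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
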