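"""Synthetic hyperspectral rice-field scenes with known ground truth.

This module generates the inputs the rest of the pipeline consumes: a
reflectance hypercube over a plot grid (3 rows x 13 cells by default, one
replicate of every line per row with the line order permuted per row), a
field map carrying line identity, replicate, measured yield (kg per mu),
yield class and lodging flags, and calibration frames from an affine
band-wise sensor model so that reflectance calibration can be verified
in closed loop.

The statistical structure mirrors what the analysis downstream assumes:

* each pixel of a plot is the plot's canopy spectrum plus independent
  Gaussian noise per band, so within-plot band histograms are normal;
* rice and soil have qualitatively distinct spectral curves (red edge and
  NIR plateau vs. a gentle monotone slope);
* lodging exposes stems to the sensor and is modelled as a convex mixture
  of the canopy spectrum with a stem endmember;
* yield classes carry small class-level spectral offsets, smaller than the
  line-to-line variation, so spectra alone separate classes only partly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_builder import YieldClassRule, assign_yield_class

__all__ = [
    "Spectrum",
    "HypercubeScene",
    "CalibrationFrames",
    "FieldMap",
    "SimConfig",
    "LayoutError",
    "FormatError",
    "default_wavelengths",
    "rice_endmember",
    "soil_endmember",
    "stem_endmember",
    "apply_lodging_effect",
    "simulate_field",
    "encode_raw",
    "write_scene",
    "read_scene",
]

DEFAULT_N_BANDS = 176
WAVELENGTH_MIN_NM = 400.0
WAVELENGTH_MAX_NM = 1000.0

#: pixel_truth label codes
SOIL = 0
RICE = 1


class LayoutError(ValueError):
    """Requested line/replicate combination cannot be laid out on the grid."""


class FormatError(ValueError):
    """On-disk scene (ENVI header + binary cube) is missing or inconsistent."""


def default_wavelengths(n_bands: int = DEFAULT_N_BANDS) -> np.ndarray:
    """Band-center wavelengths in nm, evenly spaced over 400-1000 nm."""
    return np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, n_bands)


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance spectrum with its wavelength axis."""

    values: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if values.ndim != 1 or wl.ndim != 1 or values.shape != wl.shape:
            raise ValueError(
                f"values and wavelengths_nm must be 1-D of equal length, "
                f"got {values.shape} and {wl.shape}"
            )
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "wavelengths_nm", wl)

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]


@dataclass
class HypercubeScene:
    """Reflectance cube (rows x cols x bands) with per-pixel ground truth.

    ``truth_labels`` is 0 (soil) / 1 (rice); ``truth_plot_ids`` holds the
    plot id of rice pixels and -1 elsewhere.
    """

    cube: np.ndarray
    wavelengths_nm: np.ndarray
    truth_labels: np.ndarray
    truth_plot_ids: np.ndarray

    def __post_init__(self) -> None:
        cube = np.asarray(self.cube, dtype=float)
        if cube.ndim != 3:
            raise ValueError(f"cube must be 3-D, got shape {cube.shape}")
        if not np.all(np.isfinite(cube)):
            raise ValueError("cube contains non-finite values")
        if self.truth_labels.shape != cube.shape[:2]:
            raise ValueError("truth_labels spatial shape must match cube")
        if self.truth_plot_ids.shape != cube.shape[:2]:
            raise ValueError("truth_plot_ids spatial shape must match cube")
        if cube.shape[2] != len(self.wavelengths_nm):
            raise ValueError("wavelength axis length must match band count")
        self.cube = cube

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cube.shape

    @property
    def n_bands(self) -> int:
        return self.cube.shape[2]


@dataclass
class CalibrationFrames:
    """White/dark reference frames (raw counts per band) and panel albedo.

    The white reference is a diffuse panel of known reflectance (34% by
    default), so ``reflectance = panel * (raw - dark) / (white - dark)``.
    """

    white_frame: np.ndarray
    dark_frame: np.ndarray
    panel_reflectance: float = 0.34

    def __post_init__(self) -> None:
        self.white_frame = np.asarray(self.white_frame, dtype=float)
        self.dark_frame = np.asarray(self.dark_frame, dtype=float)
        if self.white_frame.shape != self.dark_frame.shape:
            raise ValueError("white and dark frames must share a shape")
        if not np.all(self.white_frame > self.dark_frame):
            raise ValueError("white_frame must exceed dark_frame at every band")
        if not 0.0 < self.panel_reflectance < 1.0:
            raise ValueError("panel_reflectance must lie in (0, 1)")


PLOT_COLUMNS = [
    "plot_id",
    "row",
    "col",
    "line_id",
    "replicate",
    "yield_kg_per_mu",
    "class_label",
    "lodging_flag",
    "px_row0",
    "px_col0",
    "px_rows",
    "px_cols",
]


@dataclass
class FieldMap:
    """Plot-level metadata: grid position, line, replicate, yield, class,
    lodging flag and the pixel rectangle each plot occupies in the scene.
    """

    plots: pd.DataFrame
    yield_rule: YieldClassRule = field(default_factory=YieldClassRule)

    def __post_init__(self) -> None:
        missing = [c for c in PLOT_COLUMNS if c not in self.plots.columns]
        if missing:
            raise ValueError(f"FieldMap missing columns: {missing}")
        plots = self.plots.reset_index(drop=True)
        if plots["plot_id"].duplicated().any():
            raise ValueError("plot_id values must be unique")
        if not plots["lodging_flag"].isin([0, 1]).all():
            raise ValueError("lodging_flag must be 0 or 1")
        # every line exactly once per grid row
        per_row = plots.groupby("row")["line_id"].nunique()
        counts = plots.groupby("row")["line_id"].size()
        if not (per_row == counts).all():
            raise ValueError("a line appears more than once within a grid row")
        expected = plots["yield_kg_per_mu"].map(
            lambda y: assign_yield_class(y, self.yield_rule)
        )
        if not (expected == plots["class_label"]).all():
            raise ValueError("class_label inconsistent with yield thresholds")
        self.plots = plots

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def line_ids(self) -> list[str]:
        return sorted(self.plots["line_id"].unique())

    def lines_by_class(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cls, grp in self.plots.groupby("class_label"):
            out[str(cls)] = sorted(grp["line_id"].unique())
        return out

    def lodging_flags(self, line_id: str) -> list[int]:
        """Per-replicate lodging flags of one line, ordered by replicate."""
        grp = self.plots[self.plots["line_id"] == line_id]
        if grp.empty:
            raise KeyError(f"unknown line_id {line_id!r}")
        return [int(f) for f in grp.sort_values("replicate")["lodging_flag"]]

    def to_json(self, path: str | Path) -> None:
        payload = {"plots": self.plots[PLOT_COLUMNS].to_dict(orient="records")}
        Path(path).write_text(json.dumps(payload, indent=1))

    def to_csv(self, path: str | Path) -> None:
        self.plots[PLOT_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_json(cls, path: str | Path) -> "FieldMap":
        payload = json.loads(Path(path).read_text())
        return cls(pd.DataFrame(payload["plots"]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FieldMap":
        return cls(pd.read_csv(path))


@dataclass
class SimConfig:
    """Parameters of the synthetic field.

    Defaults reproduce the study layout: 13 japonica lines in triplicate on
    a 3-row x 13-cell grid, 176 bands over 400-1000 nm, class sizes
    (A, B, C) = (2, 7, 4) by yield thresholds 750/700 kg per mu.  Class A
    lines lodge in all replicates (lodging index 3); the first two class-B
    lines lodge partially (indices 2 and 1), so lodging is associated with
    -- but its spectral signature is not exclusive to -- the high-yield
    class.  Lodged plots mix the canopy spectrum with a stem endmember at
    weight ``lodging_alpha``.
    """

    n_lines: int = 13
    n_replicates: int = 3
    n_bands: int = DEFAULT_N_BANDS
    plot_size_px: int = 16
    gap_px: int = 4
    noise_sd: float = 0.01
    line_effect_sd: float = 0.025
    plot_effect_sd: float = 0.015
    class_offsets: dict[str, float] = field(
        default_factory=lambda: {"A": 0.03, "B": 0.0, "C": -0.03}
    )
    class_counts: tuple[int, int, int] | None = None  # None -> (2,7,4)-like
    yield_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "A": (755.0, 790.0),
            "B": (702.0, 748.0),
            "C": (645.0, 698.0),
        }
    )
    lodging_alpha: float = 0.4
    n_lodged_b_lines: int = 2
    panel_reflectance: float = 0.34

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.n_replicates < 1:
            raise LayoutError("need at least one line and one replicate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.lodging_alpha <= 1.0:
            raise ValueError("lodging_alpha must lie in [0, 1]")
        if self.plot_size_px < 1 or self.gap_px < 0:
            raise LayoutError("invalid plot geometry")

    def resolve_class_counts(self) -> tuple[int, int, int]:
        if self.class_counts is not None:
            if sum(self.class_counts) != self.n_lines:
                raise LayoutError("class_counts must sum to n_lines")
            return self.class_counts
        if self.n_lines == 13:
            return (2, 7, 4)
        # proportional 2:7:4 split for other line counts
        n_a = max(1, round(self.n_lines * 2 / 13))
        n_c = round(self.n_lines * 4 / 13)
        n_b = self.n_lines - n_a - n_c
        if n_b < 0:
            n_b, n_c = 0, self.n_lines - n_a
        return (n_a, n_b, n_c)


# ---------------------------------------------------------------------------
# Endmember spectra
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def rice_endmember(wavelengths_nm: np.ndarray) -> Spectrum:
    """Healthy rice canopy: low visible reflectance with a green bump near
    550 nm, chlorophyll absorption dip near 670 nm, a steep red edge around
    700-740 nm and a high NIR plateau."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    vis = 0.05 + 0.05 * np.exp(-0.5 * ((wl - 550.0) / 30.0) ** 2)
    dip = -0.01 * np.exp(-0.5 * ((wl - 670.0) / 20.0) ** 2)
    nir = 0.42 * _sigmoid((wl - 715.0) / 12.0)
    return Spectrum(vis + dip + nir, wl)


def soil_endmember(wavelengths_nm: np.ndarray) -> Spectrum:
    """Bare soil: a gentle monotone increase with wavelength."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return Spectrum(0.10 + 0.20 * (wl - WAVELENGTH_MIN_NM) / 600.0, wl)


def stem_endmember(wavelengths_nm: np.ndarray) -> Spectrum:
    """Exposed rice stems: brighter than canopy in the visible, a weak red
    edge and a much lower NIR plateau -- intermediate between canopy and
    soil."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    base = 0.10 + 0.10 * (wl - WAVELENGTH_MIN_NM) / 600.0
    edge = 0.10 * _sigmoid((wl - 715.0) / 25.0)
    return Spectrum(base + edge, wl)


def apply_lodging_effect(
    canopy: Spectrum | np.ndarray,
    stem: Spectrum | np.ndarray,
    alpha: float,
) -> Spectrum | np.ndarray:
    """Mix canopy and stem reflectance: ``(1 - alpha) * canopy + alpha * stem``.

    When a plot lodges, the sensor sees radiation from both the leaf canopy
    and the now-exposed stems; ``alpha`` is the stem fraction.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    c = canopy.values if isinstance(canopy, Spectrum) else np.asarray(canopy, float)
    s = stem.values if isinstance(stem, Spectrum) else np.asarray(stem, float)
    if c.shape != s.shape:
        raise ValueError(
            f"canopy and stem band counts differ: {c.shape} vs {s.shape}"
        )
    mixed = (1.0 - alpha) * c + alpha * s
    if isinstance(canopy, Spectrum):
        return Spectrum(mixed, canopy.wavelengths_nm)
    return mixed


# ---------------------------------------------------------------------------
# Field simulation
# ---------------------------------------------------------------------------

def _line_effect(rng: np.random.Generator, wl: np.ndarray, sd: float) -> np.ndarray:
    """Smooth line-specific relative spectral perturbation: a sum of a few
    random Gaussian bumps, applied multiplicatively to the canopy curve."""
    effect = np.zeros_like(wl)
    for _ in range(3):
        center = rng.uniform(480.0, 950.0)
        width = rng.uniform(50.0, 120.0)
        amp = rng.normal(0.0, sd)
        effect += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return effect


def _lodging_flags(config: SimConfig, classes: list[str]) -> list[list[int]]:
    """Per-line per-replicate lodging flags.

    Class A lines lodge in every replicate; the first ``n_lodged_b_lines``
    class-B lines lodge in 2 and 1 replicates respectively; all other lines
    do not lodge.
    """
    flags: list[list[int]] = []
    b_seen = 0
    for cls in classes:
        if cls == "A":
            flags.append([1] * config.n_replicates)
        elif cls == "B" and b_seen < config.n_lodged_b_lines:
            n_lodged = max(1, config.n_replicates - 1 - b_seen)
            row = [1] * n_lodged + [0] * (config.n_replicates - n_lodged)
            flags.append(row)
            b_seen += 1
        else:
            flags.append([0] * config.n_replicates)
    return flags


def simulate_field(
    config: SimConfig | None = None, seed: int = 0
) -> tuple[HypercubeScene, FieldMap, CalibrationFrames]:
    """Generate a reflectance scene, its field map and calibration frames.

    All randomness flows from ``seed``, so the output is bit-reproducible.
    The seed is split into a structure stream (layout, yields, line
    effects, calibration frames) and a noise stream, so the field structure
    is identical across noise settings.  Plots of each grid row hold one
    replicate of every line, in a row-specific random order.  Within a plot
    every rice pixel is ``endmember * (1 + class offset) * (1 + line
    effect)`` (stem-mixed if the plot lodged) plus independent
    N(0, noise_sd) noise per band; the relative class offsets are smaller
    than the line-to-line variation, so spectra alone identify the class
    only partly.
    """
    config = config or SimConfig()
    rng, rng_noise = np.random.default_rng(seed).spawn(2)
    wl = default_wavelengths(config.n_bands)
    rice = rice_endmember(wl)
    soil = soil_endmember(wl)
    stem = stem_endmember(wl)

    n_a, n_b, n_c = config.resolve_class_counts()
    classes = ["A"] * n_a + ["B"] * n_b + ["C"] * n_c
    line_ids = [f"line{i + 1:02d}" for i in range(config.n_lines)]
    yields = [
        rng.uniform(*config.yield_ranges[cls]) for cls in classes
    ]
    line_effects = {
        lid: _line_effect(rng, wl, config.line_effect_sd) for lid in line_ids
    }
    lodging = _lodging_flags(config, classes)

    # grid geometry: n_replicates rows x n_lines cols, gap_px of soil between
    step = config.plot_size_px + config.gap_px
    n_rows_px = config.n_replicates * step + config.gap_px
    n_cols_px = config.n_lines * step + config.gap_px

    cube = np.empty((n_rows_px, n_cols_px, config.n_bands))
    cube[:] = soil.values[None, None, :]
    labels = np.full((n_rows_px, n_cols_px), SOIL, dtype=np.int16)
    plot_ids_px = np.full((n_rows_px, n_cols_px), -1, dtype=np.int32)

    records = []
    plot_id = 0
    for grid_row in range(config.n_replicates):
        order = rng.permutation(config.n_lines)
        for grid_col, line_idx in enumerate(order):
            lid = line_ids[line_idx]
            cls = classes[line_idx]
            replicate = grid_row + 1
            flag = lodging[line_idx][grid_row]
            # plot-level heterogeneity: the same line varies between its
            # replicates (planting, soil and micro-weather differences)
            plot_effect = _line_effect(rng, wl, config.plot_effect_sd)
            canopy = (
                rice.values
                * (1.0 + config.class_offsets.get(cls, 0.0))
                * (1.0 + line_effects[lid])
                * (1.0 + plot_effect)
            )
            alpha = config.lodging_alpha if flag else 0.0
            plot_spectrum = apply_lodging_effect(canopy, stem.values, alpha)
            r0 = config.gap_px + grid_row * step
            c0 = config.gap_px + grid_col * step
            sz = config.plot_size_px
            block = plot_spectrum[None, None, :] + (
                rng_noise.normal(
                    0.0, config.noise_sd, size=(sz, sz, config.n_bands)
                )
                if config.noise_sd > 0
                else 0.0
            )
            cube[r0 : r0 + sz, c0 : c0 + sz, :] = block
            labels[r0 : r0 + sz, c0 : c0 + sz] = RICE
            plot_ids_px[r0 : r0 + sz, c0 : c0 + sz] = plot_id
            records.append(
                {
                    "plot_id": plot_id,
                    "row": grid_row,
                    "col": grid_col,
                    "line_id": lid,
                    "replicate": replicate,
                    "yield_kg_per_mu": yields[line_idx],
                    "class_label": cls,
                    "lodging_flag": flag,
                    "px_row0": r0,
                    "px_col0": c0,
                    "px_rows": sz,
                    "px_cols": sz,
                }
            )
            plot_id += 1

    if config.noise_sd > 0:
        soil_px = labels == SOIL
        cube[soil_px] += rng_noise.normal(
            0.0, config.noise_sd, size=(int(soil_px.sum()), config.n_bands)
        )
    np.clip(cube, 0.0, 1.0, out=cube)

    scene = HypercubeScene(cube, wl, labels, plot_ids_px)
    fieldmap = FieldMap(pd.DataFrame(records))

    # affine band-wise sensor: raw = dark + gain * reflectance / panel,
    # white frame = raw of the panel itself -> white - dark = gain
    dark = 60.0 + 20.0 * rng.random(config.n_bands)
    gain = 800.0 + 400.0 * rng.random(config.n_bands)
    frames = CalibrationFrames(
        white_frame=dark + gain,
        dark_frame=dark,
        panel_reflectance=config.panel_reflectance,
    )
    return scene, fieldmap, frames


def encode_raw(cube: np.ndarray, frames: CalibrationFrames) -> np.ndarray:
    """Map a reflectance cube to raw sensor counts under the affine model
    ``raw = dark + (white - dark) * reflectance / panel_reflectance``.

    Reflectance calibration inverts this exactly (up to float rounding).
    """
    gain = frames.white_frame - frames.dark_frame
    return frames.dark_frame + gain * np.asarray(cube, float) / frames.panel_reflectance


# ---------------------------------------------------------------------------
# Scene I/O: ENVI-style header + raw BIL binary, JSON field map
# ---------------------------------------------------------------------------

_HEADER_TEMPLATE = """ENVI
description = {{synthetic rice field scene}}
samples = {samples}
lines = {lines}
bands = {bands}
header offset = 0
file type = ENVI Standard
data type = 4
interleave = bil
byte order = 0
wavelength = {{{wavelengths}}}
"""


def write_scene(
    scene: HypercubeScene,
    fieldmap: FieldMap,
    out_dir: str | Path,
    frames: CalibrationFrames | None = None,
) -> Path:
    """Write a scene directory: ``scene.hdr``/``scene.img`` (ENVI BIL,
    float32), field map as JSON and CSV, ground truth as ASCII grids and
    optionally the calibration frames as CSV.  Returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, cols, bands = scene.shape
    header = _HEADER_TEMPLATE.format(
        samples=cols,
        lines=rows,
        bands=bands,
        wavelengths=", ".join(f"{w:.4f}" for w in scene.wavelengths_nm),
    )
    (out / "scene.hdr").write_text(header)
    # BIL: line-major, band-middle, sample-minor
    bil = np.ascontiguousarray(scene.cube.transpose(0, 2, 1)).astype("<f4")
    bil.tofile(out / "scene.img")
    np.savetxt(out / "truth_labels.txt", scene.truth_labels, fmt="%d")
    np.savetxt(out / "truth_plot_ids.txt", scene.truth_plot_ids, fmt="%d")
    fieldmap.to_json(out / "fieldmap.json")
    fieldmap.to_csv(out / "fieldmap.csv")
    if frames is not None:
        pd.DataFrame(
            {
                "white_frame": frames.white_frame,
                "dark_frame": frames.dark_frame,
            }
        ).to_csv(out / "calibration_frames.csv", index=False)
        (out / "panel_reflectance.json").write_text(
            json.dumps({"panel_reflectance": frames.panel_reflectance})
        )
    return out


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("missing ENVI magic in header")
    # join brace-delimited values onto one line before parsing
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_scene(scene_dir: str | Path) -> tuple[HypercubeScene, FieldMap]:
    """Read a scene directory written by :func:`write_scene`.

    Raises :class:`FormatError` when the header is malformed or the binary
    cube size does not match the declared dimensions.
    """
    d = Path(scene_dir)
    hdr_path = d / "scene.hdr"
    img_path = d / "scene.img"
    if not hdr_path.exists() or not img_path.exists():
        raise FormatError(f"scene files missing under {d}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"ENVI header missing dimensions: {exc}") from exc
    if fields.get("interleave", "bil").lower() != "bil":
        raise FormatError("only BIL interleave is supported")
    wl_field = fields.get("wavelength", "").strip().strip("{}")
    wavelengths = np.array(
        [float(tok) for tok in wl_field.split(",") if tok.strip()]
    )
    if wavelengths.size != bands:
        raise FormatError("wavelength list length does not match band count")
    data = np.fromfile(img_path, dtype="<f4")
    if data.size != rows * cols * bands:
        raise FormatError(
            f"binary size {data.size} does not match "
            f"{rows}x{cols}x{bands} header dimensions"
        )
    cube = data.reshape(rows, bands, cols).transpose(0, 2, 1).astype(float)
    labels = np.loadtxt(d / "truth_labels.txt", dtype=np.int16, ndmin=2)
    plot_ids = np.loadtxt(d / "truth_plot_ids.txt", dtype=np.int32, ndmin=2)
    fieldmap = FieldMap.from_json(d / "fieldmap.json")
    return HypercubeScene(cube, wavelengths, labels, plot_ids), fieldmap


def read_calibration_frames(scene_dir: str | Path) -> CalibrationFrames:
    d = Path(scene_dir)
    df = pd.read_csv(d / "calibration_frames.csv")
    panel = json.loads((d / "panel_reflectance.json").read_text())[
        "panel_reflectance"
    ]
    return CalibrationFrames(
        df["white_frame"].to_numpy(), df["dark_frame"].to_numpy(), panel
    )
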