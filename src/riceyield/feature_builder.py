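"""Fused feature construction for yield classification.

Builds the per-sample feature table: 22 averaged spectral channels
(consecutive groups of 8 of the 176 bands), a bank of 41 literature
vegetation indices evaluated at nearest-band wavelength anchors, the
per-line lodging index (0-3 lodged replicates), and the yield-class label
(A > 750 kg per mu, 700 <= B <= 750, C < 700).  A PCA alternative to band
averaging and local texture maps (range/std/entropy) are provided but not
part of the default feature set.
"""

from __future__ import annotations

import ast
import json
import operator
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.decomposition import PCA

__all__ = [
    "YieldClassRule",
    "BandGrouping",
    "VegIndexDef",
    "ValidationError",
    "CoverageError",
    "JoinError",
    "assign_yield_class",
    "lodging_index",
    "lodging_indices",
    "band_correlation_matrix",
    "average_band_groups",
    "pca_reduce",
    "default_vegetation_index_registry",
    "compute_vegetation_indices",
    "registry_to_json",
    "registry_from_json",
    "texture_features",
    "fuse_features",
    "build_feature_table",
    "feature_columns",
    "META_COLUMNS",
]

META_COLUMNS = ["plot_id", "px_row", "px_col", "line_id", "replicate", "label"]


class ValidationError(ValueError):
    """Input value outside its documented domain (negative yield, non-binary
    lodging flag, ...)."""


class CoverageError(ValueError):
    """A vegetation-index wavelength anchor falls outside the spectrum."""


class JoinError(ValueError):
    """Feature fusion inputs disagree on sample keys."""


# ---------------------------------------------------------------------------
# Yield classes and lodging index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class YieldClassRule:
    """Class thresholds in kg per mu: A above ``upper``, C below ``lower``,
    B in between (both boundaries inclusive)."""

    upper: float = 750.0
    lower: float = 700.0

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError("upper threshold must exceed lower threshold")


def assign_yield_class(
    yield_kg_per_mu: float, rule: YieldClassRule | None = None
) -> str:
    """Map a measured yield to its class: 'A' (> 750), 'B' (700-750
    inclusive) or 'C' (< 700), under the default rule."""
    rule = rule or YieldClassRule()
    y = float(yield_kg_per_mu)
    if y < 0:
        raise ValidationError(f"yield must be non-negative, got {y}")
    if y > rule.upper:
        return "A"
    if y >= rule.lower:
        return "B"
    return "C"


def lodging_index(flags, n_replicates: int = 3) -> int:
    """Count of replicates of one line with observed lodging (0-3).

    A line that never lodged scores 0; one lodged in all three replicates
    scores 3.
    """
    flags = list(flags)
    if len(flags) != n_replicates:
        raise ValidationError(
            f"expected {n_replicates} flags, got {len(flags)}"
        )
    for f in flags:
        if f not in (0, 1):
            raise ValidationError(f"lodging flag must be 0 or 1, got {f!r}")
    return int(sum(flags))


def lodging_indices(fieldmap) -> dict[str, int]:
    """Lodging index of every line of a field map."""
    n_reps = int(fieldmap.plots.groupby("line_id")["replicate"].size().iloc[0])
    return {
        lid: lodging_index(fieldmap.lodging_flags(lid), n_reps)
        for lid in fieldmap.line_ids
    }


# ---------------------------------------------------------------------------
# Band aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandGrouping:
    """Consecutive non-overlapping groups of ``group_size`` adjacent bands;
    ``r_min`` is the correlation threshold justifying the group size."""

    group_size: int = 8
    r_min: float = 0.9

    def __post_init__(self) -> None:
        if self.group_size <= 0:
            raise ValueError("group_size must be positive")

    def n_groups(self, n_bands: int) -> int:
        return -(-n_bands // self.group_size)  # ceil division

    def boundaries(self, n_bands: int) -> list[tuple[int, int]]:
        g = self.group_size
        return [(i, min(i + g, n_bands)) for i in range(0, n_bands, g)]


def band_correlation_matrix(
    spectra: np.ndarray, r_min: float = 0.9
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Pearson band-band correlation over samples, and per-band redundancy
    run lengths.

    The run length of band ``b`` is the size of the longest contiguous band
    interval containing ``b`` whose every member correlates with ``b``
    above ``r_min`` (adjacent bands of a hyperspectral sensor are highly
    redundant, which is what justifies averaging groups of them).

    Returns ``(corr, run_lengths, excluded)`` where ``excluded`` lists
    zero-variance bands, whose correlations are undefined (NaN) and whose
    run length is reported as 0.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[0] < 3:
        raise ValueError("need a 2-D samples x bands array with >= 3 samples")
    n_bands = spectra.shape[1]
    sd = spectra.std(axis=0)
    excluded = [int(i) for i in np.nonzero(sd == 0)[0]]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(spectra, rowvar=False)
    corr = np.atleast_2d(corr)
    for b in excluded:
        corr[b, :] = np.nan
        corr[:, b] = np.nan

    run_lengths = np.zeros(n_bands, dtype=int)
    for b in range(n_bands):
        if b in excluded:
            continue
        # greedy two-sided expansion is maximal: membership only constrains
        # each band's own correlation with b
        lo = b
        while lo - 1 >= 0 and corr[b, lo - 1] > r_min:
            lo -= 1
        hi = b
        while hi + 1 < n_bands and corr[b, hi + 1] > r_min:
            hi += 1
        run_lengths[b] = hi - lo + 1
    return corr, run_lengths, excluded


def average_band_groups(
    spectra: np.ndarray, grouping: BandGrouping | int = 8
) -> np.ndarray:
    """Average consecutive groups of adjacent bands.

    176 bands with the default group size of 8 reduce to 22 channels.  A
    band count not divisible by the group size leaves a final short group.
    Accepts a single spectrum (1-D) or a samples x bands matrix (2-D).
    """
    if isinstance(grouping, int):
        grouping = BandGrouping(group_size=grouping)
    arr = np.asarray(spectra, dtype=float)
    one_d = arr.ndim == 1
    if one_d:
        arr = arr[None, :]
    n_bands = arr.shape[1]
    if n_bands < grouping.group_size:
        raise ValueError(
            f"band count {n_bands} smaller than group size "
            f"{grouping.group_size}"
        )
    out = np.column_stack(
        [arr[:, lo:hi].mean(axis=1) for lo, hi in grouping.boundaries(n_bands)]
    )
    return out[0] if one_d else out


def pca_reduce(spectra: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Scores of pooled, mean-centered spectra on the first ``k`` principal
    components (an alternative to band averaging).

    Returns ``(scores, explained_variance_ratio)``; the ratio is
    non-increasing by construction.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2:
        raise ValueError("spectra must be samples x bands")
    n, p = spectra.shape
    if not 1 <= k <= min(n, p):
        raise ValueError(f"k must lie in [1, {min(n, p)}], got {k}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(spectra)
    return scores, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Vegetation indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VegIndexDef:
    """A vegetation index: named wavelength anchors (nm) and an arithmetic
    expression over them (operators + - * /, parentheses, numeric constants
    and ``sqrt``)."""

    name: str
    anchors_nm: dict[str, float]
    expression: str
    citation: str = ""

    def __post_init__(self) -> None:
        used = _expression_names(self.expression)
        undeclared = used - set(self.anchors_nm)
        if undeclared:
            raise ValueError(
                f"index {self.name}: expression uses undeclared anchors "
                f"{sorted(undeclared)}"
            )


_BIN_OPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
}
_FUNCTIONS = {"sqrt": np.sqrt}


def _expression_names(expression: str) -> set[str]:
    tree = ast.parse(expression, mode="eval")
    return {
        node.id
        for node in ast.walk(tree)
        if isinstance(node, ast.Name) and node.id not in _FUNCTIONS
    }


def _eval_node(node: ast.AST, env: dict[str, np.ndarray]):
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, env)
    if isinstance(node, ast.Constant):
        if isinstance(node.value, (int, float)):
            return float(node.value)
        raise ValueError(f"unsupported constant {node.value!r}")
    if isinstance(node, ast.Name):
        if node.id in env:
            return env[node.id]
        raise ValueError(f"unknown name {node.id!r}")
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
        val = _eval_node(node.operand, env)
        return -val if isinstance(node.op, ast.USub) else val
    if isinstance(node, ast.BinOp) and type(node.op) in _BIN_OPS:
        return _BIN_OPS[type(node.op)](
            _eval_node(node.left, env), _eval_node(node.right, env)
        )
    if isinstance(node, ast.Call) and isinstance(node.func, ast.Name):
        if node.func.id in _FUNCTIONS and len(node.args) == 1 and not node.keywords:
            return _FUNCTIONS[node.func.id](_eval_node(node.args[0], env))
    raise ValueError(f"unsupported expression element: {ast.dump(node)}")


def evaluate_index_expression(
    expression: str, env: dict[str, np.ndarray]
) -> np.ndarray:
    """Evaluate an index expression over (vectorized) anchor reflectances."""
    return _eval_node(ast.parse(expression, mode="eval"), env)


def default_vegetation_index_registry() -> list[VegIndexDef]:
    """The default bank of 41 literature vegetation indices.

    Anchors all lie within 400-1000 nm; denominators are positive on
    strictly positive spectra, so every index is finite on real canopy
    reflectance.  The registry is replaceable (``registry_from_json``) so a
    different roster can be dropped in without touching the engine.
    """
    d = [
        ("NDVI", {"NIR": 800, "RED": 670}, "(NIR - RED) / (NIR + RED)"),
        ("GNDVI", {"NIR": 800, "GRN": 550}, "(NIR - GRN) / (NIR + GRN)"),
        ("NDRE", {"NIR": 790, "RE": 720}, "(NIR - RE) / (NIR + RE)"),
        ("RENDVI", {"N750": 750, "R705": 705}, "(N750 - R705) / (N750 + R705)"),
        ("SR", {"NIR": 800, "RED": 670}, "NIR / RED"),
        ("GRVI", {"NIR": 800, "GRN": 550}, "NIR / GRN"),
        ("SR705", {"N750": 750, "R705": 705}, "N750 / R705"),
        ("DVI", {"NIR": 800, "RED": 670}, "NIR - RED"),
        ("GDVI", {"NIR": 800, "GRN": 550}, "NIR - GRN"),
        (
            "EVI2",
            {"NIR": 800, "RED": 670},
            "2.5 * (NIR - RED) / (NIR + 2.4 * RED + 1)",
        ),
        (
            "SAVI",
            {"NIR": 800, "RED": 670},
            "1.5 * (NIR - RED) / (NIR + RED + 0.5)",
        ),
        (
            "OSAVI",
            {"NIR": 800, "RED": 670},
            "1.16 * (NIR - RED) / (NIR + RED + 0.16)",
        ),
        (
            "MSAVI2",
            {"NIR": 800, "RED": 670},
            "(2 * NIR + 1 - sqrt((2 * NIR + 1) * (2 * NIR + 1)"
            " - 8 * (NIR - RED))) / 2",
        ),
        ("RDVI", {"NIR": 800, "RED": 670}, "(NIR - RED) / sqrt(NIR + RED)"),
        (
            "TVI",
            {"N750": 750, "GRN": 550, "RED": 670},
            "0.5 * (120 * (N750 - GRN) - 200 * (RED - GRN))",
        ),
        (
            "MTVI1",
            {"NIR": 800, "GRN": 550, "RED": 670},
            "1.2 * (1.2 * (NIR - GRN) - 2.5 * (RED - GRN))",
        ),
        (
            "MCARI",
            {"RE": 700, "RED": 670, "GRN": 550},
            "((RE - RED) - 0.2 * (RE - GRN)) * (RE / RED)",
        ),
        (
            "TCARI",
            {"RE": 700, "RED": 670, "GRN": 550},
            "3 * ((RE - RED) - 0.2 * (RE - GRN) * (RE / RED))",
        ),
        ("CI_GREEN", {"NIR": 800, "GRN": 550}, "NIR / GRN - 1"),
        ("CI_REDEDGE", {"NIR": 800, "RE": 720}, "NIR / RE - 1"),
        ("PRI", {"G531": 531, "G570": 570}, "(G531 - G570) / (G531 + G570)"),
        (
            "PSRI",
            {"R680": 680, "B500": 500, "RE750": 750},
            "(R680 - B500) / RE750",
        ),
        ("NPCI", {"R680": 680, "B430": 430}, "(R680 - B430) / (R680 + B430)"),
        ("ARI", {"GRN": 550, "RE": 700}, "1 / GRN - 1 / RE"),
        (
            "MARI",
            {"GRN": 550, "RE": 700, "NIR": 800},
            "(1 / GRN - 1 / RE) * NIR",
        ),
        ("CRI550", {"B510": 510, "GRN": 550}, "1 / B510 - 1 / GRN"),
        ("CRI700", {"B510": 510, "RE": 700}, "1 / B510 - 1 / RE"),
        ("WBI", {"R900": 900, "R970": 970}, "R900 / R970"),
        ("NDWI970", {"N900": 900, "N970": 970}, "(N900 - N970) / (N900 + N970)"),
        ("VOG1", {"RE740": 740, "RE720": 720}, "RE740 / RE720"),
        (
            "VOG2",
            {"RE734": 734, "RE747": 747, "RE715": 715, "RE726": 726},
            "(RE734 - RE747) / (RE715 + RE726)",
        ),
        (
            "LCI",
            {"N850": 850, "RE710": 710, "R680": 680},
            "(N850 - RE710) / (N850 + R680)",
        ),
        ("GI", {"G554": 554, "R677": 677}, "G554 / R677"),
        ("NGRDI", {"GRN": 550, "RED": 670}, "(GRN - RED) / (GRN + RED)"),
        (
            "MSR",
            {"NIR": 800, "RED": 670},
            "(NIR / RED - 1) / sqrt(NIR / RED + 1)",
        ),
        (
            "WDRVI",
            {"NIR": 800, "RED": 670},
            "(0.2 * NIR - RED) / (0.2 * NIR + RED)",
        ),
        (
            "NLI",
            {"NIR": 800, "RED": 670},
            "(NIR * NIR - RED) / (NIR * NIR + RED)",
        ),
        (
            "MNLI",
            {"NIR": 800, "RED": 670},
            "1.5 * (NIR * NIR - RED) / (NIR * NIR + RED + 0.5)",
        ),
        ("PSND_B", {"NIR": 800, "B470": 470}, "(NIR - B470) / (NIR + B470)"),
        ("PSSR_A", {"NIR": 800, "R675": 675}, "NIR / R675"),
        ("PBI", {"N810": 810, "G560": 560}, "N810 / G560"),
    ]
    return [VegIndexDef(name, anchors, expr) for name, anchors, expr in d]


def registry_to_json(registry: list[VegIndexDef], path: str | Path) -> None:
    payload = [
        {
            "name": vi.name,
            "anchors_nm": vi.anchors_nm,
            "expression": vi.expression,
            "citation": vi.citation,
        }
        for vi in registry
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def registry_from_json(path: str | Path) -> list[VegIndexDef]:
    payload = json.loads(Path(path).read_text())
    return [
        VegIndexDef(
            item["name"],
            {k: float(v) for k, v in item["anchors_nm"].items()},
            item["expression"],
            item.get("citation", ""),
        )
        for item in payload
    ]


def _resolve_anchor(
    wavelengths_nm: np.ndarray, anchor_nm: float, tolerance_nm: float
) -> int:
    idx = int(np.argmin(np.abs(wavelengths_nm - anchor_nm)))
    if abs(wavelengths_nm[idx] - anchor_nm) > tolerance_nm:
        raise CoverageError(
            f"anchor {anchor_nm} nm not covered: nearest band center is "
            f"{wavelengths_nm[idx]:.1f} nm"
        )
    return idx


def compute_vegetation_indices(
    spectra: np.ndarray,
    wavelengths_nm: np.ndarray,
    registry: list[VegIndexDef] | None = None,
    anchor_tolerance_nm: float | None = None,
) -> pd.DataFrame:
    """Evaluate a vegetation-index registry on spectra.

    Each anchor resolves to the nearest band center (error if farther than
    ``anchor_tolerance_nm``, default one band spacing).  ``spectra`` may be
    1-D (one spectrum) or 2-D (samples x bands).  Undefined values (zero
    denominators on degenerate inputs) are reported as NaN.
    """
    registry = registry if registry is not None else default_vegetation_index_registry()
    wl = np.asarray(wavelengths_nm, dtype=float)
    arr = np.asarray(spectra, dtype=float)
    one_d = arr.ndim == 1
    if one_d:
        arr = arr[None, :]
    if arr.shape[1] != wl.shape[0]:
        raise ValueError("spectra band count must match wavelength axis")
    if anchor_tolerance_nm is None:
        anchor_tolerance_nm = float(np.max(np.diff(wl))) if wl.size > 1 else 1.0
    out = {}
    for vi in registry:
        env = {
            name: arr[:, _resolve_anchor(wl, nm, anchor_tolerance_nm)]
            for name, nm in vi.anchors_nm.items()
        }
        with np.errstate(divide="ignore", invalid="ignore"):
            values = evaluate_index_expression(vi.expression, env)
        values = np.asarray(values, dtype=float)
        values[~np.isfinite(values)] = np.nan
        out[vi.name] = values
    df = pd.DataFrame(out)
    return df.iloc[0] if one_d else df


# ---------------------------------------------------------------------------
# Texture maps
# ---------------------------------------------------------------------------

def texture_features(
    image: np.ndarray,
    range_window: int = 3,
    std_window: int = 3,
    entropy_window: int = 9,
    n_bins: int = 32,
) -> dict[str, np.ndarray]:
    """Per-pixel neighborhood statistics of a grayscale image.

    Local range and standard deviation over ``range_window``/``std_window``
    neighborhoods and Shannon entropy (bits) of the ``n_bins``-quantized
    values over the ``entropy_window`` neighborhood.  Edges use reflective
    padding.  Texture maps are computed on request; they are not part of
    the default feature table.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    for w in (range_window, std_window, entropy_window):
        if w < 1 or w % 2 == 0:
            raise ValueError(f"window sizes must be odd and positive, got {w}")
    rng_map = ndimage.maximum_filter(
        img, size=range_window, mode="reflect"
    ) - ndimage.minimum_filter(img, size=range_window, mode="reflect")
    mean = ndimage.uniform_filter(img, size=std_window, mode="reflect")
    mean_sq = ndimage.uniform_filter(img * img, size=std_window, mode="reflect")
    std_map = np.sqrt(np.maximum(mean_sq - mean * mean, 0.0))

    lo, hi = img.min(), img.max()
    if hi == lo:
        entropy_map = np.zeros_like(img)
    else:
        q = np.clip(
            ((img - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1
        )
        win_area = entropy_window * entropy_window
        entropy_map = np.zeros_like(img)
        for b in range(n_bins):
            frac = ndimage.uniform_filter(
                (q == b).astype(float), size=entropy_window, mode="reflect"
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                term = -frac * np.log2(frac)
            entropy_map += np.where(frac > 1.0 / (2 * win_area), term, 0.0)
        entropy_map = np.maximum(entropy_map, 0.0)
    return {"range": rng_map, "std": std_map, "entropy": entropy_map}


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a fused table (everything that is
    not provenance or label)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def fuse_features(
    meta: pd.DataFrame,
    bands: pd.DataFrame,
    indices: pd.DataFrame,
    lodging_by_line: dict[str, int] | None,
    fieldmap,
    with_lodging: bool = True,
) -> pd.DataFrame:
    """Combine aggregated bands, vegetation indices and the lodging index
    into one labelled feature table.

    ``meta`` carries the sample provenance (plot_id, px_row, px_col,
    line_id, replicate); ``bands`` and ``indices`` must be row-aligned with
    it.  The label is the FieldMap yield class of the sample's plot.  With
    the defaults this yields 22 + 41 (+1 lodging) feature columns.
    """
    if not (len(meta) == len(bands) == len(indices)):
        raise JoinError(
            f"row mismatch: meta {len(meta)}, bands {len(bands)}, "
            f"indices {len(indices)}"
        )
    plot_class = fieldmap.plots.set_index("plot_id")["class_label"]
    orphans = sorted(set(meta["plot_id"]) - set(plot_class.index))
    if orphans:
        raise JoinError(f"plots absent from field map: {orphans}")
    if with_lodging:
        if lodging_by_line is None:
            raise JoinError("with_lodging=True but no lodging indices given")
        orphan_lines = sorted(set(meta["line_id"]) - set(lodging_by_line))
        if orphan_lines:
            raise JoinError(f"lines without lodging index: {orphan_lines}")
    if indices.isna().any().any():
        bad = [c for c in indices.columns if indices[c].isna().any()]
        raise JoinError(f"undefined vegetation-index values in: {bad}")

    table = pd.concat(
        [
            meta[["plot_id", "px_row", "px_col", "line_id", "replicate"]]
            .reset_index(drop=True),
            bands.reset_index(drop=True),
            indices.reset_index(drop=True),
        ],
        axis=1,
    )
    if with_lodging:
        table["lodging_index"] = table["line_id"].map(lodging_by_line)
    table["label"] = table["plot_id"].map(plot_class)
    return table


def build_feature_table(
    samples: pd.DataFrame,
    fieldmap,
    grouping: BandGrouping | None = None,
    registry: list[VegIndexDef] | None = None,
    wavelengths_nm: np.ndarray | None = None,
    with_lodging: bool = True,
) -> pd.DataFrame:
    """End-to-end feature construction from a SampleSet.

    Aggregates the full-resolution spectra into band-group means, evaluates
    the vegetation-index registry per pixel on the full-resolution spectra,
    attaches the per-line lodging index (optional) and the yield-class
    label.
    """
    from .field_sim import default_wavelengths
    from .hsi_preprocess import spectra_matrix

    grouping = grouping or BandGrouping()
    spectra = spectra_matrix(samples)
    if wavelengths_nm is None:
        wavelengths_nm = default_wavelengths(spectra.shape[1])
    reduced = average_band_groups(spectra, grouping)
    bands = pd.DataFrame(
        reduced,
        columns=[f"band_avg_{i:02d}" for i in range(reduced.shape[1])],
    )
    indices = compute_vegetation_indices(spectra, wavelengths_nm, registry)
    lodging = lodging_indices(fieldmap) if with_lodging else None
    return fuse_features(
        samples, bands, indices, lodging, fieldmap, with_lodging=with_lodging
    )
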