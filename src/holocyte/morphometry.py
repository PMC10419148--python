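"""Morphological feature extraction from single-cell quantitative phase images.

A reconstructed phase image assigns each pixel the optical phase delay (radians)
accumulated through the cell; with a binary cell mask it is the atomic unit of
analysis. Twenty-five morphological parameters are extracted per cell: ten mask
shape descriptors, nine phase-value statistics, three optical-path-length (OPL)
quantities and three spatial phase-gradient statistics. Quality-control rules
then remove clumps, debris and low-signal cells before any population analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .exceptions import ConfigurationError, UnsegmentableError

__all__ = [
    "PhaseImage",
    "FEATURE_NAMES",
    "QCRule",
    "phase_to_opl",
    "compute_features",
    "features_for_cells",
    "segment_cell",
    "default_qc_rules",
    "qc_filter",
]

#: The 25 morphological parameters, in canonical column order.
FEATURE_NAMES: tuple[str, ...] = (
    "area_um2",
    "perimeter_um",
    "circularity",
    "eccentricity",
    "elongation_ratio",
    "solidity",
    "extent",
    "equivalent_diameter_um",
    "aspect_ratio_bbox",
    "perimeter_area_ratio",
    "mean_phase",
    "max_phase",
    "min_phase",
    "std_phase",
    "median_phase",
    "p25_phase",
    "p75_phase",
    "skewness_phase",
    "kurtosis_phase",
    "integrated_opl_um3",
    "mean_opl_um",
    "top25_opl_um",
    "max_phase_gradient",
    "mean_phase_gradient",
    "std_phase_gradient",
)


@dataclass
class PhaseImage:
    """A single-cell phase map with its segmentation mask.

    Parameters
    ----------
    phase
        2-D array of phase values in radians. Must be finite everywhere.
    mask
        Boolean array of the same shape marking cell pixels.
    pixel_pitch_um
        Physical size of one pixel in micrometres.
    """

    phase: np.ndarray
    mask: np.ndarray
    pixel_pitch_um: float

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.phase.ndim != 2:
            raise ConfigurationError("phase must be a 2-D array")
        if self.phase.shape != self.mask.shape:
            raise ConfigurationError(
                f"phase shape {self.phase.shape} != mask shape {self.mask.shape}"
            )
        if self.pixel_pitch_um <= 0:
            raise ConfigurationError("pixel_pitch_um must be positive")
        if not np.all(np.isfinite(self.phase)):
            raise ConfigurationError("phase contains non-finite values")


def phase_to_opl(phase_rad, wavelength_nm: float):
    """Convert phase delay (radians) to optical path length in micrometres.

    OPL = phi * lambda / (2 pi), with the wavelength given in nanometres and
    the result expressed in micrometres.
    """
    if wavelength_nm <= 0:
        raise ConfigurationError("wavelength_nm must be positive")
    return np.asarray(phase_rad, dtype=float) * (wavelength_nm * 1e-3) / (2.0 * np.pi)


def _shape_descriptors(mask: np.ndarray, pitch: float) -> dict:
    """Mask shape descriptors from second central moments (via regionprops)."""
    rp = measure.regionprops(mask.astype(np.uint8))[0]
    major = rp.axis_major_length
    minor = rp.axis_minor_length
    area = rp.area * pitch**2
    perim = rp.perimeter_crofton * pitch
    h = rp.bbox[2] - rp.bbox[0]
    w = rp.bbox[3] - rp.bbox[1]
    if minor > 0:
        elong = major / minor
    else:  # degenerate (line-like) mask: report pixel-count elongation
        elong = float(rp.area)
    ecc = min(rp.eccentricity, np.nextafter(1.0, 0.0))
    return {
        "area_um2": area,
        "perimeter_um": perim,
        "circularity": 4.0 * np.pi * area / perim**2 if perim > 0 else 1.0,
        "eccentricity": ecc,
        "elongation_ratio": max(elong, 1.0),
        "solidity": rp.solidity,
        "extent": rp.extent,
        "equivalent_diameter_um": rp.equivalent_diameter_area * pitch,
        "aspect_ratio_bbox": max(h, w) / min(h, w),
        "perimeter_area_ratio": perim / area,
    }


def _phase_statistics(values: np.ndarray) -> dict:
    """Order/ moment statistics of masked phase values.

    Skewness and excess kurtosis are defined as 0 for a constant sample so that
    every feature stays finite on degenerate (uniform-phase) cells.
    """
    mean = float(np.mean(values))
    dev = values - mean
    m2 = float(np.mean(dev**2))
    sd = float(np.sqrt(m2))
    if m2 > 0:
        # biased sample moments (Fisher convention for excess kurtosis)
        skew = float(np.mean(dev**3)) / m2**1.5
        kurt = float(np.mean(dev**4)) / m2**2 - 3.0
    else:
        skew, kurt = 0.0, 0.0
    p25, p50, p75 = np.percentile(values, (25, 50, 75))
    return {
        "mean_phase": mean,
        "max_phase": float(np.max(values)),
        "min_phase": float(np.min(values)),
        "std_phase": sd,
        "median_phase": float(p50),
        "p25_phase": float(p25),
        "p75_phase": float(p75),
        "skewness_phase": skew,
        "kurtosis_phase": kurt,
    }


def compute_features(img: PhaseImage, wavelength_nm: float = 640.0) -> dict:
    """Extract the 25 morphological parameters from one phase image.

    Shape descriptors come from the mask's second central moments
    (eccentricity = inter-focal half-distance / semi-major axis,
    elongation_ratio = major/minor axis ratio). Phase statistics are computed
    over masked pixels only. ``top25_opl_um`` is the mean of the top quartile
    of per-pixel OPL inside the mask. Gradient statistics use central
    differences (one-sided at the image border) over the 1-px-eroded mask
    interior, in rad/um.

    Returns a dict keyed by :data:`FEATURE_NAMES`.
    """
    mask = img.mask
    if not mask.any():
        raise UnsegmentableError("empty mask: cell could not be segmented")
    pitch = img.pixel_pitch_um
    feats = _shape_descriptors(mask, pitch)

    vals = img.phase[mask]
    feats.update(_phase_statistics(vals))

    opl = phase_to_opl(vals, wavelength_nm)
    k = max(1, int(np.ceil(opl.size * 0.25)))
    top = np.partition(opl, opl.size - k)[opl.size - k :]
    feats["integrated_opl_um3"] = float(np.sum(opl) * pitch**2)
    feats["mean_opl_um"] = float(np.mean(opl))
    feats["top25_opl_um"] = float(np.mean(top))

    gy, gx = np.gradient(img.phase, pitch)
    gmag = np.hypot(gx, gy)
    interior = ndimage.binary_erosion(mask)
    if not interior.any():
        interior = mask
    g = gmag[interior]
    feats["max_phase_gradient"] = float(np.max(g))
    feats["mean_phase_gradient"] = float(np.mean(g))
    feats["std_phase_gradient"] = float(np.std(g))
    return feats


def features_for_cells(
    images: Iterable[PhaseImage],
    records: Sequence | pd.DataFrame | None = None,
    wavelength_nm: float = 640.0,
) -> pd.DataFrame:
    """Feature table (one row per cell) for a collection of phase images.

    If ``records`` is given (a DataFrame or a sequence of objects with
    ``as_dict()``), its metadata columns are prepended to the feature columns.
    """
    rows = [compute_features(img, wavelength_nm) for img in images]
    feat = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if records is None:
        return feat
    if isinstance(records, pd.DataFrame):
        meta = records.reset_index(drop=True)
    else:
        meta = pd.DataFrame([r.as_dict() for r in records])
    if len(meta) != len(feat):
        raise ConfigurationError("records and images differ in length")
    return pd.concat([meta, feat], axis=1)


def segment_cell(
    phase: np.ndarray, pixel_pitch_um: float, rel_threshold: float = 0.05
) -> np.ndarray:
    """Segment the dominant cell: threshold at ``rel_threshold`` x max phase,
    keep the largest connected component, fill holes."""
    if not (0.0 < rel_threshold < 1.0):
        raise ConfigurationError("rel_threshold must lie in (0, 1)")
    phase = np.asarray(phase, dtype=float)
    fg = phase > rel_threshold * phase.max()
    if not fg.any():
        raise UnsegmentableError("no pixel above threshold")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(fg)


@dataclass(frozen=True)
class QCRule:
    """One exclusion rule on a single feature.

    ``direction`` is ``exclude_below`` or ``exclude_above``; ``applies_to`` is a
    class label (``"NOR"``/``"SCD"``) or ``"all"``.
    """

    parameter: str
    bound: float
    direction: str
    applies_to: str = "all"

    def __post_init__(self):
        if self.parameter not in FEATURE_NAMES:
            raise ConfigurationError(f"unknown feature: {self.parameter!r}")
        if self.direction not in ("exclude_below", "exclude_above"):
            raise ConfigurationError(f"bad direction: {self.direction!r}")
        if not np.isfinite(self.bound):
            raise ConfigurationError("bound must be finite")

    def violates(self, value: float) -> bool:
        if self.direction == "exclude_below":
            return value < self.bound
        return value > self.bound

    def describe(self) -> str:
        op = "<" if self.direction == "exclude_below" else ">"
        return f"{self.parameter} {op} {self.bound} ({self.applies_to})"


def default_qc_rules() -> list[QCRule]:
    """Default exclusion rules.

    Low-signal cutoffs: normal cells with mean phase below 0.4 rad and SCD
    cells below 0.3 rad are excluded. Clump/debris bounds (area and solidity)
    remove merged cells and fragments.
    """
    return [
        QCRule("mean_phase", 0.4, "exclude_below", applies_to="NOR"),
        QCRule("mean_phase", 0.3, "exclude_below", applies_to="SCD"),
        QCRule("area_um2", 12.0, "exclude_below"),
        QCRule("area_um2", 90.0, "exclude_above"),
        QCRule("solidity", 0.85, "exclude_below"),
    ]


def qc_filter(
    table: pd.DataFrame, rules: Sequence[QCRule] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a feature table into (kept, excluded).

    Each excluded row is annotated (column ``excluded_by``) with the first rule
    it violated, in rule order. The partition is exhaustive and disjoint.
    """
    if rules is None:
        rules = default_qc_rules()
    for rule in rules:
        if rule.parameter not in table.columns:
            raise ConfigurationError(f"table lacks feature {rule.parameter!r}")
    labels = table["label"] if "label" in table.columns else pd.Series("all", index=table.index)
    reason = pd.Series(None, index=table.index, dtype=object)
    for rule in rules:
        applicable = reason.isna()
        if rule.applies_to != "all":
            applicable &= labels == rule.applies_to
        vals = table.loc[applicable, rule.parameter]
        bad = vals.index[[rule.violates(v) for v in vals]]
        reason.loc[bad] = rule.describe()
    kept = table[reason.isna()].copy()
    excluded = table[reason.notna()].copy()
    excluded["excluded_by"] = reason[reason.notna()]
    return kept, excluded
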