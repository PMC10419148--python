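"""Synthetic single-cell phase image generation.

Generates labeled quantitative-phase images of red blood cells for two
populations: normal (NOR) samples and sickle-cell-disease (SCD) samples. An
SCD sample is a mixture of three morphological subtypes — ``normal_like``,
``mildly_deformed`` and a small ``critically_sickled`` subpopulation — so that
the per-parameter histograms of the two populations largely overlap while the
critically sickled cells occupy distribution tails (high eccentricity and
elongation, high peak phase, high phase gradients) beyond normal support.
This reproduces the statistical structure the downstream training-set
refinement exploits.

Cell shapes are parametric: a (possibly elongated) biconcave disc profile

    phi(r) = peak * max(0, 1 - (r/R)^2)^(1/2) * (1 - d * exp(-(r/(R/2))^2))

for normal-like cells (``d`` the central dimple depth), and an elongated
crescent — the same profile with the centreline bent by a quadratic term — for
critically sickled cells. Additive Gaussian background phase noise stands in
for detection noise; no coherent-speckle model is attempted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import ConfigurationError, GeometryOverflowError
from .morphometry import PhaseImage

__all__ = [
    "SUBTYPES",
    "ImagingConfig",
    "CellShapeParams",
    "ParamDist",
    "SubtypeDistributions",
    "SamplePopulation",
    "StudyConfig",
    "CellRecord",
    "make_normal_phase_image",
    "make_sickled_phase_image",
    "draw_shape_params",
    "generate_sample",
    "generate_study",
    "default_subtype_distributions",
    "default_study_config",
    "NOR_FRACTIONS",
    "SCD_FRACTIONS",
]

SUBTYPES = ("normal_like", "mildly_deformed", "critically_sickled")

#: Default subtype mixtures. SCD samples carry a 15% critically sickled
#: subpopulation so that unrefined donor-status labels are substantially noisy
#: at the cell level. NOR samples contain no critically sickled cells and
#: otherwise show the same benign morphological diversity as the non-sickled
#: part of an SCD sample (a comparable normal-like/mildly-deformed split),
#: which makes the two populations' histograms overlap except in the tails.
NOR_FRACTIONS = (0.55, 0.45, 0.0)
SCD_FRACTIONS = (0.50, 0.35, 0.15)

#: Mask pixels are those whose noiseless phase exceeds this fraction of peak.
MASK_REL_THRESHOLD = 0.05


@dataclass(frozen=True)
class ImagingConfig:
    """Virtual imaging-system parameters.

    wavelength_nm: illumination wavelength (640 nm diode laser).
    pixel_pitch_um: object-plane pixel size.
    image_side: square crop side in pixels.
    background_phase_sd: additive Gaussian phase noise, radians.
    background_residual_sd: per-acquisition-run residual background phase
        level, radians. Each sample draws one offset from N(0, sd) that is
        added to the crop's background pixels. Cell pixels are referenced to
        the local background annulus during reconstruction, so the residual
        is visible around the cell but does not enter the masked phase
        values (and hence none of the morphological parameters).
    """

    wavelength_nm: float = 640.0
    pixel_pitch_um: float = 0.24
    image_side: int = 64
    background_phase_sd: float = 0.01
    background_residual_sd: float = 0.04

    def __post_init__(self):
        if self.wavelength_nm <= 0 or self.pixel_pitch_um <= 0:
            raise ConfigurationError("wavelength and pixel pitch must be positive")
        if self.image_side < 32:
            raise ConfigurationError("image_side must be at least 32 px")
        if self.background_phase_sd < 0 or self.background_residual_sd < 0:
            raise ConfigurationError("background noise levels must be non-negative")


@dataclass(frozen=True)
class CellShapeParams:
    """Geometric/optical parameters of one simulated cell."""

    subtype: str
    radius_um: float
    elongation: float = 1.0
    curvature: float = 0.0
    peak_phase_rad: float = 1.2
    dimple_depth: float = 0.4

    def __post_init__(self):
        if self.subtype not in SUBTYPES:
            raise ConfigurationError(f"unknown subtype {self.subtype!r}")
        if self.radius_um <= 0 or self.peak_phase_rad <= 0:
            raise ConfigurationError("radius and peak phase must be positive")
        if self.elongation < 1.0:
            raise ConfigurationError("elongation must be >= 1")
        if self.curvature < 0:
            raise ConfigurationError("curvature must be >= 0")
        if not (0.0 <= self.dimple_depth <= 1.0):
            raise ConfigurationError("dimple_depth must lie in [0, 1]")


@dataclass(frozen=True)
class ParamDist:
    """Clipped normal over one shape parameter: mean, sd, bounds [lo, hi]."""

    mean: float
    sd: float
    lo: float
    hi: float

    def value(self, z: float) -> float:
        """Parameter value at standard score ``z``, clipped to the bounds."""
        return float(np.clip(self.mean + self.sd * z, self.lo, self.hi))

    def draw(self, rng: np.random.Generator) -> float:
        return self.value(rng.normal())


@dataclass(frozen=True)
class SubtypeDistributions:
    """Per-parameter distributions for one morphological subtype.

    ``severity_coupling`` (in [0, 1]) is the loading of a per-cell latent
    deformation-severity factor shared by elongation, peak phase and (with
    negative sign) dimple depth and radius: a cell that is unusually
    elongated for its subtype also tends to be optically denser, smaller and
    to have lost its biconcave dimple. This mirrors how real deformation
    expresses itself consistently across descriptors rather than
    independently per parameter.
    """

    radius_um: ParamDist
    elongation: ParamDist
    curvature: ParamDist
    peak_phase_rad: ParamDist
    dimple_depth: ParamDist
    severity_coupling: float = 1.0
    peak_phase_coupling: float | None = None  # defaults to severity_coupling


def default_subtype_distributions() -> dict[str, SubtypeDistributions]:
    """Default shape-parameter distributions per subtype.

    normal_like and mildly_deformed are shared verbatim between NOR and SCD
    samples (so their histograms overlap exactly); critically_sickled cells are
    thinner-radius, strongly elongated, bent crescents with higher peak phase,
    placing them in upper tails of eccentricity, elongation, max phase, phase
    std, top-quartile OPL and phase gradient.

    The three subtypes sit on a single deformation-severity axis: every
    descriptor (elongation, peak phase, dimple loss, size reduction) is
    monotone from normal_like through mildly_deformed to critically_sickled,
    so a cell extreme in one parameter tends to be extreme in all.
    """
    return {
        "normal_like": SubtypeDistributions(
            radius_um=ParamDist(3.6, 0.20, 3.0, 4.2),
            elongation=ParamDist(1.06, 0.05, 1.0, 1.35),
            curvature=ParamDist(0.0, 0.0, 0.0, 0.0),
            peak_phase_rad=ParamDist(1.15, 0.12, 0.8, 1.5),
            dimple_depth=ParamDist(0.50, 0.10, 0.10, 0.80),
            peak_phase_coupling=0.95,
        ),
        "mildly_deformed": SubtypeDistributions(
            radius_um=ParamDist(3.35, 0.20, 2.75, 3.95),
            elongation=ParamDist(1.35, 0.10, 1.05, 1.70),
            curvature=ParamDist(0.0, 0.0, 0.0, 0.0),
            peak_phase_rad=ParamDist(1.35, 0.15, 0.9, 1.8),
            dimple_depth=ParamDist(0.25, 0.10, 0.0, 0.6),
            peak_phase_coupling=0.95,
        ),
        "critically_sickled": SubtypeDistributions(
            radius_um=ParamDist(2.55, 0.12, 2.20, 2.90),
            elongation=ParamDist(2.60, 0.55, 1.40, 3.80),
            curvature=ParamDist(0.50, 0.20, 0.0, 1.0),
            peak_phase_rad=ParamDist(2.00, 0.22, 1.45, 2.55),
            dimple_depth=ParamDist(0.0, 0.025, 0.0, 0.10),
            severity_coupling=0.7,
        ),
    }


def scd_subtype_distributions(bulk_phase_shift: float = -0.05) -> dict[str, SubtypeDistributions]:
    """Subtype distributions for SCD samples.

    Identical to the defaults except that the shared (non-sickled) subtypes'
    peak phase is shifted by ``bulk_phase_shift`` radians. This reproduces the
    small but statistically significant population-level shift between donor
    groups that coexists with heavy per-parameter overlap: an unrefined
    donor-status classifier latches onto this bulk shift, which points away
    from the critically sickled tail and thereby degrades its ability to
    recognise the cells that actually matter.
    """
    dists = default_subtype_distributions()
    out = {}
    for name, d in dists.items():
        if name == "critically_sickled":
            out[name] = d
        else:
            p = d.peak_phase_rad
            out[name] = SubtypeDistributions(
                radius_um=d.radius_um,
                elongation=d.elongation,
                curvature=d.curvature,
                peak_phase_rad=ParamDist(p.mean + bulk_phase_shift, p.sd, p.lo, p.hi),
                dimple_depth=d.dimple_depth,
                severity_coupling=d.severity_coupling,
            )
    return out


@dataclass(frozen=True)
class SamplePopulation:
    """One donor-level sample: a labeled mixture of cell subtypes."""

    sample_id: str
    label: str  # "NOR" or "SCD"
    n_cells: int
    subtype_fractions: tuple[float, float, float]
    seed: int
    distributions: dict[str, SubtypeDistributions] = field(
        default_factory=default_subtype_distributions
    )

    def __post_init__(self):
        if self.label not in ("NOR", "SCD"):
            raise ConfigurationError(f"label must be NOR or SCD, got {self.label!r}")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        f = np.asarray(self.subtype_fractions, dtype=float)
        if f.shape != (3,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ConfigurationError("subtype_fractions must be a 3-simplex")
        if self.label == "NOR" and f[2] != 0:
            raise ConfigurationError("NOR populations must have zero critically_sickled fraction")


@dataclass(frozen=True)
class StudyConfig:
    """A multi-sample study: training rosters plus held-out test samples."""

    imaging: ImagingConfig
    train_scd: tuple[SamplePopulation, ...]
    train_nor: tuple[SamplePopulation, ...]
    test_samples: tuple[SamplePopulation, ...]

    def __post_init__(self):
        if not self.train_scd or not self.train_nor:
            raise ConfigurationError("need at least one SCD and one NOR training sample")

    @property
    def all_samples(self) -> tuple[SamplePopulation, ...]:
        return tuple(self.train_scd) + tuple(self.train_nor) + tuple(self.test_samples)

    def to_dict(self) -> dict:
        def popdict(p: SamplePopulation) -> dict:
            d = asdict(p)
            d["distributions"] = {k: asdict(v) for k, v in p.distributions.items()}
            return d

        return {
            "imaging": asdict(self.imaging),
            "train_scd": [popdict(p) for p in self.train_scd],
            "train_nor": [popdict(p) for p in self.train_nor],
            "test_samples": [popdict(p) for p in self.test_samples],
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CellRecord:
    """Per-cell metadata carried alongside each generated image."""

    cell_id: str
    sample_id: str
    label: str
    subtype: str
    page_index: int

    def as_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "sample_id": self.sample_id,
            "label": self.label,
            "subtype": self.subtype,
            "page_index": self.page_index,
        }


def _footprint_ok(shape: CellShapeParams, imaging: ImagingConfig) -> tuple[float, float]:
    """Semi-axes (um) of the generating ellipse; raise if the cell overflows."""
    a = shape.radius_um * np.sqrt(shape.elongation)
    b = shape.radius_um / np.sqrt(shape.elongation)
    half_um = (imaging.image_side / 2 - 2) * imaging.pixel_pitch_um
    y_extent = b + shape.curvature * b  # bend pushes the arc outward by <= curvature*b
    if a > half_um or y_extent > half_um:
        raise GeometryOverflowError(
            f"cell footprint (a={a:.2f} um) exceeds image half-frame ({half_um:.2f} um)"
        )
    return a, b


def _grid(imaging: ImagingConfig) -> tuple[np.ndarray, np.ndarray]:
    n = imaging.image_side
    c = (n - 1) / 2.0
    coords = (np.arange(n) - c) * imaging.pixel_pitch_um
    return np.meshgrid(coords, coords, indexing="xy")


def _biconcave_profile(xn: np.ndarray, yn: np.ndarray, peak: float, dimple: float) -> np.ndarray:
    r2 = xn**2 + yn**2
    base = peak * np.sqrt(np.clip(1.0 - r2, 0.0, None))
    return base * (1.0 - dimple * np.exp(-4.0 * r2))


def _finish(noiseless: np.ndarray, shape: CellShapeParams, imaging: ImagingConfig,
            rng: np.random.Generator, background_offset: float = 0.0) -> PhaseImage:
    mask = noiseless > MASK_REL_THRESHOLD * shape.peak_phase_rad
    phase = noiseless
    if imaging.background_phase_sd > 0:
        phase = phase + rng.normal(0.0, imaging.background_phase_sd, noiseless.shape)
    if background_offset != 0.0:
        phase = np.where(mask, phase, phase + background_offset)
    return PhaseImage(
        phase=phase.astype(np.float64), mask=mask, pixel_pitch_um=imaging.pixel_pitch_um
    )


def make_normal_phase_image(
    shape: CellShapeParams, imaging: ImagingConfig, rng: np.random.Generator,
    background_offset: float = 0.0,
) -> PhaseImage:
    """Phase image of a (possibly elongated) biconcave disc.

    The radially symmetric biconcave profile is stretched along x by
    ``elongation`` (area-preserving: semi-axes R*sqrt(e), R/sqrt(e)).
    """
    if shape.subtype not in ("normal_like", "mildly_deformed"):
        raise ConfigurationError("make_normal_phase_image expects a non-sickled subtype")
    a, b = _footprint_ok(shape, imaging)
    x, y = _grid(imaging)
    noiseless = _biconcave_profile(x / a, y / b, shape.peak_phase_rad, shape.dimple_depth)
    return _finish(noiseless, shape, imaging, rng, background_offset)


def make_sickled_phase_image(
    shape: CellShapeParams, imaging: ImagingConfig, rng: np.random.Generator,
    background_offset: float = 0.0,
) -> PhaseImage:
    """Phase image of an elongated crescent (critically sickled cell).

    The elongated profile's centreline is bent by a quadratic displacement
    proportional to ``curvature``; at curvature 0 this reduces exactly to the
    elongated biconcave profile with no dimple.
    """
    if shape.subtype != "critically_sickled":
        raise ConfigurationError("make_sickled_phase_image expects critically_sickled")
    a, b = _footprint_ok(shape, imaging)
    x, y = _grid(imaging)
    xn = x / a
    # bend the centreline; subtract the mean of xn^2 over [-1,1] to keep the
    # arc roughly centred in the frame
    yn = y / b + shape.curvature * (xn**2 - 1.0 / 3.0)
    noiseless = _biconcave_profile(xn, yn, shape.peak_phase_rad, 0.0)
    return _finish(noiseless, shape, imaging, rng, background_offset)


def make_phase_image(
    shape: CellShapeParams, imaging: ImagingConfig, rng: np.random.Generator,
    background_offset: float = 0.0,
) -> PhaseImage:
    """Dispatch on subtype."""
    if shape.subtype == "critically_sickled":
        return make_sickled_phase_image(shape, imaging, rng, background_offset)
    return make_normal_phase_image(shape, imaging, rng, background_offset)


def draw_shape_params(
    subtype: str, dists: dict[str, SubtypeDistributions], rng: np.random.Generator
) -> CellShapeParams:
    """Draw one cell's shape parameters from its subtype's distributions.

    A latent severity factor (loading ``severity_coupling``) correlates
    elongation, curvature, peak phase, dimple loss and (negatively) radius
    within the subtype, so the low-severity end of the critically sickled
    continuum merges into the mildly deformed morphology.
    """
    d = dists[subtype]
    u = rng.normal()

    def coupled(pd_: ParamDist, sign: float = 1.0, w: float | None = None) -> float:
        w = d.severity_coupling if w is None else w
        res = np.sqrt(1.0 - w * w)
        return pd_.value(sign * w * u + res * rng.normal())

    w_peak = (d.peak_phase_coupling if d.peak_phase_coupling is not None
              else d.severity_coupling)

    return CellShapeParams(
        subtype=subtype,
        radius_um=coupled(d.radius_um, sign=-1.0),
        elongation=max(1.0, coupled(d.elongation)),
        curvature=max(0.0, coupled(d.curvature)),
        peak_phase_rad=coupled(d.peak_phase_rad, w=w_peak),
        dimple_depth=float(np.clip(coupled(d.dimple_depth, sign=-1.0), 0.0, 1.0)),
    )


def generate_sample(
    pop: SamplePopulation, imaging: ImagingConfig
) -> tuple[list[PhaseImage], list[CellRecord]]:
    """Generate all cells of one sample, reproducibly from ``pop.seed``.

    Subtype counts follow a multinomial draw with the population's fractions;
    the per-cell subtype sequence is then shuffled so stack order carries no
    information.
    """
    rng = np.random.default_rng(pop.seed)
    counts = rng.multinomial(pop.n_cells, pop.subtype_fractions)
    subtypes = np.repeat(np.arange(3), counts)
    rng.shuffle(subtypes)
    # one residual background level per acquisition run (sample)
    offset = rng.normal(0.0, imaging.background_residual_sd)
    images: list[PhaseImage] = []
    records: list[CellRecord] = []
    for i, s_idx in enumerate(subtypes):
        subtype = SUBTYPES[s_idx]
        shape = draw_shape_params(subtype, pop.distributions, rng)
        img = make_phase_image(shape, imaging, rng, offset)
        images.append(img)
        records.append(
            CellRecord(
                cell_id=f"{pop.sample_id}_{i:06d}",
                sample_id=pop.sample_id,
                label=pop.label,
                subtype=subtype,
                page_index=i,
            )
        )
    return images, records


def iter_sample_cells(pop: SamplePopulation, imaging: ImagingConfig):
    """Yield ``(PhaseImage, CellRecord)`` pairs one at a time (streaming).

    Produces the identical sequence to :func:`generate_sample` without holding
    the whole stack in memory.
    """
    rng = np.random.default_rng(pop.seed)
    counts = rng.multinomial(pop.n_cells, pop.subtype_fractions)
    subtypes = np.repeat(np.arange(3), counts)
    rng.shuffle(subtypes)
    offset = rng.normal(0.0, imaging.background_residual_sd)
    for i, s_idx in enumerate(subtypes):
        subtype = SUBTYPES[s_idx]
        shape = draw_shape_params(subtype, pop.distributions, rng)
        img = make_phase_image(shape, imaging, rng, offset)
        yield img, CellRecord(
            cell_id=f"{pop.sample_id}_{i:06d}",
            sample_id=pop.sample_id,
            label=pop.label,
            subtype=subtype,
            page_index=i,
        )


def default_study_config(
    seed: int = 0, scale: float = 1.0, imaging: ImagingConfig | None = None
) -> StudyConfig:
    """The default synthetic study: ~50k cells across a 5+5-sample roster.

    Two SCD training samples (12k cells each), two NOR training samples
    (8k + 10k), and five test samples of 2k cells (three NOR, two SCD — one of
    them with a heavier 26% critically sickled load). ``scale`` multiplies all
    cell counts (minimum 50 per sample) for reduced-size runs.
    """
    imaging = imaging or ImagingConfig()

    def n(base: int) -> int:
        return max(50, int(round(base * scale)))

    scd_dists = scd_subtype_distributions()

    def scd(sid: str, n_cells: int, fractions, s: int) -> SamplePopulation:
        return SamplePopulation(sid, "SCD", n_cells, fractions, seed=s,
                                distributions=scd_dists)

    def nor(sid: str, n_cells: int, s: int) -> SamplePopulation:
        return SamplePopulation(sid, "NOR", n_cells, NOR_FRACTIONS, seed=s)

    return StudyConfig(
        imaging=imaging,
        train_scd=(
            scd("scd_train_1", n(12000), SCD_FRACTIONS, seed * 101 + 1),
            scd("scd_train_2", n(12000), SCD_FRACTIONS, seed * 101 + 2),
        ),
        train_nor=(
            nor("nor_train_1", n(8000), seed * 101 + 3),
            nor("nor_train_2", n(10000), seed * 101 + 4),
        ),
        test_samples=(
            nor("nor_test_A", n(2000), seed * 101 + 5),
            nor("nor_test_B", n(2000), seed * 101 + 6),
            nor("nor_test_C", n(2000), seed * 101 + 7),
            scd("scd_test_1", n(2000), SCD_FRACTIONS, seed * 101 + 8),
            scd("scd_test_2", n(2000), (0.45, 0.29, 0.26), seed * 101 + 9),
        ),
    )


def generate_study(config: StudyConfig, out_dir: str | Path) -> dict:
    """Write a full study to disk and return its manifest.

    Per sample: a multi-page 32-bit float TIFF stack of phase images (radians)
    and a metadata CSV (cell_id, sample_id, label, subtype, page_index). The
    study config is written as YAML and a JSON manifest records seeds, cell
    counts, requested subtype fractions and a config hash.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise ConfigurationError(f"cannot create output dir {out}: {e}") from e
    manifest: dict = {"config_hash": config.config_hash(), "samples": []}
    for pop in config.all_samples:
        images, records = generate_sample(pop, config.imaging)
        stack = np.stack([im.phase for im in images]).astype(np.float32)
        tiff_path = out / f"{pop.sample_id}.tiff"
        csv_path = out / f"{pop.sample_id}.csv"
        try:
            tifffile.imwrite(tiff_path, stack)
            pd.DataFrame([r.as_dict() for r in records]).to_csv(csv_path, index=False)
        except OSError as e:
            raise ConfigurationError(f"I/O failure writing {tiff_path}: {e}") from e
        n_crit = sum(r.subtype == "critically_sickled" for r in records)
        manifest["samples"].append(
            {
                "sample_id": pop.sample_id,
                "label": pop.label,
                "n_cells": pop.n_cells,
                "seed": pop.seed,
                "requested_fractions": list(pop.subtype_fractions),
                "realized_critical_fraction": n_crit / pop.n_cells,
                "tiff": tiff_path.name,
                "csv": csv_path.name,
            }
        )
    with open(out / "study_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
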