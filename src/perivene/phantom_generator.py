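"""Synthetic cranial phantoms, cohorts and two-rater tables with known truth.

The phantom emulates, at configurable resolution, the appearance needed by the
measurement pipeline: a skull shell whose diploe carries tubular veins with a
signal-suppressed lumen wrapped in a high-signal sheath, a dark midline sinus
tube near the vertex flanked by high-signal dural blobs, and a brain
compartment, all with per-structure ground-truth masks and volumes.

The cohort generator draws per-subject volumes from log-normal marginals
(median/IQR-parameterized) tied to age through a Gaussian copula, and the
rater generator draws two-rater tables from an additive subject + rater +
residual model on the Ln(x+1) scale.  Default calibration constants live in
``perivene/data/calibration.yaml``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .image_io import BinaryMask, ImageVolume, mask_volume_mm3

__all__ = [
    "VeinSpec",
    "PhantomSpec",
    "PhantomTruth",
    "MarginalParams",
    "CohortParams",
    "RaterParams",
    "rasterize_tube",
    "build_phantom",
    "default_phantom_spec",
    "generate_cohort",
    "generate_rater_pairs",
    "load_calibration",
    "cohort_params_from_calibration",
    "rater_params_from_calibration",
    "fit_lognormal_sigma",
    "spearman_to_pearson",
    "pearson_to_spearman",
]

_Z75 = float(stats.norm.ppf(0.75))


# --------------------------------------------------------------------------
# phantom geometry
# --------------------------------------------------------------------------

@dataclass
class VeinSpec:
    """A tubular diploic vein: centerline polyline (mm), lumen radius and
    sheath thickness (mm)."""

    centerline: np.ndarray
    lumen_radius_mm: float
    sheath_thickness_mm: float

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ValueError("centerline must be an (N, 3) array of mm points")
        if self.centerline.shape[0] < 2:
            raise ValueError("centerline needs at least 2 points")
        if self.lumen_radius_mm < 0:
            raise ValueError("lumen radius must be >= 0")
        if self.sheath_thickness_mm <= 0:
            raise ValueError("sheath thickness must be > 0")


@dataclass
class PhantomSpec:
    """Full geometric and photometric description of a synthetic head."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    skull_center_mm: tuple[float, float, float]
    skull_outer_axes_mm: tuple[float, float, float]
    outer_table_mm: float
    diploe_mm: float
    inner_table_mm: float
    brain_axes_mm: tuple[float, float, float]
    veins: list[VeinSpec]
    sss_centerline: np.ndarray
    sss_radius_mm: float
    psd_blobs: list[tuple[tuple[float, float, float], float]]
    ventricle_top_z: int
    intensities: dict[str, float] = field(
        default_factory=lambda: {
            "air": 0.0,
            "lumen": 30.0,
            "diploe": 60.0,
            "parenchyma": 100.0,
            "high_signal": 200.0,
        }
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.sss_centerline = np.asarray(self.sss_centerline, dtype=float)
        ints = self.intensities
        if not (ints["high_signal"] > ints["diploe"] > ints["lumen"]):
            raise ValueError("intensity ordering must satisfy high_signal > diploe > lumen")
        if not 0 <= self.ventricle_top_z < self.shape[2]:
            raise ValueError("ventricle_top_z outside the grid")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for v in self.veins:
            if v.lumen_radius_mm < 0 or v.sheath_thickness_mm <= 0:
                raise ValueError("invalid vein radii")


@dataclass
class PhantomTruth:
    """Ground-truth masks and volumes for a synthetic head.

    ``rasterized_mm3`` holds the voxel-count volume of each mask (an exact
    bookkeeping identity with :func:`mask_volume_mm3`); ``analytic_mm3``
    holds closed-form volumes where the structure has one (ellipsoids,
    non-clipped spheres), else ``None``.
    """

    masks: dict[str, BinaryMask]
    rasterized_mm3: dict[str, float]
    analytic_mm3: dict[str, float | None]
    ventricle_top_z: int


def _voxel_axes_mm(shape, spacing):
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def _ellipsoid_mask(shape, spacing, center, axes) -> np.ndarray:
    xs, ys, zs = _voxel_axes_mm(shape, spacing)
    u = ((xs - center[0]) / axes[0]) ** 2
    v = ((ys - center[1]) / axes[1]) ** 2
    w = ((zs - center[2]) / axes[2]) ** 2
    return (u[:, None, None] + v[None, :, None] + w[None, None, :]) <= 1.0


def _sphere_mask(shape, spacing, center, radius) -> np.ndarray:
    return _ellipsoid_mask(shape, spacing, center, (radius, radius, radius))


def rasterize_tube(
    centerline: np.ndarray,
    radius_mm: float,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> BinaryMask:
    """Rasterize a tube around a polyline: voxels whose center lies within
    ``radius_mm`` of the (piecewise-linear) centerline are set to 1.

    A zero radius yields an empty mask; a single-point centerline is an error.
    """
    pts = np.asarray(centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("centerline must be an (N, 3) array of mm points")
    if pts.shape[0] < 2:
        raise ValueError("degenerate centerline: need at least 2 points")
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    out = np.zeros(shape, dtype=bool)
    if radius_mm == 0:
        return BinaryMask(out, spacing)
    sp = np.asarray(spacing, dtype=float)
    for p, q in zip(pts[:-1], pts[1:]):
        lo = np.minimum(p, q) - radius_mm
        hi = np.maximum(p, q) + radius_mm
        i0 = np.maximum(np.floor(lo / sp).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / sp).astype(int) + 1, np.asarray(shape))
        if np.any(i0 >= i1):
            continue
        ax = [np.arange(i0[d], i1[d]) * sp[d] for d in range(3)]
        X = ax[0][:, None, None]
        Y = ax[1][None, :, None]
        Z = ax[2][None, None, :]
        v = q - p
        vv = float(v @ v)
        if vv == 0:
            continue
        t = ((X - p[0]) * v[0] + (Y - p[1]) * v[1] + (Z - p[2]) * v[2]) / vv
        d2 = (
            (p[0] + t * v[0] - X) ** 2
            + (p[1] + t * v[1] - Y) ** 2
            + (p[2] + t * v[2] - Z) ** 2
        )
        # flat-ended cylinder per segment: perpendicular distance within the
        # axial span (no spherical end caps)
        sub = (t >= 0.0) & (t <= 1.0) & (d2 <= radius_mm**2)
        out[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]] |= sub
    return BinaryMask(out, spacing)


def default_phantom_spec(
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """The stock head phantom on a 96 x 96 x 120 mm physical extent.

    The anatomy is fixed in millimetres, so different ``spacing`` choices
    rasterize the same head.  Three diploic veins (sheath thickness 2.6 mm,
    comfortably above the 2 mm diameter criterion) arc through the diploe
    near the vertex; a dark sinus tube runs along the midline with four
    high-signal dural blobs tangent to it, all above the ventricle landmark.
    """
    extent = (96.0, 96.0, 120.0)
    shape = tuple(int(round(e / s)) for e, s in zip(extent, spacing))
    center = (48.0, 48.0, 52.0)
    skull_outer = (44.0, 44.0, 50.0)
    outer_table, diploe, inner_table = 1.0, 7.0, 1.0

    # veins: arcs on the mid-diploe ellipsoid, in x-z planes at three y levels
    mid_ax = skull_outer[0] - outer_table - diploe / 2.0   # 39.5
    mid_az = skull_outer[2] - outer_table - diploe / 2.0   # 45.5
    veins = []
    for y in (34.0, 48.0, 62.0):
        dy = y - center[1]
        scale = math.sqrt(max(0.0, 1.0 - (dy / mid_ax) ** 2))
        ax, az = mid_ax * scale, mid_az * scale
        t = np.linspace(-0.55, 0.55, 25)
        line = np.stack(
            [center[0] + ax * np.sin(t), np.full_like(t, y), center[2] + az * np.cos(t)],
            axis=1,
        )
        veins.append(VeinSpec(line, lumen_radius_mm=0.5, sheath_thickness_mm=2.6))

    # superior sagittal sinus: midline arc in the y-z plane
    t = np.linspace(-0.6, 0.6, 25)
    sss_line = np.stack(
        [np.full_like(t, center[0]), center[1] + 30.0 * np.sin(t), center[2] + 37.5 * np.cos(t)],
        axis=1,
    )

    # parasagittal blobs tangent to the sinus, alternating sides
    blobs = []
    for tt, side in ((-0.45, 1.0), (-0.15, -1.0), (0.15, 1.0), (0.45, -1.0)):
        c = (
            center[0] + side * 5.6,
            center[1] + 30.0 * math.sin(tt),
            center[2] + 37.5 * math.cos(tt),
        )
        blobs.append((c, 3.0))

    return PhantomSpec(
        shape=shape,
        spacing=tuple(float(s) for s in spacing),
        skull_center_mm=center,
        skull_outer_axes_mm=skull_outer,
        outer_table_mm=outer_table,
        diploe_mm=diploe,
        inner_table_mm=inner_table,
        brain_axes_mm=(31.0, 31.0, 33.0),
        veins=veins,
        sss_centerline=sss_line,
        sss_radius_mm=2.5,
        psd_blobs=blobs,
        ventricle_top_z=int(round(60.0 / spacing[2])),
        noise_sd=noise_sd,
        seed=seed,
    )


def build_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Rasterize a phantom: intensity image plus ground-truth masks/volumes.

    Deterministic for a fixed spec and seed.  Veins reaching outside the
    diploe are clipped to it with a warning.
    """
    shape, spacing = spec.shape, spec.spacing
    c = spec.skull_center_mm
    outer = _ellipsoid_mask(shape, spacing, c, spec.skull_outer_axes_mm)
    d_out = tuple(a - spec.outer_table_mm for a in spec.skull_outer_axes_mm)
    d_in = tuple(a - spec.diploe_mm for a in d_out)
    cavity_axes = tuple(a - spec.inner_table_mm for a in d_in)
    diploe = _ellipsoid_mask(shape, spacing, c, d_out) & ~_ellipsoid_mask(shape, spacing, c, d_in)
    cavity = _ellipsoid_mask(shape, spacing, c, cavity_axes)
    skull = outer & ~cavity
    brain = _ellipsoid_mask(shape, spacing, c, spec.brain_axes_mm)

    lumen = np.zeros(shape, dtype=bool)
    sheath = np.zeros(shape, dtype=bool)
    clipped = 0
    for vein in spec.veins:
        r_out = vein.lumen_radius_mm + vein.sheath_thickness_mm
        tube = rasterize_tube(vein.centerline, r_out, shape, spacing).as_bool()
        clipped += int(np.count_nonzero(tube & ~diploe))
        tube &= diploe
        lum = rasterize_tube(vein.centerline, vein.lumen_radius_mm, shape, spacing).as_bool()
        lum &= diploe
        lumen |= lum
        sheath |= tube & ~lum
    sheath &= ~lumen
    if clipped:
        warnings.warn(
            f"{clipped} vein voxels extended outside the diploe and were clipped",
            stacklevel=2,
        )

    sss = rasterize_tube(spec.sss_centerline, spec.sss_radius_mm, shape, spacing).as_bool()
    sss &= cavity

    psd = np.zeros(shape, dtype=bool)
    for blob_c, blob_r in spec.psd_blobs:
        psd |= _sphere_mask(shape, spacing, blob_c, blob_r)
    psd &= cavity & ~sss & ~brain

    landmark = np.zeros(shape, dtype=bool)
    zi = spec.ventricle_top_z
    ci = tuple(int(round(c[d] / spacing[d])) for d in range(3))
    landmark[ci[0] - 1 : ci[0] + 2, ci[1] - 1 : ci[1] + 2, zi] = True

    ints = spec.intensities
    img = np.full(shape, ints["air"], dtype=np.float64)
    img[brain] = ints["parenchyma"]
    img[skull] = ints["diploe"]
    img[sheath] = ints["high_signal"]
    img[lumen] = ints["lumen"]
    img[sss] = ints["lumen"]
    img[psd] = ints["high_signal"]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)

    def _mask(a: np.ndarray) -> BinaryMask:
        return BinaryMask(a, spacing)

    masks = {
        "sheath": _mask(sheath),
        "lumen": _mask(lumen),
        "sss": _mask(sss),
        "psd": _mask(psd),
        "brain": _mask(brain),
        "skull": _mask(skull),
        "diploe": _mask(diploe),
        "ventricle_landmark": _mask(landmark),
    }
    rasterized = {k: mask_volume_mm3(m) for k, m in masks.items()}

    def _ell_vol(axes):
        return 4.0 / 3.0 * math.pi * axes[0] * axes[1] * axes[2]

    analytic: dict[str, float | None] = {k: None for k in masks}
    analytic["brain"] = _ell_vol(spec.brain_axes_mm)
    analytic["skull"] = _ell_vol(spec.skull_outer_axes_mm) - _ell_vol(cavity_axes)
    analytic["psd"] = sum(4.0 / 3.0 * math.pi * r**3 for _, r in spec.psd_blobs)

    truth = PhantomTruth(
        masks=masks,
        rasterized_mm3=rasterized,
        analytic_mm3=analytic,
        ventricle_top_z=spec.ventricle_top_z,
    )
    return ImageVolume(img, spacing), truth


# --------------------------------------------------------------------------
# cohort generator
# --------------------------------------------------------------------------

def spearman_to_pearson(rho_s: float) -> float:
    """Latent Gaussian (Pearson) correlation giving Spearman ``rho_s`` under a
    Gaussian copula: r = 2 sin(pi * rho_s / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def pearson_to_spearman(r: float) -> float:
    """Inverse of :func:`spearman_to_pearson`: rho_s = 6/pi * arcsin(r / 2)."""
    return 6.0 / math.pi * math.asin(r / 2.0)


def fit_lognormal_sigma(median: float, iqr: tuple[float, float]) -> float:
    """Log-scale sigma of a log-normal with the given median whose quartile
    span q75 - q25 matches the given IQR (numeric fit)."""
    if median <= 0:
        raise ValueError("median must be > 0")
    width = float(iqr[1]) - float(iqr[0])
    if width <= 0:
        raise ValueError("IQR upper bound must exceed lower bound")

    def gap(sigma: float) -> float:
        return 2.0 * median * math.sinh(_Z75 * sigma) - width

    return float(optimize.brentq(gap, 1e-9, 30.0, xtol=1e-12))


@dataclass
class MarginalParams:
    """Log-normal marginal for one corrected volume (mm^3 cm^-3) with its age
    rank-correlation and male/female multiplicative shift."""

    median: float
    iqr: tuple[float, float]
    age_spearman: float
    male_female_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError("median must be > 0")
        if not -1.0 <= self.age_spearman <= 1.0:
            raise ValueError("rank correlation must lie in [-1, 1]")
        if self.male_female_ratio <= 0:
            raise ValueError("sex ratio must be > 0")

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        return fit_lognormal_sigma(self.median, self.iqr)


@dataclass
class CohortParams:
    n: int
    dv: MarginalParams
    psd: MarginalParams
    age_range: tuple[float, float] = (14.0, 84.0)
    male_fraction: float = 45.0 / 98.0
    dv_psd_spearman: float = 0.0
    icv_median_cm3: float = 1500.0
    icv_sigma_log: float = 0.08
    icv_male_female_ratio: float = 1.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 subjects")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male fraction must lie in [0, 1]")
        if self.age_range[1] <= self.age_range[0]:
            raise ValueError("age range must be increasing")
        if self.icv_median_cm3 <= 0 or self.icv_sigma_log < 0:
            raise ValueError("invalid ICV distribution parameters")


def _sex_shift(log_ratio: float, male: np.ndarray, p_male: float) -> np.ndarray:
    # centered so the population median is (to first order) unchanged
    return log_ratio * (male.astype(float) - p_male)


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Columns: ``id``, ``age`` (years), ``sex`` (``M``/``F``), ``dv_volume``
    (mm^3), ``psd_volume`` (mm^3), ``icv`` (cm^3).  The ICV-corrected volumes
    (volume / icv) follow the configured log-normal marginals exactly, with
    age rank-dependence induced by a Gaussian copula whose latent Pearson
    parameter is ``2 sin(pi * rho_s / 6)``.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    r_ad = spearman_to_pearson(params.dv.age_spearman)
    r_ap = spearman_to_pearson(params.psd.age_spearman)
    r_dp = spearman_to_pearson(params.dv_psd_spearman)
    corr = np.array([[1.0, r_ad, r_ap], [r_ad, 1.0, r_dp], [r_ap, r_dp, 1.0]])
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError("copula correlation matrix is not positive definite") from err

    z = rng.standard_normal((n, 3)) @ chol.T
    z_age, z_dv, z_psd = z[:, 0], z[:, 1], z[:, 2]
    z_icv = rng.standard_normal(n)
    male = rng.random(n) < params.male_fraction

    lo, hi = params.age_range
    age = lo + (hi - lo) * stats.norm.cdf(z_age)

    dv_corr = np.exp(
        params.dv.mu
        + params.dv.sigma * z_dv
        + _sex_shift(math.log(params.dv.male_female_ratio), male, params.male_fraction)
    )
    psd_corr = np.exp(
        params.psd.mu
        + params.psd.sigma * z_psd
        + _sex_shift(math.log(params.psd.male_female_ratio), male, params.male_fraction)
    )
    icv = np.exp(
        math.log(params.icv_median_cm3)
        + params.icv_sigma_log * z_icv
        + _sex_shift(math.log(params.icv_male_female_ratio), male, params.male_fraction)
    )

    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age": age,
            "sex": np.where(male, "M", "F"),
            "dv_volume": dv_corr * icv,
            "psd_volume": psd_corr * icv,
            "icv": icv,
        }
    )


# --------------------------------------------------------------------------
# rater-table generator
# --------------------------------------------------------------------------

@dataclass
class RaterParams:
    """Two-rater measurement model on the Ln(x+1) scale.

    ``ln1p(volume) = mean_log + subject + rater + residual`` with independent
    zero-mean Gaussian components; the population ICC(2,1) is
    ``subject_var / (subject_var + rater_var + residual_var)``.
    """

    n_subjects: int
    subject_var: float
    rater_var: float
    residual_var: float
    mean_log: float = 5.0
    n_raters: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_raters < 2:
            raise ValueError("need at least 2 raters")
        if min(self.subject_var, self.rater_var, self.residual_var) < 0:
            raise ValueError("variance components must be >= 0")
        if self.subject_var + self.rater_var + self.residual_var == 0:
            raise ValueError("all variance components are zero: ICC undefined")

    @property
    def population_icc(self) -> float:
        return self.subject_var / (self.subject_var + self.rater_var + self.residual_var)


def generate_rater_pairs(params: RaterParams) -> pd.DataFrame:
    """Draw an ``n_subjects x n_raters`` table of positive volumes whose
    Ln(x+1) values follow the additive components of ``params``.

    Log-scale values are floored at a tiny positive constant so volumes are
    strictly positive (the floor is hit with negligible probability at the
    default calibration).  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n, k = params.n_subjects, params.n_raters
    subj = rng.normal(0.0, math.sqrt(params.subject_var), size=n)
    rater = rng.normal(0.0, math.sqrt(params.rater_var), size=k)
    resid = rng.normal(0.0, math.sqrt(params.residual_var), size=(n, k))
    y = params.mean_log + subj[:, None] + rater[None, :] + resid
    y = np.maximum(y, 1e-9)
    vols = np.expm1(y)
    return pd.DataFrame(vols, columns=[f"rater{j + 1}" for j in range(k)])


# --------------------------------------------------------------------------
# calibration file
# --------------------------------------------------------------------------

def load_calibration(path: str | Path | None = None) -> dict:
    """Load the versioned calibration constants (packaged YAML by default)."""
    if path is None:
        text = resources.files("perivene").joinpath("data/calibration.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def cohort_params_from_calibration(
    calibration: dict | None = None, n: int | None = None, seed: int = 0
) -> CohortParams:
    cal = (calibration or load_calibration())["cohort"]

    def marg(d: dict) -> MarginalParams:
        return MarginalParams(
            median=float(d["corrected_median"]),
            iqr=tuple(float(v) for v in d["corrected_iqr"]),
            age_spearman=float(d["age_spearman"]),
            male_female_ratio=float(d.get("male_female_ratio", 1.0)),
        )

    return CohortParams(
        n=int(n if n is not None else cal["n"]),
        dv=marg(cal["dv"]),
        psd=marg(cal["psd"]),
        age_range=tuple(float(v) for v in cal["age_range"]),
        male_fraction=float(cal["male_fraction"]),
        dv_psd_spearman=float(cal.get("dv_psd_spearman", 0.0)),
        icv_median_cm3=float(cal["icv"]["median_cm3"]),
        icv_sigma_log=float(cal["icv"]["sigma_log"]),
        icv_male_female_ratio=float(cal["icv"]["male_female_ratio"]),
        seed=seed,
    )


def rater_params_from_calibration(
    structure: str, calibration: dict | None = None, n_subjects: int | None = None, seed: int = 0
) -> RaterParams:
    cal = (calibration or load_calibration())["raters"]
    if structure not in ("dv", "psd"):
        raise ValueError("structure must be 'dv' or 'psd'")
    d = cal[structure]
    return RaterParams(
        n_subjects=int(n_subjects if n_subjects is not None else cal["n_subjects"]),
        subject_var=float(d["subject_var"]),
        rater_var=float(d["rater_var"]),
        residual_var=float(d["residual_var"]),
        mean_log=float(d["mean_log"]),
        seed=seed,
    )
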