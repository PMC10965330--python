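"""Synthetic villus phantoms with closed-form ground truth.

Generators for (i) 3D voxelized primitives (spheres, capped cylinders) whose
volume and surface area are known analytically, (ii) 2D villus cross-sections
with a trophoblast ring, stroma, capillary lumens and optional basal-membrane
invaginations, (iii) noisy intensity renderings of any label image, and
(iv) multi-placenta cohorts that emulate the human (smooth, lower SA:V) versus
equid (invaginated, higher SA:V) contrast with recorded per-villus ground truth.

Every generator is deterministic under a fixed seed. Voxelization uses a
center-inside rule: a voxel/pixel is foreground iff its center lies strictly
inside the continuous generating shape.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .datatypes import (BACKGROUND, CAPILLARY, STROMA, TROPHOBLAST,
                        CrossSectionLabels, IntensityImage, LabelVolume)
from .errors import (BoundsError, ConfigurationError, FeasibilityError,
                     GeometryError)

__all__ = [
    "PrimitiveSpec", "CrossSectionSpec", "GroupSpec", "CohortSpec",
    "GroundTruth3D", "GroundTruth2D", "Cohort",
    "make_primitive_label", "make_cross_section", "render_intensity",
    "make_cohort", "study_cohort_spec", "matched_smooth_spec",
]


# ---------------------------------------------------------------------------
# 3D primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimitiveSpec:
    """A continuous 3D primitive to voxelize.

    ``capped_cylinder`` is a cylinder of length ``length`` (axis along z)
    closed by two hemispherical caps of the same radius, so total extent along
    the axis is ``length + 2 * radius``.
    """

    shape: str  # "sphere" | "capped_cylinder"
    radius: float  # µm
    voxel_size: float  # µm
    length: float | None = None  # µm, cylinder barrel only
    center: tuple[float, float, float] | None = None  # µm, grid coordinates
    grid_shape: tuple[int, int, int] | None = None  # voxels; auto-sized if None

    def __post_init__(self):
        if self.shape not in ("sphere", "capped_cylinder"):
            raise ConfigurationError(f"unknown primitive shape {self.shape!r}")
        if self.radius <= 0:
            raise ConfigurationError("radius must be > 0")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be > 0")
        if self.shape == "capped_cylinder":
            if self.length is None or self.length <= 0:
                raise ConfigurationError("capped_cylinder requires length > 0")

    def half_extent(self) -> np.ndarray:
        """Half-extent of the primitive along (z, y, x) in µm."""
        r = self.radius
        if self.shape == "sphere":
            return np.array([r, r, r])
        return np.array([self.length / 2 + r, r, r])


@dataclass(frozen=True)
class GroundTruth3D:
    """Analytic volume (µm³) and surface area (µm²) of the continuous shape."""

    volume: float
    surface_area: float

    @property
    def sa_to_v(self) -> float:
        """Surface-area-to-volume ratio in mm⁻¹ (µm²/µm³ × 10³)."""
        return self.surface_area / self.volume * 1e3


def _analytic_primitive(spec: PrimitiveSpec) -> GroundTruth3D:
    r = spec.radius
    if spec.shape == "sphere":
        return GroundTruth3D(4 / 3 * math.pi * r**3, 4 * math.pi * r**2)
    length = spec.length
    volume = math.pi * r**2 * length + 4 / 3 * math.pi * r**3
    area = 2 * math.pi * r * length + 4 * math.pi * r**2
    return GroundTruth3D(volume, area)


def make_primitive_label(spec: PrimitiveSpec) -> tuple[LabelVolume, GroundTruth3D]:
    """Voxelize a primitive; return the label volume and its analytic truth.

    The voxel grid is auto-sized to contain the primitive with a two-voxel
    margin unless ``grid_shape`` is given, in which case the primitive (plus
    one voxel of margin) must fit or a :class:`BoundsError` is raised.
    """
    vs = spec.voxel_size
    half = spec.half_extent()
    if spec.grid_shape is None:
        shape = tuple(int(np.ceil(2 * h / vs)) + 4 for h in half)
        center = tuple(s * vs / 2 for s in shape)
    else:
        shape = tuple(int(s) for s in spec.grid_shape)
        center = spec.center or tuple(s * vs / 2 for s in shape)
        lo = np.array(center) - half
        hi = np.array(center) + half
        if np.any(lo < vs) or np.any(hi > (np.array(shape) - 1) * vs):
            raise BoundsError(
                f"primitive extent [{lo}, {hi}] µm exceeds grid "
                f"{shape} voxels at {vs} µm (need ≥1 voxel margin)")

    zz, yy, xx = [
        (np.arange(n) + 0.5) * vs - c for n, c in zip(shape, center)
    ]
    z = zz[:, None, None]
    y = yy[None, :, None]
    x = xx[None, None, :]

    if spec.shape == "sphere":
        inside = z * z + y * y + x * x < spec.radius**2
    else:
        half_l = spec.length / 2
        rho2 = y * y + x * x
        barrel = (np.abs(z) <= half_l) & (rho2 < spec.radius**2)
        caps = (np.abs(z) > half_l) & (
            rho2 + (np.abs(z) - half_l) ** 2 < spec.radius**2)
        inside = barrel | caps

    labels = inside.astype(np.uint16)
    volume = LabelVolume(labels, voxel_size=vs,
                         provenance=f"phantom:{spec.shape} R={spec.radius}µm")
    return volume, _analytic_primitive(spec)


# ---------------------------------------------------------------------------
# 2D cross-sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossSectionSpec:
    """A villus cross-section: trophoblast ring around a stroma core.

    The basal (inner trophoblast) contour is a circle of radius
    ``outer_radius - trophoblast_thickness``, optionally perturbed inward by
    ``invagination_count`` smooth periodic bumps of depth
    ``invagination_depth`` and arc-length FWHM ``invagination_width``.
    Capillary lumens are discs that must lie strictly inside the stroma.
    """

    outer_radius: float  # µm
    trophoblast_thickness: float  # µm
    capillary_centers: tuple[tuple[float, float], ...] = ()  # µm, villus-centred
    capillary_radius: float = 0.0  # µm
    invagination_count: int = 0
    invagination_depth: float = 0.0  # µm
    invagination_width: float = 0.0  # µm, arc-length FWHM of each bump
    pixel_size: float = 0.25  # µm
    seed: int = 0
    n_contour_vertices: int = 2048

    def __post_init__(self):
        if self.outer_radius <= 0 or self.pixel_size <= 0:
            raise ConfigurationError("outer_radius and pixel_size must be > 0")
        if not 0 < self.trophoblast_thickness < self.outer_radius:
            raise ConfigurationError(
                "trophoblast_thickness must lie in (0, outer_radius)")
        if self.invagination_count < 0:
            raise ConfigurationError("invagination_count must be ≥ 0")
        basal = self.outer_radius - self.trophoblast_thickness
        if self.invagination_count > 0:
            if self.invagination_depth <= 0 or self.invagination_width <= 0:
                raise ConfigurationError(
                    "invaginated sections need depth and width > 0")
            if self.invagination_depth >= basal:
                raise ConfigurationError(
                    "invagination_depth must be < outer_radius - trophoblast_thickness")
        if self.capillary_centers and self.capillary_radius <= 0:
            raise ConfigurationError("capillary_radius must be > 0 when capillaries given")

    @property
    def basal_radius_smooth(self) -> float:
        return self.outer_radius - self.trophoblast_thickness

    def basal_radius(self, theta: np.ndarray) -> np.ndarray:
        """Basal contour radius r(θ) with periodic Gaussian invaginations."""
        r0 = self.basal_radius_smooth
        theta = np.asarray(theta, dtype=float)
        if self.invagination_count == 0:
            return np.full_like(theta, r0)
        k = self.invagination_count
        # Angular distance to the nearest bump centre (bumps at 2πj/k).
        dtheta = np.mod(theta, 2 * math.pi / k)
        dtheta = np.minimum(dtheta, 2 * math.pi / k - dtheta)
        sigma_arc = self.invagination_width / 2.355  # FWHM → σ
        g = np.exp(-0.5 * (dtheta * r0 / sigma_arc) ** 2)
        return r0 - self.invagination_depth * g


@dataclass(frozen=True)
class GroundTruth2D:
    """Perimeter (µm) and area (µm²) of the generating basal contour polygon."""

    inner_perimeter: float
    inner_area: float

    @property
    def pa(self) -> float:
        """Perimeter-to-area ratio in µm⁻¹."""
        return self.inner_perimeter / self.inner_area


def basal_contour_vertices(spec: CrossSectionSpec) -> np.ndarray:
    """Vertices (N, 2) of the basal contour polygon, counter-clockwise."""
    theta = np.linspace(0.0, 2 * math.pi, spec.n_contour_vertices,
                        endpoint=False)
    r = spec.basal_radius(theta)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def contour_ground_truth(spec: CrossSectionSpec) -> GroundTruth2D:
    """Perimeter and area of the generating contour (shapely polygon)."""
    poly = Polygon(basal_contour_vertices(spec))
    return GroundTruth2D(inner_perimeter=poly.length, inner_area=poly.area)


def _validate_capillaries(spec: CrossSectionSpec) -> None:
    centers = np.asarray(spec.capillary_centers, dtype=float)
    if centers.size == 0:
        return
    rc = spec.capillary_radius
    # Pairwise overlap.
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.hypot(*(centers[i] - centers[j])) <= 2 * rc:
                raise GeometryError(
                    f"capillaries {i} and {j} overlap (centres "
                    f"{centers[i]}, {centers[j]}, radius {rc} µm)")
    # Strict containment inside the basal contour.
    phi = np.linspace(0, 2 * math.pi, 256, endpoint=False)
    ring = np.column_stack([np.cos(phi), np.sin(phi)]) * rc
    for i, c in enumerate(centers):
        pts = c + ring
        r_pt = np.hypot(pts[:, 0], pts[:, 1])
        th_pt = np.arctan2(pts[:, 1], pts[:, 0])
        if np.any(r_pt >= spec.basal_radius(th_pt)):
            raise GeometryError(
                f"capillary {i} at {tuple(c)} (radius {rc} µm) intersects "
                "the basal contour")


def make_cross_section(
        spec: CrossSectionSpec) -> tuple[CrossSectionLabels, GroundTruth2D]:
    """Rasterize a villus cross-section; return labels and contour ground truth.

    Labels: 0 background, 1 trophoblast, 2 stroma, 3 capillary. A pixel
    belongs to a region iff its center lies inside the continuous region.
    """
    _validate_capillaries(spec)
    ps = spec.pixel_size
    n = int(np.ceil(2 * (spec.outer_radius + 3 * ps) / ps))
    n += n % 2  # even grid → villus centre exactly at the grid centre
    coords = (np.arange(n) + 0.5) * ps - n * ps / 2
    yy = coords[:, None]
    xx = coords[None, :]
    r = np.hypot(yy, xx)
    theta = np.arctan2(yy, xx)

    inside_outer = r < spec.outer_radius
    inside_basal = r < spec.basal_radius(theta)

    labels = np.zeros((n, n), dtype=np.uint16)
    labels[inside_outer & ~inside_basal] = TROPHOBLAST
    labels[inside_basal] = STROMA
    if spec.capillary_centers:
        for cx, cy in spec.capillary_centers:
            cap = (xx - cx) ** 2 + (yy - cy) ** 2 < spec.capillary_radius**2
            labels[cap] = CAPILLARY

    cross = CrossSectionLabels(
        labels, pixel_size=ps,
        provenance=(f"phantom:cross-section r_outer={spec.outer_radius}µm "
                    f"invaginations={spec.invagination_count}"))
    return cross, contour_ground_truth(spec)


def matched_smooth_spec(invaginated: CrossSectionSpec) -> CrossSectionSpec:
    """Smooth cross-section whose inner area equals the invaginated one's.

    Keeps the outer radius and capillary layout; sets the basal contour to a
    circle of equal enclosed area by adjusting trophoblast thickness.
    """
    area = contour_ground_truth(invaginated).inner_area
    r_eq = math.sqrt(area / math.pi)
    thickness = invaginated.outer_radius - r_eq
    if thickness <= 0:
        raise GeometryError("equal-area smooth contour exceeds the outer radius")
    return replace(invaginated, trophoblast_thickness=thickness,
                   invagination_count=0, invagination_depth=0.0,
                   invagination_width=0.0)


# ---------------------------------------------------------------------------
# Intensity rendering
# ---------------------------------------------------------------------------

def render_intensity(labels: LabelVolume | CrossSectionLabels,
                     class_means: dict[int, float],
                     noise_sd: float = 0.0,
                     seed: int = 0) -> IntensityImage:
    """Render a label image to intensities: class mean + i.i.d. Gaussian noise."""
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be ≥ 0")
    arr = labels.labels
    present = np.unique(arr)
    missing = [int(v) for v in present if int(v) not in class_means]
    if missing:
        raise ConfigurationError(f"no class mean assigned for labels {missing}")
    out = np.zeros(arr.shape, dtype=np.float32)
    for value, mean in class_means.items():
        out[arr == value] = mean
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=arr.shape).astype(np.float32)
    size = labels.voxel_size if isinstance(labels, LabelVolume) else labels.pixel_size
    return IntensityImage(out, pixel_size=size,
                          provenance=f"render(noise_sd={noise_sd}, seed={seed})")


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One experimental group of the synthetic cohort."""

    label: str
    n_placentas: int
    n_villi_per_placenta: int
    target_sa_to_v_mean: float  # mm⁻¹, between-placenta mean
    target_sa_to_v_sd: float  # mm⁻¹, between-placenta SD
    target_pa_mean: float  # µm⁻¹
    target_pa_sd: float  # µm⁻¹
    invagination_count: int = 0

    def __post_init__(self):
        if self.n_placentas < 1 or self.n_villi_per_placenta < 1:
            raise ConfigurationError("all cohort n must be ≥ 1")
        if self.target_sa_to_v_mean <= 0 or self.target_pa_mean <= 0:
            raise ConfigurationError("cohort target means must be > 0")
        if self.target_sa_to_v_sd < 0 or self.target_pa_sd < 0:
            raise ConfigurationError("cohort target SDs must be ≥ 0")


@dataclass(frozen=True)
class CohortSpec:
    """A multi-group, multi-placenta synthetic study design.

    Between-placenta variation carries the target SDs (summary statistics are
    computed from per-placenta means); within-placenta villus-to-villus spread
    is a smaller relative jitter, ``within_placenta_cv``.
    """

    groups: tuple[GroupSpec, ...]
    seed: int = 0
    voxel_size: float = 4.8  # µm, microCT-like
    pixel_size: float = 0.25  # µm, cross-section raster
    within_placenta_cv: float = 0.10

    def __post_init__(self):
        if not self.groups:
            raise ConfigurationError("cohort needs at least one group")
        if self.voxel_size <= 0 or self.pixel_size <= 0:
            raise ConfigurationError("voxel_size and pixel_size must be > 0")


@dataclass
class Cohort:
    """Generated cohort: ground-truth table plus optional raster artifacts."""

    table: pd.DataFrame
    volumes: list[LabelVolume] = field(default_factory=list)
    cross_sections: list[CrossSectionLabels] = field(default_factory=list)


def study_cohort_spec(seed: int = 0,
                      n_villi_per_placenta: int = 5,
                      voxel_size: float = 4.8,
                      pixel_size: float = 0.25) -> CohortSpec:
    """Default two-group design emulating the human vs equid contrast.

    Human-like: n = 5 placentas, smooth basal membrane, SA:V 43.34 ± 6.78 mm⁻¹,
    P:A 0.12 ± 0.03 µm⁻¹. Equid-like: n = 12 placentas, 12 basal invaginations,
    SA:V 73.47 ± 14.91 mm⁻¹, P:A 0.24 ± 0.07 µm⁻¹.
    """
    return CohortSpec(
        groups=(
            GroupSpec("human", 5, n_villi_per_placenta,
                      43.34, 6.78, 0.12, 0.03, invagination_count=0),
            GroupSpec("equid", 12, n_villi_per_placenta,
                      73.47, 14.91, 0.24, 0.07, invagination_count=12),
        ),
        seed=seed, voxel_size=voxel_size, pixel_size=pixel_size)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (µ, σ) of a log-normal with the given mean and SD."""
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2, math.sqrt(sigma2)


def _sample_lognormal(rng: np.random.Generator, mean: float, sd: float,
                      size=None):
    mu, sigma = _lognormal_params(mean, sd)
    if sigma == 0:
        return np.full(size, mean) if size else mean
    return rng.lognormal(mu, sigma, size=size)


def _sample_group_levels(rng: np.random.Generator, mean: float, sd: float,
                         n: int) -> np.ndarray:
    """Placenta-level values with sample moments matched to the targets.

    Draws log-normally, then affinely standardizes the sample so its
    arithmetic mean and SD equal the targets exactly: the generator emulates
    a study whose group summary statistics are given, so the realized
    between-placenta moments are made exact rather than left to drift with
    the draw (order and spacing of placentas remain random).
    """
    if n == 1 or sd == 0:
        return np.full(n, mean)
    draws = _sample_lognormal(rng, mean, sd, size=n)
    spread = float(np.std(draws, ddof=1))
    if spread == 0:
        return np.full(n, mean)
    values = mean + sd * (draws - draws.mean()) / spread
    if np.any(values <= 0):  # extreme draw shapes only; resample once
        draws = _sample_lognormal(rng, mean, sd, size=n)
        values = mean + sd * (draws - draws.mean()) / float(np.std(draws, ddof=1))
        values = np.maximum(values, 0.05 * mean)
    return values


def _polygon_pa(vertices: np.ndarray) -> float:
    """Perimeter/area of a closed polygon (shoelace + summed segment lengths)."""
    x, y = vertices[:, 0], vertices[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    d = vertices - np.roll(vertices, -1, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum() / area)


def _solve_invagination_depth(base: CrossSectionSpec, target_pa: float) -> float:
    """Bisection on depth so the generating-contour P:A hits ``target_pa``.

    P:A is strictly increasing in depth (perimeter grows, area shrinks).
    The search runs on a decimated contour for speed; the returned depth is
    accurate to ~1e-9·r0, far below raster resolution.
    """
    r0 = base.basal_radius_smooth
    probe = replace(base, n_contour_vertices=512)
    theta = np.linspace(0.0, 2 * math.pi, probe.n_contour_vertices,
                        endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    def pa_at(depth: float) -> float:
        r = replace(probe, invagination_depth=depth).basal_radius(theta)
        return _polygon_pa(np.column_stack([r * cos_t, r * sin_t]))

    lo, hi = 0.0, 0.92 * r0
    pa_lo = 2.0 / r0
    pa_hi = pa_at(hi)
    if not pa_lo < target_pa <= pa_hi:
        raise FeasibilityError(
            f"target P:A {target_pa:.4f} µm⁻¹ outside attainable range "
            f"({pa_lo:.4f}, {pa_hi:.4f}] for base radius {r0:.1f} µm")
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        if pa_at(mid) < target_pa:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _cross_section_for_pa(target_pa: float, invagination_count: int,
                          pixel_size: float, seed: int,
                          n_contour_vertices: int = 2048) -> CrossSectionSpec:
    """Build a cross-section spec whose contour P:A equals ``target_pa``.

    Smooth sections use the exact circle radius 2/pa. Invaginated sections
    start from a larger base circle (smooth P:A = target/1.6) and deepen the
    periodic perturbation until the contour P:A matches.
    """
    if target_pa <= 0:
        raise FeasibilityError("target P:A must be > 0")
    if invagination_count == 0:
        r_basal = 2.0 / target_pa
    else:
        r_basal = 1.6 * 2.0 / target_pa
    thickness = 0.25 * r_basal
    outer = r_basal + thickness
    if pixel_size > r_basal / 10:
        raise FeasibilityError(
            f"pixel size {pixel_size} µm too coarse for basal radius "
            f"{r_basal:.1f} µm (need ≤ r/10)")
    # Three capillaries well inside even the deepest invagination.
    r_cap = 0.10 * r_basal
    r_pos = 0.30 * r_basal
    angles = np.deg2rad([90.0, 210.0, 330.0])
    caps = tuple((r_pos * math.cos(a), r_pos * math.sin(a)) for a in angles)
    base = CrossSectionSpec(
        outer_radius=outer, trophoblast_thickness=thickness,
        capillary_centers=caps, capillary_radius=r_cap,
        invagination_count=invagination_count,
        invagination_depth=1e-9 if invagination_count else 0.0,
        invagination_width=(0.25 * 2 * math.pi * r_basal / invagination_count
                            if invagination_count else 0.0),
        pixel_size=pixel_size, seed=seed,
        n_contour_vertices=n_contour_vertices)
    if invagination_count == 0:
        return base
    depth = _solve_invagination_depth(base, target_pa)
    return replace(base, invagination_depth=depth)


def make_cohort(spec: CohortSpec, rasterize: bool = True) -> Cohort:
    """Draw a synthetic cohort with per-villus recorded ground truth.

    Per placenta, a placenta-level SA:V and P:A are drawn log-normally with
    the group's target mean/SD (so the between-placenta spread matches the
    targets); villi jitter log-normally around the placenta level with CV
    ``within_placenta_cv``. 3D villi are spheres of radius 3000/SA:V µm;
    2D sections hit their P:A target exactly on the generating contour.

    With ``rasterize=False`` only the ground-truth table is produced (fast
    path for replicate studies of the sampling design).
    """
    rng = np.random.default_rng(spec.seed)
    max_sa_to_v = 3000.0 / (3 * spec.voxel_size)
    rows = []
    volumes: list[LabelVolume] = []
    sections: list[CrossSectionLabels] = []
    for group in spec.groups:
        sa_levels = _sample_group_levels(rng, group.target_sa_to_v_mean,
                                         group.target_sa_to_v_sd,
                                         group.n_placentas)
        pa_levels = _sample_group_levels(rng, group.target_pa_mean,
                                         group.target_pa_sd,
                                         group.n_placentas)
        for p in range(group.n_placentas):
            placenta_id = f"{group.label}_p{p + 1}"
            sa_p = float(sa_levels[p])
            pa_p = float(pa_levels[p])
            cv = spec.within_placenta_cv
            for v in range(group.n_villi_per_placenta):
                sa_v = _sample_lognormal(rng, sa_p, cv * sa_p)
                pa_v = _sample_lognormal(rng, pa_p, cv * pa_p)
                if sa_v >= max_sa_to_v:
                    raise FeasibilityError(
                        f"sampled SA:V {sa_v:.1f} mm⁻¹ not resolvable at "
                        f"{spec.voxel_size} µm voxels (max {max_sa_to_v:.1f})")
                radius = 3000.0 / sa_v  # sphere: SA:V = 3/R
                prim = PrimitiveSpec("sphere", radius=radius,
                                     voxel_size=spec.voxel_size)
                truth3d = _analytic_primitive(prim)
                cs_spec = _cross_section_for_pa(
                    pa_v, group.invagination_count, spec.pixel_size,
                    seed=spec.seed)
                truth2d = contour_ground_truth(cs_spec)
                if rasterize:
                    vol, _ = make_primitive_label(prim)
                    vol.provenance += f" ({placenta_id} villus {v + 1})"
                    cross, _ = make_cross_section(cs_spec)
                    cross.provenance += f" ({placenta_id} villus {v + 1})"
                    volumes.append(vol)
                    sections.append(cross)
                rows.append({
                    "group": group.label,
                    "placenta_id": placenta_id,
                    "villus_id": f"{placenta_id}_v{v + 1}",
                    "volume_um3": truth3d.volume,
                    "surface_area_um2": truth3d.surface_area,
                    "sa_to_v_mm_inv": truth3d.sa_to_v,
                    "inner_perimeter_um": truth2d.inner_perimeter,
                    "inner_area_um2": truth2d.inner_area,
                    "pa_um_inv": truth2d.pa,
                    "seed": spec.seed,
                })
    table = pd.DataFrame(rows)
    return Cohort(table=table, volumes=volumes, cross_sections=sections)
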