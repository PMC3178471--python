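"""Voxelized vessel phantoms and synthetic cohort tables.

Real carotid CTA segmentations are not redistributable, so every imaging
stage of the pipeline is exercised on phantoms with analytically known
geometry: straight or sinusoidally curved tubes, and three-branch
bifurcations with optional carotid-sinus bulge on the proximal ICA.
Masks are voxelized at CTA-like anisotropic resolution by default
(2 x 0.5 x 0.5 mm) with world coordinates in mm, origin at the mask
corner, axis order (x, y, z) matching array axes (i, j, k).

A voxel belongs to the vessel iff its center lies within the local tube
radius of the centerline (voxel-center inclusion, no partial volume) —
the same contract assumed of the binary masks the pipeline consumes.

The cohort generator draws ICA/CCA and ECA/CCA radius ratios from
truncated normal distributions on (0, 1) (defaults: the published carotid
cohort means/SDs 0.67 (0.074) and 0.61 (0.087)) and an absolute CCA
radius from a lognormal with median 4 mm, optionally rescaling daughters
so the power law holds exactly at a chosen exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.spatial import cKDTree

__all__ = [
    "LabeledMask",
    "GroundTruth",
    "PhantomSpec",
    "CohortGenParams",
    "make_tube_mask",
    "make_elliptical_tube_mask",
    "make_bifurcation_phantom",
    "sample_cohort",
    "BRANCH_LABELS",
]

BRANCH_LABELS = {"cca": 1, "ica": 2, "eca": 3}

# centerline sampling step for voxelization, as a fraction of min spacing;
# distance-to-samples then approximates distance-to-curve to << one voxel
_SAMPLE_FRACTION = 0.4


@dataclass
class LabeledMask:
    """Binary vessel mask on a regular (possibly anisotropic) voxel grid.

    ``voxels[i, j, k]`` covers world point ``origin + (i, j, k) * spacing``
    (mm).  ``labels`` optionally assigns branch codes (1=CCA, 2=ICA,
    3=ECA) to vessel voxels.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.uint8)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous array indices of world-coordinate points (mm)."""
        p = np.atleast_2d(np.asarray(points, float))
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True where the nearest voxel to each world point is vessel."""
        idx = np.rint(self.world_to_index(points)).astype(int)
        ok = np.all((idx >= 0) & (idx < self.voxels.shape), axis=1)
        out = np.zeros(len(idx), bool)
        out[ok] = self.voxels[tuple(idx[ok].T)] > 0
        return out


@dataclass
class GroundTruth:
    """Analytic geometry behind a phantom.

    ``branches`` maps branch name -> dict with keys ``points`` (Mx3 mm,
    ordered from the bifurcation/proximal end outward), ``arc`` (M,
    arc length from the proximal end, mm) and ``radius`` (M, local tube
    radius, mm).  ``markers`` maps branch -> (proximal, distal) mm points.
    """

    branches: dict[str, dict[str, np.ndarray]]
    bifurcation_point: np.ndarray | None = None
    markers: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def tortuosity(self, branch: str) -> float:
        pts = self.branches[branch]["points"]
        arc = self.branches[branch]["arc"]
        chord = float(np.linalg.norm(pts[-1] - pts[0]))
        return float(arc[-1] / chord - 1.0)

    def radius_at(self, branch: str, s: float | np.ndarray) -> np.ndarray:
        b = self.branches[branch]
        return np.interp(s, b["arc"], b["radius"])


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic carotid bifurcation.

    Radii in mm; ``branch_angles`` are the ICA and ECA deviations from the
    CCA axis in degrees; ``sinus_bulge_factor`` >= 1 dilates the ICA over
    arc lengths [0, 5 r_ica] from the junction (leaving the 6r-12r
    measurement window untouched); ``curvature_amplitude`` bends the ICA
    sinusoidally to control its tortuosity.  Default branch lengths are
    14 local radii so every measurement window fits.
    """

    r_cca: float = 4.0
    r_ica: float = 2.68
    r_eca: float = 2.44
    branch_lengths: tuple[float, float, float] | None = None  # cca, ica, eca
    branch_angles: tuple[float, float] = (25.0, 25.0)
    sinus_bulge_factor: float = 1.0
    curvature_amplitude: float = 0.0
    spacing: tuple[float, float, float] = (2.0, 0.5, 0.5)
    margin: float = 2.0

    def __post_init__(self) -> None:
        if min(self.r_cca, self.r_ica, self.r_eca) <= 0:
            raise ValueError("all radii must be > 0")
        if self.sinus_bulge_factor < 1.0:
            raise ValueError("sinus_bulge_factor must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
        lengths = self.resolved_lengths()
        for name, length, r in zip(("cca", "ica", "eca"), lengths,
                                   (self.r_cca, self.r_ica, self.r_eca)):
            if length < 14.0 * r:
                raise ValueError(
                    f"{name} branch length {length} mm is below 14 radii "
                    f"({14 * r:.1f} mm); the measurement windows would not fit"
                )

    def resolved_lengths(self) -> tuple[float, float, float]:
        if self.branch_lengths is not None:
            return self.branch_lengths
        return (14.0 * self.r_cca, 14.0 * self.r_ica, 14.0 * self.r_eca)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def _check_resolved(radius: float, spacing: tuple[float, float, float]) -> None:
    if radius < 2.0 * max(spacing):
        raise ValueError(
            f"radius {radius} mm is under-resolved at spacing {spacing} "
            f"(need radius >= 2 * max(spacing) = {2 * max(spacing)} mm)"
        )


def _voxelize(branches: dict[str, dict[str, np.ndarray]],
              spacing: tuple[float, float, float],
              margin: float) -> LabeledMask:
    """Rasterise tube branches: voxel in vessel iff within the local radius
    of the nearest centerline sample of some branch."""
    sp = np.asarray(spacing)
    all_pts = np.vstack([b["points"] for b in branches.values()])
    max_r = max(float(b["radius"].max()) for b in branches.values())
    lo = all_pts.min(axis=0) - max_r - margin
    hi = all_pts.max(axis=0) + max_r + margin
    origin = lo
    shape = np.ceil((hi - origin) / sp).astype(int) + 1

    grids = np.meshgrid(*[origin[d] + sp[d] * np.arange(shape[d]) for d in range(3)],
                        indexing="ij")
    centers = np.stack([g.ravel() for g in grids], axis=1)

    best = np.full(len(centers), np.inf)  # signed margin d - r(s)
    label = np.zeros(len(centers), np.uint8)
    for name, b in branches.items():
        tree = cKDTree(b["points"])
        d, idx = tree.query(centers, workers=-1)
        signed = d - b["radius"][idx]
        take = signed < best
        best[take] = signed[take]
        label[take] = BRANCH_LABELS.get(name, 0)
    inside = best <= 0.0
    voxels = inside.reshape(shape).astype(np.uint8)
    labels = np.where(inside, label, 0).reshape(shape).astype(np.uint8)
    return LabeledMask(voxels=voxels, spacing=tuple(spacing), origin=tuple(origin),
                       labels=labels)


def _sample_count(length: float, spacing: tuple[float, float, float]) -> int:
    return max(int(math.ceil(length / (_SAMPLE_FRACTION * min(spacing)))) + 1, 9)


def _sinusoid_points(length: float, amplitude: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Centerline x = t, y = A sin(2 pi t / L), z = 0, equal-parameter samples;
    returns (points, cumulative arc length)."""
    t = np.linspace(0.0, length, n)
    pts = np.stack([t, amplitude * np.sin(2.0 * math.pi * t / length),
                    np.zeros_like(t)], axis=1)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, arc


def sinusoid_arc_length(length: float, amplitude: float) -> float:
    """Exact arc length of the tube centerline x=t, y=A sin(2 pi t/L)."""
    w = 2.0 * math.pi / length
    val, _ = integrate.quad(lambda t: math.hypot(1.0, amplitude * w * math.cos(w * t)),
                            0.0, length, limit=200)
    return val


def make_tube_mask(
    radius: float,
    length: float,
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
    curvature_amplitude: float = 0.0,
    margin: float = 2.0,
) -> tuple[LabeledMask, GroundTruth]:
    """Voxelized constant-radius tube along x, optionally sinusoidally bent.

    The centerline is ``(t, A sin(2 pi t / length), 0)`` for t in
    [0, length]; with A = 0 this is a straight cylinder whose interior
    distance map equals the radius on the axis (to half a voxel).
    """
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be > 0")
    _check_resolved(radius, spacing)
    if length < 4.0 * radius:
        raise ValueError("length must be at least 4 * radius")
    n = _sample_count(2.0 * length, spacing)
    pts, arc = _sinusoid_points(length, curvature_amplitude, n)
    branch = {"points": pts, "arc": arc, "radius": np.full(len(pts), float(radius))}
    mask = _voxelize({"tube": branch}, spacing, margin)
    gt = GroundTruth(
        branches={"tube": branch},
        markers={"tube": (pts[0].copy(), pts[-1].copy())},
    )
    return mask, gt


def make_elliptical_tube_mask(
    semi_axis_y: float,
    semi_axis_z: float,
    length: float,
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
    margin: float = 2.0,
) -> tuple[LabeledMask, GroundTruth]:
    """Straight tube along x with elliptical cross-section (semi-axes in y, z).

    Test fixture for non-circular lumens: the maximal inscribed sphere has
    the minor semi-axis radius, while the area-equivalent radius is
    sqrt(a b).
    """
    a, b = float(semi_axis_y), float(semi_axis_z)
    if min(a, b, length) <= 0:
        raise ValueError("semi-axes and length must be > 0")
    _check_resolved(min(a, b), spacing)
    sp = np.asarray(spacing)
    lo = np.array([-margin, -a - margin, -b - margin])
    hi = np.array([length + margin, a + margin, b + margin])
    shape = np.ceil((hi - lo) / sp).astype(int) + 1
    xi = lo[0] + sp[0] * np.arange(shape[0])
    yi = lo[1] + sp[1] * np.arange(shape[1])
    zi = lo[2] + sp[2] * np.arange(shape[2])
    X, Y, Z = np.meshgrid(xi, yi, zi, indexing="ij")
    inside = (X >= 0) & (X <= length) & ((Y / a) ** 2 + (Z / b) ** 2 <= 1.0)
    mask = LabeledMask(voxels=inside.astype(np.uint8), spacing=tuple(spacing),
                       origin=tuple(lo))
    n = _sample_count(length, spacing)
    t = np.linspace(0.0, length, n)
    pts = np.stack([t, np.zeros_like(t), np.zeros_like(t)], axis=1)
    branch = {"points": pts, "arc": t.copy(), "radius": np.full(n, min(a, b))}
    gt = GroundTruth(branches={"tube": branch},
                     markers={"tube": (pts[0].copy(), pts[-1].copy())})
    return mask, gt


def _bulge_profile(arc: np.ndarray, r: float, factor: float) -> np.ndarray:
    """Carotid-sinus dilation: smooth bump on [0, 5 r] peaking at factor*r."""
    radii = np.full(len(arc), r)
    if factor > 1.0:
        window = 5.0 * r
        in_w = arc < window
        bump = np.sin(math.pi * arc[in_w] / window) ** 2
        radii[in_w] = r * (1.0 + (factor - 1.0) * bump)
    return radii


def make_bifurcation_phantom(spec: PhantomSpec) -> tuple[LabeledMask, GroundTruth]:
    """Voxelized three-branch carotid bifurcation with known ground truth.

    The CCA runs along -x into the junction at the origin; the ICA and ECA
    leave along +x deviated by the given angles in the x-y plane (ICA
    toward +y).  Branch curves in the ground truth are ordered from the
    bifurcation outward.  Raises if the daughters, beyond the junction
    region, would overlap (angles too small).

    Resolution: branches run roughly along the coarse axis, so a radius
    only needs to span the in-plane voxels (>= 2 min(spacing)) and one
    slice (>= max(spacing)); clinical slice spacing would otherwise rule
    out normal daughter arteries.
    """
    for r in (spec.r_cca, spec.r_ica, spec.r_eca):
        if r < max(2.0 * min(spec.spacing), max(spec.spacing)):
            raise ValueError(
                f"radius {r} mm is under-resolved at spacing {spec.spacing}"
            )
    l_cca, l_ica, l_eca = spec.resolved_lengths()
    bif = np.zeros(3)

    def straight(direction: np.ndarray, length: float, n: int) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, length, n)
        return bif + t[:, None] * direction[None, :], t.copy()

    # CCA along -x so daughters fan out in +x
    n_cca = _sample_count(l_cca, spec.spacing)
    cca_pts, cca_arc = straight(np.array([-1.0, 0.0, 0.0]), l_cca, n_cca)
    th_i, th_e = (math.radians(a) for a in spec.branch_angles)
    dir_ica = np.array([math.cos(th_i), math.sin(th_i), 0.0])
    dir_eca = np.array([math.cos(th_e), -math.sin(th_e), 0.0])

    n_ica = _sample_count(l_ica, spec.spacing)
    ica_pts, t_ica = straight(dir_ica, l_ica, n_ica)
    if spec.curvature_amplitude != 0.0:
        # sinusoidal out-of-plane (z) bend of the ICA; endpoints unmoved
        ica_pts = ica_pts.copy()
        ica_pts[:, 2] += spec.curvature_amplitude * np.sin(2.0 * math.pi * t_ica / l_ica)
        seg = np.linalg.norm(np.diff(ica_pts, axis=0), axis=1)
        ica_arc = np.concatenate([[0.0], np.cumsum(seg)])
    else:
        ica_arc = t_ica
    n_eca = _sample_count(l_eca, spec.spacing)
    eca_pts, eca_arc = straight(dir_eca, l_eca, n_eca)

    branches = {
        "cca": {"points": cca_pts, "arc": cca_arc,
                "radius": np.full(n_cca, float(spec.r_cca))},
        "ica": {"points": ica_pts, "arc": ica_arc,
                "radius": _bulge_profile(ica_arc, spec.r_ica, spec.sinus_bulge_factor)},
        "eca": {"points": eca_pts, "arc": eca_arc,
                "radius": np.full(n_eca, float(spec.r_eca))},
    }

    # daughters must separate beyond the junction region
    clear = 3.0 * (spec.r_ica + spec.r_eca)
    ica_far = ica_pts[ica_arc > clear]
    eca_far = eca_pts[eca_arc > clear]
    if len(ica_far) and len(eca_far):
        d_min = cKDTree(eca_far).query(ica_far, workers=-1)[0].min()
        if d_min < branches["ica"]["radius"].max() + spec.r_eca:
            raise ValueError(
                "ICA and ECA overlap beyond the junction region; "
                "increase the branch angles"
            )

    mask = _voxelize(branches, spec.spacing, spec.margin)
    markers = {}
    for name, b in branches.items():
        prox_s = 3.0 * float(b["radius"][0])
        prox = np.stack([np.interp(prox_s, b["arc"], b["points"][:, d]) for d in range(3)])
        markers[name] = (prox, b["points"][-1].copy())
    gt = GroundTruth(branches=branches, bifurcation_point=bif.copy(), markers=markers)
    return mask, gt


# ---------------------------------------------------------------------------
# synthetic cohort tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortGenParams:
    """Distributional settings for synthetic radius-triple cohorts.

    Ratio means/SDs default to the published carotid method-A cohort
    values (ICA/CCA 0.67 (0.074), ECA/CCA 0.61 (0.087)); draws are
    truncated to (0, 1).  CCA radius is lognormal with the given median
    (mm).  ``exact_exponent`` rescales both daughters per row so
    r_cca^n = r_ica^n + r_eca^n holds exactly; ``noise_sd`` applies
    relative lognormal-free multiplicative jitter afterwards.  Each
    subject contributes a left and a right bifurcation.
    ``tortuosity_log_median``/``sigma`` give a lognormal ICA tortuosity
    whose sub-0.1 fraction (~34%) matches the published cohort.
    """

    n_subjects: int = 45
    ica_cca_mean: float = 0.67
    ica_cca_sd: float = 0.074
    eca_cca_mean: float = 0.61
    eca_cca_sd: float = 0.087
    ratio_correlation: float = 0.0
    cca_median_mm: float = 4.0
    cca_log_sigma: float = 0.15
    exact_exponent: float | None = None
    noise_sd: float = 0.0
    tortuosity_log_median: float = 0.122
    tortuosity_log_sigma: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be > 0")
        if not (0 < self.ica_cca_mean < 1 and 0 < self.eca_cca_mean < 1):
            raise ValueError("ratio means must lie in (0, 1)")
        if self.ica_cca_sd <= 0 or self.eca_cca_sd <= 0:
            raise ValueError("ratio SDs must be > 0")
        if not -1.0 < self.ratio_correlation < 1.0:
            raise ValueError("ratio_correlation must be in (-1, 1)")
        if self.exact_exponent is not None and self.exact_exponent <= 0:
            raise ValueError("exact_exponent must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _draw_ratios(params: CohortGenParams, rng: np.random.Generator, n: int):
    """Truncated-(0,1) ratio pairs, independent or Gaussian-copula correlated."""
    if params.ratio_correlation == 0.0:
        def tn(mean, sd):
            a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
            return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        return tn(params.ica_cca_mean, params.ica_cca_sd), \
            tn(params.eca_cca_mean, params.eca_cca_sd)
    # correlated case: rejection-sample a bivariate normal into (0,1)^2
    cov = np.array([
        [params.ica_cca_sd**2,
         params.ratio_correlation * params.ica_cca_sd * params.eca_cca_sd],
        [params.ratio_correlation * params.ica_cca_sd * params.eca_cca_sd,
         params.eca_cca_sd**2],
    ])
    mean = np.array([params.ica_cca_mean, params.eca_cca_mean])
    out = np.empty((0, 2))
    while len(out) < n:
        draw = rng.multivariate_normal(mean, cov, size=2 * (n - len(out)) + 8)
        keep = draw[np.all((draw > 0.0) & (draw < 1.0), axis=1)]
        out = np.vstack([out, keep])
    out = out[:n]
    return out[:, 0], out[:, 1]


def sample_cohort(params: CohortGenParams | None = None, **kwargs) -> pd.DataFrame:
    """Synthetic cohort of radius triples, one left and one right per subject.

    Returns a DataFrame with columns ``subject_id``, ``side``,
    ``r_cca_mm``, ``r_ica_mm``, ``r_eca_mm``, ``ica_tortuosity``.
    Reproducible given ``params.seed``.
    """
    if params is None:
        params = CohortGenParams(**kwargs)
    elif kwargs:
        params = replace(params, **kwargs)
    rng = np.random.default_rng(params.seed)
    n = 2 * params.n_subjects

    a, e = _draw_ratios(params, rng, n)
    if params.exact_exponent is not None:
        m = params.exact_exponent
        scale = (a**m + e**m) ** (-1.0 / m)
        a, e = a * scale, e * scale

    r_cca = params.cca_median_mm * np.exp(
        rng.normal(0.0, params.cca_log_sigma, size=n))
    r_ica = a * r_cca
    r_eca = e * r_cca
    if params.noise_sd > 0:
        for arr in (r_cca, r_ica, r_eca):
            arr *= np.clip(1.0 + rng.normal(0.0, params.noise_sd, size=n), 0.05, None)

    tort = params.tortuosity_log_median * np.exp(
        rng.normal(0.0, params.tortuosity_log_sigma, size=n))

    subjects = np.repeat([f"s{i:04d}" for i in range(1, params.n_subjects + 1)], 2)
    sides = np.tile(["left", "right"], params.n_subjects)
    return pd.DataFrame(
        {
            "subject_id": subjects,
            "side": sides,
            "r_cca_mm": r_cca,
            "r_ica_mm": r_ica,
            "r_eca_mm": r_eca,
            "ica_tortuosity": tort,
        }
    )
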