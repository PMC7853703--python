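"""Synthetic CTP acquisitions, follow-up CT volumes and patient cohorts.

The phantom emulates first-pass contrast passage through healthy, penumbral
and infarcted ("core") brain tissue on a desk-scale acquisition grid.  Each
tissue class is described by the indicator-dilution triple (CBF, CBV, MTT)
obeying the central volume principle CBV = CBF * MTT / 60, and its
enhancement curve is the convolution of a gamma-variate arterial input
function with a mono-exponential residue function scaled by flow.  Lesions
are nested ellipsoids (core inside penumbra) placed in one hemisphere of a
cylindrical brain mask; additive white Gaussian noise models acquisition
noise.  Two-period patient cohorts are sampled from distributions
parameterised by published medians / inter-quartile ranges so that the
cohort-level statistics of the synthetic population match the clinical
tables they stand in for.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "AIFModel",
    "TissueClass",
    "LesionGeometry",
    "GridSpec",
    "CTPPhantom",
    "CohortSpec",
    "PatientRecord",
    "HEALTHY_GM",
    "HEALTHY_WM",
    "PENUMBRA",
    "CORE",
    "make_aif",
    "residue_samples",
    "tissue_curve",
    "ellipsoid_mask",
    "brain_mask_for_grid",
    "geometry_for_volumes",
    "build_phantom",
    "make_followup_ct",
    "fit_lognormal_to_quartiles",
    "fit_zero_inflated_lognormal",
    "sample_cohort",
    "load_preset",
    "cohort_to_frame",
]

# Normal quantile at 0.75, used when converting IQRs to log-normal scale.
_Z75 = float(stats.norm.ppf(0.75))


# ---------------------------------------------------------------------------
# arterial input function
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AIFModel:
    """Gamma-variate arterial input function ``A (t-t0)^alpha exp(-(t-t0)/beta)``.

    Parameters
    ----------
    amplitude:
        Scale ``A`` in HU / s^alpha.  Use :meth:`with_peak` to parameterise
        by peak enhancement instead.
    t0:
        Bolus arrival delay in seconds; the curve is zero for ``t <= t0``.
    alpha, beta:
        Shape (dimensionless) and scale (s) of the gamma variate.  The curve
        peaks at ``t0 + alpha * beta``.
    """

    amplitude: float
    t0: float = 5.0
    alpha: float = 3.0
    beta: float = 1.5

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("AIF amplitude must be non-negative")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("AIF shape and scale must be positive")

    @classmethod
    def with_peak(cls, peak_hu: float = 300.0, t0: float = 5.0,
                  alpha: float = 3.0, beta: float = 1.5) -> "AIFModel":
        """Build a model whose maximum enhancement equals ``peak_hu``."""
        amp = peak_hu / ((alpha * beta) ** alpha * np.exp(-alpha))
        return cls(amplitude=amp, t0=t0, alpha=alpha, beta=beta)

    @property
    def time_to_peak(self) -> float:
        return self.t0 + self.alpha * self.beta


def _check_uniform(t: np.ndarray) -> float:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time axis must be a 1-D array with >= 2 samples")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("time axis must be uniformly spaced")
    return float(steps[0])


def make_aif(t: np.ndarray, model: AIFModel) -> np.ndarray:
    """Evaluate the gamma-variate arterial curve on a uniform time axis."""
    _check_uniform(t)
    t = np.asarray(t, dtype=float)
    tau = t - model.t0
    out = np.zeros_like(t)
    late = tau > 0
    out[late] = model.amplitude * tau[late] ** model.alpha * np.exp(-tau[late] / model.beta)
    return out


# ---------------------------------------------------------------------------
# tissue kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueClass:
    """Tissue kinetic triple; the central volume principle is enforced.

    CBF in ml/100g/min, CBV in ml/100g, MTT in seconds, with
    ``CBV = CBF * MTT / 60`` required to hold to 1e-9.
    """

    name: str
    cbf: float
    cbv: float
    mtt: float

    def __post_init__(self) -> None:
        if self.mtt <= 0:
            raise ValueError("MTT must be positive")
        if self.cbf < 0 or self.cbv < 0:
            raise ValueError("CBF and CBV must be non-negative")
        if abs(self.cbv - self.cbf * self.mtt / 60.0) > 1e-9:
            raise ValueError(
                f"central volume principle violated for {self.name!r}: "
                f"CBV={self.cbv} != CBF*MTT/60={self.cbf * self.mtt / 60.0}"
            )

    @classmethod
    def from_cbv_mtt(cls, name: str, cbv: float, mtt: float) -> "TissueClass":
        return cls(name=name, cbf=60.0 * cbv / mtt, cbv=cbv, mtt=mtt)


# Default tissue parameters.  Healthy grey matter, penumbra and core are
# chosen to straddle the 145 %-relative-MTT and 2.0 ml/100g CBV segmentation
# thresholds with margin, so that noiseless segmentation recovers the ground
# truth exactly.
HEALTHY_GM = TissueClass.from_cbv_mtt("healthy-GM", cbv=4.0, mtt=4.0)
HEALTHY_WM = TissueClass.from_cbv_mtt("healthy-WM", cbv=2.4, mtt=4.8)
PENUMBRA = TissueClass.from_cbv_mtt("penumbra", cbv=3.0, mtt=8.0)
CORE = TissueClass.from_cbv_mtt("core", cbv=1.0, mtt=12.0)

DEFAULT_CLASSES = {"healthy": HEALTHY_GM, "penumbra": PENUMBRA, "core": CORE}


def residue_samples(mtt: float, t: np.ndarray, dt: float) -> np.ndarray:
    """Interval-averaged samples of the exponential residue ``exp(-t/MTT)``.

    Averaging the residue over each sampling interval (rather than point
    sampling) makes the discrete convolution conserve area: the discrete AUC
    of a tissue curve equals CBV/100 times the arterial AUC up to the
    washout tail beyond the acquisition window.
    """
    if mtt <= 0:
        raise ValueError("MTT must be positive")
    scale = (mtt / dt) * (1.0 - np.exp(-dt / mtt))
    return scale * np.exp(-np.asarray(t, dtype=float) / mtt)


def tissue_curve(aif_curve: np.ndarray, cls: TissueClass, dt: float) -> np.ndarray:
    """Forward model: tissue enhancement for a voxel of class ``cls``.

    Returns ``(CBF/6000) * (aif * R)(t) * dt`` where ``R`` is the
    interval-averaged exponential residue and ``*`` a discrete linear
    convolution truncated to the acquisition window.
    """
    aif_curve = np.asarray(aif_curve, dtype=float)
    if not np.all(np.isfinite(aif_curve)):
        raise ValueError("arterial curve contains non-finite values")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = aif_curve.size
    t = np.arange(n) * dt
    r = residue_samples(cls.mtt, t, dt)
    flow_per_s = cls.cbf / 6000.0  # ml/100g/min -> fractional flow per second
    return flow_per_s * np.convolve(aif_curve, r)[:n] * dt


# ---------------------------------------------------------------------------
# acquisition grid, brain mask, lesion geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Acquisition grid: matrix size, voxel spacing (mm) and time axis (s)."""

    shape: tuple[int, int, int] = (64, 64, 8)
    spacing: tuple[float, float, float] = (3.0, 3.0, 5.0)
    n_time: int = 60
    dt: float = 1.0

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_time) * self.dt

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def midline_index(self) -> int:
        return self.shape[0] // 2

    def voxel_centers_mm(self):
        """Meshgrid of voxel-centre coordinates in mm (index + 0.5 scaled)."""
        axes = [(np.arange(n) + 0.5) * s for n, s in zip(self.shape, self.spacing)]
        return np.meshgrid(*axes, indexing="ij")


DEFAULT_GRID = GridSpec()


def brain_mask_for_grid(grid: GridSpec, margin_mm: float = 3.0) -> np.ndarray:
    """Elliptic-cylinder brain mask spanning the full slab thickness."""
    xm, ym, _ = grid.voxel_centers_mm()
    cx = grid.shape[0] * grid.spacing[0] / 2.0
    cy = grid.shape[1] * grid.spacing[1] / 2.0
    rx = cx - margin_mm
    ry = cy - margin_mm
    return ((xm - cx) / rx) ** 2 + ((ym - cy) / ry) ** 2 <= 1.0


@dataclass(frozen=True)
class LesionGeometry:
    """Nested core / penumbra ellipsoids in one hemisphere.

    ``center_mm`` is shared; semi-axes are (x, y, z) in mm.  The core
    ellipsoid must be contained in the penumbra ellipsoid and the whole
    lesion must stay within the lesion-side hemisphere of the brain mask.
    """

    center_mm: tuple[float, float, float]
    core_semi_mm: tuple[float, float, float]
    penumbra_semi_mm: tuple[float, float, float]
    side: str = "right"
    # Solver-produced geometries are clipped to the lesion-side hemisphere;
    # explicit geometries that cross the midline raise instead.
    clip_to_hemisphere: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if any(c > p + 1e-9 for c, p in zip(self.core_semi_mm, self.penumbra_semi_mm)):
            raise ValueError("core ellipsoid must be contained in the penumbra ellipsoid")


def ellipsoid_mask(grid: GridSpec, center_mm, semi_mm) -> np.ndarray:
    """Rasterise an ellipsoid: voxels whose centre lies inside the surface."""
    xm, ym, zm = grid.voxel_centers_mm()
    if any(s <= 0 for s in semi_mm):
        return np.zeros(grid.shape, dtype=bool)
    return (
        ((xm - center_mm[0]) / semi_mm[0]) ** 2
        + ((ym - center_mm[1]) / semi_mm[1]) ** 2
        + ((zm - center_mm[2]) / semi_mm[2]) ** 2
        <= 1.0
    )


def _hemisphere_mask(grid: GridSpec, side: str) -> np.ndarray:
    idx = np.arange(grid.shape[0])[:, None, None]
    mid = grid.midline_index
    half = idx >= mid if side == "right" else idx < mid
    return np.broadcast_to(half, grid.shape)


def _semi_axes_for_scale(a: float, max_z_mm: float) -> tuple[float, float, float]:
    # 1 : 2 in-plane aspect, z capped by slab coverage.
    return (a, 2.0 * a, min(max_z_mm, a))


def geometry_for_volumes(
    total_ml: float,
    core_ml: float,
    grid: GridSpec = DEFAULT_GRID,
    side: str = "right",
    brain: np.ndarray | None = None,
) -> tuple[LesionGeometry | None, bool]:
    """Solve lesion semi-axes so rasterised volumes match the targets.

    The penumbra (outer) and core (inner) ellipsoids share a centre placed
    mid-hemisphere and use a 1:2 in-plane aspect with the z semi-axis capped
    to remain inside the slab.  Semi-axes are found by bisection on the
    rasterised, brain-and-hemisphere-clipped voxel count, so the realised
    ground-truth volume matches the requested one to a voxel.  Returns
    ``(geometry, capped)`` where ``capped`` flags a target beyond the
    hemisphere's capacity; geometry is None for a zero-volume request.
    """
    if core_ml > total_ml + 1e-9:
        raise ValueError("core volume cannot exceed total lesion volume")
    if total_ml <= 0:
        return None, False
    if brain is None:
        brain = brain_mask_for_grid(grid)
    hemi = _hemisphere_mask(grid, side) & brain
    nz = grid.shape[2] * grid.spacing[2]
    max_z = nz / 2.0 - grid.spacing[2] / 2.0
    cx = grid.shape[0] * grid.spacing[0] / 2.0
    cy = grid.shape[1] * grid.spacing[1] / 2.0
    offset = grid.shape[0] * grid.spacing[0] / 4.0
    center = (cx + offset if side == "right" else cx - offset, cy, nz / 2.0)
    vox_ml = grid.voxel_volume_ml

    def realised(a: float, target_center) -> int:
        m = ellipsoid_mask(grid, target_center, _semi_axes_for_scale(a, max_z)) & hemi
        return int(m.sum())

    def solve(target_ml: float) -> tuple[float, bool]:
        lo, hi = 0.0, float(max(grid.shape[i] * grid.spacing[i] for i in range(3)))
        if realised(hi, center) * vox_ml < target_ml:
            return hi, True
        for _ in range(50):
            a = 0.5 * (lo + hi)
            if realised(a, center) * vox_ml < target_ml:
                lo = a
            else:
                hi = a
        # voxels rasterise in symmetric groups; pick the closer bracket
        v_lo = realised(lo, center) * vox_ml
        v_hi = realised(hi, center) * vox_ml
        if abs(v_lo - target_ml) < abs(v_hi - target_ml):
            return lo, False
        return hi, False

    a_pen, capped = solve(total_ml)
    core_ml = min(core_ml, realised(a_pen, center) * vox_ml)
    if core_ml > 0:
        a_core, core_capped = solve(core_ml)
        a_core = min(a_core, a_pen)
        capped = capped or core_capped
    else:
        a_core = 0.0
    geom = LesionGeometry(
        center_mm=center,
        core_semi_mm=_semi_axes_for_scale(a_core, max_z) if a_core > 0 else (0.0, 0.0, 0.0),
        penumbra_semi_mm=_semi_axes_for_scale(a_pen, max_z),
        side=side,
        clip_to_hemisphere=True,
    )
    return geom, capped


# ---------------------------------------------------------------------------
# the 4-D phantom
# ---------------------------------------------------------------------------


@dataclass
class CTPPhantom:
    """A synthetic 4-D CTP acquisition plus its ground truth.

    ``data`` is HU enhancement with shape ``grid.shape + (n_time,)``;
    ground-truth masks and parameter maps refer to the generating tissue
    classes, not to any estimate.
    """

    data: np.ndarray
    grid: GridSpec
    aif_model: AIFModel
    brain_mask: np.ndarray
    core_mask: np.ndarray
    penumbra_mask: np.ndarray  # full hypoperfused extent (core included)
    cbf_map: np.ndarray
    cbv_map: np.ndarray
    mtt_map: np.ndarray
    noise_sigma: float
    seed: int | None
    side: str = "right"

    @property
    def midline_index(self) -> int:
        return self.grid.midline_index

    @property
    def time(self) -> np.ndarray:
        return self.grid.time

    def aif_curve(self) -> np.ndarray:
        return make_aif(self.grid.time, self.aif_model)

    @property
    def penumbra_only_mask(self) -> np.ndarray:
        return self.penumbra_mask & ~self.core_mask

    def true_volumes_ml(self) -> dict[str, float]:
        v = self.grid.voxel_volume_ml
        return {
            "total": float(self.penumbra_mask.sum()) * v,
            "core": float(self.core_mask.sum()) * v,
            "penumbra": float(self.penumbra_only_mask.sum()) * v,
        }


def build_phantom(
    geometry: LesionGeometry | None,
    classes: dict[str, TissueClass] | None = None,
    aif: AIFModel | None = None,
    grid: GridSpec = DEFAULT_GRID,
    noise_sigma: float = 2.0,
    seed: int | None = None,
    brain: np.ndarray | None = None,
) -> CTPPhantom:
    """Rasterise a lesion geometry into a noisy 4-D CTP acquisition.

    Every voxel's time course is the forward-model curve of its tissue class
    plus seeded white Gaussian noise.  The contralateral hemisphere is
    entirely healthy.  A geometry of ``None`` produces a lesion-free
    acquisition (a stroke-mimic / TIA-like case).
    """
    classes = dict(DEFAULT_CLASSES if classes is None else classes)
    for key in ("healthy", "penumbra", "core"):
        if key not in classes:
            raise ValueError(f"classes must include {key!r}")
    aif = aif or AIFModel.with_peak()
    if brain is None:
        brain = brain_mask_for_grid(grid)

    if geometry is not None:
        hemi = _hemisphere_mask(grid, geometry.side) & brain
        pen = ellipsoid_mask(grid, geometry.center_mm, geometry.penumbra_semi_mm)
        if not geometry.clip_to_hemisphere and np.any(
            pen & brain & ~_hemisphere_mask(grid, geometry.side)
        ):
            raise ValueError("lesion crosses the midline plane")
        pen &= hemi
        core = ellipsoid_mask(grid, geometry.center_mm, geometry.core_semi_mm) & pen
        side = geometry.side
    else:
        pen = np.zeros(grid.shape, dtype=bool)
        core = np.zeros(grid.shape, dtype=bool)
        side = "right"

    aif_curve = make_aif(grid.time, aif)
    curves = {k: tissue_curve(aif_curve, c, grid.dt) for k, c in classes.items()}

    labels = np.zeros(grid.shape, dtype=np.uint8)
    labels[brain] = 1
    labels[pen & ~core] = 2
    labels[core] = 3

    data = np.zeros(grid.shape + (grid.n_time,), dtype=np.float32)
    data[labels == 1] = curves["healthy"].astype(np.float32)
    data[labels == 2] = curves["penumbra"].astype(np.float32)
    data[labels == 3] = curves["core"].astype(np.float32)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma, data.shape).astype(np.float32)

    cbf = np.zeros(grid.shape)
    cbv = np.zeros(grid.shape)
    mtt = np.zeros(grid.shape)
    for lab, key in ((1, "healthy"), (2, "penumbra"), (3, "core")):
        cls = classes[key]
        sel = labels == lab
        cbf[sel] = cls.cbf
        cbv[sel] = cls.cbv
        mtt[sel] = cls.mtt

    return CTPPhantom(
        data=data,
        grid=grid,
        aif_model=aif,
        brain_mask=brain,
        core_mask=core,
        penumbra_mask=pen,
        cbf_map=cbf,
        cbv_map=cbv,
        mtt_map=mtt,
        noise_sigma=noise_sigma,
        seed=seed,
        side=side,
    )


def make_followup_ct(
    infarct_mask: np.ndarray,
    base_hu: float = 32.0,
    delta_hu: float = 15.0,
    noise_sigma: float = 2.0,
    seed: int | None = None,
    brain: np.ndarray | None = None,
) -> np.ndarray:
    """Follow-up non-enhanced CT: hypodense infarct on uniform parenchyma.

    Infarct voxels have mean ``base_hu - delta_hu``; remaining brain voxels
    ``base_hu``; voxels outside the brain mask are 0 HU.
    """
    if delta_hu < 0:
        raise ValueError("hypodensity delta must be non-negative")
    infarct_mask = np.asarray(infarct_mask, dtype=bool)
    if brain is None:
        brain = np.ones(infarct_mask.shape, dtype=bool)
    if brain.shape != infarct_mask.shape:
        raise ValueError("brain mask and infarct mask shapes differ")
    ct = np.zeros(infarct_mask.shape, dtype=float)
    ct[brain] = base_hu
    ct[infarct_mask & brain] = base_hu - delta_hu
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        ct[brain] += rng.normal(0.0, noise_sigma, int(brain.sum()))
    return ct


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


def fit_lognormal_to_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) matching a printed median and IQR.

    ``mu = ln(median)`` reproduces the median exactly; ``sigma`` is set from
    the quartile ratio.  Published quartile triples are generally not exactly
    log-normal-consistent, so the quartiles are matched in ratio.
    """
    if not (0 < q1 <= median <= q3):
        raise ValueError("quartile triple must satisfy 0 < q1 <= median <= q3")
    sigma = float(np.log(q3 / q1) / (2.0 * _Z75))
    return float(np.log(median)), sigma


def fit_zero_inflated_lognormal(
    median: float, q3: float, p_zero: float = 0.25
) -> tuple[float, float, float]:
    """Zero-inflated log-normal matching ``q1 = 0``, a median and a q3.

    A point mass ``p_zero`` at 0 plus a log-normal on the positive part,
    with the positive-part parameters solved so the overall median and
    third quartile equal the requested values.
    """
    if not (0 < median <= q3):
        raise ValueError("need 0 < median <= q3")
    if not (0 < p_zero < 0.5):
        raise ValueError("zero-inflation must be in (0, 0.5) for a positive median")
    u_med = (0.5 - p_zero) / (1.0 - p_zero)
    u_q3 = (0.75 - p_zero) / (1.0 - p_zero)
    z_med = float(stats.norm.ppf(u_med))
    z_q3 = float(stats.norm.ppf(u_q3))
    sigma = float((np.log(q3) - np.log(median)) / (z_q3 - z_med))
    mu = float(np.log(median) - sigma * z_med)
    return p_zero, mu, sigma


@dataclass(frozen=True)
class VolumeDistribution:
    """Continuous (optionally zero-inflated) log-normal volume model."""

    median: float
    q1: float
    q3: float
    p_zero: float = 0.0

    def params(self) -> tuple[float, float, float]:
        if self.q1 <= 0:
            p0 = self.p_zero if self.p_zero > 0 else 0.25
            p0, mu, sigma = fit_zero_inflated_lognormal(self.median, self.q3, p0)
            return p0, mu, sigma
        mu, sigma = fit_lognormal_to_quartiles(self.median, self.q1, self.q3)
        return 0.0, mu, sigma

    def quantile(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF; vectorised over ``u`` in (0, 1)."""
        p0, mu, sigma = self.params()
        u = np.asarray(u, dtype=float)
        out = np.zeros_like(u)
        pos = u > p0
        upos = (u[pos] - p0) / (1.0 - p0)
        out[pos] = np.exp(mu + sigma * stats.norm.ppf(upos))
        return out

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.quantile(rng.uniform(size=n))


@dataclass(frozen=True)
class CohortSpec:
    """Sampling distributions for one admission period."""

    period: str
    n: int
    total_volume: VolumeDistribution
    core_volume: VolumeDistribution
    infarct_volume: VolumeDistribution
    nihss_median: float
    nihss_q1: float
    nihss_q3: float
    age_median: float
    age_q1: float
    age_q3: float
    p_female: float
    p_lvo: float
    p_suso: float
    risk_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in (self.p_female, self.p_lvo, self.p_suso, *self.risk_factors.values()):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n < 0:
            raise ValueError("cohort size must be non-negative")


@dataclass
class PatientRecord:
    """One synthetic patient: clinical covariates plus imaging volumes (ml).

    ``*_true`` fields are generator ground truth; ``*_recovered`` fields are
    filled by the imaging pipeline.  ``mismatch`` is penumbra as a fraction
    of the total hypoperfused volume.
    """

    period: str
    patient_id: int
    age: int
    sex: str
    nihss: int
    suso: bool
    lvo: bool
    risk_factors: dict[str, bool]
    total_true: float
    core_true: float
    infarct_true: float
    total_recovered: float | None = None
    core_recovered: float | None = None
    infarct_recovered: float | None = None

    @property
    def nihss_ge10(self) -> bool:
        return self.nihss >= 10

    @property
    def mismatch_true(self) -> float:
        if self.total_true <= 0:
            return 1.0
        return 1.0 - self.core_true / self.total_true

    def to_dict(self) -> dict:
        d = {
            "period": self.period,
            "patient_id": self.patient_id,
            "age": self.age,
            "sex": self.sex,
            "nihss": self.nihss,
            "nihss_ge10": self.nihss_ge10,
            "suso": self.suso,
            "lvo": self.lvo,
            "total_true": self.total_true,
            "core_true": self.core_true,
            "mismatch_true": self.mismatch_true,
            "infarct_true": self.infarct_true,
            "total_recovered": self.total_recovered,
            "core_recovered": self.core_recovered,
            "infarct_recovered": self.infarct_recovered,
        }
        for k, v in self.risk_factors.items():
            d[k] = v
        return d


def _quantile_positions(n: int, rng: np.random.Generator, stratified: bool) -> np.ndarray:
    if stratified:
        # Median-unbiased plotting positions in a seeded random patient order:
        # the n-patient cohort represents the fitted distribution without the
        # sampling noise of i.i.d. draws, which matters at desk-scale n.
        u = (np.arange(n) + 0.5) / n
        return rng.permutation(u)
    return rng.uniform(size=n)


def sample_cohort(
    spec: CohortSpec,
    seed: int | np.random.Generator | None = None,
    stratified: bool = False,
) -> list[PatientRecord]:
    """Draw ``spec.n`` patients for one period.

    Continuous volumes come from the spec's (zero-inflated) log-normal
    models; total, core and final-infarct volumes are drawn comonotonically
    (one uniform per patient) so that larger strokes have larger cores and
    infarcts, and ``core <= total`` holds by construction.  Categorical
    fields are Bernoulli with the spec probabilities.  NIHSS and age are
    drawn from quartile-matched distributions and the NIHSS >= 10 flag is
    derived from the sampled score.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n
    if n == 0:
        return []
    u = _quantile_positions(n, rng, stratified)
    totals = spec.total_volume.quantile(u)
    cores = np.minimum(spec.core_volume.quantile(u), totals)
    infarcts = spec.infarct_volume.quantile(u)

    mu_n, sg_n = fit_lognormal_to_quartiles(
        max(spec.nihss_median, 0.5), max(spec.nihss_q1, 0.5), max(spec.nihss_q3, 0.5)
    )
    nihss = np.clip(np.rint(np.exp(rng.normal(mu_n, sg_n, n))), 0, 42).astype(int)
    iqr = max(spec.age_q3 - spec.age_q1, 1.0)
    ages = np.clip(
        np.rint(rng.normal(spec.age_median, iqr / (2.0 * _Z75), n)), 18, 102
    ).astype(int)
    female = rng.uniform(size=n) < spec.p_female
    lvo = rng.uniform(size=n) < spec.p_lvo
    suso = rng.uniform(size=n) < spec.p_suso
    rf_draws = {k: rng.uniform(size=n) < p for k, p in spec.risk_factors.items()}

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                period=spec.period,
                patient_id=i,
                age=int(ages[i]),
                sex="F" if female[i] else "M",
                nihss=int(nihss[i]),
                suso=bool(suso[i]),
                lvo=bool(lvo[i]),
                risk_factors={k: bool(v[i]) for k, v in rf_draws.items()},
                total_true=float(totals[i]),
                core_true=float(cores[i]),
                infarct_true=float(infarcts[i]),
            )
        )
    return records


def cohort_to_frame(records: list[PatientRecord]):
    import pandas as pd

    return pd.DataFrame([r.to_dict() for r in records])


def _volume_dist_from_dict(d: dict) -> VolumeDistribution:
    return VolumeDistribution(
        median=float(d["median"]),
        q1=float(d["q1"]),
        q3=float(d["q3"]),
        p_zero=float(d.get("p_zero", 0.0)),
    )


def load_preset(name: str) -> CohortSpec:
    """Load a named cohort preset (``covid_2020`` or ``no_covid_2019``)."""
    text = (
        importlib.resources.files("ctpstroke")
        .joinpath("data/cohort_presets.yaml")
        .read_text()
    )
    presets = yaml.safe_load(text)
    if name not in presets:
        raise KeyError(f"unknown cohort preset {name!r}; have {sorted(presets)}")
    p = presets[name]
    return CohortSpec(
        period=p["period"],
        n=int(p["n"]),
        total_volume=_volume_dist_from_dict(p["total_volume"]),
        core_volume=_volume_dist_from_dict(p["core_volume"]),
        infarct_volume=_volume_dist_from_dict(p["infarct_volume"]),
        nihss_median=float(p["nihss"]["median"]),
        nihss_q1=float(p["nihss"]["q1"]),
        nihss_q3=float(p["nihss"]["q3"]),
        age_median=float(p["age"]["median"]),
        age_q1=float(p["age"]["q1"]),
        age_q3=float(p["age"]["q3"]),
        p_female=float(p["p_female"]),
        p_lvo=float(p["p_lvo"]),
        p_suso=float(p["p_suso"]),
        risk_factors={k: float(v) for k, v in p.get("risk_factors", {}).items()},
    )


def scaled_spec(spec: CohortSpec, n: int) -> CohortSpec:
    """Copy of a cohort spec with a different cohort size."""
    return replace(spec, n=n)
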