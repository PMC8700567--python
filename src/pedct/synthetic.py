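"""Synthetic chest phantoms and cohorts with known ground truth.

The parenchymal HU distribution is a two-component mixture: a narrow normal
bulk plus a right-shifted exponential tail toward denser tissue. Healthy
aerated lung shows far fewer voxels below (mean - 1SD) than a Gaussian
would give (~0.2-8% vs 15.9%) while the fraction above (mean + 1SD) stays
near 8-15%; the mixture is the smallest model that can hit all four of
mean, SD and the two tail fractions simultaneously. Calibration is a
deterministic root-find, no sampling involved.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, optimize, stats

from pedct.reference import load_reference_set, predict
from pedct.reporting import CohortRecord
from pedct.volume import HU_MAX, HU_MIN, AttenuationVolume

#: One-sided Gaussian tail mass beyond 1 SD.
GAUSSIAN_TAIL = float(stats.norm.cdf(-1.0))  # 0.15865525...

# Calibration tolerances: 0.5 HU on moments, 0.3 percentage points on tails.
_TOL_HU = 0.5
_TOL_FRAC = 0.003


class CalibrationError(RuntimeError):
    """Raised when the mixture cannot be calibrated to the requested targets."""


@dataclasses.dataclass(frozen=True)
class ParenchymaDistribution:
    """Calibrated mixture: N(bulk_mean, bulk_sd) with probability
    (1 - tail_weight), bulk_mean + Exponential(tail_scale) otherwise.

    ``achieved_*`` record the analytic moments and tail fractions actually
    attained by the calibrated parameters.
    """

    bulk_mean: float
    bulk_sd: float
    tail_weight: float
    tail_scale: float
    achieved_mean: float
    achieved_sd: float
    achieved_frac_low: float
    achieved_frac_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.tail_weight <= 0.5):
            raise ValueError(f"tail_weight must be in [0, 0.5], got {self.tail_weight}")
        if self.bulk_sd <= 0:
            raise ValueError("bulk_sd must be > 0")
        if self.tail_scale <= 0:
            raise ValueError("tail_scale must be > 0")
        if self.achieved_frac_low + self.achieved_frac_high >= 1:
            raise ValueError("tail fractions must sum to < 1")

    # -- analytic density functions ------------------------------------

    def mean(self) -> float:
        return self.bulk_mean + self.tail_weight * self.tail_scale

    def sd(self) -> float:
        mu, sig = self.bulk_mean, self.bulk_sd
        w, s = self.tail_weight, self.tail_scale
        ex2 = (1 - w) * (mu * mu + sig * sig) + w * (mu * mu + 2 * mu * s + 2 * s * s)
        return float(np.sqrt(ex2 - self.mean() ** 2))

    def cdf(self, x: float) -> float:
        mu = self.bulk_mean
        c = (1 - self.tail_weight) * stats.norm.cdf((x - mu) / self.bulk_sd)
        if x > mu:
            c += self.tail_weight * (1.0 - np.exp(-(x - mu) / self.tail_scale))
        return float(c)

    def frac_low(self) -> float:
        """Analytic mass strictly below (mean - 1SD)."""
        return self.cdf(self.mean() - self.sd())

    def frac_high(self) -> float:
        """Analytic mass strictly above (mean + 1SD)."""
        return 1.0 - self.cdf(self.mean() + self.sd())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n integer-HU values (rounded half away from zero, clipped
        to the valid HU range)."""
        in_tail = rng.random(n) < self.tail_weight
        x = np.where(
            in_tail,
            self.bulk_mean + rng.exponential(self.tail_scale, n),
            rng.normal(self.bulk_mean, self.bulk_sd, n),
        )
        x = np.copysign(np.floor(np.abs(x) + 0.5), x)  # round half away from zero
        return np.clip(x, HU_MIN, HU_MAX).astype(np.int16)


def calibrate_distribution(
    target_mean: float,
    target_sd: float,
    target_frac_low: float,
    target_frac_high: float,
) -> ParenchymaDistribution:
    """Solve for mixture parameters matching mean, SD and both tail
    fractions.

    Matches the analytic mean/SD within 0.5 HU and the fractions below
    (mean - 1SD) / above (mean + 1SD) within 0.3 percentage points, by
    root-finding on (bulk_mean, bulk_sd, tail_weight, tail_scale). Fully
    deterministic.

    Raises
    ------
    CalibrationError
        If no parameter set meets the tolerances, naming the worst target.
    """
    if target_sd <= 0:
        raise ValueError("target_sd must be > 0")
    if not (0 < target_frac_low <= target_frac_high < 0.5):
        raise ValueError(
            "need 0 < target_frac_low <= target_frac_high < 0.5, got "
            f"({target_frac_low}, {target_frac_high})"
        )

    # Symmetric targets at the Gaussian value: the tail is unidentifiable
    # (any pure normal already matches); collapse to tail_weight = 0.
    if (
        abs(target_frac_low - GAUSSIAN_TAIL) < 1e-3
        and abs(target_frac_high - GAUSSIAN_TAIL) < 1e-3
    ):
        return ParenchymaDistribution(
            bulk_mean=float(target_mean),
            bulk_sd=float(target_sd),
            tail_weight=0.0,
            tail_scale=float(target_sd),
            achieved_mean=float(target_mean),
            achieved_sd=float(target_sd),
            achieved_frac_low=GAUSSIAN_TAIL,
            achieved_frac_high=GAUSSIAN_TAIL,
        )

    targets = (target_mean, target_sd, target_frac_low, target_frac_high)

    def unpack(theta):
        mu, log_sig, logit_w, log_s = theta
        return mu, np.exp(log_sig), 0.5 / (1.0 + np.exp(-logit_w)), np.exp(log_s)

    def residuals(theta):
        d = _analytic(*unpack(theta))
        return [
            d[0] - target_mean,
            d[1] - target_sd,
            100.0 * (d[2] - target_frac_low),
            100.0 * (d[3] - target_frac_high),
        ]

    best = None
    for w0, s_factor in ((0.15, 1.2), (0.3, 1.0), (0.05, 1.5), (0.45, 0.8)):
        s0 = s_factor * target_sd
        mu0 = target_mean - w0 * s0
        sig0 = abs((target_mean - target_sd - mu0) / stats.norm.ppf(target_frac_low))
        x0 = [mu0, np.log(sig0), np.log(w0 / (0.5 - w0)), np.log(s0)]
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            sol = optimize.root(residuals, x0, method="hybr", options={"maxfev": 4000})
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            mu, sig, w, s = unpack(sol.x)
            m, sd, fl, fh = _analytic(mu, sig, w, s)
        errs = {
            "mean": abs(m - target_mean),
            "sd": abs(sd - target_sd),
            "frac_low": abs(fl - target_frac_low),
            "frac_high": abs(fh - target_frac_high),
        }
        ok = (
            errs["mean"] <= _TOL_HU
            and errs["sd"] <= _TOL_HU
            and errs["frac_low"] <= _TOL_FRAC
            and errs["frac_high"] <= _TOL_FRAC
        )
        if ok:
            return ParenchymaDistribution(
                bulk_mean=float(mu),
                bulk_sd=float(sig),
                tail_weight=float(w),
                tail_scale=float(s),
                achieved_mean=float(m),
                achieved_sd=float(sd),
                achieved_frac_low=float(fl),
                achieved_frac_high=float(fh),
            )
        worst = max(errs, key=lambda k: errs[k] / (_TOL_HU if k in ("mean", "sd") else _TOL_FRAC))
        if best is None or errs[worst] < best[1]:
            best = (worst, errs[worst])

    raise CalibrationError(
        f"calibration infeasible for targets {targets}: "
        f"worst violated target is '{best[0]}' (|error| = {best[1]:.4g})"
    )


def _analytic(mu, sig, w, s):
    """(mean, sd, frac_low, frac_high) of the mixture with given params."""
    m = mu + w * s
    ex2 = (1 - w) * (mu * mu + sig * sig) + w * (mu * mu + 2 * mu * s + 2 * s * s)
    sd = np.sqrt(max(ex2 - m * m, 1e-12))

    def cdf(x):
        c = (1 - w) * stats.norm.cdf((x - mu) / sig)
        if x > mu:
            c += w * (1.0 - np.exp(-(x - mu) / s))
        return c

    return m, sd, cdf(m - sd), 1.0 - cdf(m + sd)


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

Ellipsoid = tuple[tuple[float, float, float], tuple[float, float, float]]


@dataclasses.dataclass
class PhantomSpec:
    """Geometry + parenchyma model for one synthetic chest volume.

    The body is an elliptical cylinder along z centred in the grid; lung
    ellipsoids must lie strictly inside it (1-voxel margin). Exterior air
    fills the rest of the grid and therefore touches the lateral faces.
    ``extra_air_pockets`` are ellipsoids of exterior-air HU that may sit
    inside the body (enclosed bubble) or outside it.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    body_hu: int = 40
    outside_hu: int = -1000
    lung_ellipsoids: tuple[Ellipsoid, ...] = ()
    distribution: ParenchymaDistribution | None = None
    extra_air_pockets: tuple[Ellipsoid, ...] = ()
    body_semiaxes_yx: tuple[float, float] | None = None  # default 0.45 * grid

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape axes must all be >= 8, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not self.lung_ellipsoids:
            raise ValueError("at least one lung ellipsoid is required")
        if self.distribution is None:
            raise ValueError("a ParenchymaDistribution is required")

    def body_mask(self) -> np.ndarray:
        nz, ny, nx = self.grid_shape
        by, bx = self.body_semiaxes_yx or (0.45 * ny, 0.45 * nx)
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        yy, xx = np.ogrid[:ny, :nx]
        section = ((yy - cy) / by) ** 2 + ((xx - cx) / bx) ** 2 <= 1.0
        return np.broadcast_to(section[None, :, :], (nz, ny, nx)).copy()

    def lung_mask(self) -> np.ndarray:
        return _ellipsoid_union(self.grid_shape, self.lung_ellipsoids)

    def pocket_mask(self) -> np.ndarray:
        if not self.extra_air_pockets:
            return np.zeros(self.grid_shape, dtype=bool)
        return _ellipsoid_union(self.grid_shape, self.extra_air_pockets)


def _ellipsoid_union(shape, ellipsoids) -> np.ndarray:
    nz, ny, nx = shape
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    mask = np.zeros(shape, dtype=bool)
    for (cz, cy, cx), (rz, ry, rx) in ellipsoids:
        if min(rz, ry, rx) <= 0:
            raise ValueError("ellipsoid semi-axes must be positive")
        mask |= (
            ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        ) <= 1.0
    return mask


def generate_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[AttenuationVolume, np.ndarray, float]:
    """Render a phantom volume.

    Returns the volume, the ground-truth lung mask, and the ground-truth
    lung volume in mL (lung voxel count x voxel volume). Bit-identical for
    identical (spec, seed).
    """
    body = spec.body_mask()
    lungs = spec.lung_mask()
    pockets = spec.pocket_mask()

    grown = ndimage.binary_dilation(lungs, ndimage.generate_binary_structure(3, 1))
    if np.any(grown & ~body):
        raise ValueError("lung ellipsoids must lie strictly inside the body region")
    if np.any(pockets & lungs):
        raise ValueError("extra air pockets must not intersect the lungs")

    vol = np.full(spec.grid_shape, spec.outside_hu, dtype=np.int16)
    vol[body] = spec.body_hu
    vol[pockets] = spec.outside_hu
    rng = np.random.default_rng(seed)
    vol[lungs] = spec.distribution.sample(int(lungs.sum()), rng)

    voxel_mm3 = float(np.prod(spec.spacing))
    gt_volume_mL = float(lungs.sum()) * voxel_mm3 / 1000.0
    return AttenuationVolume(voxels=vol, spacing=spec.spacing), lungs, gt_volume_mL


def default_phantom_spec(
    distribution: ParenchymaDistribution | None = None,
    extra_air_pockets: tuple[Ellipsoid, ...] = (),
) -> PhantomSpec:
    """Two-lung phantom on the default 96^3 grid at 2 mm isotropic.

    Distribution defaults to the 10-year-old calibration targets
    (mean -803 HU, SD 147 HU, tails 0.53% / 10.20%).
    """
    if distribution is None:
        distribution = calibrate_distribution(-803.0, 147.0, 0.0053, 0.1020)
    return PhantomSpec(
        lung_ellipsoids=(
            ((47.5, 47.5, 30.0), (34.0, 22.0, 12.5)),
            ((47.5, 47.5, 65.0), (34.0, 22.0, 12.5)),
        ),
        distribution=distribution,
        extra_air_pockets=extra_air_pockets,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a synthetic cohort.

    Ground truth follows the equation set named by ``reference_set``; each
    metric gets independent Gaussian noise of the stated SD. ``noise_sd_pct``
    applies to the %-of-total-volume metrics (no separate SD is published
    for them, so it defaults to 0).
    """

    n_subjects: int
    seed: int
    age_min: int = 6
    age_max: int = 17
    reference_set: str = "pediatric_inspiratory_v1"
    noise_sd_attenuation: float = 0.0
    noise_sd_tlc: float = 0.0
    noise_sd_pct: float = 0.0

    def __post_init__(self) -> None:
        if not (6 <= self.age_min <= self.age_max):
            raise ValueError(
                f"need 6 <= age_min <= age_max, got ({self.age_min}, {self.age_max})"
            )
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("noise_sd_attenuation", "noise_sd_tlc", "noise_sd_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def generate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Draw a cohort whose noise-free points lie exactly on the generating
    equations.

    Ages are uniform over integer years. Generating equations per metric:
    total lung volume, mean attenuation, low/high thresholds and %high are
    functions of age; %low is a function of the (noisy) total volume, so a
    noise-free record stays on that curve too. The subject SD column is
    derived as (high - low threshold) / 2.
    """
    eqs = load_reference_set(spec.reference_set)
    rng = np.random.default_rng(spec.seed)
    ages = rng.integers(spec.age_min, spec.age_max + 1, size=spec.n_subjects)

    records: list[CohortRecord] = []
    for i, age in enumerate(ages):
        age = int(age)
        tlc = predict(eqs["tlc_vs_age"], age)
        if spec.noise_sd_tlc:
            tlc += rng.normal(0, spec.noise_sd_tlc)
        mean = predict(eqs["mean_hu_vs_age"], age)
        lat = predict(eqs["lat_vs_age"], age)
        hat = predict(eqs["hat_vs_age"], age)
        if spec.noise_sd_attenuation:
            # Independent draws; redraw on the (8-sigma-rare) ordering violation.
            for _ in range(100):
                e = rng.normal(0, spec.noise_sd_attenuation, size=3)
                if lat + e[1] <= mean + e[0] <= hat + e[2]:
                    mean, lat, hat = mean + e[0], lat + e[1], hat + e[2]
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not draw ordered attenuation noise")
        pct_low = predict(eqs["pct_low_vs_tlc"], tlc)
        pct_high = predict(eqs["pct_high_vs_age"], age)
        if spec.noise_sd_pct:
            pct_low += rng.normal(0, spec.noise_sd_pct)
            pct_high += rng.normal(0, spec.noise_sd_pct)
        records.append(
            CohortRecord(
                subject_id=f"synthetic-{i:03d}",
                age_years=age,
                tlc_ct_mL=float(tlc),
                mean_hu=float(mean),
                sd_hu=float((hat - lat) / 2.0),
                lat_hu=float(lat),
                hat_hu=float(hat),
                pct_low=float(max(pct_low, 0.0)),
                pct_high=float(max(pct_high, 0.0)),
            )
        )
    return records
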