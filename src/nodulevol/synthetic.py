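"""Synthetic baseline screening cohort with follow-up growth and noise.

The trial data behind the MV-vs-EV comparison are not publicly available,
so this module generates cohorts with the statistical structure the
analysis assumes:

- a zero-truncated Poisson number of solid nodules per screenee;
- lognormal baseline measured volumes (MV);
- a shape ratio ``s = MV/EV`` drawn from a rescaled Beta distribution,
  almost always below 1 (a sphere built on the maximal diameter circumscribes
  the nodule, so EV overestimates), with a little mass just above 1 so rare
  MV > EV items occur;
- the maximal diameter back-computed from EV, with nodules under the 3 mm
  eligibility floor rejected and redrawn;
- one follow-up scan where a small malignant fraction grows exponentially
  at a lognormal true doubling time and every re-measured volume carries
  multiplicative lognormal measurement noise.

Cohorts are bit-reproducible under a fixed (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import optimize

from .volumetry import NoduleObservation, diameter_from_volume

__all__ = ["GeneratorConfig", "generate_baseline", "generate_followup", "generate_cohort"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Distributional parameters for the synthetic cohort.

    Defaults emulate a baseline screening round of ~1583 screenees carrying
    ~2715 solid nodules of at least 3 mm, with measured-volume triage
    marginals of roughly 81/12/7% negative/indeterminate/positive.

    Parameters
    ----------
    n_screenees
        Number of screenees with at least one eligible nodule.
    nodules_per_screenee_mean
        Mean of the zero-truncated Poisson nodule count (2715/1583 ≈ 1.715).
    mv_log_median_mm3, mv_log_sigma
        Median (mm³) and log-scale sd of the lognormal baseline MV.
    shape_alpha, shape_beta, shape_max
        The shape ratio s = MV/EV is ``shape_max · Beta(shape_alpha,
        shape_beta)``; with (5, 3, 1.05) under 0.5% of mass lies above 1.
    followup_fraction
        Probability a nodule is re-measured at first recall (2311/2715).
    delta_days
        Days between baseline and first recall.
    malignant_fraction
        Probability a nodule truly grows.
    true_vdt_log_median_days, true_vdt_log_sigma
        Lognormal true doubling time of growing nodules.
    measurement_cv
        Coefficient of variation of the multiplicative (median-1) lognormal
        noise on re-measured volumes.
    min_diameter_mm
        Eligibility floor applied by rejection; 0 disables it.
    seed
        Seed for all randomness.
    """

    n_screenees: int = 1583
    nodules_per_screenee_mean: float = 2715 / 1583
    mv_log_median_mm3: float = 35.0
    mv_log_sigma: float = 1.3
    shape_alpha: float = 5.0
    shape_beta: float = 3.0
    shape_max: float = 1.05
    followup_fraction: float = 2311 / 2715
    delta_days: float = 365.0
    malignant_fraction: float = 0.02
    true_vdt_log_median_days: float = 150.0
    true_vdt_log_sigma: float = 0.5
    measurement_cv: float = 0.15
    min_diameter_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("followup_fraction", "malignant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "nodules_per_screenee_mean",
            "mv_log_median_mm3",
            "mv_log_sigma",
            "shape_alpha",
            "shape_beta",
            "shape_max",
            "delta_days",
            "true_vdt_log_median_days",
            "true_vdt_log_sigma",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nodules_per_screenee_mean <= 1.0:
            raise ValueError("zero-truncated Poisson mean must exceed 1")
        if self.n_screenees <= 0:
            raise ValueError("n_screenees must be positive")
        if self.measurement_cv < 0 or self.min_diameter_mm < 0:
            raise ValueError("measurement_cv and min_diameter_mm must be non-negative")

    @property
    def noise_log_sigma(self) -> float:
        """Log-scale sd equivalent to the noise coefficient of variation."""
        return float(np.sqrt(np.log1p(self.measurement_cv**2)))


def _truncated_poisson_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean (> 1)."""
    # mean = lam / (1 - exp(-lam)); bracket is safe since RHS is increasing
    return float(
        optimize.brentq(lambda lam: lam / -np.expm1(-lam) - mean, 1e-9, 50.0)
    )


def _zt_poisson(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    """n draws from a zero-truncated Poisson(lam), by redrawing zeros."""
    out = rng.poisson(lam, size=n)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.poisson(lam, size=int(zero.sum()))


def generate_baseline(config: GeneratorConfig) -> list[NoduleObservation]:
    """Draw the baseline round: one record per eligible nodule.

    MV is lognormal, EV = MV/s with s the shape ratio, and the maximal
    diameter is the sphere diameter of EV.  Draws whose diameter falls below
    ``min_diameter_mm`` are rejected and redrawn, so the returned cohort is
    left-truncated exactly as an eligibility-filtered screening database is.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    lam = _truncated_poisson_lambda(config.nodules_per_screenee_mean)
    counts = _zt_poisson(rng, lam, config.n_screenees)
    total = int(counts.sum())
    mu = np.log(config.mv_log_median_mm3)

    mv = np.empty(total)
    diam = np.empty(total)
    floor = config.min_diameter_mm
    todo = np.arange(total)
    while todo.size:
        m = np.exp(mu + config.mv_log_sigma * rng.standard_normal(todo.size))
        s = config.shape_max * rng.beta(config.shape_alpha, config.shape_beta, todo.size)
        d = np.cbrt(6.0 * (m / s) / np.pi)
        ok = d >= floor
        mv[todo[ok]] = m[ok]
        diam[todo[ok]] = d[ok]
        todo = todo[~ok]

    observations = []
    idx = 0
    for i, c in enumerate(counts):
        sid = f"S{i:05d}"
        for j in range(int(c)):
            observations.append(
                NoduleObservation(
                    screenee_id=sid,
                    nodule_id=f"N{j}",
                    timepoint=0,
                    days_from_baseline=0,
                    max_diameter_mm=float(diam[idx]),
                    measured_volume_mm3=float(mv[idx]),
                )
            )
            idx += 1
    return observations


def generate_followup(
    baseline: list[NoduleObservation], config: GeneratorConfig
) -> list[NoduleObservation]:
    """Draw the first-recall round for a re-measured subset of nodules.

    The true volume of a growing nodule evolves as ``V·2^(Δt/VDT)`` and is
    unchanged otherwise; the observed follow-up MV multiplies the true
    volume by lognormal noise, and the follow-up diameter is derived through
    the nodule's own baseline shape ratio so EV stays consistent.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sigma_n = config.noise_log_sigma
    out = []
    for obs in baseline:
        if rng.random() >= config.followup_fraction:
            continue
        true_v = obs.measured_volume_mm3
        if rng.random() < config.malignant_fraction:
            vdt = config.true_vdt_log_median_days * np.exp(
                config.true_vdt_log_sigma * rng.standard_normal()
            )
            true_v = true_v * 2.0 ** (config.delta_days / vdt)
        noise = np.exp(sigma_n * rng.standard_normal()) if sigma_n > 0 else 1.0
        mv2 = float(true_v * noise)
        s = obs.measured_volume_mm3 / obs.estimated_volume_mm3
        out.append(
            NoduleObservation(
                screenee_id=obs.screenee_id,
                nodule_id=obs.nodule_id,
                timepoint=1,
                days_from_baseline=config.delta_days,
                max_diameter_mm=diameter_from_volume(mv2 / s),
                measured_volume_mm3=mv2,
            )
        )
    return out


def generate_cohort(config: GeneratorConfig) -> list[NoduleObservation]:
    """Baseline plus follow-up observations, in cohort-file order."""
    baseline = generate_baseline(config)
    followup = generate_followup(baseline, config)
    return sorted(baseline + followup, key=lambda o: o.key)
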