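"""Synthetic patient cohorts for a pre-post antipsychotic switch study.

Each patient carries two six-month phases of resource utilization: phase A
under oral antipsychotics, phase B after the switch to a long-acting
injectable (aripiprazole-depot).  Real patient-level data from such
observational studies are not public, so this module generates cohorts whose
marginal structure is calibrated to published summary statistics — event
rates, means and standard deviations per utilization quantity — and whose
phase-A/phase-B dependence is induced by a per-patient severity latent.

Generative families
-------------------
* hospitalization occurrence: Bernoulli(rate); the number of admissions,
  conditional on any, is zero-truncated Poisson with its intensity solved so
  the *unconditional* mean matches the target;
* day quantities (hospital days, day-clinic/PIA days, sick-leave days):
  conditional on any use, log-normal with parameters solved so that the
  distribution *clipped at the phase length* reproduces the target mean and
  SD (the clip creates a point mass at a full-phase stay, which real data
  also show);
* episode and visit counts: negative binomial moment-matched to mean/SD
  (overdispersion — SD > mean — is visible in all published figures);
* euro pass-through quantities (fee-schedule services, medication):
  occurrence Bernoulli × log-normal.

All marginals are sampled through their quantile functions from uniforms
produced by a Gaussian copula: each patient carries two shared latents (one
driving occurrence events, one driving severities), and every quantity-phase
pair mixes the relevant latent with independent noise.  Keeping the two
latents independent of each other makes the marginal calibration exact
regardless of the dependence strength.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from functools import lru_cache
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import optimize, stats

PHASE_LENGTH_DAYS = 183  # six months per observation phase

#: utilization quantities, in canonical column order
UTILIZATION_FIELDS = (
    "episodes",
    "hospitalizations",
    "hospital_days",
    "day_clinic_days",
    "psychiatrist_visits",
    "emergency_service_contacts",
    "emergency_physician_contacts",
    "sick_leave_days",
    "ebm_outpatient_eur",
    "goa_outpatient_eur",
    "ebm_inpatient_eur",
    "goa_inpatient_eur",
    "non_drug_eur",
    "medication_eur",
    "comorbid_medication_eur",
    "depot_injections",
)

DAY_FIELDS = ("hospital_days", "day_clinic_days", "sick_leave_days")

DEMOGRAPHIC_FIELDS = (
    "patient_id", "age", "sex", "employment", "insurance",
    "copay_exempt", "age_at_diagnosis",
)

PHASE_PREFIX = {"a": "a_", "b": "b_"}


def phase_column(phase: str, quantity: str) -> str:
    try:
        return PHASE_PREFIX[phase] + quantity
    except KeyError:
        raise ValueError(f"unknown phase {phase!r}; expected 'a' or 'b'") from None


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass
class PhaseUtilization:
    """One patient's resource use within a single six-month phase."""

    episodes: float = 0.0
    hospitalizations: float = 0.0
    hospital_days: float = 0.0
    day_clinic_days: float = 0.0
    psychiatrist_visits: float = 0.0
    emergency_service_contacts: float = 0.0
    emergency_physician_contacts: float = 0.0
    sick_leave_days: float = 0.0
    ebm_outpatient_eur: float = 0.0
    goa_outpatient_eur: float = 0.0
    ebm_inpatient_eur: float = 0.0
    goa_inpatient_eur: float = 0.0
    non_drug_eur: float = 0.0
    medication_eur: float = 0.0
    comorbid_medication_eur: float = 0.0
    depot_injections: float = 0.0


@dataclass
class PatientRecord:
    """One patient with demographics and both treatment phases."""

    patient_id: str
    age: float
    sex: Literal["male", "female"]
    employment: Literal["employed", "unemployed", "retired", "education", "unknown"]
    insurance: Literal["statutory", "private"]
    copay_exempt: bool
    age_at_diagnosis: float
    phase_a: PhaseUtilization = field(default_factory=PhaseUtilization)
    phase_b: PhaseUtilization = field(default_factory=PhaseUtilization)

    def phase(self, which: str) -> PhaseUtilization:
        if which == "a":
            return self.phase_a
        if which == "b":
            return self.phase_b
        raise ValueError(f"unknown phase {which!r}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class MomentTarget(BaseModel):
    """Unconditional mean/SD target for one quantity in one phase."""
    mean: float = Field(ge=0)
    sd: float = Field(ge=0)


class OccurrenceTarget(BaseModel):
    """Occurrence rate plus unconditional mean/SD for a zero-inflated quantity."""
    rate: float = Field(ge=0, le=1)
    mean: float = Field(ge=0)
    sd: float = Field(ge=0)


class CountTarget(BaseModel):
    """Occurrence rate plus unconditional mean for a Bernoulli x ZTP count."""
    rate: float = Field(ge=0, le=1)
    mean: float = Field(ge=0)


class PhaseTargets(BaseModel):
    """Calibration targets for every utilization quantity of one phase."""

    hospitalization_rate: float = Field(ge=0, le=1)
    hospitalizations_mean: float = Field(ge=0)
    hospital_days: MomentTarget
    episodes: MomentTarget
    day_clinic: OccurrenceTarget
    psychiatrist_visits: MomentTarget
    emergency_services: CountTarget
    emergency_physician: CountTarget
    sick_leave: OccurrenceTarget  # employed stratum only
    depot_injections_mean: float = Field(ge=0)
    ebm_outpatient: OccurrenceTarget
    goa_outpatient: OccurrenceTarget
    ebm_inpatient: MomentTarget   # occurrence tied to hospitalization
    goa_inpatient: MomentTarget   # occurrence tied to hospitalization
    non_drug: OccurrenceTarget
    medication: OccurrenceTarget
    comorbid_medication: OccurrenceTarget

    @model_validator(mode="after")
    def _check_feasibility(self) -> "PhaseTargets":
        # zero-inflated targets: conditional variance must be non-negative,
        # i.e. rate > mean^2 / (mean^2 + sd^2)
        for name in ("day_clinic", "sick_leave", "ebm_outpatient", "goa_outpatient",
                     "non_drug", "medication", "comorbid_medication"):
            t = getattr(self, name)
            _conditional_moments(name, t.rate, t.mean, t.sd)
        for name in ("ebm_inpatient", "goa_inpatient", "hospital_days"):
            t = getattr(self, name)
            _conditional_moments(name, self.hospitalization_rate, t.mean, t.sd)
        for name in ("emergency_services", "emergency_physician"):
            t = getattr(self, name)
            if t.mean > 0 and t.rate > 0 and t.mean / t.rate < 1.0 - 1e-9:
                raise ValueError(
                    f"{name}: unconditional mean {t.mean} below occurrence "
                    f"rate {t.rate}; conditional count mean must be >= 1")
            if t.mean > 0 and t.rate == 0:
                raise ValueError(f"{name}: mean > 0 requires rate > 0")
        if self.hospitalizations_mean > 0:
            if self.hospitalization_rate == 0:
                raise ValueError(
                    "hospitalizations_mean: positive mean requires a positive "
                    "hospitalization_rate")
            if self.hospitalizations_mean / self.hospitalization_rate < 1 - 1e-9:
                raise ValueError(
                    "hospitalizations_mean: conditional admissions per "
                    "hospitalized patient must be >= 1")
        return self


def _conditional_moments(name: str, rate: float, mean: float, sd: float
                         ) -> tuple[float, float]:
    """(conditional mean, conditional SD) of X | X occurs, given the
    unconditional targets; raises if the configuration is infeasible."""
    if mean == 0:
        return 0.0, 0.0
    if rate == 0:
        raise ValueError(f"{name}: mean > 0 requires occurrence rate > 0")
    cm = mean / rate
    second = (sd * sd + mean * mean) / rate
    cvar = second - cm * cm
    if cvar < -1e-9:
        raise ValueError(
            f"{name}: occurrence rate {rate} is infeasible for mean {mean}, "
            f"sd {sd}; rate must exceed mean^2/(mean^2+sd^2) = "
            f"{mean * mean / (mean * mean + sd * sd):.4f}")
    return cm, math.sqrt(max(cvar, 0.0))


def _default_phase_a() -> PhaseTargets:
    return PhaseTargets(
        hospitalization_rate=0.551,
        hospitalizations_mean=0.63,
        hospital_days=MomentTarget(mean=27.39, sd=41.37),
        episodes=MomentTarget(mean=2.58, sd=2.91),
        day_clinic=OccurrenceTarget(rate=0.65, mean=46.13, sd=45.47),
        psychiatrist_visits=MomentTarget(mean=10.57, sd=8.0),
        emergency_services=CountTarget(rate=0.09848, mean=0.23439),
        emergency_physician=CountTarget(rate=0.05303, mean=0.07530),
        sick_leave=OccurrenceTarget(rate=0.90, mean=40.06, sd=29.62),
        depot_injections_mean=0.0,
        ebm_outpatient=OccurrenceTarget(rate=0.924, mean=314.37, sd=250.0),
        goa_outpatient=OccurrenceTarget(rate=0.076, mean=28.64, sd=120.0),
        ebm_inpatient=MomentTarget(mean=78.36, sd=120.0),
        goa_inpatient=MomentTarget(mean=4.67, sd=25.0),
        non_drug=OccurrenceTarget(rate=0.50, mean=373.42, sd=500.0),
        medication=OccurrenceTarget(rate=1.0, mean=2447.80, sd=2000.0),
        comorbid_medication=OccurrenceTarget(rate=0.60, mean=461.07, sd=600.0),
    )


def _default_phase_b() -> PhaseTargets:
    return PhaseTargets(
        hospitalization_rate=0.14,
        hospitalizations_mean=0.16,
        hospital_days=MomentTarget(mean=5.56, sd=20.70),
        episodes=MomentTarget(mean=0.41, sd=0.76),
        day_clinic=OccurrenceTarget(rate=0.25, mean=7.29, sd=15.02),
        psychiatrist_visits=MomentTarget(mean=7.73, sd=7.0),
        emergency_services=CountTarget(rate=0.02273, mean=0.04545),
        emergency_physician=CountTarget(rate=0.003788, mean=0.007576),
        sick_leave=OccurrenceTarget(rate=0.50, mean=15.80, sd=24.67),
        depot_injections_mean=4.5072,
        ebm_outpatient=OccurrenceTarget(rate=0.924, mean=286.18, sd=230.0),
        goa_outpatient=OccurrenceTarget(rate=0.076, mean=11.98, sd=50.0),
        ebm_inpatient=MomentTarget(mean=26.02, sd=70.0),
        goa_inpatient=MomentTarget(mean=1.29, sd=10.0),
        non_drug=OccurrenceTarget(rate=0.30, mean=103.79, sd=200.0),
        medication=OccurrenceTarget(rate=0.50, mean=103.35, sd=150.0),
        comorbid_medication=OccurrenceTarget(rate=0.60, mean=238.07, sd=350.0),
    )


class Demographics(BaseModel):
    age_mean: float = 37.81
    age_sd: float = 10.54
    age_min: float = 18.0
    age_max: float = 65.0
    diagnosis_age_mean: float = 30.55
    diagnosis_age_sd: float = 8.67
    diagnosis_age_min: float = 5.0
    female_rate: float = Field(default=71 / 132, ge=0, le=1)
    statutory_rate: float = Field(default=122 / 132, ge=0, le=1)
    copay_exempt_rate: float = Field(default=72 / 122, ge=0, le=1,
                                     description="among statutory-insured")
    # employed / unemployed / retired / in education / unknown
    employment_shares: dict[str, float] = Field(
        default_factory=lambda: {
            "employed": 24 / 132, "unemployed": 39 / 132, "retired": 51 / 132,
            "education": 9 / 132, "unknown": 9 / 132})

    @model_validator(mode="after")
    def _check(self) -> "Demographics":
        total = sum(self.employment_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"employment_shares must sum to 1, got {total}")
        unknown = set(self.employment_shares) - {
            "employed", "unemployed", "retired", "education", "unknown"}
        if unknown:
            raise ValueError(f"employment_shares: unknown categories {sorted(unknown)}")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be below age_max")
        return self


class CohortConfig(BaseModel):
    """Full specification of a synthetic cohort.

    The defaults encode the published study conditions: n = 132 patients,
    two six-month phases, a 55.1% vs 14% hospitalization rate, and the
    reported means/SDs of every utilization quantity.
    """

    n: int = Field(default=132, ge=1)
    seed: int = Field(default=20160516, ge=0, lt=2**31)
    phase_length_days: int = Field(default=PHASE_LENGTH_DAYS, gt=0)
    frailty_correlation: float = Field(default=0.5, ge=0, le=1)
    missingness_rate: float = Field(default=0.0, ge=0, lt=1)
    demographics: Demographics = Field(default_factory=Demographics)
    phase_a: PhaseTargets = Field(default_factory=_default_phase_a)
    phase_b: PhaseTargets = Field(default_factory=_default_phase_b)

    @model_validator(mode="after")
    def _check_day_caps(self) -> "CohortConfig":
        for pname, targets in (("phase_a", self.phase_a), ("phase_b", self.phase_b)):
            checks = (
                ("hospital_days", targets.hospitalization_rate, targets.hospital_days),
                ("day_clinic", targets.day_clinic.rate, targets.day_clinic),
                ("sick_leave", targets.sick_leave.rate, targets.sick_leave),
            )
            for qname, rate, t in checks:
                if t.mean == 0:
                    continue
                if t.mean / max(rate, 1e-12) >= self.phase_length_days:
                    raise ValueError(
                        f"{pname}.{qname}: conditional mean "
                        f"{t.mean / max(rate, 1e-12):.1f} days reaches the "
                        f"phase length of {self.phase_length_days} days")
        return self


def zero_targets() -> PhaseTargets:
    """A degenerate all-zero phase (useful for smoke tests)."""
    z = MomentTarget(mean=0, sd=0)
    zo = OccurrenceTarget(rate=0, mean=0, sd=0)
    zc = CountTarget(rate=0, mean=0)
    return PhaseTargets(
        hospitalization_rate=0, hospitalizations_mean=0, hospital_days=z,
        episodes=z, day_clinic=zo, psychiatrist_visits=z,
        emergency_services=zc, emergency_physician=zc, sick_leave=zo,
        depot_injections_mean=0, ebm_outpatient=zo, goa_outpatient=zo,
        ebm_inpatient=z, goa_inpatient=z, non_drug=zo, medication=zo,
        comorbid_medication=zo)


# ---------------------------------------------------------------------------
# marginal building blocks
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _ztp_lambda(conditional_mean: float) -> float:
    """Intensity of a zero-truncated Poisson with the given mean (>= 1)."""
    if conditional_mean <= 1.0 + 1e-12:
        return 1e-9
    f = lambda lam: lam / (-math.expm1(-lam)) - conditional_mean
    return optimize.brentq(f, 1e-9, 1e3)


def _ztp_ppf(u: np.ndarray, lam: float) -> np.ndarray:
    p0 = math.exp(-lam)
    shifted = p0 + u * (1.0 - p0)
    return np.maximum(stats.poisson.ppf(np.clip(shifted, 0, 1 - 1e-16), lam), 1.0)


def _clipped_lognorm_moments(mu: float, sigma: float, cap: float
                             ) -> tuple[float, float]:
    """Mean and SD of min(X, cap) for X ~ LogNormal(mu, sigma)."""
    lc = math.log(cap)
    z = (lc - mu) / sigma
    m1 = math.exp(mu + sigma**2 / 2) * stats.norm.cdf(z - sigma) \
        + cap * stats.norm.sf(z)
    m2 = math.exp(2 * mu + 2 * sigma**2) * stats.norm.cdf(z - 2 * sigma) \
        + cap**2 * stats.norm.sf(z)
    var = max(m2 - m1 * m1, 0.0)
    return m1, math.sqrt(var)


@lru_cache(maxsize=256)
def _lognorm_params(mean: float, sd: float, cap: Optional[float]
                    ) -> tuple[float, float]:
    """Log-normal (mu, sigma) whose cap-clipped mean/SD match the targets.

    With no cap (or a negligible tail beyond it) this is the classical
    moment match; otherwise the pair is solved numerically so that the
    clipped distribution reproduces the targets exactly.
    """
    if mean <= 0:
        raise ValueError("log-normal target mean must be positive")
    if sd == 0:
        return math.log(mean), 0.0
    cv2 = (sd / mean) ** 2
    sigma0 = math.sqrt(math.log1p(cv2))
    mu0 = math.log(mean) - sigma0**2 / 2
    if cap is None:
        return mu0, sigma0
    if mean >= cap:
        raise ValueError(f"target mean {mean} must lie below the cap {cap}")
    # negligible clipped tail: keep the closed form
    m1, _ = _clipped_lognorm_moments(mu0, sigma0, cap)
    if abs(m1 - mean) < 1e-9 * mean:
        return mu0, sigma0

    def resid(theta: np.ndarray) -> np.ndarray:
        mu, log_sigma = theta
        m, s = _clipped_lognorm_moments(mu, math.exp(log_sigma), cap)
        return np.array([m - mean, s - sd])

    sol = optimize.least_squares(resid, x0=[mu0, math.log(sigma0)],
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    mu, sigma = sol.x[0], math.exp(sol.x[1])
    m, s = _clipped_lognorm_moments(mu, sigma, cap)
    if abs(m - mean) > 1e-6 * max(mean, 1.0):
        # SD may be unattainable under clipping; fall back to matching the
        # mean alone with the unclipped sigma
        g = lambda mm: _clipped_lognorm_moments(mm, sigma0, cap)[0] - mean
        mu = optimize.brentq(g, mu0 - 10, math.log(cap))
        sigma = sigma0
    return mu, sigma


def _lognorm_ppf(u: np.ndarray, mu: float, sigma: float,
                 cap: Optional[float]) -> np.ndarray:
    x = np.exp(mu + sigma * stats.norm.ppf(np.clip(u, 1e-16, 1 - 1e-16)))
    if cap is not None:
        x = np.minimum(x, cap)
    return x


def _nbinom_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Negative-binomial quantiles moment-matched to mean/SD.

    Falls back to Poisson when the target is not overdispersed.
    """
    var = sd * sd
    uc = np.clip(u, 0, 1 - 1e-16)
    if var <= mean + 1e-12:
        return stats.poisson.ppf(uc, mean)
    r = mean * mean / (var - mean)
    p = mean / var
    return stats.nbinom.ppf(uc, r, p)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _randomized_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unbiased stochastic rounding to integers (preserves expectations)."""
    floor = np.floor(x)
    return floor + (rng.random(x.shape) < (x - floor))


class _Copula:
    """Gaussian-copula uniform source with shared per-patient latents.

    Two independent shared latents are used: one driving occurrence events
    and one driving severities (conditional counts, days, euro amounts).
    Keeping them independent is what makes the calibration exact: the
    severity drawn for a patient is then independent of whether their
    occurrence event fired, so the unconditional mean factorises as
    rate x conditional mean.  Cross-phase dependence within each stream is
    still induced by the shared latents.
    """

    def __init__(self, n: int, correlation: float, rng: np.random.Generator):
        self._shared = {"occ": rng.standard_normal(n),
                        "sev": rng.standard_normal(n)}
        self._w = math.sqrt(correlation)
        self._v = math.sqrt(1.0 - correlation)
        self._rng = rng
        self._n = n

    def uniforms(self, kind: str = "sev") -> np.ndarray:
        z = self._w * self._shared[kind] \
            + self._v * self._rng.standard_normal(self._n)
        return stats.norm.cdf(z)

    def occurs(self, rate: float) -> np.ndarray:
        """Occurrence indicator with the sicker (high-latent) patients
        experiencing the event."""
        return self.uniforms("occ") > 1.0 - rate


def _allocate_counts(n: int, shares: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n items across category shares."""
    raw = [n * s for s in shares]
    counts = [int(math.floor(r)) for r in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def _categorical(n: int, categories: Sequence[str], shares: Sequence[float],
                 rng: np.random.Generator) -> np.ndarray:
    """Fixed-composition categorical assignment (exact counts, shuffled).

    Mirrors how a finite study sample realises its composition table: with
    the default shares a 132-patient cohort has exactly 24 employed patients.
    """
    counts = _allocate_counts(n, shares)
    values = np.repeat(np.array(categories, dtype=object), counts)
    return rng.permutation(values)


def _generate_phase(targets: PhaseTargets, cop: _Copula, n: int, cap: int,
                    employed: np.ndarray, rng: np.random.Generator
                    ) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}

    # hospitalization block: one occurrence event drives admissions, days and
    # inpatient fee-schedule euros, so the logical couplings hold by design
    rate = targets.hospitalization_rate
    hosp_occ = cop.occurs(rate)
    u_count, u_days = cop.uniforms(), cop.uniforms()
    counts = np.zeros(n)
    days = np.zeros(n)
    if rate > 0 and targets.hospitalizations_mean > 0:
        lam = _ztp_lambda(targets.hospitalizations_mean / rate)
        counts[hosp_occ] = _ztp_ppf(u_count[hosp_occ], lam)
    t = targets.hospital_days
    admitted = counts >= 1  # days only for admitted patients (logical coupling)
    if rate > 0 and t.mean > 0:
        cm, cs = _conditional_moments("hospital_days", rate, t.mean, t.sd)
        mu, sigma = _lognorm_params(cm, cs, float(cap))
        days[admitted] = _lognorm_ppf(u_days[admitted], mu, sigma, float(cap))
    out["hospitalizations"] = counts
    out["hospital_days"] = np.minimum(_randomized_round(days, rng), cap)

    def zero_inflated(name: str, occ_rate: float, t, occ_mask=None,
                      day_cap: Optional[float] = None) -> np.ndarray:
        vals = np.zeros(n)
        if t.mean == 0:
            cop.uniforms("occ")  # keep the draw order stable
            return vals
        if occ_mask is None:
            occ_mask = cop.occurs(occ_rate)
        else:
            cop.uniforms("occ")
        cm, cs = _conditional_moments(name, occ_rate, t.mean, t.sd)
        mu, sigma = _lognorm_params(cm, cs, day_cap)
        vals[occ_mask] = _lognorm_ppf(cop.uniforms()[occ_mask], mu, sigma, day_cap)
        return vals

    dc = targets.day_clinic
    day_clinic = zero_inflated("day_clinic", dc.rate, dc, day_cap=float(cap))
    out["day_clinic_days"] = np.minimum(_randomized_round(day_clinic, rng), cap)

    out["episodes"] = _nbinom_ppf(cop.uniforms(), targets.episodes.mean,
                                  targets.episodes.sd)
    out["psychiatrist_visits"] = _nbinom_ppf(
        cop.uniforms(), targets.psychiatrist_visits.mean,
        targets.psychiatrist_visits.sd)

    for name, key in (("emergency_services", "emergency_service_contacts"),
                      ("emergency_physician", "emergency_physician_contacts")):
        t = getattr(targets, name)
        occ = cop.occurs(t.rate)
        u = cop.uniforms()
        vals = np.zeros(n)
        if t.mean > 0 and t.rate > 0:
            lam = _ztp_lambda(t.mean / t.rate)
            vals[occ] = _ztp_ppf(u[occ], lam)
        out[key] = vals

    # sick leave: drawn for the employed stratum only; the published
    # means/SDs describe that subsample
    sl = targets.sick_leave
    occ = cop.occurs(sl.rate) & employed
    u = cop.uniforms()
    vals = np.zeros(n)
    if sl.mean > 0:
        cm, cs = _conditional_moments("sick_leave", sl.rate, sl.mean, sl.sd)
        mu, sigma = _lognorm_params(cm, cs, float(cap))
        vals[occ] = _lognorm_ppf(u[occ], mu, sigma, float(cap))
    out["sick_leave_days"] = np.minimum(_randomized_round(vals, rng), cap)

    out["ebm_outpatient_eur"] = zero_inflated(
        "ebm_outpatient", targets.ebm_outpatient.rate, targets.ebm_outpatient)
    out["goa_outpatient_eur"] = zero_inflated(
        "goa_outpatient", targets.goa_outpatient.rate, targets.goa_outpatient)
    out["ebm_inpatient_eur"] = zero_inflated(
        "ebm_inpatient", rate, targets.ebm_inpatient, occ_mask=hosp_occ)
    out["goa_inpatient_eur"] = zero_inflated(
        "goa_inpatient", rate, targets.goa_inpatient, occ_mask=hosp_occ)
    out["non_drug_eur"] = zero_inflated(
        "non_drug", targets.non_drug.rate, targets.non_drug)
    out["medication_eur"] = zero_inflated(
        "medication", targets.medication.rate, targets.medication)
    out["comorbid_medication_eur"] = zero_inflated(
        "comorbid_medication", targets.comorbid_medication.rate,
        targets.comorbid_medication)

    out["depot_injections"] = (
        stats.poisson.ppf(np.clip(cop.uniforms(), 0, 1 - 1e-16),
                          targets.depot_injections_mean)
        if targets.depot_injections_mean > 0 else np.zeros(n))
    return out


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a cohort as a DataFrame, one row per patient.

    Columns: demographics plus ``a_``/``b_``-prefixed utilization columns.
    Identical config (including seed) yields a byte-identical table.
    """
    if not isinstance(config, CohortConfig):
        config = CohortConfig.model_validate(config)
    rng = np.random.default_rng(config.seed)
    n = config.n
    demo = config.demographics

    # demographics -----------------------------------------------------
    a = (demo.age_min - demo.age_mean) / demo.age_sd
    b = (demo.age_max - demo.age_mean) / demo.age_sd
    age = stats.truncnorm.ppf(rng.random(n), a, b,
                              loc=demo.age_mean, scale=demo.age_sd)
    lo = (demo.diagnosis_age_min - demo.diagnosis_age_mean) / demo.diagnosis_age_sd
    hi = (age - demo.diagnosis_age_mean) / demo.diagnosis_age_sd
    age_dx = stats.truncnorm.ppf(rng.random(n), lo, np.maximum(hi, lo + 1e-9),
                                 loc=demo.diagnosis_age_mean,
                                 scale=demo.diagnosis_age_sd)
    age_dx = np.minimum(age_dx, age)

    sex = _categorical(n, ["female", "male"],
                       [demo.female_rate, 1 - demo.female_rate], rng)
    emp_cats = ["employed", "unemployed", "retired", "education", "unknown"]
    employment = _categorical(n, emp_cats,
                              [demo.employment_shares[c] for c in emp_cats], rng)
    insurance = _categorical(n, ["statutory", "private"],
                             [demo.statutory_rate, 1 - demo.statutory_rate], rng)
    copay = (insurance == "statutory") & (rng.random(n) < demo.copay_exempt_rate)
    employed = employment == "employed"

    # utilization ------------------------------------------------------
    cop = _Copula(n, config.frailty_correlation, rng)
    cap = config.phase_length_days
    cols: dict[str, object] = {
        "patient_id": [f"P{i + 1:04d}" for i in range(n)],
        "age": np.round(age, 2),
        "sex": sex,
        "employment": employment,
        "insurance": insurance,
        "copay_exempt": copay,
        "age_at_diagnosis": np.round(age_dx, 2),
    }
    for phase, targets in (("a", config.phase_a), ("b", config.phase_b)):
        values = _generate_phase(targets, cop, n, cap, employed, rng)
        for q in UTILIZATION_FIELDS:
            cols[phase_column(phase, q)] = values[q]

    frame = pd.DataFrame(cols)
    if config.missingness_rate > 0:
        for phase in ("a", "b"):
            for q in UTILIZATION_FIELDS:
                mask = rng.random(n) < config.missingness_rate
                col = phase_column(phase, q)
                frame.loc[mask, col] = np.nan
    return frame


# ---------------------------------------------------------------------------
# validation, summaries, I/O
# ---------------------------------------------------------------------------

def validate_utilization(frame: pd.DataFrame,
                         phase_length_days: int = PHASE_LENGTH_DAYS
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort into plausible and implausible records.

    A record is rejected when any day count exceeds the phase length, any
    quantity is negative, or hospital days are reported without a
    hospitalization.  Rejected rows carry a ``rejection_reasons`` column;
    retained + rejected partition the input.  Filtering never raises.
    """
    if phase_length_days <= 0:
        raise ValueError("phase_length_days must be positive")
    reasons: list[list[str]] = [[] for _ in range(len(frame))]
    for phase in ("a", "b"):
        for q in DAY_FIELDS:
            col = phase_column(phase, q)
            if col not in frame.columns:
                continue
            over = frame[col].to_numpy(dtype=float) > phase_length_days
            for i in np.flatnonzero(np.nan_to_num(over)):
                reasons[i].append(f"{col} > {phase_length_days}")
        for q in UTILIZATION_FIELDS:
            col = phase_column(phase, q)
            if col not in frame.columns:
                continue
            neg = frame[col].to_numpy(dtype=float) < 0
            for i in np.flatnonzero(np.nan_to_num(neg)):
                reasons[i].append(f"{col} < 0")
        dcol, hcol = phase_column(phase, "hospital_days"), phase_column(phase, "hospitalizations")
        if dcol in frame.columns and hcol in frame.columns:
            bad = (frame[dcol].to_numpy(dtype=float) > 0) & \
                  (frame[hcol].to_numpy(dtype=float) == 0)
            for i in np.flatnonzero(np.nan_to_num(bad)):
                reasons[i].append(f"{dcol} > 0 with {hcol} = 0")
    keep = np.array([not r for r in reasons])
    retained = frame.iloc[keep].reset_index(drop=True)
    rejected = frame.iloc[~keep].reset_index(drop=True)
    rejected = rejected.assign(
        rejection_reasons=["; ".join(r) for r, k in zip(reasons, keep) if not k])
    return retained, rejected


def summarize_cohort(frame: pd.DataFrame, phase: str) -> pd.DataFrame:
    """Per-quantity mean, SD and event rate (share with value >= 1) for one
    phase, computed over non-missing values."""
    if len(frame) == 0:
        raise ValueError("cannot summarize an empty cohort")
    rows = []
    for q in UTILIZATION_FIELDS:
        col = phase_column(phase, q)
        if col not in frame.columns:
            continue
        vals = frame[col].dropna().to_numpy(dtype=float)
        rows.append({
            "quantity": q,
            "n": len(vals),
            "mean": float(np.mean(vals)) if len(vals) else np.nan,
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            "event_rate": float(np.mean(vals >= 1)) if len(vals) else np.nan,
        })
    return pd.DataFrame(rows).set_index("quantity")


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort as comma-separated text (missing values empty)."""
    frame.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in DEMOGRAPHIC_FIELDS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file lacks demographic columns: {missing}")
    return frame


def records_from_frame(frame: pd.DataFrame) -> list[PatientRecord]:
    """Materialise DataFrame rows as :class:`PatientRecord` objects."""
    util_names = [f.name for f in dc_fields(PhaseUtilization)]
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        phases = {}
        for phase in ("a", "b"):
            kwargs = {q: _nan_to_zero(d.get(phase_column(phase, q), 0.0))
                      for q in util_names}
            phases[phase] = PhaseUtilization(**kwargs)
        records.append(PatientRecord(
            patient_id=str(d["patient_id"]), age=float(d["age"]),
            sex=d["sex"], employment=d["employment"], insurance=d["insurance"],
            copay_exempt=bool(d["copay_exempt"]),
            age_at_diagnosis=float(d["age_at_diagnosis"]),
            phase_a=phases["a"], phase_b=phases["b"]))
    return records


def _nan_to_zero(x) -> float:
    x = float(x)
    return 0.0 if math.isnan(x) else x


def frame_from_records(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {f: getattr(r, f) for f in DEMOGRAPHIC_FIELDS}
        for phase in ("a", "b"):
            util = r.phase(phase)
            for q in UTILIZATION_FIELDS:
                d[phase_column(phase, q)] = getattr(util, q)
        rows.append(d)
    return pd.DataFrame(rows)
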