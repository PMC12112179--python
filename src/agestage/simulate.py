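"""Synthetic cohort and bioassay generators with known ground truth.

The cohort generator emulates a stage-structured insect life-table study:
an egg cohort passes through four larval instars and a pupal stage, each
with a stochastic duration (1 + Poisson days, so every stage lasts at least
one day, matching an integer-day census) and a per-day survival
probability; survivors emerge as adults with a drawn sex, an adult
preoviposition period (APOP), an adult longevity, and — for females — a
daily fecundity schedule whose Poisson rate follows a triangular curve of
days since first oviposition.

Default parameter values put the generator in the regime of a tomato
leafminer (*Phthorimaea absoluta*) laboratory cohort: egg ≈ 4.9 d, instars
≈ 2.7–3.0 d, pupa ≈ 7.1 d, ≈ 100 eggs per female, even sex ratio, and
preadult survival ≈ 0.7, so that R0 lands near 35 offspring per egg.

:func:`expected_parameters` evaluates the generator's implied net-maternity
schedule numerically (no simulation), providing exact targets for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import FEMALE_ADULT, MALE_ADULT, Cohort, IndividualRecord
from .lifetable import intrinsic_rate_from_schedule
from .probit import DoseResponseData

__all__ = [
    "SyntheticCohortSpec", "SyntheticBioassaySpec", "ExpectedParameters",
    "generate_cohort", "expected_parameters", "generate_bioassay",
    "cohort_spec_from_yaml", "bioassay_spec_from_yaml",
]

PREADULT_STAGES = ("egg", "L1", "L2", "L3", "L4", "pupa")


@dataclass
class SyntheticCohortSpec:
    """Ground-truth description of a synthetic life-table cohort.

    Stage durations are ``1 + Poisson(mean - 1)`` days; the ``*_mean``
    fields give the resulting mean duration in days. ``preadult_extra_days``
    and ``fecundity_multiplier`` are treatment knobs for emulating a
    sublethally stressed strain (longer development, reduced fecundity).
    """

    seed: int
    n_01: int = 100
    stage_duration_means: dict[str, float] = field(default_factory=lambda: {
        "egg": 4.9, "L1": 3.0, "L2": 2.8, "L3": 2.7, "L4": 2.8, "pupa": 7.1})
    stage_daily_survival: dict[str, float] = field(default_factory=lambda: {
        "egg": 0.985, "L1": 0.975, "L2": 0.985, "L3": 0.985,
        "L4": 0.985, "pupa": 0.99})
    female_prob: float = 0.5
    apop_mean: float = 2.1            # days; APOP ~ Poisson (0 = lays at emergence)
    female_longevity_mean: float = 18.1
    male_longevity_mean: float = 17.1
    fecundity_peak: float = 21.0      # eggs/day at the schedule peak
    fecundity_peak_day: int = 2       # days since first oviposition
    fecundity_last_day: int = 8
    fixed_eggs: int | None = None     # lay exactly this many on the first day
    fecundity_multiplier: float = 1.0
    preadult_extra_days: float = 0.0

    def __post_init__(self) -> None:
        if self.n_01 < 1:
            raise ValueError("n_01 must be at least 1")
        for stage in PREADULT_STAGES:
            if self.stage_duration_means.get(stage, 1.0) < 1.0:
                raise ValueError(f"{stage}: mean duration must be >= 1 day")
            p = self.stage_daily_survival.get(stage, 1.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{stage}: daily survival must be in [0, 1]")
        if not 0.0 <= self.female_prob <= 1.0:
            raise ValueError("female_prob must be in [0, 1]")
        if self.apop_mean < 0.0:
            raise ValueError("APOP mean must be non-negative")
        if self.female_longevity_mean < 1.0 or self.male_longevity_mean < 1.0:
            raise ValueError("longevity means must be >= 1 day")
        if self.fecundity_peak < 0 or self.fecundity_multiplier < 0:
            raise ValueError("fecundity rates must be non-negative")
        if not 0 <= self.fecundity_peak_day <= self.fecundity_last_day:
            raise ValueError("need 0 <= peak day <= last day")

    def duration_mu(self, stage: str) -> float:
        """Poisson mean of the (duration - 1) for a preadult stage, with the
        treatment prolongation spread evenly over the preadult stages."""
        extra = self.preadult_extra_days / len(PREADULT_STAGES)
        return self.stage_duration_means[stage] - 1.0 + extra

    def oviposition_rate(self, tau: int) -> float:
        """Expected eggs on day ``tau`` since first oviposition (triangular)."""
        peak, pk, last = (self.fecundity_peak, self.fecundity_peak_day,
                          self.fecundity_last_day)
        if tau < 0 or tau > last:
            r = 0.0
        elif tau <= pk:
            r = peak * (tau + 1.0) / (pk + 1.0)
        else:
            r = peak * (last + 1.0 - tau) / (last + 1.0 - pk)
        return r * self.fecundity_multiplier


def generate_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Simulate one cohort individual by individual; reproducible under the
    spec's seed. The result satisfies all cohort data-model invariants."""
    rng = np.random.default_rng(spec.seed)
    individuals: list[IndividualRecord] = []
    for i in range(spec.n_01):
        rec = _simulate_individual(spec, rng, f"ind{i:04d}")
        individuals.append(rec)
    return Cohort(individuals=individuals).require_valid()


def _simulate_individual(spec: SyntheticCohortSpec, rng: np.random.Generator,
                         rid: str) -> IndividualRecord:
    age = 0
    stage_entry: dict[str, int] = {}
    for stage in PREADULT_STAGES:
        stage_entry[stage] = age
        d = 1 + int(rng.poisson(spec.duration_mu(stage)))
        p = spec.stage_daily_survival[stage]
        for k in range(d):
            if rng.random() > p:
                return IndividualRecord(id=rid, sex="u",
                                        stage_entry=stage_entry,
                                        death_age=age + k)
        age += d
    female = rng.random() < spec.female_prob
    sex = "f" if female else "m"
    stage_entry[FEMALE_ADULT if female else MALE_ADULT] = age
    longevity_mean = (spec.female_longevity_mean if female
                      else spec.male_longevity_mean)
    longevity = 1 + int(rng.poisson(longevity_mean - 1.0))
    death_age = age + longevity - 1
    fecundity: dict[int, int] = {}
    if female:
        apop = int(rng.poisson(spec.apop_mean))
        first = age + apop
        if spec.fixed_eggs is not None:
            if first <= death_age:
                fecundity[first] = spec.fixed_eggs
        else:
            for tau in range(spec.fecundity_last_day + 1):
                day = first + tau
                if day > death_age:
                    break
                n = int(rng.poisson(spec.oviposition_rate(tau)))
                if n > 0:
                    fecundity[day] = n
    return IndividualRecord(id=rid, sex=sex, stage_entry=stage_entry,
                            death_age=death_age, fecundity=fecundity)


@dataclass
class ExpectedParameters:
    """Generator-implied population parameters, computed numerically from the
    spec's distributions (no Monte Carlo)."""

    R0: float
    r: float
    lambda_: float
    T: float
    mean_fecundity_F: float   # expected eggs per emerging female
    female_ratio: float       # P(reach adulthood) * P(female)
    preadult_survival: float
    expected_preadult_days: float  # mean adult-entry age among survivors
    schedule: np.ndarray      # expected l_x * m_x by age


def _truncated_poisson_pmf(mu: float) -> np.ndarray:
    k_max = int(np.ceil(mu + 10.0 * np.sqrt(max(mu, 1.0)) + 20.0))
    return stats.poisson.pmf(np.arange(k_max + 1), mu)


def expected_parameters(spec: SyntheticCohortSpec) -> ExpectedParameters:
    """Evaluate the spec's implied demography exactly (up to pmf truncation
    below 1e-12): survival-weighted convolution of stage durations gives the
    adult-emergence age distribution; the APOP/longevity/fecundity schedule
    gives expected eggs per adult day; their convolution is the expected
    net-maternity schedule, from which R0 and the Euler-Lotka r follow."""
    # adult-entry age distribution, survival included
    enter = np.array([1.0])
    for stage in PREADULT_STAGES:
        mu = spec.duration_mu(stage)
        p = spec.stage_daily_survival[stage]
        pmf = _truncated_poisson_pmf(mu)
        d = np.arange(1, len(pmf) + 1)             # duration = 1 + Poisson
        kernel = np.zeros(len(pmf) + 1)
        kernel[1:] = pmf * p ** d.astype(float)
        enter = np.convolve(enter, kernel)
    adult_dist = enter
    p_adult = float(adult_dist.sum())

    # expected eggs per adult-age day, marginal over APOP and longevity
    apop_pmf = _truncated_poisson_pmf(spec.apop_mean)
    lon_pmf = _truncated_poisson_pmf(spec.female_longevity_mean - 1.0)
    lon_sf = 1.0 - np.cumsum(lon_pmf)  # P(longevity - 1 > d) = P(L >= d + 2)
    def p_alive_on_adult_day(d: int) -> float:
        # alive on adult-age day d  <=>  longevity >= d + 1  <=>  (L-1) >= d
        if d <= 0:
            return 1.0
        return float(lon_sf[d - 1]) if d - 1 < len(lon_sf) else 0.0

    if spec.fixed_eggs is not None:
        taus = np.array([0])
        rates = np.array([float(spec.fixed_eggs)])
    else:
        taus = np.arange(spec.fecundity_last_day + 1)
        rates = np.array([spec.oviposition_rate(int(t)) for t in taus])
    max_day = (len(apop_pmf) + 1) + int(taus.max()) + 1
    g = np.zeros(max_day + 1)  # expected eggs on adult-age day d
    for apop, pk in enumerate(apop_pmf):
        for t, rate in zip(taus, rates):
            d = apop + int(t)
            g[d] += pk * rate * p_alive_on_adult_day(d)
    mean_fec = float(g.sum())

    schedule = spec.female_prob * np.convolve(adult_dist, g)
    R0 = float(schedule.sum())
    if R0 > 0:
        r = intrinsic_rate_from_schedule(schedule)
        lam = float(np.exp(r))
        T = float(np.log(R0) / r) if r != 0 else float("nan")
    else:
        r, lam, T = float("nan"), float("nan"), float("nan")
    ages = np.arange(len(adult_dist), dtype=float)
    mean_preadult = float((ages @ adult_dist) / p_adult) if p_adult > 0 else float("nan")
    return ExpectedParameters(
        R0=R0, r=float(r) if R0 > 0 else float("nan"), lambda_=lam, T=T,
        mean_fecundity_F=mean_fec,
        female_ratio=p_adult * spec.female_prob,
        preadult_survival=p_adult,
        expected_preadult_days=mean_preadult,
        schedule=schedule)


@dataclass
class SyntheticBioassaySpec:
    """Ground truth for a dose-mortality bioassay: binomial kills with
    probability Φ(slope · (log10 dose − log10 LC50)). Defaults follow a
    six-concentration serial-dilution design with six replicate wells of
    five larvae each and 48-h scoring."""

    seed: int
    slope: float = 1.2
    lc50: float = 10.0  # mg/L
    concentrations: tuple[float, ...] = (500.0, 125.0, 50.0, 12.5, 3.125, 0.78125)
    n_per_dose: int = 30
    n_replicates: int = 6
    control_mortality: float | None = None  # include a dose-0 control if set

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.lc50 <= 0:
            raise ValueError("slope and LC50 must be positive")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if self.n_per_dose % self.n_replicates:
            raise ValueError("n_per_dose must divide evenly into replicates")
        if self.control_mortality is not None \
                and not 0.0 <= self.control_mortality < 1.0:
            raise ValueError("control mortality must be in [0, 1)")

    def mortality(self, concentration: float) -> float:
        z = self.slope * (np.log10(concentration) - np.log10(self.lc50))
        return float(stats.norm.cdf(z))


def generate_bioassay(spec: SyntheticBioassaySpec) -> DoseResponseData:
    """Draw replicate-level binomial kill counts at each concentration."""
    rng = np.random.default_rng(spec.seed)
    per_rep = spec.n_per_dose // spec.n_replicates
    rows = []
    for conc in spec.concentrations:
        pi = spec.mortality(conc)
        for rep in range(1, spec.n_replicates + 1):
            dead = int(rng.binomial(per_rep, pi))
            rows.append({"concentration": conc, "n_treated": per_rep,
                         "n_dead": dead, "replicate": rep})
    if spec.control_mortality is not None:
        for rep in range(1, spec.n_replicates + 1):
            dead = int(rng.binomial(per_rep, spec.control_mortality))
            rows.append({"concentration": 0.0, "n_treated": per_rep,
                         "n_dead": dead, "replicate": rep})
    return DoseResponseData(pd.DataFrame(rows))


def _spec_from_yaml(path, cls):
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError(f"{path}: 'seed' is required in a simulation config")
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown fields {sorted(unknown)}")
    if "concentrations" in raw:
        raw["concentrations"] = tuple(raw["concentrations"])
    return cls(**raw)


def cohort_spec_from_yaml(path) -> SyntheticCohortSpec:
    return _spec_from_yaml(path, SyntheticCohortSpec)


def bioassay_spec_from_yaml(path) -> SyntheticBioassaySpec:
    return _spec_from_yaml(path, SyntheticBioassaySpec)
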