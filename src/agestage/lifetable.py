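"""Age-stage, two-sex life table computation.

The framework tracks a cohort in an age × stage matrix, so both sexes and
variable developmental rates are represented. From the daily census
``n_xj`` (individuals alive at age x in stage j) it derives:

* ``s_xj = n_xj / n_01`` — probability a newborn survives to age x, stage j;
* ``l_x = Σ_j s_xj`` — age-specific survival;
* ``f_xj`` — mean eggs per stage-j individual of age x (non-zero only in the
  female-adult stage) and ``m_x = Σ_j s_xj f_xj / Σ_j s_xj`` — the
  population-weighted age-specific fecundity;
* ``e_xj`` — age-stage life expectancy and ``v_xj`` — age-stage reproductive
  value, both built on the empirical age-stage transition fractions;
* the population parameters: net reproductive rate ``R0 = Σ l_x m_x``,
  intrinsic rate of increase ``r`` solving the Euler–Lotka equation
  ``Σ e^{-r(x+1)} l_x m_x = 1``, finite rate ``λ = e^r``, mean generation
  time ``T = ln(R0)/r``, and gross reproductive rate ``GRR = Σ m_x``.

All ages are integer days; sums over age run to the cohort's maximum
observed age (the empirical support of the life table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import FEMALE_ADULT, Cohort, individual_summaries

__all__ = [
    "AgeStageCounts", "SurvivalCurves", "FecundityCurves",
    "ConditionalSurvival", "PopulationParameters",
    "build_counts", "survival_rates", "fecundity_curves",
    "transition_fractions", "conditional_survival",
    "life_expectancy", "reproductive_value",
    "net_reproductive_rate", "solve_intrinsic_rate",
    "intrinsic_rate_from_schedule", "population_parameters",
]

EULER_LOTKA_TOL = 1e-10
R_BRACKET = (-2.0, 2.0)


@dataclass
class AgeStageCounts:
    """Daily census: ``n_xj[x, j]`` individuals alive at age x in stage j."""

    n_xj: np.ndarray  # (max_age+1, n_stages) integer matrix
    n_01: int
    stage_order: tuple[str, ...]


@dataclass
class SurvivalCurves:
    s_xj: np.ndarray
    l_x: np.ndarray
    stage_order: tuple[str, ...]


@dataclass
class FecundityCurves:
    f_xj: np.ndarray   # mean eggs per individual alive in (x, j)
    m_x: np.ndarray    # age-specific fecundity of the population
    lxmx: np.ndarray   # elementwise l_x * m_x
    stage_order: tuple[str, ...]


@dataclass
class ConditionalSurvival:
    """Probability of being alive in (age i, stage y) given alive in the
    origin cell; the origin itself has probability 1."""

    origin: tuple[int, int]  # (age x, stage index j)
    s_prime: np.ndarray      # (max_age+1, n_stages); zero for i < x


@dataclass
class PopulationParameters:
    """Cohort-level demographic parameters plus life-history summary means."""

    R0: float                 # offspring per initial individual
    r: float                  # intrinsic rate of increase, day^-1
    lambda_: float            # finite rate of increase, e^r
    T: float                  # mean generation time, days
    GRR: float                # gross reproductive rate
    mean_fecundity_F: float   # eggs per female adult
    female_ratio: float       # N_f / n_01
    male_female_ratio: float  # N_m / N_f
    summaries: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, float]:
        out = {
            "R0": self.R0, "r": self.r, "lambda": self.lambda_, "T": self.T,
            "GRR": self.GRR, "mean_fecundity_F": self.mean_fecundity_F,
            "female_ratio": self.female_ratio,
            "male_female_ratio": self.male_female_ratio,
        }
        out.update(self.summaries)
        return out


def build_counts(cohort: Cohort) -> AgeStageCounts:
    """Tally daily stage occupancy: an individual counts in exactly one
    stage on each day of ``[0, death_age]``, the new stage on transition days."""
    cohort.require_valid()
    stages = cohort.stage_order
    idx = {s: j for j, s in enumerate(stages)}
    n = np.zeros((cohort.max_age + 1, len(stages)), dtype=np.int64)
    for rec in cohort.individuals:
        entered = sorted(
            ((idx[s], a) for s, a in rec.stage_entry.items()), key=lambda t: t[1])
        for (j, start), nxt in zip(entered, entered[1:] + [(None, rec.death_age + 1)]):
            n[start:nxt[1], j] += 1
    return AgeStageCounts(n_xj=n, n_01=cohort.n_01, stage_order=stages)


def survival_rates(counts: AgeStageCounts) -> SurvivalCurves:
    if counts.n_01 <= 0:
        raise ValueError("empty cohort: n_01 must be positive")
    s = counts.n_xj / counts.n_01
    return SurvivalCurves(s_xj=s, l_x=s.sum(axis=1), stage_order=counts.stage_order)


def _eggs_by_age_stage(cohort: Cohort, shape: tuple[int, int]) -> np.ndarray:
    stages = cohort.stage_order
    idx = {s: j for j, s in enumerate(stages)}
    eggs = np.zeros(shape)
    for rec in cohort.individuals:
        for day, n_eggs in rec.fecundity.items():
            eggs[day, idx[rec.stage_on_day(day, stages)]] += n_eggs
    return eggs


def fecundity_curves(cohort: Cohort, curves: SurvivalCurves,
                     counts: AgeStageCounts | None = None) -> FecundityCurves:
    """Mean eggs per surviving individual per age-stage cell, and the
    population fecundity ``m_x`` (defined as 0 at ages where no one is alive)."""
    if counts is None:
        counts = build_counts(cohort)
    eggs = _eggs_by_age_stage(cohort, counts.n_xj.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_xj = np.where(counts.n_xj > 0, eggs / np.maximum(counts.n_xj, 1), 0.0)
        alive = counts.n_xj.sum(axis=1)
        m_x = np.where(alive > 0, eggs.sum(axis=1) / np.maximum(alive, 1), 0.0)
    return FecundityCurves(f_xj=f_xj, m_x=m_x, lxmx=curves.l_x * m_x,
                           stage_order=curves.stage_order)


def transition_fractions(cohort: Cohort, counts: AgeStageCounts | None = None
                         ) -> np.ndarray:
    """Empirical one-day transition fractions.

    Returns ``P[x, j, y]``: of the individuals alive at age x in stage j, the
    fraction that on day x+1 is alive in stage y (stage-skipping transitions
    allowed; the remainder died). Rows with an empty (x, j) cell are zero.
    """
    if counts is None:
        counts = build_counts(cohort)
    stages = cohort.stage_order
    idx = {s: j for j, s in enumerate(stages)}
    A, B = counts.n_xj.shape
    moves = np.zeros((A, B, B))
    for rec in cohort.individuals:
        entered = sorted(
            ((idx[s], a) for s, a in rec.stage_entry.items()), key=lambda t: t[1])
        stage_of_day = np.empty(rec.death_age + 1, dtype=np.int64)
        for (j, start), nxt in zip(entered, entered[1:] + [(None, rec.death_age + 1)]):
            stage_of_day[start:nxt[1]] = j
        for x in range(rec.death_age):
            moves[x, stage_of_day[x], stage_of_day[x + 1]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = counts.n_xj[:, :, None].astype(float)
        frac = np.where(denom > 0, moves / np.maximum(denom, 1.0), 0.0)
    return frac


def conditional_survival(counts: AgeStageCounts, cohort: Cohort,
                         origin: tuple[int, int],
                         frac: np.ndarray | None = None) -> ConditionalSurvival:
    """Forward-propagate survival probabilities from an origin cell using the
    empirical transition fractions. From origin (0, egg) this reproduces the
    marginal ``s_xj`` exactly."""
    x0, j0 = origin
    if counts.n_xj[x0, j0] <= 0:
        raise ValueError(f"origin cell (age {x0}, stage {j0}) is empty")
    if frac is None:
        frac = transition_fractions(cohort, counts)
    A, B = counts.n_xj.shape
    sp = np.zeros((A, B))
    sp[x0, j0] = 1.0
    for i in range(x0, A - 1):
        sp[i + 1] = sp[i] @ frac[i]
    return ConditionalSurvival(origin=(x0, j0), s_prime=sp)


def life_expectancy(cohort: Cohort, counts: AgeStageCounts | None = None,
                    frac: np.ndarray | None = None) -> np.ndarray:
    """Age-stage life expectancy ``e_xj``: expected remaining days of life of
    an individual alive at age x in stage j, the current day included.

    Computed by backward recursion over the empirical transition fractions,
    ``e_xj = 1 + Σ_y P[x, j, y] · e_{x+1, y}`` — identical to summing the
    forward-propagated conditional survival over all later cells. NaN for
    empty cells.
    """
    if counts is None:
        counts = build_counts(cohort)
    if frac is None:
        frac = transition_fractions(cohort, counts)
    A, B = counts.n_xj.shape
    e = np.zeros((A, B))
    e[A - 1] = np.where(counts.n_xj[A - 1] > 0, 1.0, 0.0)
    for x in range(A - 2, -1, -1):
        e[x] = 1.0 + frac[x] @ e[x + 1]
    return np.where(counts.n_xj > 0, e, np.nan)


def net_reproductive_rate(fec: FecundityCurves) -> float:
    """``R0 = Σ_x l_x m_x`` — expected offspring per initial individual."""
    return float(fec.lxmx.sum())


def _euler_lotka(r: float, lxmx: np.ndarray, ages: np.ndarray) -> float:
    return float(np.exp(-r * (ages + 1.0)) @ lxmx - 1.0)


def solve_intrinsic_rate(fec: FecundityCurves, tol: float = EULER_LOTKA_TOL,
                         bracket: tuple[float, float] = R_BRACKET) -> float:
    """Solve ``Σ_x e^{-r(x+1)} l_x m_x = 1`` for the intrinsic rate r.

    The left side is strictly decreasing in r, so the root is unique. Raises
    if the cohort produced no offspring (R0 = 0: no solution exists).
    """
    return intrinsic_rate_from_schedule(fec.lxmx, tol=tol, bracket=bracket)


def intrinsic_rate_from_schedule(lxmx: np.ndarray, tol: float = EULER_LOTKA_TOL,
                                 bracket: tuple[float, float] = R_BRACKET) -> float:
    """Euler–Lotka root for an arbitrary net-maternity schedule l_x·m_x
    indexed by age x = 0, 1, 2, ...."""
    lxmx = np.asarray(lxmx, dtype=float)
    R0 = lxmx.sum()
    if R0 <= 0:
        raise ValueError("R0 = 0: the Euler-Lotka equation has no root")
    ages = np.arange(len(lxmx), dtype=float)
    if abs(R0 - 1.0) < 1e-15:
        return 0.0
    lo, hi = bracket
    r = brentq(_euler_lotka, lo, hi, args=(lxmx, ages), xtol=tol, rtol=8.9e-16)
    # a Newton polish: the bracketed root is already near machine precision
    resid = _euler_lotka(r, lxmx, ages)
    deriv = float(-(ages + 1.0) * np.exp(-r * (ages + 1.0)) @ lxmx)
    if deriv != 0.0:
        r -= resid / deriv
    return float(r)


def reproductive_value(cohort: Cohort, fec: FecundityCurves, r: float,
                       counts: AgeStageCounts | None = None,
                       frac: np.ndarray | None = None) -> np.ndarray:
    """Age-stage reproductive value ``v_xj``: the expected contribution of an
    individual alive at (x, j) to future population growth,

        v_xj = e^{r(x+1)} Σ_{i≥x} e^{-r(i+1)} Σ_y s'_iy f_iy,

    with s' the survival probabilities conditional on being alive at (x, j).
    Evaluated by backward recursion; v(0, egg) equals λ by the Euler–Lotka
    identity. NaN for empty cells, 0 where no future reproduction is reachable.
    """
    if counts is None:
        counts = build_counts(cohort)
    if frac is None:
        frac = transition_fractions(cohort, counts)
    A, B = counts.n_xj.shape
    w = np.zeros((A, B))
    w[A - 1] = np.exp(-r * A) * fec.f_xj[A - 1]
    for x in range(A - 2, -1, -1):
        w[x] = np.exp(-r * (x + 1.0)) * fec.f_xj[x] + frac[x] @ w[x + 1]
    ages = np.arange(A, dtype=float)[:, None]
    v = np.exp(r * (ages + 1.0)) * w
    return np.where(counts.n_xj > 0, v, np.nan)


def population_parameters(cohort: Cohort,
                          curves: SurvivalCurves | None = None,
                          fec: FecundityCurves | None = None) -> PopulationParameters:
    """All population parameters plus cohort life-history summary means.

    By construction λ = e^r, T = ln(R0)/r, and the two-sex identity
    R0 = (mean eggs per female) × (N_f / n_01) holds exactly.
    """
    counts = build_counts(cohort)
    if curves is None:
        curves = survival_rates(counts)
    if fec is None:
        fec = fecundity_curves(cohort, curves, counts)
    R0 = net_reproductive_rate(fec)
    n_f = len(cohort.females())
    n_m = len(cohort.males())
    total_eggs = sum(rec.total_fecundity() for rec in cohort.individuals)
    if R0 > 0:
        r = solve_intrinsic_rate(fec)
        lam = float(np.exp(r))
        T = float(np.log(R0) / r) if r != 0.0 else float("nan")
    else:
        r = float("nan")
        lam = float("nan")
        T = float("nan")
    summ = individual_summaries(cohort)
    summary_means = {
        col: float(summ[col].mean())
        for col in summ.columns if col != "sex"
    }
    return PopulationParameters(
        R0=R0,
        r=r,
        lambda_=lam,
        T=T,
        GRR=float(fec.m_x.sum()),
        mean_fecundity_F=(total_eggs / n_f) if n_f else float("nan"),
        female_ratio=n_f / cohort.n_01,
        male_female_ratio=(n_m / n_f) if n_f else float("nan"),
        summaries=summary_means,
    )


def curves_long_format(counts: AgeStageCounts, curves: SurvivalCurves,
                       fec: FecundityCurves, e_xj: np.ndarray | None = None,
                       v_xj: np.ndarray | None = None) -> dict[str, pd.DataFrame]:
    """Tidy long-format tables (age, stage, value) for each matrix, plus the
    age-indexed vectors, ready for CSV export and plotting."""
    stages = list(curves.stage_order)
    ages = np.arange(counts.n_xj.shape[0])

    def melt(mat: np.ndarray, name: str) -> pd.DataFrame:
        df = pd.DataFrame(mat, columns=stages)
        df.insert(0, "age", ages)
        long = df.melt(id_vars="age", var_name="stage", value_name=name)
        return long.dropna(subset=[name]).reset_index(drop=True)

    out = {
        "s_xj": melt(curves.s_xj, "s_xj"),
        "f_xj": melt(fec.f_xj, "f_xj"),
        "age_vectors": pd.DataFrame({
            "age": ages, "l_x": curves.l_x, "m_x": fec.m_x, "lxmx": fec.lxmx}),
    }
    if e_xj is not None:
        out["e_xj"] = melt(e_xj, "e_xj")
    if v_xj is not None:
        out["v_xj"] = melt(v_xj, "v_xj")
    return out
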