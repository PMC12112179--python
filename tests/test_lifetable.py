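"""Age-stage life table: census, survival, fecundity, expectancy,
reproductive value and population parameters, checked against hand
computations and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agestage.cohort import Cohort, IndividualRecord, individual_summaries
from agestage.lifetable import (
    build_counts,
    conditional_survival,
    fecundity_curves,
    intrinsic_rate_from_schedule,
    life_expectancy,
    net_reproductive_rate,
    population_parameters,
    reproductive_value,
    solve_intrinsic_rate,
    survival_rates,
    transition_fractions,
)
from agestage.simulate import SyntheticCohortSpec, generate_cohort

FA = 6  # column index of female_adult in the default stage order


def pipeline(cohort):
    counts = build_counts(cohort)
    curves = survival_rates(counts)
    fec = fecundity_curves(cohort, curves, counts)
    return counts, curves, fec


# ---------------------------------------------------------------- census


def test_toy_census_row_sums(toy_cohort):
    counts = build_counts(toy_cohort)
    alive = counts.n_xj.sum(axis=1)
    assert alive[0] == 4
    assert alive[7] == 2
    assert alive[31] == 1


def test_single_egg_dying_day_zero():
    cohort = Cohort(individuals=[
        IndividualRecord("x", "u", {"egg": 0}, death_age=0)])
    counts = build_counts(cohort)
    assert counts.n_xj.shape == (1, 8)
    assert counts.n_xj[0, 0] == 1 and counts.n_xj.sum() == 1


def test_census_total_equals_sum_of_lifespans(synthetic_cohort):
    counts = build_counts(synthetic_cohort)
    lifespans = sum(r.lifespan for r in synthetic_cohort.individuals)
    assert counts.n_xj.sum() == lifespans


# ------------------------------------------------------------- survival


def test_toy_survival_values(toy_cohort):
    curves = survival_rates(build_counts(toy_cohort))
    assert curves.s_xj[0, 0] == 1.0
    assert curves.l_x[0] == 1.0
    assert curves.l_x[7] == 0.5
    assert curves.l_x[31] == 0.25


@given(seed=st.integers(0, 10_000))
@settings(max_examples=20, deadline=None)
def test_lx_non_increasing_and_bounded(seed):
    cohort = generate_cohort(SyntheticCohortSpec(seed=seed, n_01=40))
    curves = survival_rates(build_counts(cohort))
    assert np.all(np.diff(curves.l_x) <= 1e-12)
    assert np.all((curves.s_xj >= 0) & (curves.s_xj <= 1))


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        survival_rates(build_counts(Cohort(individuals=[])))


# ------------------------------------------------------------ fecundity


def test_toy_fecundity_and_net_maternity(toy_cohort):
    counts, curves, fec = pipeline(toy_cohort)
    assert fec.f_xj[25, FA] == 3.0          # 3 eggs, one female in the cell
    assert fec.m_x[25] == pytest.approx(1.5)  # 3 eggs over 2 alive
    assert fec.lxmx[25] == pytest.approx(0.75)
    assert net_reproductive_rate(fec) == pytest.approx(6 / 4)


def test_all_male_cohort_has_zero_fecundity(toy_cohort):
    males = Cohort(individuals=[toy_cohort.individuals[2]])
    _, _, fec = pipeline(males)
    assert np.all(fec.m_x == 0)
    assert net_reproductive_rate(fec) == 0.0


def test_net_maternity_sums_to_egg_total(synthetic_cohort):
    _, _, fec = pipeline(synthetic_cohort)
    eggs = sum(r.total_fecundity() for r in synthetic_cohort.individuals)
    assert fec.lxmx.sum() == pytest.approx(eggs / synthetic_cohort.n_01, rel=1e-12)


# -------------------------------------------- conditional survival and e_xj


def test_markov_propagation_reproduces_marginals(small_cohort):
    counts = build_counts(small_cohort)
    curves = survival_rates(counts)
    cond = conditional_survival(counts, small_cohort, origin=(0, 0))
    np.testing.assert_allclose(cond.s_prime, curves.s_xj, atol=1e-12)


def test_conditional_survival_from_last_day(small_cohort):
    counts = build_counts(small_cohort)
    last = counts.n_xj.shape[0] - 1
    j = int(np.flatnonzero(counts.n_xj[last])[0])
    cond = conditional_survival(counts, small_cohort, origin=(last, j))
    assert cond.s_prime[last, j] == 1.0
    assert cond.s_prime.sum() == 1.0


def test_conditional_row_sums_non_increasing(small_cohort):
    counts = build_counts(small_cohort)
    frac = transition_fractions(small_cohort, counts)
    x, j = 5, int(np.flatnonzero(counts.n_xj[5])[0])
    cond = conditional_survival(counts, small_cohort, (x, j), frac)
    rows = cond.s_prime[x:].sum(axis=1)
    assert np.all(np.diff(rows) <= 1e-12)


def test_empty_origin_rejected(toy_cohort):
    counts = build_counts(toy_cohort)
    with pytest.raises(ValueError):
        conditional_survival(counts, toy_cohort, origin=(0, FA))


def test_life_expectancy_counts_current_day():
    cohort = Cohort(individuals=[
        IndividualRecord("a", "u", {"egg": 0}, death_age=0),
        IndividualRecord("b", "u", {"egg": 0}, death_age=0)])
    e = life_expectancy(cohort)
    assert e[0, 0] == 1.0


def test_life_expectancy_two_lifespans():
    cohort = Cohort(individuals=[
        IndividualRecord("a", "u", {"egg": 0}, death_age=0),   # 1 day
        IndividualRecord("b", "u", {"egg": 0}, death_age=2)])  # 3 days
    e = life_expectancy(cohort)
    assert e[0, 0] == pytest.approx(2.0)


def test_e00_equals_mean_lifespan(synthetic_cohort):
    e = life_expectancy(synthetic_cohort)
    mean_lifespan = np.mean([r.lifespan for r in synthetic_cohort.individuals])
    assert e[0, 0] == pytest.approx(mean_lifespan, rel=1e-12)


def test_backward_recursion_matches_forward_definition(small_cohort):
    """e_xj must equal the double sum of forward-propagated conditional
    survival over all later ages and stages (the defining formula)."""
    counts = build_counts(small_cohort)
    frac = transition_fractions(small_cohort, counts)
    e = life_expectancy(small_cohort, counts, frac)
    rng = np.random.default_rng(0)
    cells = np.argwhere(counts.n_xj > 0)
    for x, j in cells[rng.choice(len(cells), size=8, replace=False)]:
        cond = conditional_survival(counts, small_cohort, (x, j), frac)
        assert e[x, j] == pytest.approx(cond.s_prime.sum(), rel=1e-10)


# -------------------------------------------------- intrinsic rate and v_xj


def test_point_reproduction_at_replacement_gives_zero_rate():
    lxmx = np.zeros(9)
    lxmx[6] = 1.0
    assert intrinsic_rate_from_schedule(lxmx) == 0.0


def test_point_reproduction_closed_form():
    lxmx = np.zeros(5)
    lxmx[4] = 2.0
    r = intrinsic_rate_from_schedule(lxmx)
    assert r == pytest.approx(np.log(2) / 5, rel=1e-10)
    assert np.log(2.0) / r == pytest.approx(5.0, rel=1e-10)


def test_no_offspring_has_no_rate():
    with pytest.raises(ValueError):
        intrinsic_rate_from_schedule(np.zeros(4))


def test_euler_lotka_residual_below_tolerance(synthetic_cohort):
    _, _, fec = pipeline(synthetic_cohort)
    r = solve_intrinsic_rate(fec)
    ages = np.arange(len(fec.lxmx))
    residual = np.exp(-r * (ages + 1)) @ fec.lxmx - 1.0
    assert abs(residual) < 1e-8


def test_reproductive_value_at_origin_equals_lambda(synthetic_cohort):
    _, curves, fec = pipeline(synthetic_cohort)
    r = solve_intrinsic_rate(fec)
    v = reproductive_value(synthetic_cohort, fec, r)
    assert v[0, 0] == pytest.approx(np.exp(r), abs=1e-8)


def test_reproductive_value_zero_after_last_oviposition(synthetic_cohort):
    counts, curves, fec = pipeline(synthetic_cohort)
    r = solve_intrinsic_rate(fec)
    v = reproductive_value(synthetic_cohort, fec, r)
    last_egg_age = max(d for rec in synthetic_cohort.individuals
                       for d in rec.fecundity)
    tail = v[last_egg_age + 1:]
    assert np.nansum(np.abs(tail)) == 0.0


def test_toy_reproductive_value_matches_hand_evaluation(toy_cohort):
    """v(25, female_adult): single female alive through day 35, laying on
    days 25-27; evaluate the defining sum explicitly."""
    counts, curves, fec = pipeline(toy_cohort)
    r = solve_intrinsic_rate(fec)
    v = reproductive_value(toy_cohort, fec, r)
    hand = np.exp(r * 26) * sum(
        np.exp(-r * (i + 1)) * eggs
        for i, eggs in [(25, 3.0), (26, 2.0), (27, 1.0)])
    assert v[25, FA] == pytest.approx(hand, rel=1e-10)


# ------------------------------------------------- population parameters


def test_population_parameter_identities(synthetic_cohort):
    p = population_parameters(synthetic_cohort)
    assert p.lambda_ == pytest.approx(np.exp(p.r), rel=1e-14)
    assert p.T == pytest.approx(np.log(p.R0) / p.r, rel=1e-14)
    assert p.R0 == pytest.approx(
        p.mean_fecundity_F * p.female_ratio, rel=1e-12)
    assert p.GRR >= p.R0
    summ = individual_summaries(synthetic_cohort)
    assert p.summaries["preadult"] == pytest.approx(summ["preadult"].mean())


def test_toy_population_parameters(toy_cohort):
    p = population_parameters(toy_cohort)
    assert p.R0 == pytest.approx(1.5)
    assert p.mean_fecundity_F == 6.0
    assert p.female_ratio == 0.25
    assert p.male_female_ratio == 1.0


def test_no_female_cohort_parameters(toy_cohort):
    males = Cohort(individuals=toy_cohort.individuals[:3])
    p = population_parameters(males)
    assert p.R0 == 0.0
    assert np.isnan(p.r) and np.isnan(p.T)
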