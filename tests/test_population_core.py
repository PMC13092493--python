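"""Demographic engine: initialization, the six cycle steps, conservation,
equilibrium, and determinism."""

import numpy as np
import pytest
from scipy import stats

from lastmile import genetics
from lastmile.interface_io import make_fixture_island
from lastmile.interventions import ControlProgram
from lastmile.population_core import (
    SEX_F,
    SEX_M,
    IslandState,
    LifeHistoryParams,
    _matings_arrays,
    _movement_prob,
    adult_survival,
    breeding_dispersal,
    burn_in,
    form_matings,
    init_island,
    mate_search,
    natal_dispersal,
    reproduce,
    step_cycle,
)

from conftest import add_individuals, make_state


def chebyshev(p, q, cols):
    return max(abs(p // cols - q // cols), abs(p % cols - q % cols))


# ---------------------------------------------------------------------------
# initialization


def test_init_island_counts_and_bounds():
    params = LifeHistoryParams()
    empty = init_island(params, founders=0, seed=1)
    assert empty.census() == 0

    state = init_island(params, founders=500, seed=1)
    assert state.census() == 500
    assert state.n_patches == 256 and state.dims == (16, 16)
    assert np.all((state.patch >= 0) & (state.patch < 256))
    assert np.all(state.age >= params.maturity_cycles)
    assert np.all(state.geno == genetics.WT)
    # 1:1 sex draw
    frac_f = np.mean(state.sex == SEX_F)
    assert abs(frac_f - 0.5) < 3 * np.sqrt(0.25 / 500)

    with pytest.raises(ValueError):
        init_island(params, dims=(0, 16), founders=10, seed=1)
    with pytest.raises(ValueError):
        init_island(params, founders=-1, seed=1)


# ---------------------------------------------------------------------------
# step 1: mate search


def test_mate_search_zero_radius_is_static(big_K_params):
    from dataclasses import replace

    params = replace(big_K_params, D=0)
    state = make_state()
    add_individuals(state, 50, sex=SEX_M, patch=100)
    before = state.patch.copy()
    mate_search(state, params)
    assert np.array_equal(state.patch, before)


def test_released_male_relocates_within_distance():
    params = LifeHistoryParams(D=1)
    cols = 16
    site = 8 * cols + 8
    for seed in range(200):
        state = make_state(seed=seed)
        add_individuals(state, 1, sex=SEX_M, patch=site, geno=genetics.GL, fresh=True)
        mate_search(state, params)
        assert chebyshev(int(state.patch[0]), site, cols) <= 1
        assert not state.fresh[0]


def test_lone_adult_moves_at_m_max():
    """A lone adult sees zero conspecific density, so it relocates with
    probability m_max; its destination is uniform over the 9-patch
    neighborhood, so P(stay) = (1 - m_max) + m_max/9 (binomial oracle)."""
    params = LifeHistoryParams(D=1, m_min=0.1, m_max=0.9)
    center = 8 * 16 + 8
    n = 10_000
    stays = 0
    state = make_state(seed=0)
    add_individuals(state, 1, sex=SEX_F, patch=center)
    for i in range(n):
        state.patch[0] = center
        state.rng = np.random.default_rng(i)
        mate_search(state, params)
        stays += int(state.patch[0]) == center
    p_stay = (1 - params.m_max) + params.m_max / 9
    se = np.sqrt(p_stay * (1 - p_stay) / n)
    assert abs(stays / n - p_stay) < 3 * se


# ---------------------------------------------------------------------------
# step 2: mating


def test_no_males_no_matings(big_K_params):
    state = make_state()
    add_individuals(state, 1, sex=SEX_F, patch=10)
    assert form_matings(state, big_K_params) == []


def test_no_mating_bias_against_transgenic_males():
    """1 female with 3 co-located males (1 transgenic): the transgenic male
    is chosen with frequency 1/3 (uniform-choice oracle)."""
    from dataclasses import replace

    params = replace(LifeHistoryParams(K=1e9), p_r=1.0, p_m=0.0)
    state = make_state()
    add_individuals(state, 1, sex=SEX_F, patch=7)
    add_individuals(state, 2, sex=SEX_M, patch=7, geno=genetics.WT)
    tg = add_individuals(state, 1, sex=SEX_M, patch=7, geno=genetics.GL)[0]
    n = 10_000
    hits = 0
    for i in range(n):
        state.rng = np.random.default_rng(i)
        (rec,) = form_matings(state, params)
        hits += rec.mates[0] == tg
    se = np.sqrt((1 / 3) * (2 / 3) / n)
    assert abs(hits / n - 1 / 3) < 3 * se


def test_mating_probability_p_r():
    from dataclasses import replace

    params = replace(LifeHistoryParams(K=1e9), p_r=0.8, p_m=0.0)
    state = make_state()
    n = 10_000
    add_individuals(state, n, sex=SEX_F, patch=12)
    add_individuals(state, 50, sex=SEX_M, patch=12)
    dams, _, _ = _matings_arrays(state, params, np.random.default_rng(3))
    se = np.sqrt(0.8 * 0.2 / n)
    assert abs(dams.size / n - 0.8) < 3 * se


def test_polyandry_yields_two_distinct_mates():
    from dataclasses import replace

    params = replace(LifeHistoryParams(K=1e9), p_r=1.0, p_m=1.0)
    state = make_state()
    add_individuals(state, 1, sex=SEX_F, patch=3)
    add_individuals(state, 5, sex=SEX_M, patch=3)
    for i in range(50):
        state.rng = np.random.default_rng(i)
        (rec,) = form_matings(state, params)
        assert len(rec.mates) == 2 and rec.mates[0] != rec.mates[1]


def test_sterile_individuals_excluded_from_mating(big_K_params):
    state = make_state()
    add_individuals(state, 1, sex=SEX_F, patch=5, sterile=True)
    add_individuals(state, 3, sex=SEX_M, patch=5)
    assert form_matings(state, big_K_params) == []


# ---------------------------------------------------------------------------
# step 3: reproduction


def test_density_ceiling_stops_reproduction():
    params = LifeHistoryParams(K=20.0)
    state = make_state()
    add_individuals(state, 25, sex=SEX_F, patch=9)
    add_individuals(state, 5, sex=SEX_M, patch=9)
    matings = form_matings(state, params)
    offspring, dead = reproduce(state, matings, params)
    assert offspring == [] and dead == []


def test_litter_distribution_is_poisson(big_K_params):
    """At negligible density the realized litter of one WT x WT mating is
    Poisson with mean litter_mean (chi-square against the closed-form pmf)."""
    from dataclasses import replace

    params = replace(big_K_params, p_r=1.0, p_m=0.0)
    counts = []
    for i in range(3000):
        state = make_state(seed=i)
        add_individuals(state, 1, sex=SEX_F, patch=30)
        add_individuals(state, 1, sex=SEX_M, patch=30)
        matings = form_matings(state, params)
        offspring, _ = reproduce(state, matings, params)
        counts.append(len(offspring))
    counts = np.array(counts)
    lam = params.litter_mean  # density term is ~0 at K = 1e9
    edges = list(range(0, 14))
    observed = np.array([(counts == k).sum() for k in edges] + [(counts >= 14).sum()])
    pmf = np.array([stats.poisson.pmf(k, lam) for k in edges])
    expected = np.append(pmf, 1 - pmf.sum()) * counts.size
    chi2 = ((observed - expected) ** 2 / expected).sum()
    assert chi2 < stats.chi2.ppf(0.999, df=len(expected) - 1)


def test_fertility_declines_with_density():
    """Mean per-mating recruitment at half capacity exceeds recruitment
    near capacity (density-dependent fertility)."""
    params = LifeHistoryParams(K=40.0, p_r=1.0, p_m=0.0)

    def mean_offspring(occupancy):
        total = 0
        for i in range(300):
            state = make_state(seed=i)
            add_individuals(state, occupancy - 2, sex=SEX_F, patch=50, age=0)
            add_individuals(state, 1, sex=SEX_F, patch=50)
            add_individuals(state, 1, sex=SEX_M, patch=50)
            matings = form_matings(state, params)
            offspring, _ = reproduce(state, matings, params)
            total += len(offspring)
        return total / 300

    assert mean_offspring(20) > mean_offspring(36)


def test_monotone_density_response():
    """Mean per-female recruitment is non-increasing in local density over
    a 0..2K grid (allowing sampling noise via a fitted slope)."""
    params = LifeHistoryParams(K=30.0, p_r=1.0, p_m=0.0)
    densities = [2, 8, 15, 22, 29, 36, 50, 60]
    means = []
    for occ in densities:
        total = 0
        reps = 150
        for i in range(reps):
            state = make_state(seed=1000 + i)
            add_individuals(state, occ - 2, sex=SEX_F, patch=8, age=0)
            add_individuals(state, 1, sex=SEX_F, patch=8)
            add_individuals(state, 1, sex=SEX_M, patch=8)
            offspring, _ = reproduce(state, form_matings(state, params), params)
            total += len(offspring)
        means.append(total / reps)
    diffs = np.diff(means)
    assert np.all(diffs <= 0.5)  # non-increasing up to sampling noise
    assert means[0] > means[-1]


# ---------------------------------------------------------------------------
# step 4: natal dispersal


def test_natal_dispersal_corner_uniform():
    """A newborn at the corner with D = 1 lands uniformly on the 4
    in-bounds patches (boundary-truncated uniform oracle)."""
    params = LifeHistoryParams(D=1)
    state = make_state(seed=5)
    n = 10_000
    add_individuals(state, n, sex=SEX_F, patch=0, age=0)
    natal_dispersal(state, params)
    dests = [0, 1, 16, 17]
    counts = np.array([(state.patch == d).sum() for d in dests])
    assert counts.sum() == n
    se = np.sqrt(0.25 * 0.75 / n)
    assert np.all(np.abs(counts / n - 0.25) < 3 * se)


def test_natal_dispersal_distance_bound():
    from dataclasses import replace

    params = replace(LifeHistoryParams(), D=3)
    state = make_state(seed=2)
    origin = 7 * 16 + 7
    add_individuals(state, 2000, sex=SEX_M, patch=origin, age=0)
    natal_dispersal(state, params)
    assert max(chebyshev(int(p), origin, 16) for p in state.patch) <= 3

    params0 = replace(params, D=0)
    state = make_state(seed=2)
    add_individuals(state, 100, sex=SEX_M, patch=origin, age=0)
    natal_dispersal(state, params0)
    assert np.all(state.patch == origin)


# ---------------------------------------------------------------------------
# step 5: survival


def test_survival_modifier_zero_kills_everyone():
    state = make_state(seed=1)
    add_individuals(state, 300, sex=SEX_F, patch=4, age=3)
    add_individuals(state, 100, sex=SEX_M, patch=4, age=0)
    deaths = adult_survival(state, LifeHistoryParams(), modifier=0.0)
    assert deaths == 400 and state.n == 0


def test_survival_fraction_matches_binomial():
    from dataclasses import replace

    params = replace(LifeHistoryParams(), s=0.75)
    state = make_state(seed=9)
    n = 10_000
    add_individuals(state, n, sex=SEX_M, patch=0, age=2)
    adult_survival(state, params, modifier=1.0)
    se = np.sqrt(0.75 * 0.25 / n)
    assert abs(state.n / n - 0.75) < 3 * se


def test_newborns_insulated_from_background_mortality():
    state = make_state(seed=9)
    add_individuals(state, 5000, sex=SEX_M, patch=0, age=0)
    adult_survival(state, LifeHistoryParams(), modifier=1.0)
    assert state.n == 5000


def test_invalid_modifier_rejected():
    state = make_state()
    with pytest.raises(ValueError):
        adult_survival(state, LifeHistoryParams(), modifier=1.5)


# ---------------------------------------------------------------------------
# step 6: breeding dispersal


def test_movement_probability_density_rule():
    params = LifeHistoryParams(K=30.0, m_min=0.1, m_max=0.9)
    # at or above carrying capacity: p_move = m_min
    state = make_state()
    add_individuals(state, 40, sex=SEX_F, patch=11)
    assert np.allclose(_movement_prob(state, params), params.m_min)
    # non-increasing in density over 0..2K
    probs = []
    for occ in range(1, 61, 6):
        st = make_state()
        add_individuals(st, occ, sex=SEX_F, patch=11)
        probs.append(_movement_prob(st, params)[0])
    assert np.all(np.diff(probs) <= 1e-12)
    # lone adult: p_move = m_max
    st = make_state()
    add_individuals(st, 1, sex=SEX_F, patch=11)
    assert np.isclose(_movement_prob(st, params)[0], params.m_max)


def test_breeding_dispersal_moves_within_distance():
    params = LifeHistoryParams(D=1)
    state = make_state(seed=3)
    origin = 5 * 16 + 5
    add_individuals(state, 500, sex=SEX_F, patch=origin, age=1)
    breeding_dispersal(state, params)
    assert max(chebyshev(int(p), origin, 16) for p in state.patch) <= 1


# ---------------------------------------------------------------------------
# full cycles


def test_empty_island_stays_empty():
    params = LifeHistoryParams()
    state = init_island(params, founders=0, seed=4)
    _, log = step_cycle(state, params)
    assert log.n_end == 0 and log.births == 0 and log.deaths_total == 0


def test_conservation_identity_over_full_scenario():
    """N(t+1) = N(t) + births - deaths + releases, exactly, every cycle of
    a complete mini-island control scenario."""
    cfg = make_fixture_island("mini", seed=11)
    params = cfg.life_history
    state = init_island(
        params, dims=(cfg.island.rows, cfg.island.cols),
        founders=cfg.island.founders, seed=cfg.seed,
    )
    program = ControlProgram(cfg.toxicant, cfg.release, state.dims)
    for _ in range(90):
        step_cycle(state, params, program)
    assert len(state.log) == 90
    for log in state.log:
        assert log.n_end == log.n_start + log.births - log.deaths_total + log.released
    assert state.log[0].n_start == cfg.island.founders
    for prev, cur in zip(state.log, state.log[1:]):
        assert cur.n_start == prev.n_end


def test_six_cycles_advance_one_year():
    params = LifeHistoryParams()
    state = init_island(params, founders=50, seed=0)
    for _ in range(6):
        _, log = step_cycle(state, params)
    assert state.cycle == 6
    assert log.year == pytest.approx(5 / 6)
    _, log = step_cycle(state, params)
    assert log.year == pytest.approx(1.0)


def test_spatial_containment_through_scenario():
    cfg = make_fixture_island("mini", seed=3)
    params = cfg.life_history
    state = init_island(params, dims=(8, 8), founders=250, seed=3)
    program = ControlProgram(cfg.toxicant, cfg.release, state.dims)
    for _ in range(80):
        step_cycle(state, params, program)
        if state.n:
            assert state.patch.min() >= 0 and state.patch.max() < 64


def test_burn_in_equilibrium_and_cap():
    """Burn-in reaches a stable census below the hard demographic cap
    implied by density-dependent fertility, with modest spread."""
    cfg = make_fixture_island("mini")
    params = cfg.life_history
    totals = []
    for seed in range(20):
        state = init_island(params, dims=(8, 8), founders=250, seed=100 + seed)
        burn_in(state, params, years=8)
        cap = 64 * params.K * (1 + params.litter_mean)
        assert all(log.n_end <= cap for log in state.log)
        totals.append(state.n)
    totals = np.array(totals)
    assert totals.std() / totals.mean() < 0.15

    state = init_island(params, dims=(8, 8), founders=100, seed=0)
    burn_in(state, params, years=0)
    assert state.cycle == 0 and state.n == 100


def test_determinism_bit_identical_logs():
    cfg = make_fixture_island("mini", seed=21)

    def run():
        params = cfg.life_history
        state = init_island(params, dims=(8, 8), founders=250, seed=cfg.seed)
        program = ControlProgram(cfg.toxicant, cfg.release, state.dims)
        for _ in range(70):
            step_cycle(state, params, program)
        return [log.as_row() for log in state.log]

    assert run() == run()
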