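"""Effort-cube experiment, outcome summaries, calibration, sensitivity.

The release-effort design is a 3 x 2 x 3 factorial "cube": number of
release sites ``n_p`` in {16, 36, 64}, number of release events ``n_i`` in
{6, 12}, and males per selected site per event ``N_i`` in {10, 15, 20} -
18 combinations, indexed 1..18 by

    index = 6 * (N_i level - 1) + 2 * (n_p level - 1) + n_i level.

Each combination is run under three release strategies and three genetic
strategies, pooled over a 24-member set of life-history variants
(D in {1, 3}, c_s in {0.15, 0.2}, p_r in {0.6, 0.8}, p_m in {0, 0.5, 0.8});
18 x 3 x 24 = 1296 parameter combinations, and at 30 replicates each per
genetic strategy the full design is 116,640 simulations.

A replicate runs burn-in (8 years), the 1-year toxicant window, releases,
and continues to the 200-cycle horizon.  Replicates whose post-toxicant
census is zero are excluded and redrawn - the question is what biocontrol
adds when the toxicant alone fails.  Eradication means zero individuals of
ANY genotype (wild-type and transgenic alike); the wild-type extinction
time is also logged.  Times are measured in years from the first scheduled
release event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genetics import Strategy
from .interventions import (
    RELEASE_STRATEGIES,
    ControlProgram,
    ReleasePlan,
    ToxicantPlan,
)
from .interface_io import RunConfig, default_config
from .population_core import IslandState, LifeHistoryParams, init_island, step_cycle

__all__ = [
    "EffortCombo",
    "RunOutcome",
    "Summary",
    "N_P_LEVELS",
    "N_I_LEVELS",
    "NI_PER_SITE_LEVELS",
    "enumerate_effort_cube",
    "decode_effort_index",
    "encode_effort_index",
    "life_history_variants",
    "full_design",
    "run_scenario",
    "run_experiment",
    "run_effort_cell",
    "summarize",
    "outcomes_frame",
    "calibrate_K",
    "sensitivity_analysis",
]

N_P_LEVELS = (16, 36, 64)
N_I_LEVELS = (6, 12)
NI_PER_SITE_LEVELS = (10, 15, 20)  # middle per-site level is config-exposed

VARIANT_D = (1, 3)
VARIANT_CS = (0.15, 0.2)
VARIANT_PR = (0.6, 0.8)
VARIANT_PM = (0.0, 0.5, 0.8)


@dataclass(frozen=True)
class EffortCombo:
    """One cell of the effort cube."""

    index: int
    n_p: int
    n_i: int
    N_i: int


def decode_effort_index(index: int) -> EffortCombo:
    """Invert the cube indexing: #1 = (16, 6, 10) ... #18 = (64, 12, 20)."""
    if not 1 <= index <= 18:
        raise ValueError(f"effort index must be in 1..18, got {index}")
    z = index - 1
    ni_level = z % 2
    np_level = (z // 2) % 3
    Ni_level = z // 6
    return EffortCombo(
        index=index,
        n_p=N_P_LEVELS[np_level],
        n_i=N_I_LEVELS[ni_level],
        N_i=NI_PER_SITE_LEVELS[Ni_level],
    )


def encode_effort_index(n_p: int, n_i: int, N_i: int) -> int:
    return (
        6 * NI_PER_SITE_LEVELS.index(N_i)
        + 2 * N_P_LEVELS.index(n_p)
        + N_I_LEVELS.index(n_i)
        + 1
    )


def enumerate_effort_cube() -> list[EffortCombo]:
    """All 18 effort combinations, in index order."""
    return [decode_effort_index(i) for i in range(1, 19)]


def life_history_variants() -> list[dict]:
    """The 24 pooled life-history / culling variants (overrides applied on
    top of the default rates)."""
    out = []
    for D, c_s, p_r, p_m in product(VARIANT_D, VARIANT_CS, VARIANT_PR, VARIANT_PM):
        out.append({"D": D, "c_s": c_s, "p_r": p_r, "p_m": p_m})
    return out


def full_design() -> dict:
    """Size of the complete factorial experiment."""
    combos = (
        len(enumerate_effort_cube())
        * len(RELEASE_STRATEGIES)
        * len(life_history_variants())
    )
    genetic = 3  # FSRIDL, Y_EDITOR, GRAVID_LETHAL
    reps = 30
    return {
        "parameter_combinations": combos,
        "genetic_strategies": genetic,
        "replicates_per_combination": reps,
        "total_simulations": combos * genetic * reps,
    }


@dataclass
class RunOutcome:
    """Outcome of one replicate."""

    eradicated: bool
    time_to_eradication: Optional[float]  # years from the first release event
    wt_extinction_time: Optional[float]
    post_toxicant_census: int
    total_released: int
    final_census: int
    seed: int
    config_id: str
    census_series: Optional[list[int]] = None


@dataclass(frozen=True)
class Summary:
    """Pooled summary of a set of replicates."""

    n: int
    eradication_probability: float
    median_time_years: Optional[float]
    median_total_released: Optional[float]


def run_scenario(cfg: RunConfig, seed: Optional[int] = None, keep_series: bool = False) -> RunOutcome:
    """Execute one full replicate of the configured scenario.

    Runs to the configured horizon, with an early exit once the island is
    empty and no future release event could restock it.  The eradication
    clock starts at the first scheduled release event.
    """
    seed = cfg.seed if seed is None else seed
    params = cfg.life_history
    state = init_island(
        params,
        dims=(cfg.island.rows, cfg.island.cols),
        founders=cfg.island.founders,
        seed=seed,
    )
    program = ControlProgram(cfg.toxicant, cfg.release, state.dims)
    release_start = cfg.release.start_cycle if cfg.release else cfg.cycles
    checkpoint = (
        cfg.toxicant.start_cycle + cfg.toxicant.duration_cycles - 1
        if cfg.toxicant
        else release_start - 1
    )

    post_toxicant = -1
    extinct_cycle: Optional[int] = None
    wt_extinct_cycle: Optional[int] = None
    series: list[int] = []
    for _ in range(cfg.cycles):
        step_cycle(state, params, program)
        if keep_series:
            series.append(state.n)
        cycle_done = state.cycle - 1
        if cycle_done == checkpoint:
            post_toxicant = state.n
        if cycle_done >= release_start:
            if wt_extinct_cycle is None and state.wild_type_census() == 0:
                wt_extinct_cycle = cycle_done
            if state.n == 0:
                if not program.can_restock(cycle_done + 1):
                    extinct_cycle = cycle_done
                    break
            else:
                extinct_cycle = None

    eradicated = extinct_cycle is not None and state.n == 0
    time = None
    wt_time = None
    if eradicated:
        time = (extinct_cycle + 1 - release_start) / params.n_c
    if wt_extinct_cycle is not None:
        wt_time = (wt_extinct_cycle + 1 - release_start) / params.n_c
    return RunOutcome(
        eradicated=eradicated,
        time_to_eradication=time,
        wt_extinction_time=wt_time,
        post_toxicant_census=post_toxicant,
        total_released=program.total_released,
        final_census=state.n,
        seed=seed,
        config_id=cfg.config_id,
        census_series=series if keep_series else None,
    )


def _derive_seed(*entropy: int) -> int:
    ss = np.random.SeedSequence(tuple(int(e) for e in entropy))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_experiment(
    cfg: RunConfig,
    n_reps: int,
    root_seed: int,
    max_redraws: int = 20,
) -> list[RunOutcome]:
    """Run ``n_reps`` replicates with deterministically derived seeds.

    Replicates whose post-toxicant census is zero (the toxicant alone
    already eradicated the island) are excluded and redrawn with a fresh
    derived seed, up to ``max_redraws`` attempts per slot.
    """
    if n_reps < 0:
        raise ValueError("n_reps must be >= 0")
    outcomes: list[RunOutcome] = []
    for rep in range(n_reps):
        for attempt in range(max_redraws):
            seed = _derive_seed(root_seed, rep, attempt)
            out = run_scenario(cfg, seed=seed)
            if cfg.toxicant is None or out.post_toxicant_census > 0:
                outcomes.append(out)
                break
        else:
            warnings.warn(
                f"replicate {rep}: no surviving post-toxicant population in "
                f"{max_redraws} redraws; slot dropped"
            )
    return outcomes


def _cell_config(
    base: RunConfig,
    combo: EffortCombo,
    release_strategy: str,
    genetic_strategy: Strategy,
    variant: Optional[dict] = None,
) -> RunConfig:
    lh = base.life_history
    tox = base.toxicant
    if variant:
        lh = replace(
            lh,
            D=variant.get("D", lh.D),
            p_r=variant.get("p_r", lh.p_r),
            p_m=variant.get("p_m", lh.p_m),
        )
        if tox is not None and "c_s" in variant:
            tox = replace(tox, c_s=variant["c_s"])
    rel = replace(
        base.release,
        strategy=release_strategy,
        n_p=combo.n_p,
        n_i=combo.n_i,
        N_i=combo.N_i,
        genetic_strategy=genetic_strategy,
    )
    return base.replace(life_history=lh, toxicant=tox, release=rel)


def run_effort_cell(
    combo: EffortCombo | int,
    release_strategy: str,
    genetic_strategy: Strategy,
    reps_per_variant: int,
    root_seed: int,
    base: Optional[RunConfig] = None,
    variants: Optional[Sequence[dict]] = None,
) -> list[RunOutcome]:
    """Replicates of one effort-cube cell pooled over life-history variants.

    Replicate seeds are derived from (root seed, combo, variant, rep) -
    deliberately independent of the release and genetic strategy, so
    strategies can be compared on matched seeds.
    """
    if isinstance(combo, int):
        combo = decode_effort_index(combo)
    base = base or default_config()
    variants = list(variants) if variants is not None else life_history_variants()
    outcomes: list[RunOutcome] = []
    for v_idx, variant in enumerate(variants):
        cfg = _cell_config(base, combo, release_strategy, genetic_strategy, variant)
        for rep in range(reps_per_variant):
            for attempt in range(20):
                seed = _derive_seed(root_seed, combo.index, v_idx, rep, attempt)
                out = run_scenario(cfg, seed=seed)
                if cfg.toxicant is None or out.post_toxicant_census > 0:
                    outcomes.append(out)
                    break
    return outcomes


def summarize(outcomes: Sequence[RunOutcome]) -> Summary:
    """Eradication probability over all runs; median time and median total
    released over the successful runs only."""
    if not outcomes:
        raise ValueError("cannot summarize an empty outcome set")
    n = len(outcomes)
    wins = [o for o in outcomes if o.eradicated]
    prob = len(wins) / n
    med_t = float(np.median([o.time_to_eradication for o in wins])) if wins else None
    med_r = float(np.median([o.total_released for o in wins])) if wins else None
    return Summary(
        n=n,
        eradication_probability=prob,
        median_time_years=med_t,
        median_total_released=med_r,
    )


def outcomes_frame(outcomes: Sequence[RunOutcome], **labels) -> pd.DataFrame:
    """One row per replicate, with optional constant label columns."""
    rows = []
    for o in outcomes:
        row = {
            "eradicated": o.eradicated,
            "time_to_eradication": o.time_to_eradication,
            "wt_extinction_time": o.wt_extinction_time,
            "post_toxicant_census": o.post_toxicant_census,
            "total_released": o.total_released,
            "final_census": o.final_census,
            "seed": o.seed,
            "config_id": o.config_id,
        }
        row.update(labels)
        rows.append(row)
    return pd.DataFrame(rows)


def calibrate_K(
    params: LifeHistoryParams,
    target: float = 11000.0,
    tol: float = 0.05,
    dims: tuple[int, int] = (16, 16),
    founders: int = 2000,
    years: int = 8,
    n_seeds: int = 10,
    root_seed: int = 0,
    max_iter: int = 30,
) -> float:
    """Bisect the per-patch carrying capacity K until the mean end-of-burn-in
    census over ``n_seeds`` seeds is within ``tol`` of ``target``.

    The search bracket is the logistic-equilibrium bound
    ``[0.5, 4] * target / n_patches``; the mean census is monotone in K, so
    bisection converges or raises with diagnostics.
    """
    if target <= 0:
        raise ValueError("calibration target must be > 0")
    n_patches = dims[0] * dims[1]
    lo, hi = 0.5 * target / n_patches, 4.0 * target / n_patches

    def mean_census(K: float) -> float:
        totals = []
        for i in range(n_seeds):
            p = replace(params, K=K)
            state = init_island(
                p, dims=dims, founders=founders, seed=_derive_seed(root_seed, i)
            )
            for _ in range(years * p.n_c):
                step_cycle(state, p)
            totals.append(state.n)
        return float(np.mean(totals))

    f_lo, f_hi = mean_census(lo), mean_census(hi)
    if not f_lo <= target <= f_hi:
        raise RuntimeError(
            f"calibration target {target} outside bracket response "
            f"[{f_lo:.0f}, {f_hi:.0f}] for K in [{lo:.1f}, {hi:.1f}]"
        )
    K = (lo + hi) / 2
    for _ in range(max_iter):
        K = (lo + hi) / 2
        mean = mean_census(K)
        if abs(mean - target) / target <= tol:
            return K
        if mean < target:
            lo = K
        else:
            hi = K
    raise RuntimeError(
        f"carrying-capacity calibration did not converge in {max_iter} "
        f"iterations; last K={K:.2f}, mean census {mean:.0f}, target {target}"
    )


# ordinal encoding for the release strategy, by monitoring intensity
_STRATEGY_ORDINAL = {"broad": 0, "tactical": 1, "when_detected": 2}


def sensitivity_analysis(
    grid_outcomes: pd.DataFrame,
    outcome_col: str = "eradicated",
    param_cols: Optional[Sequence[str]] = None,
    n_permutation_repeats: int = 5,
    random_state: int = 0,
) -> pd.DataFrame:
    """Global sensitivity of eradication to design/life-history parameters.

    Fits a logistic surrogate of the binary outcome on standardized
    parameters and combines the absolute standardized main-effect
    coefficients with model-based permutation importance; the combined
    scores are normalized to sum to one.  Parameters observed at a single
    level get score 0 with a warning.
    """
    from sklearn.inspection import permutation_importance
    from sklearn.linear_model import LogisticRegression

    if param_cols is None:
        param_cols = [c for c in grid_outcomes.columns if c != outcome_col]
    y = grid_outcomes[outcome_col].astype(int).to_numpy()

    X = np.empty((len(grid_outcomes), len(param_cols)))
    active = []
    for j, col in enumerate(param_cols):
        v = grid_outcomes[col]
        if v.dtype == object or str(v.dtype) == "category":
            v = v.map(_STRATEGY_ORDINAL)
            if v.isna().any():
                raise ValueError(f"cannot encode parameter column {col!r}")
        X[:, j] = v.to_numpy(dtype=float)
        if np.unique(X[:, j]).size < 2:
            warnings.warn(f"parameter {col!r} has a single level; score set to 0")
            active.append(False)
        else:
            active.append(True)
    active = np.array(active)

    coef = np.zeros(len(param_cols))
    perm = np.zeros(len(param_cols))
    if active.any() and np.unique(y).size > 1:
        Xa = X[:, active]
        mu, sd = Xa.mean(axis=0), Xa.std(axis=0)
        Xs = (Xa - mu) / sd
        model = LogisticRegression(max_iter=2000)
        model.fit(Xs, y)
        coef[active] = np.abs(model.coef_[0])
        pi = permutation_importance(
            model,
            Xs,
            y,
            n_repeats=n_permutation_repeats,
            random_state=random_state,
            scoring="roc_auc",
        )
        perm[active] = np.clip(pi.importances_mean, 0.0, None)

    def _norm(v: np.ndarray) -> np.ndarray:
        s = v.sum()
        return v / s if s > 0 else v

    combined = _norm(_norm(coef) + _norm(perm))
    return pd.DataFrame(
        {
            "coef_score": _norm(coef),
            "permutation_score": _norm(perm),
            "score": combined,
        },
        index=pd.Index(param_cols, name="parameter"),
    ).sort_values("score", ascending=False)
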