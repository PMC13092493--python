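"""Demographic engine: the patch lattice, breeding-cycle steps, and burn-in.

The island is a rectangular array of patches (default 16 x 16, one patch
~70 m x 70 m).  Each breeding cycle (six per year) runs six ordered steps:

1. mate search, 2. mating, 3. reproduction, 4. natal dispersal,
5. survival of adults, 6. breeding dispersal.

Distances are Chebyshev (square neighborhoods, boundaries truncated: it is
an island).  Movement in steps 1 and 6 is density dependent,

    p_move = m_min + (m_max - m_min) * max(0, 1 - N_patch / K),

so individuals sit tight near carrying capacity and roam at low density.
Fertility is density dependent through the expected litter size
``litter_mean * max(0, 1 - N_patch / K)`` evaluated at the dam's patch
before births; realized litters are Poisson.

The population lives in structure-of-arrays form inside
:class:`IslandState`, so every step is a handful of NumPy operations and a
full 200-cycle island run takes well under a second.  The per-individual
dataclass view (:class:`Individual`) and the record-based ``form_matings`` /
``reproduce`` wrappers expose the same operations at object granularity for
inspection and testing.

Randomness: one root seed per run; at the top of every cycle the state's
generator is reseeded from ``(seed, cycle)``, so each cycle has its own
deterministic substream and any step reordering changes the log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Optional

import numpy as np

from . import genetics
from .genetics import GL, MatingRecord, Strategy

__all__ = [
    "LifeHistoryParams",
    "Individual",
    "IslandState",
    "CycleLog",
    "init_island",
    "mate_search",
    "form_matings",
    "reproduce",
    "natal_dispersal",
    "adult_survival",
    "breeding_dispersal",
    "step_cycle",
    "burn_in",
]

SEX_F, SEX_M = 0, 1
ORIGIN_WILD, ORIGIN_RELEASED = 0, 1


@dataclass(frozen=True)
class LifeHistoryParams:
    """Demographic rates of the simulated mouse population.

    All rates are per breeding cycle (two months at ``n_c = 6``).

    p_r: probability an adult female with an available mate breeds.
    p_m: probability a breeding female takes a second, distinct mate.
    D: maximum mate-search / dispersal distance, in patches (Chebyshev).
    n_c: breeding cycles per year.
    s: baseline per-cycle survival probability (individuals born in
        earlier cycles; current-cycle pups face it from their next cycle).
    litter_mean: maximum expected litter size at zero density.
    maturity_cycles: cycles from birth to adulthood.
    K: per-patch carrying capacity (individuals).
    m_min, m_max: movement probability at density >= K and at density 0.
    """

    p_r: float = 0.8
    p_m: float = 0.8
    D: int = 1
    n_c: int = 6
    s: float = 0.55
    litter_mean: float = 8.0
    maturity_cycles: int = 1
    K: float = 49.7
    m_min: float = 0.1
    m_max: float = 0.9

    def __post_init__(self) -> None:
        for name in ("p_r", "p_m", "s", "m_min", "m_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.m_min > self.m_max:
            raise ValueError("m_min must not exceed m_max")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if self.n_c < 1 or self.maturity_cycles < 1:
            raise ValueError("n_c and maturity_cycles must be >= 1")
        if self.litter_mean <= 0:
            raise ValueError("litter_mean must be > 0")


@dataclass(frozen=True)
class Individual:
    """Read-only per-individual view used by the object-level API."""

    id: int
    sex: str  # "F" or "M"
    age: int
    patch: tuple[int, int]
    genotype: genetics.Genotype
    origin: str  # "wild" or "released"
    sterile: bool


@dataclass
class CycleLog:
    """Census and bookkeeping for one breeding cycle.

    The conservation identity
    ``n_end == n_start + births - deaths + releases``
    holds exactly every cycle; ``births`` counts every pup instantiated
    (including fsRIDL daughters that die at birth, logged under
    ``deaths_female_lethal``), while litters lost to Gravid Lethal maternal
    death contribute nothing.
    """

    cycle: int
    year: float
    n_start: int
    n_end: int
    counts: dict[str, int]
    counts_f: dict[str, int]
    counts_m: dict[str, int]
    births: int
    deaths_background: int
    deaths_toxicant: int
    deaths_gravid: int
    deaths_female_lethal: int
    released: int

    @property
    def deaths_total(self) -> int:
        return (
            self.deaths_background
            + self.deaths_toxicant
            + self.deaths_gravid
            + self.deaths_female_lethal
        )

    CSV_COLUMNS = (
        "cycle",
        "year",
        "N_total",
        "N_WT",
        "N_FS1",
        "N_FS2",
        "N_YE",
        "N_GL",
        "births",
        "deaths_background",
        "deaths_toxicant",
        "deaths_gravid",
        "deaths_female_lethal",
        "released",
    )

    def as_row(self) -> dict:
        row = {
            "cycle": self.cycle,
            "year": self.year,
            "N_total": self.n_end,
            "births": self.births,
            "deaths_background": self.deaths_background,
            "deaths_toxicant": self.deaths_toxicant,
            "deaths_gravid": self.deaths_gravid,
            "deaths_female_lethal": self.deaths_female_lethal,
            "released": self.released,
        }
        for cls in genetics.CLASS_CODES:
            row[f"N_{cls}"] = self.counts[cls]
        return row


@lru_cache(maxsize=32)
def _neighbor_table(rows: int, cols: int, D: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-patch list of in-bounds patches within Chebyshev distance D
    (own patch included), padded with -1."""
    n = rows * cols
    width = (2 * D + 1) ** 2
    nb = np.full((n, width), -1, dtype=np.int64)
    cnt = np.zeros(n, dtype=np.int64)
    offsets = [(dr, dc) for dr in range(-D, D + 1) for dc in range(-D, D + 1)]
    for r in range(rows):
        for c in range(cols):
            p = r * cols + c
            k = 0
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    nb[p, k] = rr * cols + cc
                    k += 1
            cnt[p] = k
    return nb, cnt


class IslandState:
    """Mutable island population in structure-of-arrays form.

    Every individual appears in exactly one patch; patches are flattened
    row-major indices.  ``log`` accumulates one :class:`CycleLog` per
    executed cycle.
    """

    def __init__(self, dims: tuple[int, int], seed: int):
        rows, cols = dims
        if rows <= 0 or cols <= 0:
            raise ValueError(f"island dims must be positive, got {dims}")
        self.dims = (int(rows), int(cols))
        self.seed = int(seed)
        self.cycle = 0
        self.rng = np.random.default_rng(np.random.SeedSequence((self.seed, 0)))
        self._next_id = 0
        self.log: list[CycleLog] = []

        self.ids = np.empty(0, dtype=np.int64)
        self.sex = np.empty(0, dtype=np.int8)
        self.age = np.empty(0, dtype=np.int32)
        self.patch = np.empty(0, dtype=np.int64)
        self.geno = np.empty(0, dtype=np.int8)
        self.origin = np.empty(0, dtype=np.int8)
        self.sterile = np.empty(0, dtype=bool)
        self.fresh = np.empty(0, dtype=bool)  # released this cycle, pre-dispersal

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return self.ids.size

    @property
    def n_patches(self) -> int:
        return self.dims[0] * self.dims[1]

    def census(self) -> int:
        return self.n

    def patch_counts(self) -> np.ndarray:
        return np.bincount(self.patch, minlength=self.n_patches)

    def counts_by_class(self, sex: Optional[int] = None) -> dict[str, int]:
        mask = np.ones(self.n, dtype=bool) if sex is None else self.sex == sex
        c = np.bincount(self.geno[mask], minlength=len(genetics.CLASS_CODES))
        return {cls: int(c[i]) for i, cls in enumerate(genetics.CLASS_CODES)}

    def wild_type_census(self) -> int:
        """Fertile wild-type individuals (sterilized daughters of Y-editor
        males carry detectable edits, so they do not count as wild type)."""
        return int(np.count_nonzero((self.geno == genetics.WT) & ~self.sterile))

    def transgenic_census(self) -> int:
        return int(np.count_nonzero(self.geno != genetics.WT))

    # -- mutation helpers --------------------------------------------------

    def reseed_cycle(self) -> np.random.Generator:
        """Derive this cycle's RNG substream from (root seed, cycle)."""
        self.rng = np.random.default_rng(
            np.random.SeedSequence((self.seed, self.cycle + 1))
        )
        return self.rng

    def add(
        self,
        *,
        sex: np.ndarray,
        age: np.ndarray,
        patch: np.ndarray,
        geno: np.ndarray,
        origin: np.ndarray,
        sterile: np.ndarray,
        fresh: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        k = sex.size
        ids = np.arange(self._next_id, self._next_id + k, dtype=np.int64)
        self._next_id += k
        self.ids = np.concatenate([self.ids, ids])
        self.sex = np.concatenate([self.sex, sex.astype(np.int8)])
        self.age = np.concatenate([self.age, age.astype(np.int32)])
        self.patch = np.concatenate([self.patch, patch.astype(np.int64)])
        self.geno = np.concatenate([self.geno, geno.astype(np.int8)])
        self.origin = np.concatenate([self.origin, origin.astype(np.int8)])
        self.sterile = np.concatenate([self.sterile, sterile.astype(bool)])
        if fresh is None:
            fresh = np.zeros(k, dtype=bool)
        self.fresh = np.concatenate([self.fresh, fresh.astype(bool)])
        return ids

    def keep(self, mask: np.ndarray) -> None:
        self.ids = self.ids[mask]
        self.sex = self.sex[mask]
        self.age = self.age[mask]
        self.patch = self.patch[mask]
        self.geno = self.geno[mask]
        self.origin = self.origin[mask]
        self.sterile = self.sterile[mask]
        self.fresh = self.fresh[mask]

    def index_of(self, ids) -> np.ndarray:
        order = np.argsort(self.ids)
        pos = np.searchsorted(self.ids, ids, sorter=order)
        idx = order[pos]
        if not np.array_equal(self.ids[idx], np.asarray(ids)):
            raise KeyError("unknown individual id")
        return idx

    def individuals(self) -> Iterator[Individual]:
        cols = self.dims[1]
        for i in range(self.n):
            yield Individual(
                id=int(self.ids[i]),
                sex="F" if self.sex[i] == SEX_F else "M",
                age=int(self.age[i]),
                patch=(int(self.patch[i]) // cols, int(self.patch[i]) % cols),
                genotype=genetics.genotype_of(self.geno[i]),
                origin="wild" if self.origin[i] == ORIGIN_WILD else "released",
                sterile=bool(self.sterile[i]),
            )


def init_island(
    params: LifeHistoryParams,
    dims: tuple[int, int] = (16, 16),
    founders: int = 2000,
    seed: int = 0,
) -> IslandState:
    """Create an island with wild-type adult founders scattered uniformly
    at random over the patches, sexes drawn 1:1."""
    if founders < 0:
        raise ValueError("founder count must be >= 0")
    state = IslandState(dims, seed)
    rng = state.rng
    if founders:
        state.add(
            sex=(rng.random(founders) < 0.5).astype(np.int8),
            age=np.full(founders, params.maturity_cycles),
            patch=rng.integers(0, state.n_patches, size=founders),
            geno=np.zeros(founders, dtype=np.int8),
            origin=np.zeros(founders, dtype=np.int8),
            sterile=np.zeros(founders, dtype=bool),
        )
    return state


# ---------------------------------------------------------------------------
# movement helpers


def _uniform_dest(
    patches: np.ndarray, nb: np.ndarray, cnt: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform draw over each patch's in-bounds Chebyshev neighborhood."""
    if patches.size == 0:
        return patches
    j = rng.integers(0, cnt[patches])
    return nb[patches, j]


def _preferring_dest(
    patches: np.ndarray,
    target: np.ndarray,
    nb: np.ndarray,
    cnt: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform over in-range patches where ``target`` holds; falls back to a
    plain uniform neighborhood draw when no in-range patch qualifies."""
    out = np.empty(patches.size, dtype=np.int64)
    if patches.size == 0:
        return out
    nbr = nb[patches]
    hit = (nbr >= 0) & target[np.clip(nbr, 0, None)]
    nhit = hit.sum(axis=1)
    some = nhit > 0
    if some.any():
        r = rng.integers(0, nhit[some])
        cs = np.cumsum(hit[some], axis=1)
        col = (cs > r[:, None]).argmax(axis=1)
        out[some] = nbr[some][np.arange(col.size), col]
    rest = ~some
    if rest.any():
        out[rest] = _uniform_dest(patches[rest], nb, cnt, rng)
    return out


def _movement_prob(state: IslandState, params: LifeHistoryParams) -> np.ndarray:
    # conspecific density excludes the focal animal: a lone adult moves at m_max
    occ = state.patch_counts()
    dens = (occ[state.patch] - 1) / params.K
    return params.m_min + (params.m_max - params.m_min) * np.clip(1.0 - dens, 0.0, None)


# ---------------------------------------------------------------------------
# the six breeding-cycle steps


def mate_search(state: IslandState, params: LifeHistoryParams) -> IslandState:
    """Step 1: adults relocate within distance D before mating.

    Movement fires with the density-dependent probability shared with
    breeding dispersal.  Wild movers whose own patch holds no opposite-sex
    adult prefer an in-range patch that does (uniform among those); all
    other movers pick uniformly over the in-bounds neighborhood.  Newly
    released males always execute exactly one uniform relocation within D
    of their release site before joining the mating pool.
    """
    rng = state.rng
    nb, cnt = _neighbor_table(*state.dims, params.D)
    adult = state.age >= params.maturity_cycles
    p_move = _movement_prob(state, params)
    move = adult & ((rng.random(state.n) < p_move) | state.fresh)
    idx = np.flatnonzero(move)
    if idx.size == 0:
        state.fresh[:] = False
        return state

    has_adult_m = np.zeros(state.n_patches, dtype=bool)
    has_adult_m[state.patch[adult & (state.sex == SEX_M)]] = True
    has_adult_f = np.zeros(state.n_patches, dtype=bool)
    has_adult_f[state.patch[adult & (state.sex == SEX_F)]] = True

    dest = np.empty(idx.size, dtype=np.int64)
    is_f = state.sex[idx] == SEX_F
    forced = state.fresh[idx]
    for female, opp in ((True, has_adult_m), (False, has_adult_f)):
        grp = is_f == female
        if not grp.any():
            continue
        gi = idx[grp]
        lacks = ~opp[state.patch[gi]] & ~forced[grp]
        sub = np.empty(gi.size, dtype=np.int64)
        sub[lacks] = _preferring_dest(state.patch[gi[lacks]], opp, nb, cnt, rng)
        plain = ~lacks
        sub[plain] = _uniform_dest(state.patch[gi[plain]], nb, cnt, rng)
        dest[grp] = sub

    state.patch[idx] = dest
    state.fresh[:] = False
    return state


def _matings_arrays(
    state: IslandState, params: LifeHistoryParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Step 2 core: returns (dam_index, mate1_index, mate2_index) arrays,
    mate2 = -1 for monandrous matings.  Mate choice is uniform without
    replacement over all co-located fertile adult males, irrespective of
    genotype (no bias against transgenic males)."""
    empty = np.empty(0, dtype=np.int64)
    if state.n == 0:
        return empty, empty, empty
    adult = state.age >= params.maturity_cycles
    fertile = ~state.sterile
    male = adult & fertile & (state.sex == SEX_M)
    female = adult & fertile & (state.sex == SEX_F)
    midx = np.flatnonzero(male)
    fidx = np.flatnonzero(female)
    if midx.size == 0 or fidx.size == 0:
        return empty, empty, empty

    order = np.argsort(state.patch[midx], kind="stable")
    midx = midx[order]
    mcnt = np.bincount(state.patch[midx], minlength=state.n_patches)
    mstart = np.concatenate(([0], np.cumsum(mcnt)[:-1]))

    fp = state.patch[fidx]
    ok = mcnt[fp] > 0
    fidx, fp = fidx[ok], fp[ok]
    if fidx.size == 0:
        return empty, empty, empty
    mated = rng.random(fidx.size) < params.p_r
    dams, dp = fidx[mated], fp[mated]
    if dams.size == 0:
        return empty, empty, empty

    c = mcnt[dp]
    j1 = rng.integers(0, c)
    mate1 = midx[mstart[dp] + j1]
    poly = (rng.random(dams.size) < params.p_m) & (c >= 2)
    j2 = rng.integers(0, np.maximum(c - 1, 1))
    j2 = j2 + (j2 >= j1)
    mate2 = np.where(poly, midx[mstart[dp] + np.minimum(j2, c - 1)], -1)
    return dams, mate1, mate2


def form_matings(state: IslandState, params: LifeHistoryParams) -> list[MatingRecord]:
    """Step 2: pair each breeding female with one or two co-located mates."""
    dams, m1, m2 = _matings_arrays(state, params, state.rng)
    cols = state.dims[1]
    records = []
    for d, a, b in zip(dams, m1, m2):
        mates = (int(state.ids[a]),) if b < 0 else (int(state.ids[a]), int(state.ids[b]))
        p = int(state.patch[d])
        records.append(
            MatingRecord(dam=int(state.ids[d]), mates=mates, patch=(p // cols, p % cols))
        )
    return records


def _reproduce_arrays(
    state: IslandState,
    dams: np.ndarray,
    mate1: np.ndarray,
    mate2: np.ndarray,
    params: LifeHistoryParams,
    rng: np.random.Generator,
) -> tuple[dict, np.ndarray, int, int]:
    """Step 3 core.  Returns (pup arrays, dam-death mask over `dams`,
    births, female-lethal deaths).  Pup arrays exclude fsRIDL daughters and
    the litters of dams killed by Gravid Lethal embryos."""
    occ = state.patch_counts()
    lam = params.litter_mean * np.clip(1.0 - occ[state.patch[dams]] / params.K, 0.0, None)
    litter = rng.poisson(lam)
    total = int(litter.sum())
    dam_dies = np.zeros(dams.size, dtype=bool)
    if total == 0:
        return {}, dam_dies, 0, 0

    rep = np.repeat(np.arange(dams.size), litter)
    has2 = mate2[rep] >= 0
    use2 = has2 & (rng.random(total) < 0.5)
    sire = np.where(use2, mate2[rep], mate1[rep])
    pup_female = rng.random(total) < 0.5
    codes, viable, pup_sterile, embryo = genetics.batch_fates(
        state.geno[sire], pup_female, rng
    )

    if embryo.any():
        dam_dies = np.bincount(rep, weights=embryo, minlength=dams.size) > 0
    litter_kept = ~dam_dies[rep]
    births = int(np.count_nonzero(litter_kept))
    fem_lethal = int(np.count_nonzero(litter_kept & ~viable))
    keep = litter_kept & viable
    pups = {
        "sex": np.where(pup_female[keep], SEX_F, SEX_M).astype(np.int8),
        "age": np.zeros(int(keep.sum()), dtype=np.int32),
        "patch": state.patch[dams][rep[keep]],
        "geno": codes[keep],
        "origin": np.zeros(int(keep.sum()), dtype=np.int8),
        "sterile": pup_sterile[keep],
    }
    return pups, dam_dies, births, fem_lethal


def reproduce(
    state: IslandState,
    matings: list[MatingRecord],
    params: LifeHistoryParams,
) -> tuple[list[Individual], list[int]]:
    """Step 3: realize litters for the given matings; adds surviving pups
    to the island and removes dams killed by Gravid Lethal embryos.
    Returns (new individuals, ids of dams that died)."""
    if not matings:
        return [], []
    dams = state.index_of([m.dam for m in matings])
    mate1 = state.index_of([m.mates[0] for m in matings])
    mate2 = np.full(len(matings), -1, dtype=np.int64)
    two = [i for i, m in enumerate(matings) if len(m.mates) == 2]
    if two:
        mate2[two] = state.index_of([matings[i].mates[1] for i in two])

    pups, dam_dies, _, _ = _reproduce_arrays(state, dams, mate1, mate2, params, state.rng)
    dead_ids = [int(i) for i in state.ids[dams[dam_dies]]]
    if dam_dies.any():
        mask = np.ones(state.n, dtype=bool)
        mask[dams[dam_dies]] = False
        state.keep(mask)
    new_ids: list[int] = []
    if pups:
        new_ids = list(state.add(**pups))
    id_set = set(new_ids)
    offspring = [ind for ind in state.individuals() if ind.id in id_set]
    return offspring, dead_ids


def natal_dispersal(state: IslandState, params: LifeHistoryParams) -> IslandState:
    """Step 4: every newborn relocates (unconditionally) to a uniform
    in-bounds patch within Chebyshev distance D of its natal patch."""
    nb, cnt = _neighbor_table(*state.dims, params.D)
    newborn = np.flatnonzero(state.age == 0)
    if newborn.size:
        state.patch[newborn] = _uniform_dest(state.patch[newborn], nb, cnt, state.rng)
    return state


def adult_survival(
    state: IslandState, params: LifeHistoryParams, modifier: float = 1.0
) -> int:
    """Step 5: independent Bernoulli survival.

    Background mortality acts on individuals born in previous cycles
    (age >= 1), which survive with probability ``s * modifier``; pups born
    this cycle are insulated from background mortality until their next
    cycle but are exposed to lethal control, surviving with probability
    ``modifier``.  Returns the number of deaths.
    """
    if not 0.0 <= modifier <= 1.0:
        raise ValueError(f"survival modifier must be in [0, 1], got {modifier}")
    if state.n == 0:
        return 0
    p = np.where(state.age >= 1, params.s * modifier, modifier)
    alive = state.rng.random(state.n) < p
    deaths = int(state.n - np.count_nonzero(alive))
    state.keep(alive)
    return deaths


def breeding_dispersal(state: IslandState, params: LifeHistoryParams) -> IslandState:
    """Step 6: adults move with the density-dependent probability
    ``m_min + (m_max - m_min) * max(0, 1 - N_patch/K)``, relocating
    uniformly within distance D."""
    rng = state.rng
    nb, cnt = _neighbor_table(*state.dims, params.D)
    adult = state.age >= params.maturity_cycles
    p_move = _movement_prob(state, params)
    movers = np.flatnonzero(adult & (rng.random(state.n) < p_move))
    if movers.size:
        state.patch[movers] = _uniform_dest(state.patch[movers], nb, cnt, rng)
    return state


def step_cycle(
    state: IslandState,
    params: LifeHistoryParams,
    program=None,
) -> tuple[IslandState, CycleLog]:
    """Run one full breeding cycle.

    Interventions execute first (release of transgenic males, then
    monitoring records), followed by the six demographic steps in order;
    survivors age by one cycle.  The emitted :class:`CycleLog` satisfies
    the exact conservation identity.
    """
    rng = state.reseed_cycle()
    n_start = state.n

    released = 0
    modifier = 1.0
    if program is not None:
        released = program.release_step(state, params)
        program.monitor_step(state)
        modifier = program.survival_modifier(state.cycle)

    mate_search(state, params)
    dams, m1, m2 = _matings_arrays(state, params, rng)
    births = fem_lethal = gravid = 0
    if dams.size:
        pups, dam_dies, births, fem_lethal = _reproduce_arrays(
            state, dams, m1, m2, params, rng
        )
        gravid = int(np.count_nonzero(dam_dies))
        if gravid:
            mask = np.ones(state.n, dtype=bool)
            mask[dams[dam_dies]] = False
            state.keep(mask)
        if pups:
            state.add(**pups)
    natal_dispersal(state, params)
    step5_deaths = adult_survival(state, params, modifier)
    breeding_dispersal(state, params)
    state.age += 1

    toxicant_deaths = step5_deaths if modifier < 1.0 else 0
    background_deaths = step5_deaths if modifier >= 1.0 else 0
    log = CycleLog(
        cycle=state.cycle,
        year=state.cycle / params.n_c,
        n_start=n_start,
        n_end=state.n,
        counts=state.counts_by_class(),
        counts_f=state.counts_by_class(SEX_F),
        counts_m=state.counts_by_class(SEX_M),
        births=births,
        deaths_background=background_deaths,
        deaths_toxicant=toxicant_deaths,
        deaths_gravid=gravid,
        deaths_female_lethal=fem_lethal,
        released=released,
    )
    if log.n_end != log.n_start + log.births - log.deaths_total + log.released:
        raise RuntimeError(
            f"conservation identity violated at cycle {state.cycle}: {log}"
        )
    state.cycle += 1
    state.log.append(log)
    return state, log


def burn_in(
    state: IslandState, params: LifeHistoryParams, years: int = 8
) -> IslandState:
    """Run ``years * n_c`` cycles with no control, bringing the island to
    demographic equilibrium."""
    if years < 0:
        raise ValueError("years must be >= 0")
    for _ in range(years * params.n_c):
        step_cycle(state, params)
    return state
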