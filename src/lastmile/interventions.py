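"""Control measures: toxicant culling, release layout/scheduling, monitoring.

A control campaign combines a one-year toxicant knockdown with subsequent
releases of transgenic males under one of three strategies:

* ``broad`` — every scheduled event restocks all release sites; no
  monitoring is assumed.
* ``tactical`` — sites are monitored, and an event restocks only sites
  where any mouse was detected in the previous breeding cycle.
* ``when_detected`` — monitoring distinguishes wild-type from transgenic
  animals (e.g., discriminating eDNA assays); an event restocks only sites
  where a wild-type mouse was detected in the previous cycle.

Monitoring is perfect by default (a config hook exposes a detection
probability) and confined to the release sites.  Release sites form an
evenly spaced square lattice over the island.  During the toxicant window
the per-cycle survival probability becomes ``s * c_s``: the culling
parameter is the post-control survival scaling, so ``c_s = 0.2`` removes
80% of the per-cycle survivors and knocks an equilibrium population down
by two to three orders of magnitude over six treated cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import genetics
from .genetics import Strategy
from .population_core import IslandState, LifeHistoryParams, SEX_M

__all__ = [
    "ToxicantPlan",
    "ReleasePlan",
    "DetectionMap",
    "ControlProgram",
    "layout_release_sites",
    "apply_toxicant",
    "monitor",
    "plan_release_event",
    "execute_release",
    "total_release_effort",
    "MONITOR_MODE",
]

RELEASE_STRATEGIES = ("broad", "tactical", "when_detected")

# monitoring intensity implied by each release strategy
MONITOR_MODE = {"broad": "none", "tactical": "presence", "when_detected": "wt_presence"}


@dataclass(frozen=True)
class ToxicantPlan:
    """Lethal-control window: per-cycle survival is scaled by ``c_s`` for
    ``duration_cycles`` cycles starting at ``start_cycle``."""

    c_s: float = 0.2
    start_cycle: int = 48
    duration_cycles: int = 6

    def __post_init__(self) -> None:
        if not 0.0 < self.c_s <= 1.0:
            raise ValueError(f"c_s must be in (0, 1], got {self.c_s}")
        if self.duration_cycles < 0:
            raise ValueError("duration_cycles must be >= 0")


@dataclass(frozen=True)
class ReleasePlan:
    """Schedule of transgenic-male releases.

    ``n_p`` sites receive ``N_i`` males per selected site at each of
    ``n_i`` events, spaced ``cadence`` cycles apart from ``start_cycle``.
    The ceiling on total effort is ``N_T = N_i * n_p * n_i`` (attained by
    the broad strategy when every event fires).
    """

    strategy: str = "broad"
    n_p: int = 64
    n_i: int = 12
    N_i: int = 10
    cadence: int = 2
    start_cycle: int = 54
    genetic_strategy: Strategy = Strategy.GRAVID_LETHAL
    detection_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.strategy not in RELEASE_STRATEGIES:
            raise ValueError(f"unknown release strategy {self.strategy!r}")
        if self.n_i <= 0 or self.N_i <= 0 or self.n_p <= 0:
            raise ValueError("n_p, n_i and N_i must be > 0")
        if self.cadence <= 0:
            raise ValueError("cadence must be > 0")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")
        if self.genetic_strategy == Strategy.WT:
            raise ValueError("released males must carry a biocontrol construct")

    @property
    def last_event_cycle(self) -> int:
        return self.start_cycle + self.cadence * (self.n_i - 1)


@dataclass
class DetectionMap:
    """Monitoring snapshot over the release sites at one cycle."""

    sites: np.ndarray  # flattened patch indices, shape (n_p,)
    any_mouse: np.ndarray  # bool, per site
    wt: np.ndarray  # bool, per site; wt implies any_mouse
    cycle: int

    def __post_init__(self) -> None:
        if np.any(self.wt & ~self.any_mouse):
            raise ValueError("wt detection implies mouse detection")

    @property
    def n_detected(self) -> int:
        return int(self.any_mouse.sum())

    @property
    def n_wt_detected(self) -> int:
        return int(self.wt.sum())


def layout_release_sites(n_p: int, dims: tuple[int, int]) -> list[tuple[int, int]]:
    """Evenly spaced sqrt(n_p) x sqrt(n_p) lattice of release sites.

    Along each axis, site k sits at ``floor((k + 0.5) * extent / sqrt(n_p))``;
    e.g., 16 sites on a 16 x 16 island land on rows/cols {2, 6, 10, 14}.
    """
    rows, cols = dims
    side = math.isqrt(n_p)
    if side * side != n_p:
        raise ValueError(f"n_p must be a perfect square, got {n_p}")
    if n_p > rows * cols:
        raise ValueError(f"n_p={n_p} exceeds the {rows}x{cols} island")
    rr = [math.floor((k + 0.5) * rows / side) for k in range(side)]
    cc = [math.floor((k + 0.5) * cols / side) for k in range(side)]
    return [(r, c) for r in rr for c in cc]


def apply_toxicant(plan: Optional[ToxicantPlan], cycle: int) -> float:
    """Survival modifier for a cycle: ``c_s`` inside the treatment window,
    1.0 outside (or when no toxicant is planned)."""
    if plan is None:
        return 1.0
    if plan.start_cycle <= cycle < plan.start_cycle + plan.duration_cycles:
        return plan.c_s
    return 1.0


def monitor(
    state: IslandState,
    sites: list[tuple[int, int]],
    mode: str,
    detection_prob: float = 1.0,
) -> DetectionMap:
    """Survey the release sites for occupancy.

    ``mode`` is ``none`` (no monitoring; empty map), ``presence`` (any
    mouse) or ``wt_presence`` (wild-type mice discriminated from
    transgenics).  Detection is perfect at ``detection_prob = 1``.
    """
    if mode not in ("none", "presence", "wt_presence"):
        raise ValueError(f"unknown monitoring mode {mode!r}")
    cols = state.dims[1]
    flat = np.array([r * cols + c for r, c in sites], dtype=np.int64)
    if mode == "none":
        z = np.zeros(flat.size, dtype=bool)
        return DetectionMap(sites=flat, any_mouse=z, wt=z.copy(), cycle=state.cycle)
    occ = state.patch_counts()
    wt_occ = np.bincount(
        state.patch[(state.geno == genetics.WT) & ~state.sterile],
        minlength=state.n_patches,
    )
    any_mouse = occ[flat] > 0
    wt = wt_occ[flat] > 0
    if detection_prob < 1.0:
        seen = state.rng.random(flat.size) < detection_prob
        any_mouse &= seen
        wt &= seen
    return DetectionMap(sites=flat, any_mouse=any_mouse, wt=wt, cycle=state.cycle)


def plan_release_event(plan: ReleasePlan, cycle: int) -> bool:
    """True iff ``cycle`` is one of the n_i scheduled event cycles
    (start, start + cadence, ...)."""
    if cycle < plan.start_cycle or cycle > plan.last_event_cycle:
        return False
    return (cycle - plan.start_cycle) % plan.cadence == 0


def execute_release(
    state: IslandState,
    plan: ReleasePlan,
    detections: Optional[DetectionMap],
    params: LifeHistoryParams,
    sites: Optional[list[tuple[int, int]]] = None,
) -> int:
    """Add ``N_i`` adult transgenic males per selected site.

    Site selection: all sites (broad); sites where any mouse was detected
    in the previous cycle (tactical); sites where a wild-type mouse was
    detected (when_detected).  Released males are flagged to execute one
    relocation within D during the mate-search step.  Returns the number
    released.
    """
    if sites is None:
        sites = layout_release_sites(plan.n_p, state.dims)
    cols = state.dims[1]
    flat = np.array([r * cols + c for r, c in sites], dtype=np.int64)
    if plan.strategy == "broad":
        chosen = flat
    else:
        if detections is None:
            raise ValueError(
                f"{plan.strategy} releases require a detection map from the "
                "previous cycle"
            )
        mask = detections.any_mouse if plan.strategy == "tactical" else detections.wt
        chosen = detections.sites[mask]
    k = int(chosen.size) * plan.N_i
    if k == 0:
        return 0
    code = genetics.released_code(plan.genetic_strategy)
    state.add(
        sex=np.full(k, SEX_M, dtype=np.int8),
        age=np.full(k, params.maturity_cycles, dtype=np.int32),
        patch=np.repeat(chosen, plan.N_i),
        geno=np.full(k, code, dtype=np.int8),
        origin=np.ones(k, dtype=np.int8),
        sterile=np.zeros(k, dtype=bool),
        fresh=np.ones(k, dtype=bool),
    )
    return k


def total_release_effort(plan: ReleasePlan) -> int:
    """Broad-release ceiling N_T = N_i * n_p * n_i; tactical strategies
    realize at most this many."""
    return plan.N_i * plan.n_p * plan.n_i


class ControlProgram:
    """Stateful coupling of a toxicant plan and a release plan to a run.

    Within each cycle the program releases first (using detections recorded
    in the previous cycle), then records monitoring, then the demographic
    steps run.  Monitoring begins one cycle before the first scheduled
    event, so the first tactical release is detection-conditioned like all
    later ones.
    """

    def __init__(
        self,
        toxicant: Optional[ToxicantPlan],
        release: Optional[ReleasePlan],
        dims: tuple[int, int],
    ):
        self.toxicant = toxicant
        self.release = release
        self.sites = layout_release_sites(release.n_p, dims) if release else []
        self.detections: Optional[DetectionMap] = None
        self.total_released = 0
        self.release_log: list[tuple[int, int]] = []  # (cycle, count)

    def survival_modifier(self, cycle: int) -> float:
        return apply_toxicant(self.toxicant, cycle)

    def release_step(self, state: IslandState, params: LifeHistoryParams) -> int:
        plan = self.release
        if plan is None or not plan_release_event(plan, state.cycle):
            return 0
        count = execute_release(state, plan, self.detections, params, self.sites)
        self.total_released += count
        self.release_log.append((state.cycle, count))
        return count

    def monitor_step(self, state: IslandState) -> None:
        plan = self.release
        if plan is None:
            return
        mode = MONITOR_MODE[plan.strategy]
        if mode == "none" or state.cycle < plan.start_cycle - 1:
            return
        self.detections = monitor(state, self.sites, mode, plan.detection_prob)

    def can_restock(self, cycle: int) -> bool:
        """Whether any future event could still add individuals.  Used to
        recognize terminal extinction: an empty island stays empty unless a
        pending broad event (unconditional) or a tactical event with live
        detections restocks it."""
        plan = self.release
        if plan is None or cycle > plan.last_event_cycle:
            return False
        if plan.strategy == "broad":
            return True
        if self.detections is None:
            return True  # monitoring not started yet
        mask = (
            self.detections.any_mouse
            if plan.strategy == "tactical"
            else self.detections.wt
        )
        return bool(mask.any())
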