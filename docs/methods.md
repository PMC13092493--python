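# Methods

## Model structure

The simulator is a stochastic, patch-based, individual-based model of a
closed island population of house mice. Space is a rectangular lattice of
patches (default 16 × 16; each patch ≈ 70 m × 70 m, so the default island
is ≈ 125 ha). Every individual carries sex, age (in breeding cycles),
patch, genotype class, origin (wild-born or released) and a sterility
flag. Time advances in breeding cycles, six per year, with overlapping
generations. Each cycle executes, in order:

1. **Mate search.** Adults relocate within Chebyshev distance `D` with the
   density-dependent probability below. Wild movers whose own patch holds
   no opposite-sex adult prefer an in-range patch that does (uniform among
   such patches; uniform over the whole in-bounds neighborhood otherwise).
   Males released this cycle always perform exactly one uniform relocation
   within `D` of their release site before joining the mating pool.
2. **Mating.** Each fertile adult female co-located with at least one
   fertile adult male breeds with probability `p_r`; she draws one mate
   uniformly among co-located fertile males — irrespective of genotype, so
   there is no avoidance of transgenic males — and, with probability `p_m`
   (given ≥ 2 males present), a second distinct mate. Litters of
   polyandrous females have mixed paternity: each pup's sire is drawn
   uniformly from the mate set.
3. **Reproduction.** Expected litter size is
   `litter_mean · max(0, 1 − N/K)` with `N` the occupancy of the dam's
   patch before births; the realized litter is Poisson. Genotype-dependent
   fates (below) are applied at conception/birth.
4. **Natal dispersal.** Every newborn relocates, unconditionally, to a
   uniform in-bounds patch within `D` of its natal patch.
5. **Survival.** Individuals born in earlier cycles survive independently
   with probability `s·c`, where `c` is the control modifier (1 outside
   the toxicant window). Pups born this cycle are insulated from
   background mortality until their next cycle but are exposed to lethal
   control (they survive a treated cycle with probability `c`). See
   "Interpretation choices".
6. **Breeding dispersal.** Adults move with probability
   `p_move = m_min + (m_max − m_min)·max(0, 1 − N/K)`, relocating
   uniformly within `D`.

Survivors then age by one cycle. All neighborhoods are truncated at the
island edge (no wrap-around), and a destination draw includes the current
patch. Density for the movement rule counts conspecifics other than the
focal animal, so a lone adult moves at exactly `m_max`; density for the
fertility rule is total patch occupancy.

## Genetic biocontrol mechanisms

Genotypes are five classes: wild type (WT), fsRIDL heterozygote/homozygote
(FS1/FS2), Y-linked editor carrier (YE), Gravid Lethal carrier (GL).
Released males are FS2, YE, or GL; they are adult, fertile, and subject to
normal survival from their release cycle onward.

- **fsRIDL**: a homozygous sire transmits one construct copy to every pup;
  a heterozygous sire to half. Daughters carrying a copy die before
  entering the population (counted as births and as female-lethality
  deaths in the same cycle); carrier sons are viable and fertile, so the
  construct persists for a few generations but, lacking drive, disappears
  once releases stop.
- **Y-linked editor**: modeled phenomenologically — every daughter of a
  carrier male is sterile (viable, occupying habitat and competing for
  matings); every son carries the Y cargo. Edited autosomal/X alleles are
  not tracked separately, since sons carry the Y element regardless.
- **Gravid Lethal**: a dam that conceives at least one embryo sired by a
  carrier dies during gestation, producing nothing that cycle; she is
  removed before the survival step. A GL-mated female whose litter draw is
  zero survives. Under polyandry with mate set {WT, GL} and litter size
  L, P(dam dies) = 1 − (1/2)^L — the mechanism *benefits* from polyandry,
  unlike fsRIDL and the Y editor, which polyandry undermines by letting
  wild-type sires keep producing wild-type pups. No GL pup is ever born,
  so the strategy leaves no genetic trace.

## Interventions

**Toxicant.** During a 1-year window (6 cycles) following the 8-year
burn-in, per-cycle survival is scaled by `c_s` (0.15 or 0.2): survival of
previously-born animals becomes `s·c_s`, and newborn pups survive their
birth cycle with probability `c_s`. This removes well over 99% of the
population and leaves a remnant of a few tens of mice.

**Releases.** Release sites form an evenly spaced `√n_p × √n_p` lattice
(site k at `floor((k + 0.5)·extent/√n_p)` per axis). Events occur every
other cycle starting the cycle after the toxicant window ends, `n_i`
times, adding `N_i` males per selected site. Strategies: *broad* (all
sites), *tactical* (sites where any mouse was detected in the previous
cycle), *tactical when-detected* (sites where a wild-type mouse was
detected). Within a cycle the order is: release (using the previous
cycle's detections), then monitoring records, then the six demographic
steps; monitoring begins one cycle before the first event so the first
tactical release is detection-conditioned like all others.

**Monitoring.** Detection is perfect within monitored patches (a
`detection_prob` hook exists, default 1). Wild-type detection counts
fertile wild-type animals only: the sterile daughters of Y-editor males
carry detectable edits and would not read as wild type to a
discriminating eDNA assay.

## Outcomes

A replicate runs burn-in → toxicant → releases to a 200-cycle horizon.
Replicates whose post-toxicant census is zero are excluded and redrawn:
the study question is what biocontrol adds when the toxicant alone fails.
**Eradication** means zero individuals of *any* genotype; because released
males are self-limiting, an empty island stays empty once no future event
can restock it, and the runner exits early at that point. Time to
eradication is measured in years from the first scheduled release event
(the wild-type extinction time is logged separately). Per-cycle logs
satisfy the exact bookkeeping identity
`N(t+1) = N(t) + births − deaths + releases`, enforced at runtime.

## Parameters, defaults, and calibration

| Parameter | Meaning | Default | Basis |
|---|---|---|---|
| `n_c` | cycles per year | 6 | fixed by the study design |
| `D` | search/dispersal radius (patches) | 1 (variants 1, 3) | 140–280 m |
| `p_r` | P(female breeds per cycle) | 0.8 (variants 0.6, 0.8) | showcased value |
| `p_m` | P(second mate) | 0.8 (variants 0, 0.5, 0.8) | showcased value |
| `c_s` | toxicant survival scaling | 0.2 (variants 0.15, 0.2) | study values |
| `s` | per-cycle survival | 0.55 | calibrated, see below |
| `litter_mean` | max expected litter | 8 | calibrated, see below |
| `maturity_cycles` | cycles to adulthood | 1 | mice breed at ~2 months |
| `K` | per-patch carrying capacity | 49.7 | calibrated to the 11,000 equilibrium |
| `m_min`, `m_max` | movement prob. at high/zero density | 0.1, 0.9 | qualitative density rule |

The demographic rates that the published description leaves unspecified
(`s`, `litter_mean`, `K`) were treated as calibration parameters and
pinned, once, against three printed anchors of the study system, in this
order: (i) the burn-in must equilibrate at ~11,000 mice (sets `K` via
`experiments.calibrate_K`, a bisection whose bracket comes from the
logistic equilibrium bound); (ii) six treated cycles at `c_s = 0.2` must
leave a remnant of a few tens of mice that can rebound if left alone
(sets the fecundity side: `litter_mean = 8`, at the upper end of wild
house-mouse litters); (iii) the decay of the standing release cohort must
reproduce the ~5.8-year broad-release eradication lag at the top effort
corner, which is governed almost entirely by `s` (a cohort of ~1,900
standing males must vanish ~13 cycles after the last event; `s = 0.55`
per 2-month cycle, plausible for wild island mice). These three anchors
identify the three free rates nearly independently, and all other
reported quantities are out-of-sample with respect to this calibration.

The pooled "life-history variant" set crosses `D ∈ {1,3}`,
`c_s ∈ {0.15, 0.2}`, `p_r ∈ {0.6, 0.8}`, `p_m ∈ {0, 0.5, 0.8}` — 24
variants; with 18 effort combinations and 3 release strategies this gives
the 1296 parameter combinations of the full factorial (× 3 genetic
strategies × 30 replicates = 116,640 runs). The `p_r`/`p_m` level sets
are a reconstruction: only the showcased values (0.8, 0.8) are published.

## Interpretation choices

- **Toxicant semantics.** "Survival scaled by `c_s`" is implemented as
  multiplying per-cycle survival by `c_s` (an 80–85% cut in survivors per
  treated cycle). The milder reading (multiply by `1 − c_s`) cannot knock
  11,000 mice down to tens within six cycles under any plausible
  demography and was rejected; a config flag is unnecessary since the two
  readings are related by `c_s ↦ 1 − c_s`.
- **Newborn survival.** The survival step applies to animals born in
  earlier cycles; pups are insulated from background mortality in their
  birth cycle (their early mortality is already folded into the realized
  litter) but exposed to lethal control. Applying full background
  mortality to birth-cycle pups as well makes the knockdown so strong
  that the toxicant alone almost always eradicates, contradicting the
  premise of the exercise; exempting pups from the toxicant entirely
  makes the knockdown fail. The asymmetric rule is the only one of the
  three consistent with both anchors.
- **Eradication accounting** includes released males: under broad release
  the clock runs until the last transgenic male dies, which is why
  detection-conditioned strategies (which stop releasing once wild-type
  mice disappear) are ~3× faster at the same effort corner despite
  releasing two orders of magnitude fewer animals.

## Randomness and determinism

Each run has one root seed; at the top of every cycle the generator is
reseeded from `(seed, cycle)` (a `SeedSequence` over the pair), so cycles
have independent substreams and any step reordering changes the log.
Replicate seeds derive from `SeedSequence((root, combo, variant, rep,
attempt))` and are deliberately independent of the release and genetic
strategy, so strategies are compared on matched seeds (identical
burn-in and knockdown trajectories). Identical config + seed reproduces
the per-cycle log bit for bit.

## Problem sizes used in tests and the acceptance script

The packaged summaries run 72 pooled replicates per effort-cube cell
(3 per variant × 24 variants) — the package's chosen replicate count for
stable medians with binomial error ≈ 0.03 on probabilities — plus an 8 × 8
"mini" island fixture (burn-in equilibrium ≈ 700; its culling level is
0.35 so the small population reliably leaves a remnant) for fast
structural tests. The full 116,640-run factorial is enumerable through
`lastmile grid` but is not executed by the test suite.

## What the generator emulates, and what it does not

The synthetic island reproduces the study conditions: homogeneous
habitat, uniform founder placement, demographic equilibrium before
control, spatially uniform culling, perfect monitoring at release sites.
Real eradications violate most of these — terrain-driven habitat
heterogeneity, bait-shy survivors clustered in refugia, imperfect and
costly detection, seasonal breeding. Passing tests therefore validate the
mechanisms and their interactions, not field-level forecasts for a
specific island.

## Known limitations

- The realized release total under the *when-detected* strategy is the
  quantity most sensitive to the unpublished life-history level sets: it
  counts site-by-cycle wild-type detections, so it scales with both the
  remnant's size and its persistence. Under this reconstruction the
  weaker variants (low `p_r`, `c_s = 0.15`) leave remnants of only a few
  animals that vanish after one or two small releases, pulling the pooled
  median release total to ~10² where stronger variants sit at ~4×10²;
  conditioning on eradication compounds this, because runs with large,
  persistent remnants are the ones that fail. Median times are robust to
  this; the when-detected release total is not.
- Transgene fitness costs, resistance evolution, bait uptake, seasonal
  breeding, and age-structured fecundity beyond the maturity threshold
  are not modeled.
- The Y-editor model does not track edited non-Y alleles through sons
  separately from the Y cargo.
- The sensitivity surrogate (standardized logistic main effects +
  permutation importance) measures main-effect influence; strong
  interactions between effort axes are summarized only through their
  marginal contributions.
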