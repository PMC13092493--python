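"""Genotypes, inheritance, and the three self-limiting biocontrol mechanisms.

The simulator tracks three non-driving genetic biocontrol constructs carried
by released males:

* **fsRIDL** (female-specific Repressible Inducible Dominant Lethal):
  released males are homozygous for an autosomal dominant construct; every
  daughter inheriting at least one copy dies before entering the population,
  while sons carrying the construct are viable and fertile and keep
  transmitting it.
* **Y-linked editor**: a Y-chromosome cargo acting in the paternal germline.
  Every daughter of a carrier male is sterile (but viable); every son is a
  carrier.  Modeled phenomenologically: sterility travels with paternal
  carrier status, edited non-Y alleles are not tracked separately.
* **Gravid Lethal**: embryos sired by a carrier male express a transgene
  that kills the pregnant dam.  A female that conceives at least one such
  embryo dies producing nothing; elimination acts within the release
  generation and leaves no genetic trace, because no carrier pup is ever
  born.

Genotypes are represented two ways: a frozen :class:`Genotype` dataclass for
the per-individual API, and small integer codes (``WT/FS1/FS2/YE/GL``) used
by the vectorized population engine.  :func:`batch_fates` is the array
counterpart of :func:`inherit` and the two are cross-checked in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Strategy",
    "Genotype",
    "GenotypeFate",
    "MatingRecord",
    "WT",
    "FS1",
    "FS2",
    "YE",
    "GL",
    "CLASS_CODES",
    "code_of",
    "genotype_of",
    "released_genotype",
    "released_code",
    "inherit",
    "resolve_litter",
    "is_fertile",
    "batch_fates",
]


class Strategy(str, Enum):
    """Genetic biocontrol strategy (``WT`` denotes no construct)."""

    WT = "WT"
    FSRIDL = "FSRIDL"
    Y_EDITOR = "Y_EDITOR"
    GRAVID_LETHAL = "GRAVID_LETHAL"


# Integer genotype classes used by the array engine and in logs.
WT, FS1, FS2, YE, GL = 0, 1, 2, 3, 4
CLASS_CODES = ("WT", "FS1", "FS2", "YE", "GL")


@dataclass(frozen=True)
class Genotype:
    """Genetic state of one individual.

    ``autosomal_copies`` is the fsRIDL transgene dose (0, 1 or 2);
    ``y_linked`` marks Y-editor carrier males; ``gl_carrier`` marks Gravid
    Lethal males.  Wild type has all fields at zero/false.
    """

    strategy: Strategy = Strategy.WT
    autosomal_copies: int = 0
    y_linked: bool = False
    gl_carrier: bool = False

    def __post_init__(self) -> None:
        if self.strategy == Strategy.WT and (
            self.autosomal_copies or self.y_linked or self.gl_carrier
        ):
            raise ValueError("wild type carries no transgene fields")
        if self.autosomal_copies not in (0, 1, 2):
            raise ValueError("autosomal_copies must be 0, 1 or 2")

    @property
    def is_wild_type(self) -> bool:
        return not (self.autosomal_copies or self.y_linked or self.gl_carrier)


@dataclass(frozen=True)
class GenotypeFate:
    """Outcome of a single conception.

    ``viable=False`` means the pup is never instantiated (fsRIDL daughters).
    ``sterile`` is only ever true for females (Y-editor daughters).
    ``embryo_transgenic`` flags a Gravid Lethal embryo whose litter-level
    consequence (maternal death) is applied in :func:`resolve_litter`.
    """

    genotype: Genotype
    viable: bool
    sterile: bool
    embryo_transgenic: bool = False


@dataclass(frozen=True)
class MatingRecord:
    """One mated female and her one or two co-located mates."""

    dam: int
    mates: tuple[int, ...]
    patch: tuple[int, int]

    def __post_init__(self) -> None:
        if not 1 <= len(self.mates) <= 2:
            raise ValueError("a mating involves one or two mates")
        if len(set(self.mates)) != len(self.mates):
            raise ValueError("mates must be distinct")


_WILD = Genotype()
_BY_CODE = {
    WT: _WILD,
    FS1: Genotype(Strategy.FSRIDL, autosomal_copies=1),
    FS2: Genotype(Strategy.FSRIDL, autosomal_copies=2),
    YE: Genotype(Strategy.Y_EDITOR, y_linked=True),
    GL: Genotype(Strategy.GRAVID_LETHAL, gl_carrier=True),
}


def code_of(g: Genotype) -> int:
    """Map a :class:`Genotype` to its engine/log class code."""
    if g.gl_carrier:
        return GL
    if g.y_linked:
        return YE
    if g.autosomal_copies == 2:
        return FS2
    if g.autosomal_copies == 1:
        return FS1
    return WT


def genotype_of(code: int) -> Genotype:
    return _BY_CODE[int(code)]


def released_genotype(strategy: Strategy) -> Genotype:
    """Genotype carried by release-cohort males of a given strategy."""
    if strategy == Strategy.FSRIDL:
        return _BY_CODE[FS2]
    if strategy == Strategy.Y_EDITOR:
        return _BY_CODE[YE]
    if strategy == Strategy.GRAVID_LETHAL:
        return _BY_CODE[GL]
    raise ValueError(f"no release genotype for strategy {strategy!r}")


def released_code(strategy: Strategy) -> int:
    return code_of(released_genotype(strategy))


def inherit(
    strategy: Strategy,
    sire: Genotype,
    dam: Genotype,
    pup_sex: str,
    rng: np.random.Generator,
) -> GenotypeFate:
    """Resolve one conception from a (sire, dam) cross.

    ``pup_sex`` is ``"F"`` or ``"M"``.  The dam must be fertile (sterile
    females are filtered by the caller); dams never carry an fsRIDL copy
    because carrier daughters die before breeding.
    """
    if pup_sex not in ("F", "M"):
        raise ValueError("pup_sex must be 'F' or 'M'")
    if dam.autosomal_copies:
        raise ValueError("a breeding dam cannot carry an fsRIDL copy")

    female = pup_sex == "F"

    # fsRIDL: Mendelian segregation of the paternal autosomal construct.
    copies = 0
    if sire.autosomal_copies == 2:
        copies = 1
    elif sire.autosomal_copies == 1:
        copies = int(rng.random() < 0.5)
    if copies:
        geno = Genotype(Strategy.FSRIDL, autosomal_copies=copies)
        # dominant female-specific lethality acts before birth
        return GenotypeFate(geno, viable=not female, sterile=False)

    # Y-linked editor: sons inherit the Y cargo, daughters are sterilized
    # by paternal germline editing.
    if sire.y_linked:
        if female:
            return GenotypeFate(_WILD, viable=True, sterile=True)
        return GenotypeFate(
            Genotype(Strategy.Y_EDITOR, y_linked=True), viable=True, sterile=False
        )

    # Gravid Lethal: the embryo is flagged; maternal death is a litter-level
    # event applied in resolve_litter, and the pup itself is never born.
    if sire.gl_carrier:
        return GenotypeFate(
            Genotype(Strategy.GRAVID_LETHAL, gl_carrier=True),
            viable=True,
            sterile=False,
            embryo_transgenic=True,
        )

    return GenotypeFate(_WILD, viable=True, sterile=False)


def resolve_litter(
    strategy: Strategy,
    dam: Genotype,
    mates: list[Genotype],
    litter_size: int,
    rng: np.random.Generator,
) -> tuple[list[GenotypeFate], bool]:
    """Assign sires and fates across one litter.

    Each pup's sire is drawn uniformly from the dam's mate set (mixed
    paternity under polyandry).  Returns the surviving pups and whether the
    dam dies.  The dam dies iff at least one conceived embryo is Gravid
    Lethal transgenic, in which case the whole litter is lost; with a litter
    of zero she survives.
    """
    if not mates:
        raise ValueError("mate set must be non-empty")
    if litter_size < 0:
        raise ValueError("litter_size must be >= 0")

    fates: list[GenotypeFate] = []
    dam_dies = False
    for _ in range(litter_size):
        sire = mates[int(rng.integers(len(mates)))]
        sex = "F" if rng.random() < 0.5 else "M"
        fate = inherit(strategy, sire, dam, sex, rng)
        if fate.embryo_transgenic:
            dam_dies = True
        fates.append(fate)
    if dam_dies:
        return [], True
    return [f for f in fates if f.viable], False


def is_fertile(individual) -> bool:
    """Fertility predicate: transgenic males of every strategy are fertile;
    only the ``sterile`` flag (Y-editor daughters) blocks mating."""
    return not individual.sterile


def batch_fates(
    sire_codes: np.ndarray,
    pup_is_female: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`inherit` over one cycle's conceptions.

    Parameters are the per-pup paternal genotype codes and pup sexes.
    Returns ``(codes, viable, sterile, embryo_transgenic)`` arrays; Gravid
    Lethal litter pruning and maternal death are handled by the caller,
    which knows the dam of each pup.
    """
    n = sire_codes.size
    codes = np.zeros(n, dtype=np.int8)
    viable = np.ones(n, dtype=bool)
    sterile = np.zeros(n, dtype=bool)
    embryo = np.zeros(n, dtype=bool)
    if n == 0:
        return codes, viable, sterile, embryo

    carries = (sire_codes == FS2) | ((sire_codes == FS1) & (rng.random(n) < 0.5))
    codes[carries] = FS1
    viable &= ~(carries & pup_is_female)

    ye_sire = sire_codes == YE
    codes[ye_sire & ~pup_is_female] = YE
    sterile |= ye_sire & pup_is_female

    gl_sire = sire_codes == GL
    codes[gl_sire] = GL
    embryo |= gl_sire

    return codes, viable, sterile, embryo
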