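"""Domain types and the ordered-tetrad meiosis engine.

The model follows the classical genetics of perithecial fungi.  One meiosis
produces four haploid products arranged as two first-division (MI) poles of
two products each; a post-meiotic mitosis duplicates every product, giving
eight nuclei per ascus.  For a heterozygous locus the two alleles always
segregate 2:2 among the four products; what varies is *when* they separate:

* **FDS** (first-division segregation): no crossover between the locus and
  its centromere, so each MI pole is pure for one parental allele.
* **SDS** (second-division segregation): a crossover places one allele of
  each parent in every pole.  The SDS frequency ``s`` grows with the
  locus-centromere map distance, up to the theoretical ceiling of 2/3.

Two packaging modes are supported.  In the *Podospora*-style binucleate
tetrad, each ascospore encloses the two distinct products of one MI pole, so
an FDS locus yields homokaryotic spores while an SDS locus makes all four
spores heterokaryotic.  In the *Sordaria*-style uninucleate octad every
nucleus becomes its own spore and heterokaryosis is impossible.

Two linkage modes are provided:

* *phenomenological* (default): each locus draws FDS/SDS with its own
  probability ``s``; the parental phase of same-chromosome loci is coupled
  through pairwise recombination fractions (see
  :func:`phase_conditional`).
* *mechanistic*: crossovers are placed by a Poisson process on an interval
  map with no interference, two of four chromatids chosen uniformly per
  crossover; SDS frequencies and recombination fractions then emerge, with
  the closed form ``s(x) = (2/3)(1 - exp(-3x))`` at map length ``x`` Morgans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, ParameterError

# Parental-origin vectors over the four meiotic products.  Products 0,1 form
# MI pole one; products 2,3 form pole two.  A heterozygous locus always shows
# a 2:2 vector; pole-pure vectors are FDS, pole-mixed vectors are SDS.
Vector = Tuple[int, int, int, int]
FDS_VECTORS: Tuple[Vector, ...] = ((0, 0, 1, 1), (1, 1, 0, 0))
SDS_VECTORS: Tuple[Vector, ...] = ((0, 1, 0, 1), (0, 1, 1, 0), (1, 0, 0, 1), (1, 0, 1, 0))
ALL_VECTORS: Tuple[Vector, ...] = FDS_VECTORS + SDS_VECTORS

BINUCLEATE_TETRAD = "binucleate_tetrad"
UNINUCLEATE_OCTAD = "uninucleate_octad"
PACKAGING_MODES = (BINUCLEATE_TETRAD, UNINUCLEATE_OCTAD)

PHENOMENOLOGICAL = "phenomenological"
MECHANISTIC = "mechanistic"
CROSSOVER_MODELS = (PHENOMENOLOGICAL, MECHANISTIC)

SDS_CEILING = 2.0 / 3.0


def _as_frozenset(value: Optional[Iterable[str]]) -> FrozenSet[str]:
    if value is None:
        return frozenset()
    return frozenset(value)


@dataclass(frozen=True)
class Allele:
    """One allele of the drive rule system.

    ``distorter_active`` marks a killer ("toxin") activity.
    ``responder_covers`` lists the distorter allele ids this allele protects
    a spore against — for wild-type spore-killer genes this includes the
    allele itself.  If ``trans_activators`` is non-empty, the responder is
    dormant unless at least one activator allele is present anywhere in the
    zygote (the behaviour of N-terminally tagged and active-site-mutant
    killer alleles, which kill but only resist in the presence of a
    wild-type copy).  ``pigment_functional`` marks a working copy of the
    spore-pigmentation gene whose locus doubles as a dominant colour marker.
    ``killing_efficiency`` is the per-spore probability that an uncovered
    copy of this distorter kills; the default of 1.0 reproduces the
    all-or-none spore death observed in real asci.
    """

    id: str
    locus_id: str
    distorter_active: bool = False
    responder_covers: FrozenSet[str] = frozenset()
    trans_activators: FrozenSet[str] = frozenset()
    pigment_functional: bool = False
    selectable_markers: FrozenSet[str] = frozenset()
    killing_efficiency: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "responder_covers", _as_frozenset(self.responder_covers))
        object.__setattr__(self, "trans_activators", _as_frozenset(self.trans_activators))
        object.__setattr__(self, "selectable_markers", _as_frozenset(self.selectable_markers))
        if not 0.0 <= self.killing_efficiency <= 1.0:
            raise ParameterError(
                f"killing_efficiency of allele {self.id!r} must be in [0, 1]"
            )


@dataclass(frozen=True)
class Locus:
    """A genetic locus with its second-division segregation probability.

    ``sds_prob`` is the per-meiosis probability ``s`` that the locus shows
    SDS; it is the quantity tetrad analysis estimates and maps to
    centromere distance.  ``position_morgans`` (distance from the
    centromere) is used only by the mechanistic crossover model.
    """

    id: str
    chromosome: str
    sds_prob: float
    position_morgans: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.sds_prob <= 1.0:
            raise ParameterError(f"sds_prob of locus {self.id!r} must be in [0, 1]")
        if self.position_morgans is not None and self.position_morgans < 0:
            raise ParameterError(f"position_morgans of locus {self.id!r} must be >= 0")


@dataclass(frozen=True)
class Haplotype:
    """A set of nuclear alleles, one per locus (a strain or a meiotic product).

    Absence of a gene at a locus is itself an allele (an "empty-site"
    allele), so every locus of a cross has exactly one allele per haplotype.
    """

    strain_id: str
    alleles: Mapping[str, str]

    def allele_at(self, locus_id: str) -> str:
        return self.alleles[locus_id]


@dataclass
class Spore:
    """An ascospore: one or two nuclei plus phenotype flags.

    ``viable`` and ``pigmented`` start unset and are assigned only by the
    killing and pigmentation operations.
    """

    nuclei: Tuple[Haplotype, ...]
    viable: Optional[bool] = None
    pigmented: Optional[bool] = None

    def allele_ids(self) -> FrozenSet[str]:
        return frozenset(a for n in self.nuclei for a in n.alleles.values())

    def is_homokaryotic(self, locus_id: str) -> bool:
        first = self.nuclei[0].alleles[locus_id]
        return all(n.alleles[locus_id] == first for n in self.nuclei[1:])


@dataclass
class Ascus:
    """The ordered product of one meiosis: 4 binucleate or 8 uninucleate spores."""

    spores: List[Spore]
    sds_pattern: Dict[str, str]  # locus id -> "FDS" | "SDS"

    def nuclei(self) -> List[Haplotype]:
        return [n for s in self.spores for n in s.nuclei]


def _normalise_linkage(linkage: Optional[Mapping]) -> Dict[FrozenSet[str], float]:
    out: Dict[FrozenSet[str], float] = {}
    if not linkage:
        return out
    for key, r in linkage.items():
        pair = frozenset(key)
        if len(pair) != 2:
            raise ConfigurationError(f"linkage key {key!r} must name two distinct loci")
        if not 0.0 <= r <= 0.5:
            raise ConfigurationError(f"recombination fraction for {sorted(pair)} must be in [0, 0.5]")
        out[pair] = float(r)
    return out


@dataclass
class CrossSpec:
    """Everything needed to simulate or enumerate one cross.

    ``alleles`` is the declaration table for every allele id the cross may
    reference (including ids that appear only in responder-coverage sets).
    ``linkage`` holds pairwise recombination fractions for same-chromosome
    loci; pairs not listed default to r = 0.5, and loci on different
    chromosomes always assort independently.
    """

    parent1: Haplotype
    parent2: Haplotype
    loci: Tuple[Locus, ...]
    alleles: Mapping[str, Allele]
    linkage: Mapping = field(default_factory=dict)
    packaging: str = BINUCLEATE_TETRAD
    n_asci: int = 1000
    seed: int = 0
    crossover_model: str = PHENOMENOLOGICAL
    name: str = ""

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        self.linkage = _normalise_linkage(self.linkage)
        if self.packaging not in PACKAGING_MODES:
            raise ConfigurationError(f"unknown packaging mode {self.packaging!r}")
        if self.crossover_model not in CROSSOVER_MODELS:
            raise ConfigurationError(f"unknown crossover model {self.crossover_model!r}")
        locus_ids = {l.id for l in self.loci}
        if len(locus_ids) != len(self.loci):
            raise ConfigurationError("duplicate locus ids in cross")
        for parent in (self.parent1, self.parent2):
            missing = locus_ids - set(parent.alleles)
            if missing:
                raise ConfigurationError(
                    f"haplotype {parent.strain_id!r} lacks alleles at loci {sorted(missing)}"
                )
        declared = set(self.alleles)
        for parent in (self.parent1, self.parent2):
            for lid in locus_ids:
                aid = parent.alleles[lid]
                if aid not in declared:
                    raise ConfigurationError(
                        f"allele {aid!r} of {parent.strain_id!r} is not declared in the cross"
                    )
                if self.alleles[aid].locus_id != lid:
                    raise ConfigurationError(
                        f"allele {aid!r} is declared at locus "
                        f"{self.alleles[aid].locus_id!r}, not {lid!r}"
                    )
        for allele in self.alleles.values():
            undeclared = (allele.responder_covers | allele.trans_activators) - declared
            if undeclared:
                raise ConfigurationError(
                    f"allele {allele.id!r} references undeclared allele ids {sorted(undeclared)}"
                )
        if self.crossover_model == MECHANISTIC:
            for locus in self.loci:
                if locus.position_morgans is None:
                    raise ConfigurationError(
                        f"mechanistic mode needs position_morgans for locus {locus.id!r}"
                    )
        if self.n_asci <= 0:
            raise ParameterError("n_asci must be positive")

    # -- convenience ---------------------------------------------------
    def locus(self, locus_id: str) -> Locus:
        for locus in self.loci:
            if locus.id == locus_id:
                return locus
        raise KeyError(locus_id)

    def is_heterozygous(self, locus_id: str) -> bool:
        return self.parent1.alleles[locus_id] != self.parent2.alleles[locus_id]

    def heterozygous_loci(self) -> Tuple[Locus, ...]:
        return tuple(l for l in self.loci if self.is_heterozygous(l.id))

    def recombination_fraction(self, a: str, b: str) -> float:
        la, lb = self.locus(a), self.locus(b)
        if la.chromosome != lb.chromosome:
            return 0.5
        return self.linkage.get(frozenset((a, b)), 0.5)

    def chromosome_chains(self) -> List[List[Locus]]:
        """Loci grouped by chromosome in map order (position, else declaration)."""
        groups: Dict[str, List[Tuple[int, Locus]]] = {}
        for idx, locus in enumerate(self.loci):
            groups.setdefault(locus.chromosome, []).append((idx, locus))
        chains = []
        for chrom in sorted(groups):
            entries = groups[chrom]
            if all(l.position_morgans is not None for _, l in entries):
                entries.sort(key=lambda e: (e[1].position_morgans, e[0]))
            else:
                entries.sort(key=lambda e: e[0])
            chains.append([l for _, l in entries])
        return chains


# ---------------------------------------------------------------------------
# Tetrad mapping closed forms (Poisson crossovers, no interference)
# ---------------------------------------------------------------------------

def sds_from_map_length(x: float) -> float:
    """SDS frequency at centromere-locus map length ``x`` Morgans."""
    if x < 0:
        raise ParameterError("map length must be >= 0")
    return SDS_CEILING * (1.0 - math.exp(-3.0 * x))


def map_length_from_sds(s: float) -> float:
    """Invert :func:`sds_from_map_length`; requires ``s < 2/3``."""
    if not 0.0 <= s < SDS_CEILING:
        raise ParameterError("SDS frequency must be in [0, 2/3) for a finite map length")
    return -math.log(1.0 - s / SDS_CEILING) / 3.0


def haldane_r(d: float) -> float:
    """Recombination fraction for map distance ``d`` Morgans (Haldane)."""
    if d < 0:
        raise ParameterError("map distance must be >= 0")
    return 0.5 * (1.0 - math.exp(-2.0 * d))


# ---------------------------------------------------------------------------
# Phenomenological segregation model
# ---------------------------------------------------------------------------

def phase_conditional(
    s: float, r: float = 0.5, prev: Optional[Vector] = None
) -> Tuple[Tuple[Vector, ...], np.ndarray]:
    """Distribution of a locus's parental-origin vector.

    The FDS/SDS *pattern type* is drawn with the locus's own probability
    ``s`` regardless of its neighbours.  The *phase* within the type (which
    pole, which chromatid) is coupled to the previous locus on the same
    chromosome: within each type, a vector ``v`` is weighted by
    ``r**d * (1-r)**(4-d)`` where ``d`` counts meiotic products whose
    parental origin differs between the two loci, i.e. per-product
    recombination with probability ``r`` conditioned on the drawn type.
    At r = 0.5 all phases are equally likely and loci are independent, the
    regime used for loci on different chromosomes or far apart.
    """
    if not 0.0 <= s <= 1.0:
        raise ParameterError("SDS probability must be in [0, 1]")
    if not 0.0 <= r <= 0.5:
        raise ParameterError("recombination fraction must be in [0, 0.5]")
    probs = np.empty(len(ALL_VECTORS))
    if prev is None:
        probs[:2] = (1.0 - s) / 2.0
        probs[2:] = s / 4.0
        return ALL_VECTORS, probs
    weights = np.array(
        [
            (r ** d) * ((1.0 - r) ** (4 - d))
            for d in (sum(a != b for a, b in zip(v, prev)) for v in ALL_VECTORS)
        ]
    )
    fds_w, sds_w = weights[:2], weights[2:]
    # At r == 0 a pattern-type change relative to the neighbour has zero
    # weight everywhere; fall back to a uniform phase within the drawn type.
    if fds_w.sum() == 0.0:
        fds_w = np.ones_like(fds_w)
    if sds_w.sum() == 0.0:
        sds_w = np.ones_like(sds_w)
    probs[:2] = (1.0 - s) * fds_w / fds_w.sum()
    probs[2:] = s * sds_w / sds_w.sum()
    return ALL_VECTORS, probs


@lru_cache(maxsize=4096)
def _phase_cumulative(s: float, r: float, prev: Optional[Vector]) -> np.ndarray:
    _, probs = phase_conditional(s, r, prev)
    return np.cumsum(probs)


def sample_origin_vectors(cross: CrossSpec, rng: np.random.Generator) -> Dict[str, Vector]:
    """Draw one parental-origin vector per locus for a single meiosis."""
    vectors: Dict[str, Vector] = {}
    for chain in cross.chromosome_chains():
        prev_vec: Optional[Vector] = None
        prev_id: Optional[str] = None
        for locus in chain:
            r = 0.5 if prev_id is None else cross.recombination_fraction(prev_id, locus.id)
            cum = _phase_cumulative(locus.sds_prob, r, prev_vec)
            idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
            prev_vec = ALL_VECTORS[min(idx, len(ALL_VECTORS) - 1)]
            prev_id = locus.id
            vectors[locus.id] = prev_vec
    return vectors


# ---------------------------------------------------------------------------
# Mechanistic crossover model
# ---------------------------------------------------------------------------

def _mechanistic_chain_vectors(
    chain: Sequence[Locus], rng: np.random.Generator
) -> Dict[str, Vector]:
    """Simulate one bivalent with Poisson crossovers and read off origins.

    Chromatids 0,1 are sisters attached to the parent-1 centromere, 2,3 to
    the parent-2 centromere; MI sends 0,1 to pole one and 2,3 to pole two.
    Each crossover picks one chromatid per homolog uniformly (no chromatid
    interference) and exchanges everything distal to its position.
    """
    arm_length = max(l.position_morgans for l in chain)  # type: ignore[type-var]
    origins = {}
    current = [0, 0, 1, 1]
    events: List[Tuple[float, int, int]] = []
    if arm_length > 0:
        n_events = rng.poisson(2.0 * arm_length)
        positions = rng.uniform(0.0, arm_length, size=n_events)
        chroms1 = rng.integers(0, 2, size=n_events)
        chroms2 = rng.integers(2, 4, size=n_events)
        events = sorted(zip(positions.tolist(), chroms1.tolist(), chroms2.tolist()))
    loci_sorted = sorted(chain, key=lambda l: l.position_morgans)  # type: ignore[arg-type]
    ev = 0
    for locus in loci_sorted:
        pos = locus.position_morgans
        while ev < len(events) and events[ev][0] < pos:
            _, a, b = events[ev]
            current[a], current[b] = current[b], current[a]
            ev += 1
        origins[locus.id] = tuple(current)
    return origins


# ---------------------------------------------------------------------------
# Meiosis + spore packaging
# ---------------------------------------------------------------------------

def simulate_meiosis(cross: CrossSpec, rng: np.random.Generator) -> Ascus:
    """Produce the pre-killing ascus of one meiosis.

    Viability and pigmentation are left unset; apply the killing engine and
    :func:`assign_pigment` afterwards.
    """
    if cross.crossover_model == MECHANISTIC:
        vectors = {}
        for chain in cross.chromosome_chains():
            vectors.update(_mechanistic_chain_vectors(chain, rng))
    else:
        vectors = sample_origin_vectors(cross, rng)
    return build_ascus(cross, vectors)


def build_ascus(cross: CrossSpec, vectors: Mapping[str, Vector]) -> Ascus:
    """Deterministically package an ascus from per-locus origin vectors."""
    parents = (cross.parent1.alleles, cross.parent2.alleles)
    products = []
    for i in range(4):
        alleles = {l.id: parents[vectors[l.id][i]][l.id] for l in cross.loci}
        products.append(Haplotype(strain_id=f"product{i}", alleles=alleles))
    sds_pattern = {
        lid: ("SDS" if vec[0] != vec[1] else "FDS") for lid, vec in vectors.items()
    }
    if cross.packaging == BINUCLEATE_TETRAD:
        spores = [
            Spore(nuclei=(products[0], products[1])),
            Spore(nuclei=(products[0], products[1])),
            Spore(nuclei=(products[2], products[3])),
            Spore(nuclei=(products[2], products[3])),
        ]
    else:
        spores = [Spore(nuclei=(products[i],)) for i in (0, 0, 1, 1, 2, 2, 3, 3)]
    return Ascus(spores=spores, sds_pattern=dict(sds_pattern))


def spore_pigment(spore: Spore, alleles: Mapping[str, Allele]) -> bool:
    """A spore is pigmented iff any nucleus carries a functional pigment allele.

    Pigmentation is dominant: a heterokaryotic spore with one wild-type
    pigment-gene nucleus is dark even when the other nucleus carries an
    insertion allele.
    """
    return any(
        alleles[aid].pigment_functional
        for nucleus in spore.nuclei
        for aid in nucleus.alleles.values()
    )


def assign_pigment(ascus: Ascus, alleles: Mapping[str, Allele]) -> Ascus:
    for spore in ascus.spores:
        spore.pigmented = spore_pigment(spore, alleles)
    return ascus
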