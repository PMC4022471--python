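"""Exact ascus-class distributions by exhaustive enumeration.

For a handful of segregating loci the whole sample space of one meiosis is
tiny: each locus takes one of six 2:2 parental-origin vectors, and the
phase-chain model assigns every joint configuration a probability.  Summing
the deterministic killing/pigmentation outcome over all configurations gives
the exact distribution over ascus classes — the brute-force oracle the Monte
Carlo simulator is checked against, and the source of the "exact" cross
predictions (a single heterozygous killer with SDS frequency ``s`` gives
2-spored asci with probability exactly ``1 - s``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from .errors import ConfigurationError, EnumerationSizeError
from .genetics import CrossSpec, Locus, Vector, build_ascus, assign_pigment, phase_conditional
from .killing import ZygoteContext, apply_spore_killing
from .simulate import AscusClass, classify_ascus

#: hard cap on heterozygous loci for exact enumeration
MAX_HETEROZYGOUS_LOCI = 3


@dataclass
class CrossDistribution:
    """Exact per-meiosis outcome distribution of a cross.

    ``class_probs`` sums to one over ascus classes.
    ``survivor_homokaryon_freqs`` gives, per locus, the distribution of
    alleles among surviving spores that are *homokaryotic at that locus* —
    the material actually scored when segregation ratios of survivors are
    reported.  ``expected_viable`` is the mean number of surviving spores
    per ascus.
    """

    cross_id: str
    class_probs: Dict[AscusClass, float]
    survivor_homokaryon_freqs: Dict[str, Dict[str, float]]
    survivor_carrier_freqs: Dict[str, Dict[str, float]]
    expected_viable: float

    def prob(self, n_viable: Optional[int] = None, n_pigmented: Optional[int] = None) -> float:
        total = 0.0
        for cls, p in self.class_probs.items():
            if n_viable is not None and cls.n_viable != n_viable:
                continue
            if n_pigmented is not None and cls.n_pigmented != n_pigmented:
                continue
            total += p
        return total

    def percent(self, **kwargs) -> float:
        return 100.0 * self.prob(**kwargs)


def _chain_states(
    cross: CrossSpec, chain: List[Locus]
) -> List[Tuple[Dict[str, Vector], float]]:
    """All joint origin-vector assignments for one chromosome with probabilities."""
    states: List[Tuple[Dict[str, Vector], float]] = [({}, 1.0)]
    prev_id: Optional[str] = None
    for locus in chain:
        new_states = []
        for assigned, prob in states:
            prev_vec = assigned[prev_id] if prev_id is not None else None
            r = 0.5 if prev_id is None else cross.recombination_fraction(prev_id, locus.id)
            vecs, probs = phase_conditional(locus.sds_prob, r, prev_vec)
            for vec, p in zip(vecs, probs):
                if p == 0.0:
                    continue
                nxt = dict(assigned)
                nxt[locus.id] = vec
                new_states.append((nxt, prob * p))
        states = new_states
        prev_id = locus.id
    return states


def enumerate_cross(cross: CrossSpec) -> CrossDistribution:
    """Exact distribution over ascus classes and survivor genotypes.

    Only chromosomes carrying at least one heterozygous locus contribute
    branching; fully homozygous chromosomes are collapsed to a single
    representative configuration.  Raises for more than
    ``MAX_HETEROZYGOUS_LOCI`` segregating loci or stochastic killing.
    """
    het = cross.heterozygous_loci()
    if len(het) > MAX_HETEROZYGOUS_LOCI:
        raise EnumerationSizeError(
            f"exact enumeration supports at most {MAX_HETEROZYGOUS_LOCI} "
            f"heterozygous loci, got {len(het)}"
        )
    ctx = ZygoteContext.from_cross(cross)
    if not ctx.deterministic:
        raise ConfigurationError(
            "exact enumeration requires killing efficiencies of exactly 1.0"
        )
    het_ids = {l.id for l in het}
    per_chrom: List[List[Tuple[Dict[str, Vector], float]]] = []
    for chain in cross.chromosome_chains():
        if any(l.id in het_ids for l in chain):
            per_chrom.append(_chain_states(cross, chain))
        else:
            # Homozygous chromosome: every configuration packages the same
            # alleles, so a single representative carries all the mass.
            rep = {l.id: (0, 0, 1, 1) for l in chain}
            per_chrom.append([(rep, 1.0)])

    class_probs: Dict[AscusClass, float] = {}
    homokaryon_mass: Dict[str, Dict[str, float]] = {l.id: {} for l in cross.loci}
    carrier_mass: Dict[str, Dict[str, float]] = {l.id: {} for l in cross.loci}
    expected_viable = 0.0
    for combo in itertools.product(*per_chrom):
        vectors: Dict[str, Vector] = {}
        prob = 1.0
        for assigned, p in combo:
            vectors.update(assigned)
            prob *= p
        ascus = build_ascus(cross, vectors)
        apply_spore_killing(ascus, ctx)
        assign_pigment(ascus, cross.alleles)
        cls = classify_ascus(ascus)
        class_probs[cls] = class_probs.get(cls, 0.0) + prob
        expected_viable += prob * cls.n_viable
        for spore in ascus.spores:
            if not spore.viable:
                continue
            for locus in cross.loci:
                alleles = {n.alleles[locus.id] for n in spore.nuclei}
                for aid in alleles:
                    bucket = carrier_mass[locus.id]
                    bucket[aid] = bucket.get(aid, 0.0) + prob
                if len(alleles) == 1:
                    aid = next(iter(alleles))
                    bucket = homokaryon_mass[locus.id]
                    bucket[aid] = bucket.get(aid, 0.0) + prob

    # Homokaryon frequencies are conditional on being homokaryotic at the
    # locus (each such spore carries exactly one allele there).  Carrier
    # frequencies are per-survivor probabilities of containing the allele,
    # so heterokaryotic spores count towards both alleles and the entries
    # need not sum to one.
    homokaryon_freqs: Dict[str, Dict[str, float]] = {}
    for lid, bucket in homokaryon_mass.items():
        total = sum(bucket.values())
        homokaryon_freqs[lid] = (
            {aid: m / total for aid, m in bucket.items()} if total else {}
        )
    carrier_freqs: Dict[str, Dict[str, float]] = {}
    for lid, bucket in carrier_mass.items():
        carrier_freqs[lid] = (
            {aid: m / expected_viable for aid, m in bucket.items()}
            if expected_viable
            else {}
        )

    return CrossDistribution(
        cross_id=cross.name or f"{cross.parent1.strain_id}x{cross.parent2.strain_id}",
        class_probs=class_probs,
        survivor_homokaryon_freqs=homokaryon_freqs,
        survivor_carrier_freqs=carrier_freqs,
        expected_viable=expected_viable,
    )
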