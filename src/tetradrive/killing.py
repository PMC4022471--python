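"""The distorter/responder survival rule.

Spore killing in the modelled system is a toxin-antitoxin game played out
inside one ascus.  Every *distorter-active* allele present in the zygote
poisons the whole ascus; a spore survives only if, for every such distorter,
at least one of its nuclei carries an allele whose responder covers that
distorter.  Both activities can sit on the same allele (a wild-type spore
killer covers itself), on a responder-only allele (a resistant non-killer),
or be decoupled the other way (a killer whose responder works only when
trans-activated by a wild-type copy elsewhere in the cross).

Killing is spore-autonomous and heterokaryotic rescue is complete: a single
resistant nucleus saves its spore, which is why second-division segregation
of a killer locus yields four surviving heterokaryotic spores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Mapping, Optional

import numpy as np

from .errors import ConfigurationError
from .genetics import Ascus, CrossSpec, Spore


@dataclass(frozen=True)
class ZygoteContext:
    """Allele content of the zygote with trans-activation resolved.

    ``resolved_covers`` maps every declared allele id to the distorter set
    it effectively protects against in *this* cross: an allele with
    trans-activation requirements contributes nothing unless one of its
    activators is present somewhere in the zygote.  Because both parents
    contribute to every ascus, a distorter carried by both parents is
    covered in every spore that model can build, so homozygous killers are
    automatically silent.
    """

    alleles_present: FrozenSet[str]
    active_distorters: FrozenSet[str]
    resolved_covers: Mapping[str, FrozenSet[str]]
    killing_efficiency: Mapping[str, float]

    @classmethod
    def from_cross(cls, cross: CrossSpec) -> "ZygoteContext":
        present = frozenset(
            cross.parent1.alleles[l.id] for l in cross.loci
        ) | frozenset(cross.parent2.alleles[l.id] for l in cross.loci)
        active = frozenset(
            aid for aid in present if cross.alleles[aid].distorter_active
        )
        resolved: Dict[str, FrozenSet[str]] = {}
        for aid, allele in cross.alleles.items():
            if allele.trans_activators and not (allele.trans_activators & present):
                resolved[aid] = frozenset()
            else:
                resolved[aid] = allele.responder_covers
        efficiency = {
            aid: cross.alleles[aid].killing_efficiency for aid in active
        }
        return cls(
            alleles_present=present,
            active_distorters=active,
            resolved_covers=resolved,
            killing_efficiency=efficiency,
        )

    @property
    def deterministic(self) -> bool:
        return all(e == 1.0 for e in self.killing_efficiency.values())


def effective_responders(spore: Spore, ctx: ZygoteContext) -> FrozenSet[str]:
    """Union of the distorters this spore's alleles protect it against."""
    covered: FrozenSet[str] = frozenset()
    for nucleus in spore.nuclei:
        for aid in nucleus.alleles.values():
            try:
                covered |= ctx.resolved_covers[aid]
            except KeyError:
                raise ConfigurationError(
                    f"allele {aid!r} is not declared in the zygote context"
                ) from None
    return covered


def apply_spore_killing(
    ascus: Ascus, ctx: ZygoteContext, rng: Optional[np.random.Generator] = None
) -> Ascus:
    """Set the viability of every spore in place and return the ascus.

    With the default killing efficiency of 1.0 the outcome is deterministic:
    a spore dies iff some active distorter is uncovered.  Sub-unit
    efficiencies make each uncovered distorter kill independently with its
    own probability, which is the only way odd spore counts can arise in
    the binucleate packaging (the two spores of one pole are genetically
    identical twins).
    """
    stochastic = not ctx.deterministic
    if stochastic and rng is None:
        raise ConfigurationError(
            "killing efficiencies below 1.0 require a random generator"
        )
    for spore in ascus.spores:
        uncovered = ctx.active_distorters - effective_responders(spore, ctx)
        if not uncovered:
            spore.viable = True
        elif not stochastic:
            spore.viable = False
        else:
            survive = 1.0
            for d in uncovered:
                survive *= 1.0 - ctx.killing_efficiency[d]
            spore.viable = bool(rng.random() < survive)
    return ascus
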