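"""Monte Carlo cross simulation and ascus classification.

``simulate_cross`` runs many independent meioses through the killing engine
and tallies asci by class — the phenotype a geneticist scores in a rosette:
how many spores survived and how many of the survivors are pigmented.  A
companion exact enumerator (:mod:`tetradrive.exact`) computes the same
distribution analytically and serves as the oracle the simulator is tested
against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .genetics import Ascus, CrossSpec, assign_pigment, simulate_meiosis
from .killing import ZygoteContext, apply_spore_killing

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class AscusClass:
    """An ascus class: number of viable spores and how many of them are dark."""

    n_viable: int
    n_pigmented: int

    @property
    def label(self) -> str:
        if self.n_viable == 0:
            return "empty"
        return f"{self.n_viable}-spored"


def classify_ascus(ascus: Ascus) -> AscusClass:
    """Classify an ascus after viability and pigmentation are assigned."""
    viable = [s for s in ascus.spores if s.viable]
    return AscusClass(
        n_viable=len(viable),
        n_pigmented=sum(1 for s in viable if s.pigmented),
    )


@dataclass
class AscusCountTable:
    """Raw counts of ascus classes for one simulated cross.

    Percentages are always derived from the raw counts with *all* asci —
    including empty ones — in the denominator, so any reporting convention
    can be recomputed downstream.
    """

    cross_id: str
    counts: Dict[AscusClass, int]
    n_asci: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_asci:
            raise ParameterError("ascus class counts must sum to n_asci")

    def fraction(
        self, n_viable: Optional[int] = None, n_pigmented: Optional[int] = None
    ) -> float:
        """Fraction of asci matching the given class filters (None = any)."""
        total = 0
        for cls, count in self.counts.items():
            if n_viable is not None and cls.n_viable != n_viable:
                continue
            if n_pigmented is not None and cls.n_pigmented != n_pigmented:
                continue
            total += count
        return total / self.n_asci

    def percent(self, **kwargs) -> float:
        return 100.0 * self.fraction(**kwargs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cross": self.cross_id,
                "class": cls.label,
                "n_viable": cls.n_viable,
                "n_pigmented": cls.n_pigmented,
                "count": count,
                "n_asci": self.n_asci,
                "seed": self.seed,
            }
            for cls, count in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)


def _survivor_records(
    cross: CrossSpec, ascus: Ascus, ascus_index: int, cls: AscusClass
) -> List[dict]:
    records = []
    for spore_index, spore in enumerate(ascus.spores):
        if not spore.viable:
            continue
        rec: dict = {
            "ascus": ascus_index,
            "spore": spore_index,
            "ascus_class": cls.label,
            "pigmented": bool(spore.pigmented),
        }
        for locus in cross.loci:
            alleles = sorted({n.alleles[locus.id] for n in spore.nuclei})
            rec[locus.id] = "/".join(alleles)
            rec[f"homokaryotic_{locus.id}"] = len(alleles) == 1
        records.append(rec)
    return records


def simulate_cross(
    cross: CrossSpec,
    rng: Optional[np.random.Generator] = None,
    collect_survivors: bool = True,
) -> Tuple[AscusCountTable, pd.DataFrame]:
    """Simulate ``cross.n_asci`` meioses and return counts plus survivors.

    Deterministic given the cross seed: a fresh generator seeded with
    ``cross.seed`` is used unless an explicit generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(cross.seed)
    ctx = ZygoteContext.from_cross(cross)
    counts: Dict[AscusClass, int] = {}
    survivors: List[dict] = []
    odd_seen = False
    for i in range(cross.n_asci):
        ascus = simulate_meiosis(cross, rng)
        apply_spore_killing(ascus, ctx, rng=rng)
        assign_pigment(ascus, cross.alleles)
        cls = classify_ascus(ascus)
        counts[cls] = counts.get(cls, 0) + 1
        if cls.n_viable % 2 == 1:
            odd_seen = True
        if collect_survivors:
            survivors.extend(_survivor_records(cross, ascus, i, cls))
    if odd_seen:
        logger.warning(
            "cross %s produced odd-numbered ascus classes (partial-penetrance "
            "killing); such classes are not observed in wild-type crosses",
            cross.name or "<unnamed>",
        )
    table = AscusCountTable(
        cross_id=cross.name or f"{cross.parent1.strain_id}x{cross.parent2.strain_id}",
        counts=counts,
        n_asci=cross.n_asci,
        seed=cross.seed,
    )
    frame = pd.DataFrame(survivors)
    return table, frame


def sample_count_table(
    cross: CrossSpec, rng: Optional[np.random.Generator] = None
) -> AscusCountTable:
    """Fast count-only sampling: multinomial draw from the exact distribution.

    Statistically identical to counting ``simulate_cross`` output but
    several orders of magnitude faster, which matters for calibration
    studies with hundreds of replicates.  Requires deterministic killing.
    """
    from .exact import enumerate_cross  # local import to avoid a cycle

    if rng is None:
        rng = np.random.default_rng(cross.seed)
    dist = enumerate_cross(cross)
    classes = sorted(dist.class_probs)
    probs = np.array([dist.class_probs[c] for c in classes])
    draws = rng.multinomial(cross.n_asci, probs / probs.sum())
    counts = {c: int(k) for c, k in zip(classes, draws) if k > 0}
    return AscusCountTable(
        cross_id=cross.name or f"{cross.parent1.strain_id}x{cross.parent2.strain_id}",
        counts=counts,
        n_asci=cross.n_asci,
        seed=cross.seed,
    )
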