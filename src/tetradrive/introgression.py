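"""Recurrent-backcross introgression of a driver locus.

Models the construction of a near-isogenic spore-killer strain: a hybrid
carrying the driver is crossed to the recurrent parent generation after
generation, each time keeping one surviving ascospore that (a) carries the
driver and (b) comes from a killing (FDS) ascus — heterokaryotic SDS
survivors are discarded.  Donor chromatin shrinks towards the selected
locus; unselected genome is lost at the usual halving rate, while the
driver-linked donor segment persists indefinitely and only its length decays.

The chromosome carrying the driver is simulated in full (Poisson crossovers
on an interval map, no interference, centromere at position 0); the rest of
the genome is summarised by the closed-form expectation that an unselected
region is still donor with probability ``(1/2)**(generation+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .genetics import Locus

Segment = Tuple[float, float]


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome arm lengths in Morgans, measured from the centromere."""

    chromosomes: Mapping[str, float]

    def length_of(self, chromosome: str) -> float:
        try:
            return self.chromosomes[chromosome]
        except KeyError:
            raise ConfigurationError(
                f"chromosome {chromosome!r} is not on the genome map"
            ) from None


@dataclass
class IntrogressionState:
    """Donor content of the selected lineage at one generation.

    ``donor_segments`` are non-overlapping sorted intervals (Morgans) of
    the driver chromosome still of donor origin on the selected homolog;
    the homolog inherited from the recurrent parent is donor-free, so the
    diploid donor fraction of this chromosome is half the segment share.
    """

    generation: int
    chromosome: str
    donor_segments: Tuple[Segment, ...]
    carries_driver: bool

    def __post_init__(self) -> None:
        segs = sorted(self.donor_segments)
        for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
            if a2 < b1:
                raise ParameterError("donor segments must be non-overlapping")
        self.donor_segments = tuple(segs)

    def donor_length(self) -> float:
        return sum(b - a for a, b in self.donor_segments)

    def donor_fraction(self, chrom_length: float) -> float:
        return self.donor_length() / (2.0 * chrom_length)

    def segment_containing(self, position: float) -> Optional[Segment]:
        for a, b in self.donor_segments:
            if a <= position <= b:
                return (a, b)
        return None


def _merge(segments: List[Segment]) -> Tuple[Segment, ...]:
    if not segments:
        return ()
    segments = sorted(segments)
    merged = [segments[0]]
    for a, b in segments[1:]:
        la, lb = merged[-1]
        if a <= lb:
            merged[-1] = (la, max(lb, b))
        else:
            merged.append((a, b))
    return tuple(m for m in merged if m[1] > m[0])


def _intersect(a: Sequence[Segment], b: Sequence[Segment]) -> Tuple[Segment, ...]:
    out: List[Segment] = []
    for a1, a2 in a:
        for b1, b2 in b:
            lo, hi = max(a1, b1), min(a2, b2)
            if hi > lo:
                out.append((lo, hi))
    return _merge(out)


def _bivalent_chromatids(
    length: float, rng: np.random.Generator
) -> List[List[Tuple[float, int]]]:
    """Segment lists ``(start, homolog)`` for the four chromatids of one meiosis.

    Chromatids 0,1 descend from the hybrid's selected (mosaic) homolog and
    2,3 from the recurrent homolog; crossovers exchange distal segments
    between one chromatid of each homolog.
    """
    n_events = rng.poisson(2.0 * length) if length > 0 else 0
    positions = np.sort(rng.uniform(0.0, length, size=n_events))
    c1 = rng.integers(0, 2, size=n_events)
    c2 = rng.integers(2, 4, size=n_events)
    chromatids: List[List[Tuple[float, int]]] = [[(0.0, h)] for h in (0, 0, 1, 1)]
    current = [0, 0, 1, 1]
    for pos, a, b in zip(positions.tolist(), c1.tolist(), c2.tolist()):
        current[a], current[b] = current[b], current[a]
        chromatids[a].append((pos, current[a]))
        chromatids[b].append((pos, current[b]))
    return chromatids


def _chromatid_origin_at(chromatid: List[Tuple[float, int]], position: float) -> int:
    origin = chromatid[0][1]
    for start, h in chromatid:
        if start <= position:
            origin = h
        else:
            break
    return origin


def _chromatid_segments_of_origin(
    chromatid: List[Tuple[float, int]], length: float, homolog: int
) -> Tuple[Segment, ...]:
    segs: List[Segment] = []
    for i, (start, h) in enumerate(chromatid):
        end = chromatid[i + 1][0] if i + 1 < len(chromatid) else length
        if h == homolog and end > start:
            segs.append((start, end))
    return _merge(segs)


def _select_fds_gamete(
    donor: Sequence[Segment],
    length: float,
    driver_pos: float,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> Tuple[Segment, ...]:
    """One backcross: draw meioses until the driver shows FDS, then keep a
    random driver-carrying chromatid and intersect its selected-homolog
    segments with the lineage's donor intervals."""
    for _ in range(max_tries):
        chromatids = _bivalent_chromatids(length, rng)
        at_driver = [_chromatid_origin_at(c, driver_pos) for c in chromatids]
        if at_driver[0] != at_driver[1]:  # pole mixed -> SDS, not selected
            continue
        carriers = [i for i, h in enumerate(at_driver) if h == 0]
        pick = chromatids[carriers[rng.integers(len(carriers))]]
        inherited = _chromatid_segments_of_origin(pick, length, homolog=0)
        return _intersect(inherited, donor)
    raise ParameterError("failed to draw an FDS meiosis; map length too extreme")


def simulate_backcross_program(
    driver: Locus,
    genome_map: GenomeMap,
    n_generations: int,
    n_replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate repeated backcrosses with selection for the driver.

    Returns one row per (replicate, generation) with the realised donor
    fraction of the driver chromosome, the length of the donor segment
    around the driver, and the closed-form expected donor fraction of
    unlinked genome, ``0.5**(generation+1)``.  Generation 0 is the F1.
    """
    if driver.position_morgans is None:
        raise ConfigurationError("driver locus needs position_morgans")
    if n_generations < 1:
        raise ParameterError("n_generations must be >= 1")
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    length = genome_map.length_of(driver.chromosome)
    pos = driver.position_morgans
    if pos > length:
        raise ConfigurationError("driver lies beyond the end of its chromosome")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        segments: Tuple[Segment, ...] = ((0.0, length),)
        for gen in range(n_generations + 1):
            state = IntrogressionState(
                generation=gen,
                chromosome=driver.chromosome,
                donor_segments=segments,
                carries_driver=True,
            )
            linked = state.segment_containing(pos)
            if linked is None:
                raise AssertionError(
                    "selection invariant violated: driver outside donor segments"
                )
            rows.append(
                {
                    "replicate": rep,
                    "generation": gen,
                    "donor_fraction": state.donor_fraction(length),
                    "driver_segment_length": linked[1] - linked[0],
                    "expected_unlinked_donor_fraction": 0.5 ** (gen + 1),
                }
            )
            if gen < n_generations:
                segments = _select_fds_gamete(segments, length, pos, rng)
    return pd.DataFrame(rows)


def simulate_neutral_chromosome(
    length: float,
    n_generations: int,
    rng: np.random.Generator,
) -> List[float]:
    """Donor fractions of an *unselected* chromosome over a backcross series.

    A random chromatid is kept each generation with no conditioning, so the
    expected diploid donor fraction at generation g is ``0.5**(g+1)`` —
    the closed form the selected simulation is benchmarked against.
    """
    segments: Tuple[Segment, ...] = ((0.0, length),)
    fractions = [sum(b - a for a, b in segments) / (2.0 * length)]
    for _ in range(n_generations):
        chromatids = _bivalent_chromatids(length, rng)
        pick = chromatids[rng.integers(4)]
        inherited = _chromatid_segments_of_origin(pick, length, homolog=0)
        segments = _intersect(inherited, segments)
        fractions.append(sum(b - a for a, b in segments) / (2.0 * length))
    return fractions
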