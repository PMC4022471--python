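"""Estimators and tests for ascus-count and survivor-genotype data.

Three tools cover how a spore-killer element is located and quantified:

* :func:`estimate_sds` turns counts of killing (FDS) versus intact (SDS)
  asci into an estimate of the second-division segregation frequency ``s``
  of the killer locus, with an exact (Clopper-Pearson) confidence interval
  and the standard tetrad-mapping centromere distance ``s/2`` in cM.
* :func:`transmission_scan` screens marker genotypes of surviving progeny
  for transmission-ratio distortion: each marker gets an exact binomial
  test against Mendelian 50:50, Benjamini-Hochberg adjustment across
  markers, and the maximal run of contiguous significant markers is
  flagged as the candidate driver region.
* :func:`goodness_of_fit` compares an observed ascus-class table to an
  exact model distribution (chi-square with pooling of thin classes, or an
  exact multinomial test for small samples).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import MaskedLocusError, ParameterError
from .genetics import CrossSpec
from .killing import ZygoteContext
from .simulate import AscusClass, AscusCountTable


# ---------------------------------------------------------------------------
# SDS frequency estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SDSEstimate:
    """Point estimate and exact CI for a second-division segregation frequency."""

    s_hat: float
    ci_low: float
    ci_high: float
    n_asci: int
    ci_level: float = 0.95

    @property
    def map_distance_cM(self) -> float:
        """Centromere distance in centiMorgans (half the SDS frequency).

        Standard tetrad mapping: each SDS ascus carries one crossover, which
        recombines half the chromatids.
        """
        return 100.0 * self.s_hat / 2.0


def estimate_sds(
    n_2spored: int,
    n_4spored: int,
    locus_is_killer: bool = True,
    ci_level: float = 0.95,
) -> SDSEstimate:
    """Estimate ``s`` from ascus counts of a single-unmasked-killer cross.

    For a killer locus, killing in FDS asci leaves two spores while SDS
    asci survive intact (heterokaryotic rescue), so the 4-spored fraction
    is the maximum-likelihood estimate of ``s``.  With
    ``locus_is_killer=False`` the two arguments are read as direct counts
    of FDS-pattern and SDS-pattern asci of a visible (e.g. pigment) marker;
    the arithmetic is identical.
    """
    if n_2spored < 0 or n_4spored < 0:
        raise ParameterError("ascus counts must be non-negative")
    total = n_2spored + n_4spored
    if total == 0:
        raise ParameterError("at least one ascus is required")
    result = stats.binomtest(n_4spored, total)
    ci = result.proportion_ci(confidence_level=ci_level, method="exact")
    return SDSEstimate(
        s_hat=n_4spored / total,
        ci_low=ci.low,
        ci_high=ci.high,
        n_asci=total,
        ci_level=ci_level,
    )


def _segregating_distorters(cross: CrossSpec, ctx: ZygoteContext) -> Dict[str, str]:
    """Active distorters carried by exactly one parent, keyed by locus."""
    out = {}
    for locus in cross.heterozygous_loci():
        for aid in (cross.parent1.alleles[locus.id], cross.parent2.alleles[locus.id]):
            if aid in ctx.active_distorters:
                out[aid] = locus.id
    return out


def estimate_sds_for_cross(
    cross: CrossSpec,
    table: AscusCountTable,
    locus_id: str,
    ci_level: float = 0.95,
) -> SDSEstimate:
    """Estimate the SDS frequency of ``locus_id`` from a cross's count table.

    Refuses when the requested locus does not host the unique *unmasked*
    segregating killer: a killer is masked when another allele present in
    the zygote covers it, in which case survivors of the other element
    shield its targets and the 2-spored fraction carries no information
    about the requested locus (e.g. a *Spok2*-style killer crossed into a
    zygote that also segregates a *Spok1*-style resistance-bearing killer).
    """
    ctx = ZygoteContext.from_cross(cross)
    seg = _segregating_distorters(cross, ctx)
    at_locus = [aid for aid, lid in seg.items() if lid == locus_id]
    if not at_locus:
        raise MaskedLocusError(
            f"locus {locus_id!r} does not segregate an active distorter in this cross"
        )
    killer = at_locus[0]
    for aid in ctx.alleles_present:
        if aid != killer and killer in ctx.resolved_covers.get(aid, frozenset()):
            raise MaskedLocusError(
                f"killer {killer!r} is masked by the responder of {aid!r}; "
                "the ascus-class counts are uninformative for this locus"
            )
    for other, lid in seg.items():
        if other == killer:
            continue
        if other not in ctx.resolved_covers.get(killer, frozenset()):
            raise MaskedLocusError(
                f"a second unmasked killer {other!r} segregates; the 2-spored "
                "fraction compounds both loci"
            )
    n2 = round(table.fraction(n_viable=2) * table.n_asci)
    n4 = round(table.fraction(n_viable=4) * table.n_asci)
    return estimate_sds(n2, n4, locus_is_killer=True, ci_level=ci_level)


# ---------------------------------------------------------------------------
# Transmission-ratio scan
# ---------------------------------------------------------------------------

@dataclass
class TransmissionScan:
    """Per-marker transmission statistics and the flagged biased region."""

    table: pd.DataFrame
    flagged_region: Tuple[str, ...]
    alpha: float

    def is_flagged(self, marker: str) -> bool:
        return marker in self.flagged_region


def transmission_scan(
    genotypes: pd.DataFrame,
    positions: Optional[Mapping[str, float]] = None,
    donor: str = "T",
    alpha: float = 0.05,
) -> TransmissionScan:
    """Scan survivor genotypes for transmission-ratio distortion.

    ``genotypes`` holds one row per surviving progeny and one column per
    marker, coded by parental origin.  Each marker is tested with an exact
    two-sided binomial test of the donor-allele fraction against 0.5;
    p-values are Benjamini-Hochberg adjusted across markers.  Markers are
    ordered by ``positions`` when given (column order otherwise) and the
    longest run of contiguous significant markers is flagged as the
    candidate drive region.
    """
    if genotypes.empty or genotypes.shape[1] == 0:
        raise ParameterError("genotype matrix must contain progeny and markers")
    markers = list(genotypes.columns)
    if positions:
        markers.sort(key=lambda m: positions.get(m, np.inf))
    rows = []
    for marker in markers:
        col = genotypes[marker]
        n = int(col.notna().sum())
        k = int((col == donor).sum())
        p = stats.binomtest(k, n, 0.5).pvalue if n else np.nan
        rows.append(
            {
                "marker": marker,
                "position": positions.get(marker) if positions else None,
                "n": n,
                "n_donor": k,
                "fraction": k / n if n else np.nan,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    pvals = table["p_value"].to_numpy()
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    table["p_adjusted"] = np.maximum(adjusted, pvals)  # adjusted p >= raw p
    table["significant"] = table["p_adjusted"] < alpha

    best: Tuple[str, ...] = ()
    current: list = []
    for _, row in table.iterrows():
        if row["significant"]:
            current.append(row["marker"])
            if len(current) > len(best):
                best = tuple(current)
        else:
            current = []
    return TransmissionScan(table=table, flagged_region=best, alpha=alpha)


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoodnessOfFit:
    statistic: float
    p_value: float
    dof: Optional[int]
    method: str


def goodness_of_fit(
    observed: Mapping[AscusClass, int] | AscusCountTable,
    expected: Mapping[AscusClass, float],
    method: str = "auto",
) -> GoodnessOfFit:
    """Test observed ascus-class counts against an exact distribution.

    ``method`` is ``"chisq"`` (classes with expectation < 5 pooled),
    ``"exact"`` (full multinomial enumeration, feasible for small counts)
    or ``"auto"`` (exact when the total count is at most 40).
    """
    counts = observed.counts if isinstance(observed, AscusCountTable) else dict(observed)
    unknown = set(counts) - set(expected)
    if unknown:
        raise ParameterError(
            f"observed classes {sorted(str(c) for c in unknown)} missing from "
            "the expected distribution"
        )
    classes = sorted(expected)
    obs = np.array([counts.get(c, 0) for c in classes], dtype=float)
    probs = np.array([expected[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    n = int(obs.sum())
    if n == 0:
        raise ParameterError("observed table is empty")
    if method == "auto":
        method = "exact" if n <= 40 else "chisq"
    if method == "exact":
        return _exact_multinomial(obs.astype(int), probs)
    if method != "chisq":
        raise ParameterError(f"unknown method {method!r}")
    exp = probs * n
    # Pool thin classes so the chi-square approximation holds.
    keep = exp >= 5.0
    if (~keep).any():
        obs = np.append(obs[keep], obs[~keep].sum())
        exp = np.append(exp[keep], exp[~keep].sum())
    if len(obs) < 2:
        raise ParameterError("fewer than two classes after pooling; use method='exact'")
    statistic, p = stats.chisquare(obs, exp)
    return GoodnessOfFit(
        statistic=float(statistic), p_value=float(p), dof=len(obs) - 1, method="chisq"
    )


def _exact_multinomial(obs: np.ndarray, probs: np.ndarray) -> GoodnessOfFit:
    """Exact multinomial test: p = total probability of outcomes no more
    likely than the observed one (point-probability ordering)."""
    n = int(obs.sum())
    k = len(probs)
    p_obs = stats.multinomial.pmf(obs, n, probs)
    total = 0.0
    for combo in itertools.combinations_with_replacement(range(k), n):
        vec = np.bincount(combo, minlength=k)
        p_vec = stats.multinomial.pmf(vec, n, probs)
        if p_vec <= p_obs * (1 + 1e-9):
            total += p_vec
    return GoodnessOfFit(
        statistic=float(p_obs), p_value=float(min(total, 1.0)), dof=None, method="exact"
    )
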