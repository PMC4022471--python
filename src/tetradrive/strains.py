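"""Strain library, cross registry and synthetic marker-genotype data.

Everything here encodes the published genetics of the *Podospora anserina*
Spok spore-killer system as model objects:

* three loci — the *Spok1* site near the centromere of chromosome 5
  (SDS 10%), the *Spok2* site 600 kb away on the same arm (SDS 60%,
  unlinked to *Spok1* for practical purposes, r = 0.5), and the *PaPKS1*
  pigment gene at the centromere of chromosome 2 (SDS 1%), which doubles as
  a dominant colour marker and as the landing site for transgene insertions;
* the allele rule set: wild-type *Spok1* kills and resists everything in
  the family (it is a resistance factor to *Spok2*); wild-type *Spok2*
  kills and resists the *Spok2*-derived killers and the heterologous
  *Spok^N* but not *Spok1*; tagged/mutant alleles decouple the two
  activities (responder-only alleles, and killers whose responder works
  only when trans-activated by a wild-type *Spok2* copy in the cross);
* every cross of the published tables and transgene experiments as a
  ready-made :class:`~tetradrive.genetics.CrossSpec` with its expected
  outcome, usable both as documentation and as an exhaustive test harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .genetics import (
    Allele,
    BINUCLEATE_TETRAD,
    CrossSpec,
    Haplotype,
    Locus,
    UNINUCLEATE_OCTAD,
    haldane_r,
    sds_from_map_length,
)

# ---------------------------------------------------------------------------
# Allele groups (who can kill, who is covered by whom)
# ---------------------------------------------------------------------------

# Distorter-active alleles producing a wild-type Spok1 product.
SPOK1_KILLERS = frozenset({"Spok1", "pks1::Spok1", "pks1::GFP-Spok1", "SmSpok1"})
# Distorter-active alleles producing a wild-type Spok2 product.
SPOK2_KILLERS = frozenset({"Spok2", "pks1::Spok2"})
# Spok2 derivatives that kill but cannot resist on their own.
SPOK2_VARIANT_KILLERS = frozenset({"pks1::mCherry-Spok2", "pks1::Spok2AA"})
# The heterologous killer from another genus.
SPOKN_KILLERS = frozenset({"pks1::SpokN"})

# Responder ranges.  A Spok1 product resists the entire family; a Spok2
# product resists everything except Spok1.
SPOK1_RESPONDER_RANGE = (
    SPOK1_KILLERS | SPOK2_KILLERS | SPOK2_VARIANT_KILLERS | SPOKN_KILLERS
)
SPOK2_RESPONDER_RANGE = SPOK2_KILLERS | SPOK2_VARIANT_KILLERS | SPOKN_KILLERS


@dataclass
class StrainLibrary:
    """All loci, alleles and named strains of the published experiments."""

    loci: Dict[str, Locus]
    alleles: Dict[str, Allele]
    linkage: Dict[frozenset, float]
    strains: Dict[str, Haplotype]

    def strain(self, name: str) -> Haplotype:
        try:
            return self.strains[name]
        except KeyError:
            raise KeyError(
                f"unknown strain {name!r}; known: {sorted(self.strains)}"
            ) from None


def build_strain_library() -> StrainLibrary:
    """Construct the full strain/allele library.

    Backgrounds follow the construction history of each strain: transgene
    insertions at *PaPKS1* carrying a wild-type *Spok2* product or made in
    the *Spok2*-deletion strain keep that background at the *Spok2* locus.
    """
    loci = {
        "spok1": Locus("spok1", chromosome="5", sds_prob=0.10),
        "spok2": Locus("spok2", chromosome="5", sds_prob=0.60),
        "pks1": Locus("pks1", chromosome="2", sds_prob=0.01),
        # Sordaria macrospora transgene insertion site; the insertion point is
        # not mapped, but in the uninucleate octad the killing outcome does
        # not depend on it — pick an uninformative mid-range value.
        "sma_ins": Locus("sma_ins", chromosome="sm_1", sds_prob=0.5),
    }
    # The two Spok loci are 600 kb apart but segregate independently in
    # practice (survivor genotypes split 50:50), so the default r is 0.5.
    linkage = {frozenset(("spok1", "spok2")): 0.5}

    def allele(aid: str, locus: str, **kw) -> Allele:
        return Allele(id=aid, locus_id=locus, **kw)

    alleles = {
        a.id: a
        for a in [
            # --- spok1 locus (chromosome 5 centromere region) ---
            allele(
                "Spok1", "spok1", distorter_active=True,
                responder_covers=SPOK1_RESPONDER_RANGE,
            ),
            allele("Spok1-0", "spok1"),  # empty site (strain S and derivatives)
            allele("Spok1-del", "spok1", selectable_markers=frozenset({"hygR"})),
            allele("A406-r1", "spok1", responder_covers=SPOK1_KILLERS),
            # --- spok2 locus ---
            allele(
                "Spok2", "spok2", distorter_active=True,
                responder_covers=SPOK2_RESPONDER_RANGE,
            ),
            allele("Spok2-0", "spok2"),  # empty site (strain T)
            allele("Spok2-del", "spok2", selectable_markers=frozenset({"hygR"})),
            # Strain A variant: responder intact, distorter dead.
            allele("Spok2-A", "spok2", responder_covers=SPOK2_RESPONDER_RANGE),
            allele("A406-r2", "spok2", responder_covers=SPOK2_KILLERS),
            # --- pks1 locus (pigment gene, chromosome 2 centromere) ---
            allele("PaPKS1", "pks1", pigment_functional=True),
            allele(
                "pks1::Spok1", "pks1", distorter_active=True,
                responder_covers=SPOK1_RESPONDER_RANGE,
            ),
            allele(
                "pks1::Spok2", "pks1", distorter_active=True,
                responder_covers=SPOK2_RESPONDER_RANGE,
            ),
            allele(
                "pks1::GFP-Spok1", "pks1", distorter_active=True,
                responder_covers=SPOK1_RESPONDER_RANGE,
            ),
            # Responder-only tags (C-terminal fusions kill nothing).
            allele(
                "pks1::Spok1-GFP", "pks1",
                responder_covers=SPOK1_KILLERS | SPOK2_KILLERS,
            ),
            allele("pks1::Spok2-mCherry", "pks1", responder_covers=SPOK2_KILLERS),
            # Killers whose responder needs a wild-type Spok2 in the zygote.
            allele(
                "pks1::mCherry-Spok2", "pks1", distorter_active=True,
                responder_covers=SPOK2_KILLERS | SPOK2_VARIANT_KILLERS,
                trans_activators=SPOK2_KILLERS,
            ),
            allele(
                "pks1::Spok2AA", "pks1", distorter_active=True,
                responder_covers=SPOK2_KILLERS | SPOK2_VARIANT_KILLERS,
                trans_activators=SPOK2_KILLERS,
            ),
            allele(
                "pks1::SpokN", "pks1", distorter_active=True,
                responder_covers=SPOKN_KILLERS | SPOK2_KILLERS,
                trans_activators=SPOK2_KILLERS,
            ),
            # --- Sordaria macrospora ---
            allele(
                "SmSpok1", "sma_ins", distorter_active=True,
                responder_covers=SPOK1_RESPONDER_RANGE,
                pigment_functional=True,
                selectable_markers=frozenset({"hygR"}),
            ),
            allele("Sm-wt", "sma_ins", pigment_functional=True),
        ]
    }

    pa = ("spok1", "spok2", "pks1")

    def strain(name: str, spok1: str, spok2: str, pks1: str = "PaPKS1") -> Haplotype:
        return Haplotype(strain_id=name, alleles=dict(zip(pa, (spok1, spok2, pks1))))

    strains = {
        "S": strain("S", "Spok1-0", "Spok2"),
        "T": strain("T", "Spok1", "Spok2-0"),
        "SKT20": strain("SKT20", "Spok1", "Spok2"),
        "SKT20del": strain("SKT20del", "Spok1-del", "Spok2"),
        "Spok1del": strain("Spok1del", "Spok1-del", "Spok2-0"),
        "Spok2del": strain("Spok2del", "Spok1-0", "Spok2-del"),
        "SKT20-Spok2del": strain("SKT20-Spok2del", "Spok1", "Spok2-del"),
        # Transgene strains; backgrounds per construction history.
        "PaPKS1::Spok1": strain("PaPKS1::Spok1", "Spok1-0", "Spok2", "pks1::Spok1"),
        "PaPKS1::Spok2": strain("PaPKS1::Spok2", "Spok1-0", "Spok2-del", "pks1::Spok2"),
        "PaPKS1::Spok2AA": strain(
            "PaPKS1::Spok2AA", "Spok1-0", "Spok2-del", "pks1::Spok2AA"
        ),
        "PaPKS1::mCherry-Spok2": strain(
            "PaPKS1::mCherry-Spok2", "Spok1-0", "Spok2-del", "pks1::mCherry-Spok2"
        ),
        "PaPKS1::GFP-Spok1": strain(
            "PaPKS1::GFP-Spok1", "Spok1-0", "Spok2", "pks1::GFP-Spok1"
        ),
        "PaPKS1::Spok1-GFP": strain(
            "PaPKS1::Spok1-GFP", "Spok1-0", "Spok2", "pks1::Spok1-GFP"
        ),
        "PaPKS1::Spok2-mCherry": strain(
            "PaPKS1::Spok2-mCherry", "Spok1-0", "Spok2-del", "pks1::Spok2-mCherry"
        ),
        "PaPKS1::SpokN": strain("PaPKS1::SpokN", "Spok1-0", "Spok2-del", "pks1::SpokN"),
        # Geographic races.
        "A": strain("A", "Spok1-0", "Spok2-A"),
        "A406": strain("A406", "A406-r1", "A406-r2"),
        "X": strain("X", "Spok1-0", "Spok2-0"),
        "CBS411.78": strain("CBS411.78", "Spok1-0", "Spok2-0"),
        # Sordaria macrospora transformant and untransformed tester.
        "Sm-Spok1": Haplotype(strain_id="Sm-Spok1", alleles={"sma_ins": "SmSpok1"}),
        "Sm-wt": Haplotype(strain_id="Sm-wt", alleles={"sma_ins": "Sm-wt"}),
        # Strain Y / CBS237.71 carry a further Spok-family killer ("Spok3")
        # whose interaction with the Spok1 strain is uncharacterised; they
        # are deliberately not encoded.
        # "Y": strain("Y", "?", "?"),
        # "CBS237.71": strain("CBS237.71", "?", "?"),
    }
    return StrainLibrary(loci=loci, alleles=alleles, linkage=linkage, strains=strains)


def make_cross(
    library: StrainLibrary,
    parent1: str,
    parent2: str,
    n_asci: int = 10_000,
    seed: int = 1,
    packaging: Optional[str] = None,
    name: Optional[str] = None,
    crossover_model: str = "phenomenological",
) -> CrossSpec:
    """Build a CrossSpec between two named library strains.

    The cross carries every locus both parents define; *P. anserina*
    strains span the three fungal loci, the *Sordaria* strains only their
    insertion site (and default to octad packaging).
    """
    p1 = library.strain(parent1)
    p2 = library.strain(parent2)
    shared = [lid for lid in p1.alleles if lid in p2.alleles]
    if set(p1.alleles) != set(p2.alleles):
        raise ConfigurationError(
            f"strains {parent1!r} and {parent2!r} are not defined over the same loci"
        )
    loci = tuple(library.loci[lid] for lid in shared)
    if packaging is None:
        packaging = UNINUCLEATE_OCTAD if "sma_ins" in shared else BINUCLEATE_TETRAD
    return CrossSpec(
        parent1=p1,
        parent2=p2,
        loci=loci,
        alleles=library.alleles,
        linkage=library.linkage,
        packaging=packaging,
        n_asci=n_asci,
        seed=seed,
        crossover_model=crossover_model,
        name=name or f"{parent1}x{parent2}",
    )


# ---------------------------------------------------------------------------
# Cross registry
# ---------------------------------------------------------------------------

@dataclass
class RegistryEntry:
    """One published cross with its documented expected outcome.

    ``expected_class_pct`` maps viable-spore counts to exact model
    percentages; ``expected_2sp_unpigmented_pct`` refines the 2-spored
    class by pigment where that is the scored phenotype.  Survivor claims:
    ``survivors_all_carry`` is an allele every viable spore must contain;
    ``homokaryon_freq_pct`` gives, per locus, allele percentages among
    surviving spores homokaryotic at that locus.  ``outcome`` is
    "quantitative" when the model reproduces printed numbers exactly,
    "qualitative" when only a pattern is claimed, "untestable" for sterile
    crosses with no progeny to score.
    """

    name: str
    cross: Optional[CrossSpec]
    outcome: str = "quantitative"
    expected_class_pct: Dict[int, float] = field(default_factory=dict)
    expected_2sp_unpigmented_pct: Optional[float] = None
    survivors_all_carry: Optional[str] = None
    homokaryon_freq_pct: Dict[str, Dict[str, float]] = field(default_factory=dict)
    notes: str = ""


def build_cross_registry(
    library: Optional[StrainLibrary] = None,
    n_asci: int = 10_000,
    seed: int = 1,
) -> List[RegistryEntry]:
    """All published crosses with their expected ascus-class percentages."""
    lib = library or build_strain_library()

    def entry(name, p1, p2, **kw) -> RegistryEntry:
        packaging = kw.pop("packaging", None)
        outcome = kw.pop("outcome", "quantitative")
        cross = make_cross(
            lib, p1, p2, n_asci=n_asci, seed=seed, packaging=packaging, name=name
        )
        return RegistryEntry(name=name, cross=cross, outcome=outcome, **kw)

    fifty_fifty = {"Spok2": 50.0, "Spok2-0": 50.0}
    entries = [
        # --- the main cross table ---
        entry("SxS", "S", "S", expected_class_pct={4: 100.0}),
        entry("TxT", "T", "T", expected_class_pct={4: 100.0}),
        entry(
            "SxT", "S", "T",
            expected_class_pct={2: 90.0, 4: 10.0},
            survivors_all_carry="Spok1",
            homokaryon_freq_pct={"spok2": fifty_fifty},
        ),
        entry(
            "SKT20xS", "SKT20", "S",
            expected_class_pct={2: 90.0, 4: 10.0},
            survivors_all_carry="Spok1",
        ),
        entry(
            "SKT20xT", "SKT20", "T",
            expected_class_pct={4: 100.0},
            homokaryon_freq_pct={"spok2": fifty_fifty},
        ),
        entry("SKT20xSKT20", "SKT20", "SKT20", expected_class_pct={4: 100.0}),
        entry(
            "SKT20delxSKT20", "SKT20del", "SKT20",
            expected_class_pct={2: 90.0, 4: 10.0},
            survivors_all_carry="Spok1",
        ),
        entry("SKT20delxSKT20del", "SKT20del", "SKT20del", expected_class_pct={4: 100.0}),
        entry(
            "Spok1delxT", "Spok1del", "T",
            expected_class_pct={2: 90.0, 4: 10.0},
            survivors_all_carry="Spok1",
        ),
        entry("Spok1delxSpok1del", "Spok1del", "Spok1del", expected_class_pct={4: 100.0}),
        entry(
            "Spok1delxS", "Spok1del", "S",
            expected_class_pct={2: 40.0, 4: 60.0},
            survivors_all_carry="Spok2",
            homokaryon_freq_pct={"spok2": {"Spok2": 100.0}},
        ),
        entry(
            "Spok2delxS", "Spok2del", "S",
            expected_class_pct={2: 40.0, 4: 60.0},
            survivors_all_carry="Spok2",
            homokaryon_freq_pct={"spok2": {"Spok2": 100.0}},
        ),
        entry("Spok2delxSpok2del", "Spok2del", "Spok2del", expected_class_pct={4: 100.0}),
        entry(
            "Spok2delxT", "Spok2del", "T",
            expected_class_pct={2: 90.0, 4: 10.0},
            survivors_all_carry="Spok1",
            homokaryon_freq_pct={"spok2": {"Spok2-0": 50.0, "Spok2-del": 50.0}},
        ),
        entry("Spok1delxSpok2del", "Spok1del", "Spok2del", expected_class_pct={4: 100.0}),
        entry(
            "SKT20xSpok2del", "SKT20", "Spok2del",
            expected_class_pct={2: 90.0, 4: 10.0},
            survivors_all_carry="Spok1",
            homokaryon_freq_pct={"spok2": {"Spok2": 50.0, "Spok2-del": 50.0}},
        ),
        entry(
            "SKT20-Spok2delxSKT20", "SKT20-Spok2del", "SKT20",
            expected_class_pct={4: 100.0},
            homokaryon_freq_pct={"spok2": {"Spok2": 50.0, "Spok2-del": 50.0}},
        ),
        entry(
            "SKT20-Spok2delxSKT20-Spok2del", "SKT20-Spok2del", "SKT20-Spok2del",
            expected_class_pct={4: 100.0},
        ),
        # --- transgene insertions at the pigment locus ---
        entry(
            "PaPKS1::Spok1xS", "PaPKS1::Spok1", "S",
            expected_class_pct={2: 99.0, 4: 1.0},
            expected_2sp_unpigmented_pct=99.0,
            survivors_all_carry="pks1::Spok1",
        ),
        entry(
            "PaPKS1::Spok2xSpok2del", "PaPKS1::Spok2", "Spok2del",
            expected_class_pct={2: 99.0, 4: 1.0},
            expected_2sp_unpigmented_pct=99.0,
            survivors_all_carry="pks1::Spok2",
        ),
        entry(
            "mCherry-Spok2xSpok2del", "PaPKS1::mCherry-Spok2", "Spok2del",
            expected_class_pct={0: 100.0},
        ),
        entry(
            "mCherry-Spok2xPaPKS1::Spok2", "PaPKS1::mCherry-Spok2", "PaPKS1::Spok2",
            expected_class_pct={4: 100.0},
        ),
        entry(
            "Spok2AAxSpok2del", "PaPKS1::Spok2AA", "Spok2del",
            expected_class_pct={0: 100.0},
        ),
        entry(
            "Spok2AAxPaPKS1::Spok2", "PaPKS1::Spok2AA", "PaPKS1::Spok2",
            expected_class_pct={4: 100.0},
        ),
        entry(
            "Spok2AAxPaPKS1::Spok1", "PaPKS1::Spok2AA", "PaPKS1::Spok1",
            expected_class_pct={2: 99.0, 4: 1.0},
            expected_2sp_unpigmented_pct=99.0,
            survivors_all_carry="pks1::Spok1",
        ),
        entry(
            "SpokNxSpok2del", "PaPKS1::SpokN", "Spok2del",
            expected_class_pct={0: 100.0},
        ),
        entry(
            "SpokNxPaPKS1::Spok2", "PaPKS1::SpokN", "PaPKS1::Spok2",
            expected_class_pct={4: 100.0},
        ),
        entry(
            "SpokNxPaPKS1::Spok1", "PaPKS1::SpokN", "PaPKS1::Spok1",
            expected_class_pct={2: 99.0, 4: 1.0},
            expected_2sp_unpigmented_pct=99.0,
            survivors_all_carry="pks1::Spok1",
        ),
        entry(
            "SpokNxS", "PaPKS1::SpokN", "S",
            outcome="qualitative",
            expected_class_pct={0: 0.0},
            notes="killing with full resistance conferred by wild-type Spok2; "
            "never barren",
        ),
        entry(
            "Spok1-GFPxS", "PaPKS1::Spok1-GFP", "S",
            expected_class_pct={4: 100.0},
        ),
        entry(
            "Spok2-mCherryxSpok2del", "PaPKS1::Spok2-mCherry", "Spok2del",
            expected_class_pct={4: 100.0},
        ),
        # --- geographic races ---
        entry("AxS", "A", "S", expected_class_pct={4: 100.0}),
        entry(
            "AxSKT20", "A", "SKT20",
            expected_class_pct={2: 90.0, 4: 10.0},
            survivors_all_carry="Spok1",
        ),
        entry("AxSpok1del", "A", "Spok1del", expected_class_pct={4: 100.0}),
        entry(
            "AxSpok2del", "A", "Spok2del",
            expected_class_pct={4: 100.0},
            homokaryon_freq_pct={"spok2": {"Spok2-A": 50.0, "Spok2-del": 50.0}},
        ),
        entry(
            "XxT", "X", "T",
            expected_class_pct={2: 90.0, 4: 10.0},
            survivors_all_carry="Spok1",
        ),
        entry(
            "XxS", "X", "S",
            expected_class_pct={2: 40.0, 4: 60.0},
            survivors_all_carry="Spok2",
            notes="Spok-free strain crossed to a Spok2 carrier; the model "
            "prediction follows the Spok2 SDS frequency",
        ),
        entry("A406xS", "A406", "S", expected_class_pct={4: 100.0}),
        entry("A406xT", "A406", "T", expected_class_pct={4: 100.0}),
        RegistryEntry(
            name="A406xSKT20", cross=None, outcome="untestable",
            notes="sterile cross; no progeny to score",
        ),
        # --- heterologous octads ---
        entry(
            "Sm-Spok1xSm-wt", "Sm-Spok1", "Sm-wt",
            expected_class_pct={4: 100.0},
            survivors_all_carry="SmSpok1",
            notes="uninucleate octads: every ascus has exactly four viable "
            "pigmented and four dead spores, independent of SDS frequency",
        ),
    ]
    return entries


def registry_cross(name: str, **kwargs) -> CrossSpec:
    """Look up a registry cross by name (raises KeyError if absent/sterile)."""
    for e in build_cross_registry(**kwargs):
        if e.name == name:
            if e.cross is None:
                raise KeyError(f"registry cross {name!r} is untestable (sterile)")
            return e.cross
    raise KeyError(f"unknown registry cross {name!r}")


# ---------------------------------------------------------------------------
# Synthetic marker-genotype datasets (driver scans)
# ---------------------------------------------------------------------------

def default_scan_panel(
    n_linked: int = 10, n_unlinked: int = 3
) -> Tuple[Locus, List[Locus], Dict[frozenset, float]]:
    """A marker panel emulating a genome scan around a centromeric driver.

    The driver sits 5 cM from the centromere of its chromosome (SDS 10%);
    linked markers are placed every 10 cM outward, with SDS frequencies and
    adjacent recombination fractions from the standard no-interference map
    functions.  Unlinked markers live on other chromosomes.
    """
    driver = Locus("driver", chromosome="5", sds_prob=0.10, position_morgans=0.05)
    markers: List[Locus] = []
    linkage: Dict[frozenset, float] = {}
    prev = driver
    for i in range(n_linked):
        pos = 0.1 * (i + 1)
        m = Locus(
            f"m{i + 1:02d}", chromosome="5",
            sds_prob=sds_from_map_length(pos), position_morgans=pos,
        )
        linkage[frozenset((prev.id, m.id))] = haldane_r(pos - prev.position_morgans)
        markers.append(m)
        prev = m
    for i in range(n_unlinked):
        markers.append(Locus(f"u{i + 1:02d}", chromosome=f"chr_u{i + 1}", sds_prob=0.3))
    return driver, markers, linkage


def generate_marker_dataset(
    n_progeny: int,
    driver: Locus,
    markers: Sequence[Locus],
    seed: int,
    linkage: Optional[Mapping] = None,
    homokaryons_only: bool = True,
) -> pd.DataFrame:
    """Genotype matrix of surviving progeny from a driver-bearing cross.

    Parent "S" is the sensitive recurrent parent, parent "T" carries a
    self-resistant killer at the driver locus.  One surviving spore is
    sampled per ascus and genotyped; with ``homokaryons_only`` (default)
    only spores homokaryotic at the driver are retained — these exist only
    in killing (FDS) asci, so the driver column is fixed for the "T" allele,
    mirroring how segregation of survivors is scored.  Values are parental
    origins ("S"/"T"); rows are progeny, columns markers.
    """
    if not markers:
        raise ParameterError("at least one marker is required")
    if n_progeny <= 0:
        raise ParameterError("n_progeny must be positive")
    loci = (driver,) + tuple(markers)
    alleles: Dict[str, Allele] = {}
    p1_map: Dict[str, str] = {}
    p2_map: Dict[str, str] = {}
    for locus in loci:
        a_s = Allele(id=f"{locus.id}-S", locus_id=locus.id)
        if locus.id == driver.id:
            a_t = Allele(
                id=f"{locus.id}-T", locus_id=locus.id,
                distorter_active=True,
                responder_covers=frozenset({f"{locus.id}-T"}),
            )
        else:
            a_t = Allele(id=f"{locus.id}-T", locus_id=locus.id)
        alleles[a_s.id] = a_s
        alleles[a_t.id] = a_t
        p1_map[locus.id] = a_s.id
        p2_map[locus.id] = a_t.id
    cross = CrossSpec(
        parent1=Haplotype("S-like", p1_map),
        parent2=Haplotype("T-like", p2_map),
        loci=loci,
        alleles=alleles,
        linkage=dict(linkage) if linkage else {},
        n_asci=1,
        seed=seed,
        name="marker-scan",
    )
    from .genetics import simulate_meiosis
    from .killing import ZygoteContext, apply_spore_killing

    rng = np.random.default_rng(seed)
    ctx = ZygoteContext.from_cross(cross)
    rows: List[Dict[str, str]] = []
    attempts = 0
    max_attempts = 200 * n_progeny + 1000
    while len(rows) < n_progeny:
        attempts += 1
        if attempts > max_attempts:
            raise ParameterError(
                "could not collect the requested number of progeny; "
                "check the driver SDS frequency"
            )
        ascus = simulate_meiosis(cross, rng)
        apply_spore_killing(ascus, ctx)
        candidates = [
            s for s in ascus.spores
            if s.viable and (not homokaryons_only or s.is_homokaryotic(driver.id))
        ]
        if not candidates:
            continue
        spore = candidates[rng.integers(len(candidates))]
        nucleus = spore.nuclei[rng.integers(len(spore.nuclei))]
        rows.append(
            {l.id: ("T" if nucleus.alleles[l.id].endswith("-T") else "S") for l in loci}
        )
    frame = pd.DataFrame(rows, index=[f"ST{i + 1}" for i in range(n_progeny)])
    return frame
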