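"""Meiosis engine: segregation geometry, packaging, and mapping closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tetradrive import (
    Allele,
    CrossSpec,
    Haplotype,
    Locus,
    ParameterError,
    map_length_from_sds,
    sds_from_map_length,
    simulate_meiosis,
    spore_pigment,
)
from tetradrive.genetics import FDS_VECTORS, SDS_VECTORS, phase_conditional

from .conftest import single_killer_cross


def two_locus_cross(s1, s2, r, seed=3, n_asci=100):
    alleles = {
        aid: Allele(aid, lid)
        for aid, lid in [("A", "L1"), ("a", "L1"), ("B", "L2"), ("b", "L2")]
    }
    return CrossSpec(
        parent1=Haplotype("p1", {"L1": "A", "L2": "B"}),
        parent2=Haplotype("p2", {"L1": "a", "L2": "b"}),
        loci=(Locus("L1", "c", s1), Locus("L2", "c", s2)),
        alleles=alleles,
        linkage={("L1", "L2"): r},
        n_asci=n_asci,
        seed=seed,
    )


class TestSegregationGeometry:
    @pytest.mark.parametrize("s", [0.0, 0.35, 1.0])
    def test_nucleus_conservation_and_dosage(self, s, rng):
        """Eight nuclei per ascus; heterozygous loci segregate 4:4."""
        cross = single_killer_cross(s)
        for _ in range(50):
            ascus = simulate_meiosis(cross, rng)
            nuclei = ascus.nuclei()
            assert len(nuclei) == 8
            carriers = sum(1 for n in nuclei if n.alleles["L"] == "K")
            assert carriers == 4

    def test_fds_spores_homokaryotic_sds_heterokaryotic(self, rng):
        """Binucleate packaging turns per-locus FDS/SDS into spore karyotype."""
        cross = single_killer_cross(0.5)
        for _ in range(100):
            ascus = simulate_meiosis(cross, rng)
            homo = [s.is_homokaryotic("L") for s in ascus.spores]
            if ascus.sds_pattern["L"] == "FDS":
                assert all(homo)
            else:
                assert not any(homo)

    def test_s_zero_gives_two_spores_per_genotype(self, rng):
        """No crossover: every spore homokaryotic, 2 spores per parental type."""
        cross = single_killer_cross(0.0)
        for _ in range(30):
            ascus = simulate_meiosis(cross, rng)
            genotypes = [s.nuclei[0].alleles["L"] for s in ascus.spores]
            assert all(s.is_homokaryotic("L") for s in ascus.spores)
            assert sorted(genotypes).count("K") == 2

    def test_s_one_gives_four_heterokaryons(self, rng):
        cross = single_killer_cross(1.0)
        for _ in range(30):
            ascus = simulate_meiosis(cross, rng)
            assert not any(s.is_homokaryotic("L") for s in ascus.spores)

    def test_homozygous_cross_identical_nuclei(self, rng):
        alleles = {"K": Allele("K", "L", distorter_active=True,
                               responder_covers=frozenset({"K"}))}
        cross = CrossSpec(
            parent1=Haplotype("p", {"L": "K"}),
            parent2=Haplotype("p", {"L": "K"}),
            loci=(Locus("L", "c", 0.6),),
            alleles={**alleles},
            n_asci=1,
        )
        for _ in range(10):
            ascus = simulate_meiosis(cross, rng)
            assert all(n.alleles["L"] == "K" for n in ascus.nuclei())

    def test_octad_packaging_uninucleate(self, rng):
        cross = single_killer_cross(0.5, packaging="uninucleate_octad")
        ascus = simulate_meiosis(cross, rng)
        assert len(ascus.spores) == 8
        assert all(len(s.nuclei) == 1 for s in ascus.spores)

    def test_sds_marginal_frequency(self, rng):
        """Observed SDS fraction approaches s within 3 binomial SE."""
        s, n = 0.6, 4000
        cross = single_killer_cross(s)
        hits = sum(
            simulate_meiosis(cross, rng).sds_pattern["L"] == "SDS" for _ in range(n)
        )
        se = math.sqrt(s * (1 - s) / n)
        assert abs(hits / n - s) < 3 * se


class TestPhaseConditional:
    def test_marginals_and_normalisation(self):
        vecs, probs = phase_conditional(0.37, 0.2, prev=(0, 0, 1, 1))
        assert probs.sum() == pytest.approx(1.0)
        assert probs[:2].sum() == pytest.approx(1 - 0.37)  # FDS mass preserved
        assert probs[2:].sum() == pytest.approx(0.37)

    def test_half_r_is_independence(self):
        _, free = phase_conditional(0.6, 0.5, prev=None)
        for prev in FDS_VECTORS + SDS_VECTORS:
            _, probs = phase_conditional(0.6, 0.5, prev=prev)
            assert np.allclose(probs, free)

    def test_tight_linkage_keeps_phase(self, rng):
        """At r=0 two FDS loci always co-segregate parental alleles."""
        cross = two_locus_cross(0.0, 0.0, 0.0)
        for _ in range(50):
            ascus = simulate_meiosis(cross, rng)
            for spore in ascus.spores:
                pairs = {(n.alleles["L1"], n.alleles["L2"]) for n in spore.nuclei}
                assert pairs <= {("A", "B"), ("a", "b")}

    @given(s=st.floats(0, 1), r=st.floats(0, 0.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_distribution_valid_for_all_parameters(self, s, r):
        for prev in (None,) + FDS_VECTORS + SDS_VECTORS:
            _, probs = phase_conditional(s, r, prev=prev)
            assert np.all(probs >= 0)
            assert probs.sum() == pytest.approx(1.0)


class TestMechanisticMode:
    def test_sds_matches_no_interference_closed_form(self):
        """Poisson-crossover SDS frequency follows s=(2/3)(1-e^(-3x))."""
        for x in (0.05, 0.5, 2.0):
            cross = single_killer_cross(0.0)
            cross = CrossSpec(
                parent1=cross.parent1, parent2=cross.parent2,
                loci=(Locus("L", "chr1", 0.0, position_morgans=x),),
                alleles=dict(cross.alleles), crossover_model="mechanistic",
                n_asci=1, seed=5,
            )
            rng = np.random.default_rng(42)
            n = 6000
            hits = sum(
                simulate_meiosis(cross, rng).sds_pattern["L"] == "SDS"
                for _ in range(n)
            )
            expected = sds_from_map_length(x)
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(hits / n - expected) < 3 * se

    def test_map_length_round_trip(self):
        for s in (0.01, 0.10, 0.60):
            assert sds_from_map_length(map_length_from_sds(s)) == pytest.approx(s)

    def test_ceiling_two_thirds(self):
        assert sds_from_map_length(50.0) == pytest.approx(2 / 3, abs=1e-12)
        with pytest.raises(ParameterError):
            map_length_from_sds(0.7)


class TestPigment:
    def test_dominant_pigment_rule(self, library):
        alleles = library.alleles
        dark = Haplotype("wt", {"pks1": "PaPKS1"})
        pale = Haplotype("ins", {"pks1": "pks1::Spok1"})
        from tetradrive import Spore

        assert spore_pigment(Spore(nuclei=(pale, pale)), alleles) is False
        assert spore_pigment(Spore(nuclei=(dark, pale)), alleles) is True
        assert spore_pigment(Spore(nuclei=(dark,)), alleles) is True


class TestValidation:
    def test_bad_probabilities_rejected(self):
        with pytest.raises(ParameterError):
            Locus("L", "c", 1.2)
        with pytest.raises(Exception):
            two_locus_cross(0.5, 0.5, 0.9)

    def test_undeclared_allele_rejected(self):
        from tetradrive import ConfigurationError

        with pytest.raises(ConfigurationError):
            CrossSpec(
                parent1=Haplotype("p1", {"L": "missing"}),
                parent2=Haplotype("p2", {"L": "k0"}),
                loci=(Locus("L", "c", 0.1),),
                alleles={"k0": Allele("k0", "L")},
                n_asci=1,
            )
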