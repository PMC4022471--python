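"""Killing engine: responder resolution, trans-activation, masking, rescue."""

import numpy as np
import pytest

from tetradrive import (
    Haplotype,
    Spore,
    ZygoteContext,
    apply_spore_killing,
    effective_responders,
    enumerate_cross,
    make_cross,
    simulate_cross,
    simulate_meiosis,
)
from tetradrive.genetics import build_ascus

from .conftest import single_killer_cross


def spore_with(library, **locus_alleles):
    hap = Haplotype("test", dict(locus_alleles))
    return Spore(nuclei=(hap,))


class TestEffectiveResponders:
    def test_spok1_covers_whole_family(self, library):
        """A Spok1-carrying spore resists Spok1, Spok2 and the heterologous killer."""
        cross = make_cross(library, "S", "T")
        ctx = ZygoteContext.from_cross(cross)
        spore = spore_with(library, spok1="Spok1", spok2="Spok2-0", pks1="PaPKS1")
        covered = effective_responders(spore, ctx)
        assert {"Spok1", "Spok2", "pks1::SpokN"} <= covered

    def test_trans_activation_requires_wild_type_copy(self, library):
        """mCherry-Spok2's responder is dead without, alive with, wild-type Spok2."""
        spore = spore_with(
            library, spok1="Spok1-0", spok2="Spok2-del", pks1="pks1::mCherry-Spok2"
        )
        no_wt = make_cross(library, "PaPKS1::mCherry-Spok2", "Spok2del")
        assert effective_responders(spore, ZygoteContext.from_cross(no_wt)) == frozenset()
        with_wt = make_cross(library, "PaPKS1::mCherry-Spok2", "PaPKS1::Spok2")
        covered = effective_responders(spore, ZygoteContext.from_cross(with_wt))
        assert {"pks1::Spok2", "pks1::mCherry-Spok2"} <= covered

    def test_undeclared_allele_raises(self, library):
        from tetradrive import ConfigurationError

        cross = make_cross(library, "S", "T")
        ctx = ZygoteContext.from_cross(cross)
        rogue = Spore(nuclei=(Haplotype("x", {"spok1": "not-an-allele"}),))
        with pytest.raises(ConfigurationError):
            effective_responders(rogue, ctx)


class TestApplySporeKilling:
    def test_fds_killer_ascus_two_survivors(self, library):
        """FDS at the killer locus: the two killer-homokaryotic spores live."""
        cross = make_cross(library, "S", "T")
        ctx = ZygoteContext.from_cross(cross)
        vectors = {"spok1": (1, 1, 0, 0), "spok2": (0, 0, 1, 1), "pks1": (0, 0, 1, 1)}
        ascus = build_ascus(cross, vectors)  # parent2 = T carries Spok1
        apply_spore_killing(ascus, ctx)
        viable = [s for s in ascus.spores if s.viable]
        assert len(viable) == 2
        assert all("Spok1" in s.allele_ids() for s in viable)

    def test_sds_killer_ascus_all_heterokaryons_survive(self, library):
        """SDS at Spok1 in SKT20×S: every spore is rescued regardless of Spok2."""
        cross = make_cross(library, "SKT20", "S")
        ctx = ZygoteContext.from_cross(cross)
        for spok2_vec in [(0, 0, 1, 1), (0, 1, 0, 1), (1, 0, 0, 1)]:
            vectors = {"spok1": (0, 1, 1, 0), "spok2": spok2_vec, "pks1": (0, 0, 1, 1)}
            ascus = build_ascus(cross, vectors)
            apply_spore_killing(ascus, ctx)
            assert all(s.viable for s in ascus.spores)

    def test_no_active_distorter_all_viable(self, library, rng):
        cross = make_cross(library, "Spok1del", "Spok2del")
        ctx = ZygoteContext.from_cross(cross)
        ascus = simulate_meiosis(cross, rng)
        apply_spore_killing(ascus, ctx)
        assert all(s.viable for s in ascus.spores)

    def test_uncovered_killer_empties_the_ascus(self, library, rng):
        cross = make_cross(library, "PaPKS1::mCherry-Spok2", "Spok2del")
        ctx = ZygoteContext.from_cross(cross)
        ascus = simulate_meiosis(cross, rng)
        apply_spore_killing(ascus, ctx)
        assert not any(s.viable for s in ascus.spores)


class TestRuleProperties:
    def test_homozygosity_silence(self, library):
        """Killers present in both parents can never kill."""
        for name in ("SxS", "TxT", "SKT20xSKT20", "SKT20-Spok2delxSKT20-Spok2del"):
            from tetradrive import registry_cross

            dist = enumerate_cross(registry_cross(name))
            assert dist.prob(n_viable=4) == pytest.approx(1.0)

    def test_masking_spok1_covers_spok2(self, library):
        """Adding heterozygous Spok2 to a Spok1 cross changes nothing.

        The S×T ascus-class distribution equals that of the same cross with
        the Spok2 locus made homozygous-empty: Spok1's responder shields
        every Spok1 survivor from Spok2, and non-carriers die anyway.
        """
        full = enumerate_cross(make_cross(library, "S", "T"))
        s_no_spok2 = Haplotype("S*", {"spok1": "Spok1-0", "spok2": "Spok2-0",
                                      "pks1": "PaPKS1"})
        stripped = make_cross(library, "S", "T")
        stripped.parent1 = s_no_spok2
        reduced = enumerate_cross(stripped)
        assert full.class_probs == pytest.approx(reduced.class_probs)

    def test_survivor_guarantee(self, library):
        """Every viable spore's effective responders cover the active distorters."""
        cross = make_cross(library, "S", "T", n_asci=300, seed=11)
        ctx = ZygoteContext.from_cross(cross)
        rng = np.random.default_rng(11)
        for _ in range(cross.n_asci):
            ascus = simulate_meiosis(cross, rng)
            apply_spore_killing(ascus, ctx)
            for spore in ascus.spores:
                if spore.viable:
                    assert ctx.active_distorters <= effective_responders(spore, ctx)

    def test_partial_penetrance_allows_odd_classes(self):
        """Killing efficiency below 1 breaks the twin-spore symmetry."""
        cross = single_killer_cross(0.0, n_asci=400, seed=2)
        weak = dict(cross.alleles)
        weak["K"] = type(weak["K"])(
            "K", "L", distorter_active=True,
            responder_covers=frozenset({"K"}), killing_efficiency=0.5,
        )
        cross.alleles = weak
        table, _ = simulate_cross(cross, collect_survivors=False)
        observed = {cls.n_viable for cls in table.counts}
        assert observed & {1, 3}
        assert sum(table.counts.values()) == 400
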