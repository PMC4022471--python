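"""Estimators: SDS frequency, transmission scan, goodness of fit."""

import math

import numpy as np
import pandas as pd
import pytest

from tetradrive import (
    AscusClass,
    MaskedLocusError,
    ParameterError,
    default_scan_panel,
    enumerate_cross,
    estimate_sds,
    estimate_sds_for_cross,
    generate_marker_dataset,
    goodness_of_fit,
    make_cross,
    sample_count_table,
    simulate_cross,
    transmission_scan,
)


class TestEstimateSDS:
    def test_point_estimate_and_map_distance(self):
        est = estimate_sds(9000, 1000)
        assert est.s_hat == pytest.approx(0.10)
        assert est.map_distance_cM == pytest.approx(5.0)
        assert est.ci_low <= est.s_hat <= est.ci_high

    def test_zero_sds_boundary(self):
        est = estimate_sds(100, 0)
        assert est.s_hat == 0.0
        assert est.ci_low == 0.0
        assert est.ci_high > 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ParameterError):
            estimate_sds(0, 0)
        with pytest.raises(ParameterError):
            estimate_sds(-1, 5)

    def test_cross_aware_estimation_and_masking_refusal(self, library):
        cross = make_cross(library, "S", "T", n_asci=4000, seed=8)
        table, _ = simulate_cross(cross, collect_survivors=False)
        est = estimate_sds_for_cross(cross, table, "spok1")
        assert abs(est.s_hat - 0.10) < 0.03
        # Spok2 is masked by Spok1's responder in this zygote.
        with pytest.raises(MaskedLocusError):
            estimate_sds_for_cross(cross, table, "spok2")
        # Homozygous Spok2 does not even segregate a killer.
        skt = make_cross(library, "SKT20", "S", n_asci=500, seed=8)
        t2, _ = simulate_cross(skt, collect_survivors=False)
        with pytest.raises(MaskedLocusError):
            estimate_sds_for_cross(skt, t2, "spok2")

    def test_ci_coverage_small_replicates(self, library):
        """Exact CIs cover the true s at roughly the nominal rate (quick check)."""
        cross = make_cross(library, "Spok1del", "S", n_asci=2000)
        hits = 0
        reps = 60
        rng = np.random.default_rng(17)
        for _ in range(reps):
            table = sample_count_table(cross, rng=rng)
            est = estimate_sds(
                round(table.fraction(n_viable=2) * 2000),
                round(table.fraction(n_viable=4) * 2000),
            )
            hits += est.ci_low <= 0.60 <= est.ci_high
        assert hits / reps > 0.85


class TestTransmissionScan:
    def test_fully_biased_marker_exact_p(self):
        """A fixed driver allele at n=50 has raw p = 2*(1/2)^50."""
        frame = pd.DataFrame({"drv": ["T"] * 50, "other": ["S", "T"] * 25})
        scan = transmission_scan(frame)
        drv = scan.table.set_index("marker").loc["drv"]
        assert drv["fraction"] == 1.0
        assert drv["p_value"] == pytest.approx(2 * 0.5**50, rel=1e-9)
        other = scan.table.set_index("marker").loc["other"]
        assert other["fraction"] == pytest.approx(0.5)
        assert not other["significant"]

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            rng.choice(["S", "T"], size=(40, 8)), columns=[f"m{i}" for i in range(8)]
        )
        scan = transmission_scan(frame)
        assert (scan.table["p_adjusted"] >= scan.table["p_value"] - 1e-15).all()

    def test_flagged_region_contains_driver(self):
        driver, markers, linkage = default_scan_panel()
        geno = generate_marker_dataset(50, driver, markers, seed=21, linkage=linkage)
        positions = {m.id: m.position_morgans for m in [driver, *markers]
                     if m.position_morgans is not None}
        scan = transmission_scan(geno, positions=positions)
        assert scan.is_flagged("driver")

    def test_empty_inputs_rejected(self):
        with pytest.raises(ParameterError):
            transmission_scan(pd.DataFrame())


class TestGoodnessOfFit:
    def test_zero_statistic_at_exact_proportions(self):
        expected = {AscusClass(2, 0): 0.9, AscusClass(4, 0): 0.1}
        observed = {AscusClass(2, 0): 9000, AscusClass(4, 0): 1000}
        fit = goodness_of_fit(observed, expected)
        assert fit.statistic == pytest.approx(0.0)
        assert fit.p_value == pytest.approx(1.0)

    def test_rejects_wrong_model_at_scale(self, library):
        """An S×T-sized table is decisively incompatible with s=0.5."""
        cross = make_cross(library, "S", "T", n_asci=10_000, seed=1)
        table, _ = simulate_cross(cross, collect_survivors=False)
        # Survivors all carry the functional pigment gene, hence the
        # pigmented class labels.
        wrong = {AscusClass(2, 2): 0.5, AscusClass(4, 4): 0.5}
        fit = goodness_of_fit(table, wrong)
        assert fit.p_value < 1e-10

    def test_calibration_under_the_null(self):
        """P-values are roughly uniform when data are drawn from the model."""
        probs = np.array([0.9, 0.1])
        classes = [AscusClass(2, 0), AscusClass(4, 0)]
        expected = dict(zip(classes, probs))
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(600):
            draw = rng.multinomial(400, probs)
            fit = goodness_of_fit(dict(zip(classes, draw.tolist())), expected)
            pvals.append(fit.p_value)
        pvals = np.array(pvals)
        assert 0.02 <= (pvals < 0.05).mean() <= 0.09
        assert 0.42 <= pvals.mean() <= 0.58

    def test_exact_small_sample_path(self):
        expected = {AscusClass(2, 0): 0.9, AscusClass(4, 0): 0.1}
        fit = goodness_of_fit({AscusClass(2, 0): 9, AscusClass(4, 0): 1}, expected)
        assert fit.method == "exact"
        assert 0.0 < fit.p_value <= 1.0
        skew = goodness_of_fit({AscusClass(2, 0): 0, AscusClass(4, 0): 10}, expected)
        assert skew.p_value < 1e-8

    def test_mismatched_labels_rejected(self):
        with pytest.raises(ParameterError):
            goodness_of_fit({AscusClass(3, 0): 5}, {AscusClass(2, 0): 1.0})
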