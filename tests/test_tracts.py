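"""Tract calling on the synthetic chr12-like panel and the chi-square tests."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import CEN12, FIG12_CAUSAL, FIG12_INTERVALS, FIG12_LENGTH, fig12_calls
from lohkit.simulate import LOHMechanismMix, simulate_loh_clone
from lohkit.tracts import (
    CloneGenotypes,
    call_tracts,
    chisq_homogeneity,
    chisq_size_model,
    classify_clone,
    endpoint_midpoint,
    tally_endpoints,
)


def clone_from(hom: dict[int, str], clone_id="c") -> CloneGenotypes:
    return CloneGenotypes(
        clone_id=clone_id, chrom="chr12", calls=fig12_calls(hom),
        selected_marker_id=FIG12_CAUSAL, selected_direction="M",
    )


class TestCallTracts:
    def test_point_event_bounded_by_flanking_markers(self, fig12_map):
        """Homozygosity at the causal marker only: interstitial tract whose
        maximum span is the 8.7 kb between the immediate flanking markers."""
        reports = call_tracts(clone_from({405_000: "M"}), fig12_map, CEN12)
        right = reports["right"]
        assert right.informative and len(right.tracts) == 1
        t = right.tracts[0]
        assert t.terminal_flag == "interstitial"
        assert t.length_bound_kb == (0.0, pytest.approx(8.7))
        assert t.proximal_endpoint_bp == pytest.approx((401_300 + 405_000) / 2)
        assert t.distal_endpoint_bp == pytest.approx((405_000 + 410_000) / 2)

    def test_terminal_tract_with_coincident_left_arm(self, fig12_map):
        """A right-arm run to the most distal marker plus an unselected
        left-arm run in the opposite direction."""
        hom = {p: "M" for p in (366_000, 380_000, 401_300, 405_000,
                                410_000, 430_000, 450_000)}
        hom[33_000] = "P"
        reports = call_tracts(clone_from(hom), fig12_map, CEN12,
                              chrom_length=FIG12_LENGTH)
        right, left = reports["right"], reports["left"]
        assert len(right.tracts) == 1 and len(left.tracts) == 1
        assert right.tracts[0].direction == "M" and left.tracts[0].direction == "P"
        assert right.tracts[0].terminal_flag == "reaches-last-marker"
        assert right.tracts[0].distal_endpoint_bp is None
        # max span extends to the chromosome end when its length is known
        assert right.tracts[0].length_bound_kb[1] == pytest.approx(
            (FIG12_LENGTH - 292_000) / 1000)
        cls = classify_clone(reports, clone_from(hom), fig12_map)
        assert cls.label == "simple" and cls.coincident_multi_arm

    def test_all_het_clone_has_no_tracts(self, fig12_map):
        reports = call_tracts(clone_from({}), fig12_map, CEN12)
        assert all(not rep.tracts for rep in reports.values())

    def test_missing_is_transparent_by_default(self, fig12_map):
        clone = clone_from({380_000: "M", 405_000: "M"})
        clone.calls[7] = "MISSING"  # 401.3 kb, between the two hom markers
        reports = call_tracts(clone, fig12_map, CEN12)
        assert len(reports["right"].tracts) == 1  # one run across the gap
        broken = call_tracts(clone, fig12_map, CEN12, missing_breaks=True)
        assert len(broken["right"].tracts) == 2

    def test_interrupted_run_is_complex(self, fig12_map):
        clone = clone_from({380_000: "M", 410_000: "M", 405_000: "M"})
        clone.calls[7] = "HET"  # 401.3 kb splits the run
        reports = call_tracts(clone, fig12_map, CEN12)
        cls = classify_clone(reports, clone, fig12_map)
        assert cls.label == "complex"

    def test_opposite_direction_homozygosity_is_complex(self, fig12_map):
        clone = clone_from({405_000: "M", 430_000: "P"})
        reports = call_tracts(clone, fig12_map, CEN12)
        cls = classify_clone(reports, clone, fig12_map)
        assert cls.label == "complex"

    def test_uninformative_arm_flagged(self, fig12_map):
        hom = {p: "M" for p in (162_000, 227_000, 292_000, 366_000, 380_000,
                                401_300, 405_000, 410_000, 430_000, 450_000)}
        reports = call_tracts(clone_from(hom), fig12_map, CEN12)
        assert not reports["right"].informative
        assert reports["left"].informative

    def test_min_span_never_exceeds_max_span(self, fig12_map):
        rng = np.random.default_rng(8)
        mix = LOHMechanismMix()
        for _ in range(50):
            clone, _ = simulate_loh_clone(fig12_map, mix, FIG12_CAUSAL, "M",
                                          CEN12, seed=rng)
            for rep in call_tracts(clone, fig12_map, CEN12,
                                   chrom_length=FIG12_LENGTH).values():
                for t in rep.tracts:
                    assert t.length_bound_kb[0] <= t.length_bound_kb[1]


class TestEndpointMidpoint:
    def test_published_interval_midpoint(self):
        assert endpoint_midpoint(227_000, 292_000) == 259_500

    def test_symmetry_and_equal_error(self):
        assert endpoint_midpoint(292_000, 227_000) == 259_500
        with pytest.raises(ValueError):
            endpoint_midpoint(5, 5)


class TestTallyEndpoints:
    def test_midpoint_lands_in_spanning_interval(self):
        table = tally_endpoints([259_500.0], FIG12_INTERVALS)
        assert table.observed.tolist() == [0, 0, 1, 0, 0]

    def test_empty_tract_list_all_zero(self):
        table = tally_endpoints([], FIG12_INTERVALS)
        assert table.observed.sum() == 0

    def test_boundary_endpoint_assigned_to_left_interval(self):
        table = tally_endpoints([227_000.0], FIG12_INTERVALS)
        assert table.observed.tolist() == [0, 1, 0, 0, 0]

    def test_outside_endpoint_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="outside"):
            table = tally_endpoints([100.0, 259_500.0], FIG12_INTERVALS)
        assert table.n_outside == 1 and table.observed.sum() == 1

    def test_43_endpoints_match_bruteforce_binning(self):
        rng = np.random.default_rng(13)
        eps = rng.uniform(151_001, 401_300, size=43)
        table = tally_endpoints(list(eps), FIG12_INTERVALS)
        brute = [sum(1 for e in eps if lo < e <= hi) for lo, hi in FIG12_INTERVALS]
        assert table.observed.tolist() == brute
        assert table.observed.sum() == 43


class TestChisquare:
    def test_five_interval_df_convention(self):
        with pytest.warns(UserWarning):
            res = chisq_size_model([10, 5, 9, 6, 13], [l for _, l in [
                (0, 11_000), (0, 65_000), (0, 65_000), (0, 74_000), (0, 35_300)]])
        assert res.df == 4

    def test_proportional_counts_give_zero(self):
        res = chisq_size_model([10, 20, 30], [1_000, 2_000, 3_000])
        assert res.chi2 == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_random_tables_match_textbook_formula(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            counts = rng.integers(5, 60, size=5).astype(float)
            lengths = rng.uniform(1e4, 1e5, size=5)
            res = chisq_size_model(counts, lengths)
            expected = counts.sum() * lengths / lengths.sum()
            assert np.allclose(expected.sum(), counts.sum())
            chi2 = float(((counts - expected) ** 2 / expected).sum())
            assert res.chi2 == pytest.approx(chi2)
            from scipy.stats import chi2 as chi2_dist

            assert res.p == pytest.approx(float(chi2_dist.sf(chi2, 4)))

    def test_homogeneity_identical_rows_zero(self):
        res = chisq_homogeneity([4, 6, 2, 5, 3], [4, 6, 2, 5, 3])
        assert res.chi2 == 0.0 and res.p == 1.0 and res.df == 4

    def test_homogeneity_symmetric(self):
        a, b = [4, 6, 2, 5, 3], [2, 8, 3, 4, 2]
        r1, r2 = chisq_homogeneity(a, b), chisq_homogeneity(b, a)
        assert r1.chi2 == pytest.approx(r2.chi2) and r1.p == pytest.approx(r2.p)


class TestBreakpointContainment:
    def test_called_endpoint_interval_contains_true_breakpoint(self, fig12_map):
        """For simulated terminal events the proximal endpoint's flanking
        marker interval must contain the planted breakpoint, and the
        midpoint error is bounded by half the local marker spacing."""
        positions = [m.pos for m in fig12_map.chromosome("chr12")]
        mix = LOHMechanismMix(p_terminal=1.0, p_conversion=0.0, p_contraction=0.0)
        rng = np.random.default_rng(23)
        checked = 0
        for _ in range(100):
            clone, truth = simulate_loh_clone(fig12_map, mix, FIG12_CAUSAL, "M",
                                              CEN12, seed=rng)
            rep = call_tracts(clone, fig12_map, CEN12, chrom_length=FIG12_LENGTH)
            (tract,) = rep["right"].tracts
            if tract.proximal_endpoint_bp is None:
                continue
            i = positions.index(
                fig12_map.chromosome("chr12")[tract.first_hom_idx].pos)
            left, right = positions[i - 1], positions[i]
            bp = truth["breakpoint_bp"]
            assert left < bp <= right
            assert abs(tract.proximal_endpoint_bp - bp) <= (right - left) / 2
            checked += 1
        assert checked >= 80
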