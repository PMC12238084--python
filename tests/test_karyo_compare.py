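"""Signal-site tables, karyotype diffs and summary-statistic arithmetic."""

import math
import random

import numpy as np
import pytest

from repeatprobe.karyo_compare import (
    ComparisonReport,
    GroupSummary,
    SignalSite,
    compare_karyotypes,
    count_probe_chromosomes,
    load_signal_table,
    pooled_t_from_summary,
    ratio_of_means,
    round_half_up,
    welch_t_from_summary,
    write_signal_table,
)

HEADER = "chrom_label\tarm\tregion\tprobe_id\tintensity"


def make_sites(n: int, probe="red") -> list[SignalSite]:
    """n distinct-keyed sites over labels A01..; deterministic."""
    arms = ["short", "long"]
    regions = ["centromere", "terminal", "interstitial"]
    out = []
    for i in range(n):
        out.append(
            SignalSite(
                f"A{(i // 6) + 1:02d}", arms[i % 2], regions[(i // 2) % 3],
                probe, "strong",
            )
        )
    return out


class TestSignalTableIO:
    def test_roundtrip_preserves_rows(self):
        sites = make_sites(61)
        text = write_signal_table(sites)
        assert load_signal_table(text) == sites
        assert len(load_signal_table(text)) == 61

    def test_empty_body(self):
        assert load_signal_table(HEADER + "\n") == []

    def test_bad_arm_reports_line_number(self):
        text = HEADER + "\nA01\tmiddle\tcentromere\tred\tstrong\n"
        with pytest.raises(ValueError, match="line 2"):
            load_signal_table(text)

    def test_missing_header_rejected(self):
        with pytest.raises(ValueError, match="header"):
            load_signal_table("A01\tshort\tcentromere\tred\tstrong\n")

    def test_wrong_column_count_reports_line(self):
        text = HEADER + "\nA01\tshort\tcentromere\tred\n"
        with pytest.raises(ValueError, match="line 2"):
            load_signal_table(text)


def perturb(sites: list[SignalSite], k: int) -> list[SignalSite]:
    """Query table whose first k sites mismatch the reference by probe swap."""
    out = []
    for i, s in enumerate(sites):
        if i < k:
            out.append(SignalSite(s.chrom_label, s.arm, s.region,
                                  s.probe_id + "-other", s.intensity))
        else:
            out.append(s)
    return out


class TestCompareKaryotypes:
    def test_25_of_61_mismatch_is_41_0_percent(self):
        ref = make_sites(61)
        report = compare_karyotypes(ref, perturb(ref, 25))
        assert report.total_ref_sites == 61
        assert report.mismatched == 25
        assert report.mismatch_percent == 41.0

    def test_21_of_61_mismatch_is_34_4_percent(self):
        ref = make_sites(61)
        report = compare_karyotypes(ref, perturb(ref, 21))
        assert report.mismatched == 21
        assert report.mismatch_percent == 34.4

    def test_self_comparison_yields_zero(self):
        ref = make_sites(30)
        report = compare_karyotypes(ref, list(ref))
        assert report.mismatched == 0
        assert report.mismatch_percent == 0.0
        assert report.mismatch_list == ()

    def test_percent_consistent_with_list_length(self):
        ref = make_sites(47)
        for k in (0, 3, 12, 47):
            r = compare_karyotypes(ref, perturb(ref, k))
            assert len(r.mismatch_list) == r.mismatched == k
            assert r.mismatch_percent == round_half_up(100 * k / 47, 1)

    def test_absent_on_one_homolog_never_corroborates(self):
        a = SignalSite("A01", "short", "terminal", "red", "strong")
        b = SignalSite("A01", "short", "terminal", "red", "absent-on-one-homolog")
        assert compare_karyotypes([a], [b]).mismatched == 1
        assert compare_karyotypes([b], [a]).mismatched == 1
        # strong vs weak is compatible (same site, different brightness)
        c = SignalSite("A01", "short", "terminal", "red", "weak")
        assert compare_karyotypes([a], [c]).mismatched == 0

    def test_duplicate_key_rejected(self):
        s = SignalSite("A01", "short", "terminal", "red", "strong")
        with pytest.raises(ValueError, match="duplicate"):
            compare_karyotypes([s, s], [s])

    def test_coarse_matching_without_region(self):
        a = SignalSite("A01", "short", "terminal", "red", "strong")
        b = SignalSite("A01", "short", "interstitial", "red", "strong")
        assert compare_karyotypes([a], [b]).mismatched == 1
        assert compare_karyotypes([a], [b], use_region=False).mismatched == 0


class TestCountProbeChromosomes:
    def test_probe_on_every_label(self):
        sites = []
        labels = [f"A{i:02d}" for i in range(1, 18)] + [
            f"B{i:02d}" for i in range(1, 18)
        ]  # 34 labels
        for lb in labels:
            sites.append(SignalSite(lb, "short", "terminal", "Tel-1", "strong"))
            sites.append(SignalSite(lb, "long", "terminal", "Tel-1", "weak"))
        assert count_probe_chromosomes(sites, "Tel-1") == 34

    def test_absent_probe_counts_zero(self):
        assert count_probe_chromosomes(make_sites(10), "ghost") == 0

    def test_matches_set_oracle(self):
        rng = random.Random(3)
        sites = []
        for i in range(200):
            sites.append(
                SignalSite(
                    f"A{rng.randint(1, 20):02d}",
                    rng.choice(["short", "long"]),
                    rng.choice(["centromere", "terminal", "interstitial"]),
                    rng.choice(["red", "green", "45S"]),
                    "strong",
                )
            )
        for probe in ("red", "green", "45S"):
            expected = len({s.chrom_label for s in sites if s.probe_id == probe})
            assert count_probe_chromosomes(sites, probe) == expected


def samples_with(mean: float, sd: float, n: int) -> np.ndarray:
    """Construct raw samples having exactly the given mean and sd."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestSummaryStats:
    def test_pollen_fertility_t_statistic(self):
        t = pooled_t_from_summary(
            GroupSummary(95.68, 1.36, 10), GroupSummary(55.23, 8.27, 10)
        )
        assert round(t, 2) == 15.26

    def test_identical_groups_t_zero(self):
        g = GroupSummary(5.0, 1.0, 8)
        assert pooled_t_from_summary(g, g) == 0.0
        assert pooled_t_from_summary(
            GroupSummary(5.0, 0.0, 8), GroupSummary(5.0, 0.0, 8)
        ) == 0.0

    def test_antisymmetric(self):
        g1, g2 = GroupSummary(10.0, 2.0, 6), GroupSummary(7.5, 1.0, 9)
        assert pooled_t_from_summary(g1, g2) == pytest.approx(
            -pooled_t_from_summary(g2, g1)
        )

    def test_equal_n_closed_form(self):
        g1, g2 = GroupSummary(12.0, 3.0, 10), GroupSummary(9.0, 2.0, 10)
        expected = (12.0 - 9.0) / math.sqrt((3.0**2 + 2.0**2) / 10)
        assert pooled_t_from_summary(g1, g2) == pytest.approx(expected)

    def test_matches_t_from_constructed_raw_samples(self):
        for g1, g2 in [
            (GroupSummary(95.68, 1.36, 10), GroupSummary(55.23, 8.27, 10)),
            (GroupSummary(4.23, 0.57, 7), GroupSummary(2.40, 0.43, 12)),
        ]:
            x = samples_with(g1.mean, g1.sd, g1.n)
            y = samples_with(g2.mean, g2.sd, g2.n)
            sp2 = ((g1.n - 1) * x.var(ddof=1) + (g2.n - 1) * y.var(ddof=1)) / (
                g1.n + g2.n - 2
            )
            t_raw = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
            assert pooled_t_from_summary(g1, g2) == pytest.approx(t_raw, rel=1e-9)

    def test_welch_equals_pooled_at_equal_n_equal_sd(self):
        g1, g2 = GroupSummary(8.0, 2.0, 10), GroupSummary(6.0, 2.0, 10)
        assert welch_t_from_summary(g1, g2) == pytest.approx(
            pooled_t_from_summary(g1, g2)
        )

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary(1.0, 1.0, 1)

    def test_moxa_length_ratio(self):
        full, rounded = ratio_of_means(
            GroupSummary(4.23, 0.57, 10), GroupSummary(2.40, 0.43, 10)
        )
        assert full == pytest.approx(1.7625)
        assert rounded == 1.8

    def test_equal_means_ratio_one(self):
        g = GroupSummary(3.0, 1.0, 5)
        assert ratio_of_means(g, g) == (1.0, 1.0)

    def test_moxa_content_per_leaf_area_ratio(self):
        full, rounded = ratio_of_means(
            GroupSummary(1.25, 0.03, 10), GroupSummary(1.03, 0.02, 10)
        )
        assert full == pytest.approx(1.25 / 1.03)
        assert rounded == 1.2

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            ratio_of_means(GroupSummary(1.0, 0.1, 5), GroupSummary(0.0, 0.1, 5))


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(40.98, 41.0), (34.43, 34.4), (1.75, 1.8), (1.25, 1.3), (2.04999, 2.0)],
    )
    def test_half_up_one_decimal(self, x, expected):
        assert round_half_up(x, 1) == expected
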