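"""Scan machinery: centring, allelic differences, normalization, probe
selection, window tests and region calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from segscan import bsa
from segscan.bsa import QTLRegion, ScanParameters
from segscan.errors import DegenerateNormalizationError, InputError, StructuralError
from conftest import make_signal_table


def bh_bruteforce(p):
    """Independent step-up Benjamini-Hochberg oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestCenterLogRatios:
    @staticmethod
    def _raw(green, red, blocks):
        n = len(green)
        return pd.DataFrame(
            {"probe": [f"p{i}" for i in range(n)], "block": blocks, "green": green, "red": red}
        )

    def test_equal_channels_center_to_zero(self):
        out = bsa.center_log_ratios(self._raw([4.0, 8.0], [4.0, 8.0], [1, 1]))
        assert np.allclose(out["ratio"], 0.0)

    def test_constant_fold_change_centers_to_zero(self):
        out = bsa.center_log_ratios(self._raw([8.0, 16.0], [4.0, 8.0], [1, 1]))
        assert np.allclose(out["ratio"], 0.0)  # raw ratios all 1, centred away

    def test_mean_removal_within_block(self):
        # raw log2 ratios 1 and 3 within one block -> centred -1 and +1
        out = bsa.center_log_ratios(self._raw([8.0, 32.0], [4.0, 4.0], [1, 1]))
        assert sorted(out["ratio"].tolist()) == [-1.0, 1.0]

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(InputError):
            bsa.center_log_ratios(self._raw([1.0, -2.0], [1.0, 1.0], [1, 1]))


class TestAllelicDifference:
    @staticmethod
    def _centered(ratios_by_probe, block=1):
        return pd.DataFrame(
            {
                "probe": list(ratios_by_probe),
                "block": block,
                "ratio": list(ratios_by_probe.values()),
            }
        )

    @staticmethod
    def _pairs(order=("pa", "pb")):
        return pd.DataFrame(
            {"locus": ["L1"], "probe_A": [order[0]], "probe_B": [order[1]], "chrom": ["chrI"], "pos": [100]}
        )

    def test_equal_signal_gives_zero(self):
        d = bsa.allelic_difference(self._centered({"pa": 0.3, "pb": 0.3}), self._pairs())
        assert d["d"].iloc[0] == 0.0

    def test_subtraction(self):
        d = bsa.allelic_difference(self._centered({"pa": 0.8, "pb": -0.7}), self._pairs())
        assert d["d"].iloc[0] == pytest.approx(1.5)

    def test_swapping_pair_order_negates_d(self):
        cen = self._centered({"pa": 0.8, "pb": -0.7})
        d1 = bsa.allelic_difference(cen, self._pairs(("pa", "pb")))["d"].iloc[0]
        d2 = bsa.allelic_difference(cen, self._pairs(("pb", "pa")))["d"].iloc[0]
        assert d1 == -d2

    def test_missing_pair_member_raises(self):
        with pytest.raises(StructuralError):
            bsa.allelic_difference(self._centered({"pa": 0.8}), self._pairs())


class TestNormalizeParental:
    def test_already_anchored_is_identity(self):
        table = make_signal_table(
            {"parentA": [1.5, 1.5], "parentB": [-1.5, -1.5], "bulk_low": [0.2, 0.1], "bulk_high": [0.4, 0.2]}
        )
        gain, offset = bsa.parental_affine(table)
        assert (gain, offset) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_hand_solved_two_point_map(self):
        # raw parental means 2 and 0 -> gain 1.5, offset -1.5; raw 1 -> 0
        table = make_signal_table(
            {"parentA": [2.0, 2.0], "parentB": [0.0, 0.0], "bulk_low": [1.0, 1.0], "bulk_high": [1.0, 1.0]}
        )
        gain, offset = bsa.parental_affine(table)
        assert (gain, offset) == (pytest.approx(1.5), pytest.approx(-1.5))
        out = bsa.normalize_parental(table)
        assert np.allclose(out.loc[out["sample"] == "bulk_low", "d"], 0.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        mean_a=st.floats(-5, 5),
        sep=st.floats(0.2, 6),
        noise=st.floats(0, 1),
        seed=st.integers(0, 2**16),
    )
    def test_anchors_exact_for_any_nondegenerate_scale(self, mean_a, sep, noise, seed):
        rng = np.random.default_rng(seed)
        table = make_signal_table(
            {
                "parentA": np.full(30, mean_a),
                "parentB": np.full(30, mean_a - sep),
                "bulk_low": rng.normal(0, 1, 30),
                "bulk_high": rng.normal(0, 1, 30),
            },
            n_blocks=3,
            noise_sd=noise,
            rng=rng,
        )
        out = bsa.normalize_parental(table)
        assert out.loc[out["sample"] == "parentA", "d"].mean() == pytest.approx(1.5, abs=1e-9)
        assert out.loc[out["sample"] == "parentB", "d"].mean() == pytest.approx(-1.5, abs=1e-9)

    def test_equal_parental_means_degenerate(self):
        table = make_signal_table(
            {"parentA": [1.0], "parentB": [1.0], "bulk_low": [0.0], "bulk_high": [0.0]}
        )
        with pytest.raises(DegenerateNormalizationError):
            bsa.normalize_parental(table)


class TestBenjaminiHochberg:
    def test_stepup_hand_example(self):
        adj = multipletests([0.01, 0.02, 0.04, 0.5], method="fdr_bh")[1]
        assert np.allclose(adj, [0.04, 0.04, 0.0533333333, 0.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=100)
    )
    def test_matches_bruteforce_oracle(self, p):
        ours = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, bh_bruteforce(p), atol=1e-12)


class TestSelectParentalProbes:
    def test_strong_parental_separation_selects_everything(self, rng):
        table = make_signal_table(
            {
                "parentA": np.full(100, 1.5),
                "parentB": np.full(100, -1.5),
                "bulk_low": np.zeros(100),
                "bulk_high": np.zeros(100),
            },
            n_blocks=8,
            noise_sd=0.1,
            rng=rng,
        )
        probes = bsa.select_parental_probes(table, probe_alpha=0.05)
        assert probes["selected"].all()

    def test_null_parents_select_about_alpha_fraction(self):
        rng = np.random.default_rng(17)
        table = make_signal_table(
            {
                "parentA": np.zeros(400),
                "parentB": np.zeros(400),
                "bulk_low": np.zeros(400),
                "bulk_high": np.zeros(400),
            },
            n_blocks=8,
            noise_sd=0.3,
            rng=rng,
        )
        probes = bsa.select_parental_probes(table, probe_alpha=0.05)
        # BH under the full null controls FDR; selections should be rare
        assert probes["selected"].mean() <= 0.05

    def test_single_block_rejected(self, rng):
        table = make_signal_table(
            {"parentA": [1.0], "parentB": [-1.0], "bulk_low": [0.0], "bulk_high": [0.0]},
            n_blocks=1,
        )
        with pytest.raises(InputError):
            bsa.select_parental_probes(table)


def _scan_fixture_table(n=40, region=None, noise=0.05, seed=2, n_blocks=4):
    """One-chromosome table; optionally plant a bulk-separated region."""
    rng = np.random.default_rng(seed)
    high = np.zeros(n)
    low = np.zeros(n)
    if region is not None:
        lo, hi = region
        high[lo:hi] = 1.5
        low[lo:hi] = -1.5
    return make_signal_table(
        {
            "parentA": np.full(n, 1.5),
            "parentB": np.full(n, -1.5),
            "bulk_low": low,
            "bulk_high": high,
        },
        n_blocks=n_blocks,
        noise_sd=noise,
        rng=rng,
    )


class TestWindowScan:
    def test_window_combinatorics(self):
        table = _scan_fixture_table(n=40)
        probes = [f"p{i:04d}" for i in range(40)]
        nonoverlap = bsa.window_scan(table, probes, ScanParameters(window_size=20, step=20))
        assert len(nonoverlap.windows) == 2
        sliding = bsa.window_scan(table, probes, ScanParameters(window_size=20, step=1))
        assert len(sliding.windows) == 21

    def test_truncated_window_flagged(self):
        table = _scan_fixture_table(n=10)
        probes = [f"p{i:04d}" for i in range(10)]
        res = bsa.window_scan(table, probes, ScanParameters(window_size=20))
        assert len(res.windows) == 1
        assert bool(res.windows["truncated"].iloc[0])
        assert res.windows["n_probes"].iloc[0] == 10

    def test_identical_bulks_rarely_significant(self):
        table = _scan_fixture_table(n=200, noise=0.2, seed=5)
        probes = [f"p{i:04d}" for i in range(200)]
        res = bsa.window_scan(table, probes, ScanParameters())
        assert (res.windows["p_adj"] < 0.01).mean() < 0.05

    def test_paired_t_matches_textbook_oracle(self):
        rng = np.random.default_rng(9)
        table = _scan_fixture_table(n=60, region=(20, 40), noise=0.3, seed=9)
        probes = [f"p{i:04d}" for i in range(60)]
        params = ScanParameters(window_size=20, step=3)
        res = bsa.window_scan(table, probes, params)
        pm = res.probes
        for _, w in res.windows.iterrows():
            sl = slice(int(w["start_idx"]), int(w["end_idx"]) + 1)
            t_ref, p_ref = sps.ttest_rel(pm["bulk_high"].iloc[sl], pm["bulk_low"].iloc[sl])
            assert w["t"] == pytest.approx(t_ref, rel=1e-9)
            assert w["p"] == pytest.approx(p_ref, rel=1e-9)

    def test_planted_region_windows_are_overwhelming(self):
        table = _scan_fixture_table(n=80, region=(30, 60), noise=0.1, seed=3, n_blocks=8)
        probes = [f"p{i:04d}" for i in range(80)]
        res = bsa.window_scan(table, probes, ScanParameters(window_size=20))
        inside = res.windows[(res.windows["start_idx"] >= 30) & (res.windows["end_idx"] < 60)]
        assert (inside["p_adj"] < 1e-6).all()


class TestCallRegions:
    def test_no_signal_no_regions(self):
        table = _scan_fixture_table(n=100, noise=0.1, seed=4, n_blocks=8)
        probes, scan, regions = bsa.scan_table(table)
        assert regions == []

    def test_single_planted_region_recovered(self):
        table = _scan_fixture_table(n=120, region=(50, 80), noise=0.1, seed=6, n_blocks=8)
        probes, scan, regions = bsa.scan_table(table)
        assert len(regions) == 1
        r = regions[0]
        # positions are (index + 1) kb in the fixture
        assert r.start_bp <= 51_000 and r.end_bp >= 79_000
        assert r.enriched == {"bulk_low": "B", "bulk_high": "A"}
        assert r.min_adjusted_p < 0.01

    def test_direction_follows_planted_origin(self):
        # flip the planted enrichment: bulk_high carries B alleles
        rng = np.random.default_rng(13)
        n = 120
        high = np.zeros(n)
        low = np.zeros(n)
        high[40:70] = -1.5
        low[40:70] = 1.5
        table = make_signal_table(
            {
                "parentA": np.full(n, 1.5),
                "parentB": np.full(n, -1.5),
                "bulk_low": low,
                "bulk_high": high,
            },
            n_blocks=8,
            noise_sd=0.1,
            rng=rng,
        )
        _, _, regions = bsa.scan_table(table)
        assert len(regions) == 1
        assert regions[0].enriched == {"bulk_low": "A", "bulk_high": "B"}
        direct = bsa.assign_direction(regions[0], bsa.normalize_parental(table))
        assert direct == regions[0].enriched

    def test_full_parental_fraction_blocks_strict_mixtures(self):
        # bulks are strict mixtures (|d| <= 0.9 < parental diff), fraction=1
        table = _scan_fixture_table(n=60, noise=0.0, seed=1)
        idx = table["sample"] == "bulk_high"
        table.loc[idx, "d"] = 0.9
        table.loc[table["sample"] == "bulk_low", "d"] = -0.9
        _, _, regions = bsa.scan_table(table, ScanParameters(parental_fraction=1.0))
        assert regions == []

    def test_merge_bridges_small_gaps_only(self):
        table = _scan_fixture_table(n=200, region=(40, 80), noise=0.1, seed=8, n_blocks=8)
        # knock a 2-probe hole in the middle of the planted block
        hole = table["probe"].isin(["p0060", "p0061"]) & table["sample"].isin(
            ["bulk_high", "bulk_low"]
        )
        table.loc[hole, "d"] = 0.0
        _, _, regions = bsa.scan_table(table, ScanParameters(merge_gap=2))
        assert len(regions) == 1
        _, _, split = bsa.scan_table(table, ScanParameters(merge_gap=0))
        assert len(split) == 2


def test_region_length_in_kb():
    region = QTLRegion(
        chromosome="chrVII",
        start_bp=674_690,
        end_bp=691_654,
        n_probes=10,
        peak_probe="p",
        min_adjusted_p=1e-4,
        mean_bulk_difference=1.0,
    )
    assert round(region.length_bp / 1000) == 17
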