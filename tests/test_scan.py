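"""Scan statistics, track fitting, thresholding and region calling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bsamap.intervals import GenomicInterval, intersect_regions
from bsamap.scan import (
    IndexTrack,
    build_track,
    call_regions,
    delta_snp_index,
    euclidean_distance,
    filter_informative_sites,
    fit_track,
    scan_sites,
    snp_index,
    threshold_median_3sd,
)
from bsamap.variants import VariantSite


def site(fuzzy=(30, 0), fuzzless=(30, 0), parents=True, pos=100, var_class="SNP"):
    depths = {"fuzzy": fuzzy, "fuzzless": fuzzless}
    if parents:
        depths |= {"parent_wt": (50, 0), "parent_mut": (0, 50)}
    return VariantSite("chr1", pos, "A", "C" if var_class == "SNP" else "AT",
                       var_class=var_class, depths=depths)


class TestPerSiteStatistics:
    def test_snp_index_is_alt_fraction(self):
        s = site(fuzzy=(20, 40))
        assert snp_index(s, "fuzzy") == pytest.approx(0.6667, abs=1e-4)
        assert snp_index(site(fuzzy=(60, 0)), "fuzzy") == 0.0
        assert snp_index(site(fuzzy=(0, 35)), "fuzzy") == 1.0

    def test_delta_snp_index_orientation(self):
        s = site(fuzzless=(20, 40), fuzzy=(60, 0))
        assert delta_snp_index(s) == pytest.approx(0.6667, abs=1e-4)
        assert delta_snp_index(site(fuzzy=(10, 10), fuzzless=(20, 20))) == 0.0

    def brute_force_ed(self, s, power=1):
        """Oracle: explicit sum over the site's allele set."""
        alleles = "ACGT" if s.var_class == "SNP" else [s.ref, s.alt]
        total = 0.0
        for a in alleles:
            fs = []
            for pool in ("fuzzless", "fuzzy"):
                f_alt = s.alt_fraction(pool)
                fs.append(f_alt if a == s.alt else (1 - f_alt) if a == s.ref else 0.0)
            total += (fs[0] - fs[1]) ** 2
        return (total ** 0.5) ** power

    @pytest.mark.parametrize("var_class", ["SNP", "InDel"])
    def test_euclidean_distance_closed_forms(self, var_class):
        fixed = site(fuzzless=(0, 60), fuzzy=(60, 0), var_class=var_class)
        assert euclidean_distance(fixed) == pytest.approx(np.sqrt(2), abs=1e-9)
        assert euclidean_distance(
            site(fuzzless=(20, 40), fuzzy=(60, 0), var_class=var_class)
        ) == pytest.approx(np.sqrt(2) * 2 / 3, abs=1e-9)
        same = site(fuzzless=(30, 30), fuzzy=(10, 10), var_class=var_class)
        assert euclidean_distance(same) == pytest.approx(0.0, abs=1e-12)

    def test_euclidean_distance_matches_brute_force_and_power(self, rng):
        for _ in range(50):
            f1, f2 = rng.integers(0, 40, size=2), rng.integers(0, 40, size=2)
            if f1.sum() == 0 or f2.sum() == 0:
                continue
            vc = "SNP" if rng.random() < 0.5 else "InDel"
            s = site(fuzzy=tuple(f1), fuzzless=tuple(f2), var_class=vc)
            ed = euclidean_distance(s)
            assert ed == pytest.approx(self.brute_force_ed(s), abs=1e-12)
            assert euclidean_distance(s, power=4) == pytest.approx(ed**4, abs=1e-12)
            assert 0 <= ed <= np.sqrt(2) + 1e-12


class TestInformativeFilter:
    def test_low_pool_depth_dropped(self):
        s = site(fuzzy=(2, 1))
        assert filter_informative_sites([s], min_depth=10) == []

    def test_clean_site_kept(self):
        s = site(fuzzy=(25, 25), fuzzless=(10, 40))
        assert filter_informative_sites([s]) == [s]

    def test_inconsistent_parents_dropped(self):
        s = site()
        s.depths["parent_mut"] = (30, 20)  # alt fraction 0.4 in mutant parent
        assert filter_informative_sites([s]) == []

    def test_simulated_truth_retention(self, small_f2_scan):
        cfg, pop, pools, sites = small_f2_scan
        kept = filter_informative_sites(sites)
        # parents are simulated as opposite homozygotes at 50x with error
        # 1e-3, so nearly every site passes both filters
        assert len(kept) / len(sites) > 0.99


class TestFitTrack:
    def track(self, raw, positions=None, statistic="ED"):
        raw = np.asarray(raw, dtype=float)
        if positions is None:
            positions = np.arange(1, raw.size + 1) * 1e5
        return IndexTrack("chr1", positions, raw, statistic)

    def test_constant_track_is_fixed_point(self):
        fitted = fit_track(self.track(np.full(40, 0.3)), window=5e5).fitted
        assert fitted == pytest.approx(np.full(40, 0.3))

    def test_window_below_spacing_returns_raw(self, rng):
        raw = rng.random(30)
        t = fit_track(self.track(raw), window=1e4)  # spacing is 1e5
        assert t.fitted == pytest.approx(raw)

    def test_step_signal_fitted_monotone(self):
        raw = np.concatenate([np.zeros(25), np.full(25, 0.8)])
        t = fit_track(self.track(raw), window=8e5)
        assert (np.diff(t.fitted) >= -1e-12).all()
        # direct evaluation of the tricube mean at the step midpoint
        pos = t.positions
        i = 25
        half = 4e5
        mask = np.abs(pos - pos[i]) <= half
        w = (1 - (np.abs(pos[mask] - pos[i]) / half) ** 3) ** 3
        assert t.fitted[i] == pytest.approx(np.dot(w, raw[mask]) / w.sum())

    def test_fitted_within_raw_range(self, rng):
        raw = rng.random(100)
        t = fit_track(self.track(raw), window=7e5)
        assert t.fitted.min() >= raw.min() - 1e-12
        assert t.fitted.max() <= raw.max() + 1e-12

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            fit_track(self.track(np.array([])))


class TestThreshold:
    def test_constant_fitted_gives_itself(self):
        t = IndexTrack("c", [1, 2], [0.1, 0.1], "ED", fitted=np.array([0.1, 0.1]))
        assert threshold_median_3sd(t) == pytest.approx(0.1)
        t0 = IndexTrack("c", [1, 2, 3, 4], [0] * 4, "ED", fitted=np.zeros(4))
        assert threshold_median_3sd(t0) == 0.0

    def test_hand_computed_example(self):
        # fitted {0.0, 0.1, 0.2, 0.9}: median 0.15, sample SD 0.40825
        fitted = np.array([0.0, 0.1, 0.2, 0.9])
        t = IndexTrack("c", [1, 2, 3, 4], fitted, "ED", fitted=fitted)
        assert threshold_median_3sd(t) == pytest.approx(0.15 + 3 * 0.4082483, abs=1e-6)

    def test_single_point_rejected(self):
        t = IndexTrack("c", [1], [0.1], "ED", fitted=np.array([0.1]))
        with pytest.raises(ValueError):
            threshold_median_3sd(t)


def brute_force_regions(positions, fitted, threshold, merge_gap):
    """Oracle: enumerate maximal above-threshold runs, then merge by gap."""
    runs = []
    current = None
    for i, (p, f) in enumerate(zip(positions, fitted)):
        if f >= threshold:
            if current is None:
                current = [i, i]
            else:
                current[1] = i
        else:
            if current is not None:
                runs.append(current)
            current = None
    if current is not None:
        runs.append(current)
    merged = []
    for s, e in runs:
        if merged and positions[s] - positions[merged[-1][1]] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(int(positions[s]), int(positions[e])) for s, e in merged]


class TestCallRegions:
    def test_worked_example(self):
        fitted = np.array([0.1, 0.4, 0.5, 0.2, 0.6])
        pos = np.array([1, 2, 3, 4, 5]) * 1e5
        t = IndexTrack("c", pos, fitted, "ED", fitted=fitted)
        regions = call_regions(t, threshold=0.35, merge_gap=0)
        assert [(iv.start, iv.end) for iv in regions] == [(200000, 300000), (500000, 500000)]

    def test_threshold_above_max_gives_empty(self):
        fitted = np.array([0.1, 0.2])
        t = IndexTrack("c", [1, 2], fitted, "ED", fitted=fitted)
        assert call_regions(t, threshold=0.5) == []

    def test_merge_gap_bridges_nearby_runs(self):
        fitted = np.array([0.9, 0.0, 0.9])
        t = IndexTrack("c", [100, 200, 300], fitted, "ED", fitted=fitted)
        assert len(call_regions(t, 0.5, merge_gap=500)) == 1
        assert len(call_regions(t, 0.5, merge_gap=50)) == 2

    @given(st.data())
    def test_matches_brute_force_enumeration(self, data):
        n = data.draw(st.integers(1, 50))
        fitted = np.array(data.draw(
            st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)
        ))
        gaps = np.array(data.draw(
            st.lists(st.integers(1, 200_000), min_size=n, max_size=n)
        ))
        positions = np.cumsum(gaps).astype(float)
        threshold = data.draw(st.floats(0, 1))
        merge_gap = data.draw(st.sampled_from([0, 50_000, 150_000]))
        t = IndexTrack("c", positions, fitted, "ED", fitted=fitted)
        got = [(iv.start, iv.end) for iv in call_regions(t, threshold, merge_gap)]
        assert got == brute_force_regions(positions, fitted, threshold, merge_gap)
        for iv in call_regions(t, threshold, merge_gap):
            inside = (positions >= iv.start) & (positions <= iv.end)
            assert (fitted[inside] >= threshold).any()


class TestIntersectRegions:
    def test_published_region_overlap(self):
        ed = [GenomicInterval("A08", 76_294, 2_305_623)]
        dsnp = [GenomicInterval("A08", 68_670, 2_195_304)]
        merged = intersect_regions(ed, dsnp)
        assert merged == [GenomicInterval("A08", 76_294, 2_195_304)]
        assert ed[0].length / 1e6 == pytest.approx(2.23, abs=0.005)

    def test_disjoint_and_idempotent(self):
        a = [GenomicInterval("c", 1, 10)]
        b = [GenomicInterval("c", 20, 30)]
        assert intersect_regions(a, b) == []
        assert intersect_regions(a, a) == a

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(0, 500)), max_size=8),
           st.lists(st.tuples(st.integers(0, 500), st.integers(0, 500)), max_size=8))
    def test_commutative(self, raw_a, raw_b):
        a = [GenomicInterval("c", min(x, y), max(x, y)) for x, y in raw_a]
        b = [GenomicInterval("c", min(x, y), max(x, y)) for x, y in raw_b]
        assert intersect_regions(a, b) == intersect_regions(b, a)


class TestScanEndToEnd:
    def test_simulated_scan_covers_causal_position(self, small_f2_scan):
        cfg, pop, pools, sites = small_f2_scan
        result = scan_sites(sites)
        assert result.intersected, "no candidate region called"
        assert any(iv.contains(cfg.causal_pos) for iv in result.intersected)

    def test_by_class_scans_snps_and_indels_separately(self, small_f2_scan):
        cfg, pop, pools, sites = small_f2_scan
        result = scan_sites(sites, by_class=True)
        assert set(result.tracks) == {
            "ED/SNP", "ED/InDel", "delta_snp_index/SNP", "delta_snp_index/InDel"
        }
        assert any(iv.contains(cfg.causal_pos) for iv in result.intersected)

    def test_region_width_does_not_grow_with_depth(self):
        """Read depth reduces only read-sampling noise; the called width is
        linkage-dominated, so it must not widen at higher coverage."""
        from bsamap.simulate import (
            SimulationConfig, make_pools, simulate_pool_depths, simulate_population,
        )

        widths = {}
        for depth in (20.0, 100.0):
            per_run = []
            for r in range(8):
                cfg = SimulationConfig(
                    n_individuals=1000, n_sites=1200, mean_depth=depth, seed=300 + r
                )
                pop = simulate_population(cfg)
                pools = make_pools(pop, cfg.pool_size, seed=cfg.seed)
                sites = simulate_pool_depths(pop, pools, cfg)
                res = scan_sites(sites)
                per_run.append(sum(iv.length for iv in res.intersected))
            widths[depth] = np.median(per_run)
        assert widths[100.0] <= 1.25 * widths[20.0]
        assert widths[100.0] < 0.2 * 10_000_000
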