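"""search: local chain search, global difference search, orchestration."""

import logging

import numpy as np
import pytest

from unitfinder.peaklist import PeakList
from unitfinder.search import (
    ChainEvidence,
    DifferenceMatch,
    SearchConfig,
    find_units,
    global_search,
    local_search,
    pairwise_differences,
)
from unitfinder.selection import UnitCandidate, default_criteria

from conftest import CF2, PEG, PPG, make_mixture

U = PEG.exact_mass  # 44.0262 Da


def ladder(start, unit_mass, n):
    mz = start + np.arange(n) * unit_mass
    return PeakList(mz, np.full(n, 10.0))


def cfg(**kwargs):
    defaults = dict(selection_error=0.001, loop_error=0.001, m=3)
    defaults.update(kwargs)
    return SearchConfig(**defaults)


def hit_formulas(hits):
    return {h.candidate.formula_string for h in hits}


class TestLocalSearch:
    def test_exact_ladder_single_chain(self):
        peaks = ladder(100.0, U, 4)
        hits = local_search(peaks, [PEG], cfg(m=3))
        assert len(hits) == 1
        assert hits[0].count == 1
        assert hits[0].evidence[0].start_mz == 100.0
        assert len(hits[0].evidence[0].matched_mz) == 3

    def test_m_exceeding_ladder_yields_nothing(self):
        peaks = ladder(100.0, U, 4)
        assert local_search(peaks, [PEG], cfg(m=4)) == []

    def test_two_starts_at_m_one(self):
        peaks = PeakList(
            np.array([100.0, 144.0262, 200.0, 244.0262]), np.full(4, 1.0)
        )
        hits = local_search(peaks, [PEG], cfg(m=1))
        assert len(hits) == 1
        assert hits[0].count == 2

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(21)
        mz = np.sort(
            np.concatenate(
                [100.0 + np.arange(6) * U, rng.uniform(80, 600, 40)]
            )
        )
        peaks = PeakList(np.unique(mz), np.ones(len(np.unique(mz))))
        for m in (1, 2, 3):
            hits = local_search(peaks, [PEG], cfg(m=m))
            # oracle: direct scan over starting peaks
            expected = 0
            for p in peaks.mz:
                if all(
                    np.any(np.abs(peaks.mz - (p + k * U)) <= 0.001)
                    for k in range(1, m + 1)
                ):
                    expected += 1
            got = hits[0].count if hits else 0
            assert got == expected

    def test_chain_uses_theoretical_sums(self):
        # rungs drift +0.0009 Da each: against the theoretical sum p + n*u
        # the n-th rung is off by 0.0009*n, while observed-mass chaining
        # would see only 0.0009 per step and wrongly pass at loop_error=0.002
        drift = np.array([0.0, 0.0009, 0.0018, 0.0027])
        peaks = PeakList(100.0 + np.arange(4) * U + drift, np.ones(4))
        hits = local_search(peaks, [PEG], cfg(m=3, loop_error=0.003))
        assert hits and hits[0].count == 1
        assert local_search(peaks, [PEG], cfg(m=3, loop_error=0.002)) == []

    def test_empty_peaklist_rejected(self):
        with pytest.raises(ValueError):
            local_search(PeakList(np.array([]), np.array([])), [PEG], cfg())

    def test_evidence_matches_are_real_peaks(self):
        peaks = ladder(100.0, U, 5)
        hits = local_search(peaks, [PEG], cfg(m=3))
        for chain in hits[0].evidence:
            assert len(chain.matched_mz) == 3
            for v in chain.matched_mz:
                assert v in peaks.mz


class TestPairwiseDifferences:
    def test_simple(self):
        peaks = PeakList(np.array([100.0, 150.0, 175.0]), np.ones(3))
        diffs = pairwise_differences(peaks)
        np.testing.assert_allclose(diffs.values, [25.0, 50.0, 75.0])

    def test_count_formula(self):
        rng = np.random.default_rng(2)
        n = 17
        peaks = PeakList(np.sort(rng.uniform(10, 500, n)), np.ones(n))
        assert len(pairwise_differences(peaks)) == n * (n - 1) // 2

    def test_equally_spaced_ladder_multiplicities(self):
        d = 7.5
        peaks = PeakList(100.0 + d * np.arange(5), np.ones(5))
        diffs = pairwise_differences(peaks)
        values, counts = np.unique(np.round(diffs.values, 9), return_counts=True)
        np.testing.assert_allclose(values, d * np.array([1, 2, 3, 4]))
        np.testing.assert_array_equal(counts, [4, 3, 2, 1])

    def test_provenance(self):
        peaks = PeakList(np.array([100.0, 150.0, 175.0]), np.ones(3))
        diffs = pairwise_differences(peaks)
        recon = peaks.mz[diffs.high_index] - peaks.mz[diffs.low_index]
        np.testing.assert_allclose(recon, diffs.values)

    def test_needs_two_peaks(self):
        with pytest.raises(ValueError):
            pairwise_differences(PeakList(np.array([100.0]), np.ones(1)))


class TestGlobalSearch:
    def test_exact_ladder_count_six(self):
        peaks = ladder(100.0, U, 4)
        hits = global_search(peaks, [PEG], cfg(m=3))
        assert len(hits) == 1
        assert hits[0].count == 6  # multiples {1,2,3} x multiplicities {3,2,1}
        ks = sorted(ev.multiple for ev in hits[0].evidence)
        assert ks == [1, 1, 1, 2, 2, 3]

    def test_missing_intermediate_multiple_fails(self):
        # 2*u absent: {100, 144.0262, 300, 432.0786} has 1*u and 3*u only
        peaks = PeakList(
            np.array([100.0, 100.0 + U, 300.0, 300.0 + 3 * U]), np.ones(4)
        )
        hits = global_search(peaks, [PEG], cfg(m=3))
        assert hits == []
        assert global_search(peaks, [PEG], cfg(m=1))

    def test_all_multiples_present_is_reported(self):
        # the 3-peak set {100, 144.0262, 232.0786} contains u, 2u AND 3u
        peaks = PeakList(
            np.array([100.0, 100.0 + U, 100.0 + 3 * U]), np.ones(3)
        )
        hits = global_search(peaks, [PEG], cfg(m=3))
        assert len(hits) == 1 and hits[0].count == 3

    def test_lenient_mode(self):
        peaks = PeakList(
            np.array([100.0, 100.0 + U, 300.0, 300.0 + 3 * U]), np.ones(4)
        )
        hits = global_search(
            peaks, [PEG], cfg(m=3, strict_multiples=False)
        )
        assert len(hits) == 1  # 1*u plus some higher multiple suffices

    def test_oversized_candidate_never_hits(self):
        peaks = ladder(100.0, U, 4)
        huge = UnitCandidate((("C", 50),), 600.0, 0, formula_string="huge")
        assert global_search(peaks, [huge], cfg(m=1)) == []

    def test_needs_two_peaks(self):
        with pytest.raises(ValueError):
            global_search(PeakList(np.array([100.0]), np.ones(1)), [PEG], cfg())

    def test_count_matches_brute_force(self):
        rng = np.random.default_rng(9)
        mz = np.unique(
            np.concatenate([150.0 + np.arange(5) * U, rng.uniform(80, 700, 30)])
        )
        peaks = PeakList(mz, np.ones(len(mz)))
        hits = global_search(peaks, [PEG], cfg(m=3))
        # oracle: count pair differences within tolerance of k*u directly
        expected = 0
        for k in (1, 2, 3):
            for i in range(len(mz)):
                for j in range(i + 1, len(mz)):
                    if abs((mz[j] - mz[i]) - k * U) <= 0.001:
                        expected += 1
        got = hits[0].count if hits else 0
        assert got == expected


class TestFindUnits:
    def test_untargeted_uses_global(self, mixture_peaks, chofx_candidates):
        hits = find_units(
            mixture_peaks, SearchConfig(mode="untargeted"),
            library=chofx_candidates,
        )
        assert hits and all(h.algorithm == "global" for h in hits)

    def test_targeted_local_matches_direct_call(self, chofx_candidates):
        from unitfinder.selection import select_units

        peaks = ladder(100.0, U, 5)
        cfg_t = SearchConfig(mode="targeted", algorithm="local", m=3)
        via_workflow = find_units(
            peaks, cfg_t, criteria=default_criteria(), library=chofx_candidates
        )
        selected = select_units(chofx_candidates, default_criteria())
        direct = local_search(peaks, selected, cfg_t)
        as_map = lambda hits: {h.candidate.formula_string: h.count for h in hits}
        assert as_map(via_workflow) == as_map(direct)
        assert as_map(direct).get("C2H4OX2", 0) >= 1

    def test_empty_candidates_warns_and_returns_empty(self, caplog):
        peaks = ladder(100.0, U, 4)
        with caplog.at_level(logging.WARNING, logger="unitfinder.search"):
            hits = find_units(peaks, SearchConfig(), library=[])
        assert hits == []
        assert any("no candidate units" in r.message for r in caplog.records)

    def test_hits_sorted_by_count_then_mass(self, mixture_peaks, chofx_candidates):
        hits = find_units(mixture_peaks, SearchConfig(), library=chofx_candidates)
        keys = [(-h.count, h.candidate.exact_mass) for h in hits]
        assert keys == sorted(keys)


class TestProperties:
    def _random_dataset(self, seed):
        rng = np.random.default_rng(seed)
        units = [PEG, PPG, CF2]
        unit = units[seed % 3]
        base = rng.uniform(80, 200)
        series = base + np.arange(rng.integers(4, 8)) * unit.exact_mass
        noise = rng.uniform(60, 800, rng.integers(10, 40))
        mz = np.unique(np.concatenate([series, noise]))
        return PeakList(mz, np.ones(len(mz)))

    @pytest.mark.parametrize("seed", range(20))
    def test_local_contained_in_global(self, seed, chofx_candidates):
        peaks = self._random_dataset(seed)
        c = cfg(m=3, selection_error=0.0025, loop_error=0.0025)
        local = hit_formulas(local_search(peaks, chofx_candidates, c))
        glob = hit_formulas(global_search(peaks, chofx_candidates, c))
        assert local <= glob

    @pytest.mark.parametrize("seed", range(0, 12, 3))
    def test_monotone_in_m(self, seed, chofx_candidates):
        peaks = self._random_dataset(seed)
        for algo in (local_search, global_search):
            prev = None
            for m in (1, 2, 3, 4):
                got = hit_formulas(algo(peaks, chofx_candidates, cfg(m=m)))
                if prev is not None:
                    assert got <= prev
                prev = got

    @pytest.mark.parametrize("seed", range(0, 12, 3))
    def test_monotone_in_tolerance(self, seed, chofx_candidates):
        peaks = self._random_dataset(seed)
        for algo in (local_search, global_search):
            prev = None
            for err in (0.0005, 0.0025, 0.01):
                got = hit_formulas(
                    algo(peaks, chofx_candidates,
                         cfg(selection_error=err, loop_error=err))
                )
                if prev is not None:
                    assert prev <= got
                prev = got

    def test_planted_unit_recovery_both_algorithms(self, chofx_candidates):
        # sequential ladders longer than m, jitter bounded inside tolerance:
        # both detectors must recover every planted unit (100% recall)
        from unitfinder.simulate import SeriesSpec, generate_spectrum

        for seed in (1, 2, 3):
            series = [
                SeriesSpec(PEG, 150.0, 0, 6, jitter_sd=0.0003),
                SeriesSpec(PPG, 201.0, 0, 6, jitter_sd=0.0003),
                SeriesSpec(CF2, 351.0, 0, 6, jitter_sd=0.0003),
            ]
            peaks = generate_spectrum(
                series, n_noise=30, mz_range=(60, 900), seed=seed
            )
            c = cfg(m=3, selection_error=0.0025, loop_error=0.0025)
            expected = {"C2H4OX2", "C3H6OX2", "CF2X2"}
            for algo in (local_search, global_search):
                found = hit_formulas(algo(peaks, chofx_candidates, c))
                assert expected <= found


class TestEvaluationMirror:
    """Sequential ladders are found by both detectors; the sparse pattern
    only by the global one at defaults, and by the local one after loosening."""

    def test_global_untargeted_finds_all_three(self, chofx_candidates):
        peaks, _ = make_mixture()
        hits = find_units(
            peaks, SearchConfig(mode="untargeted"), library=chofx_candidates
        )
        found = hit_formulas(hits)
        assert {"C2H4OX2", "C3H6OX2", "CF2X2"} <= found

    def test_local_default_misses_sparse_cf2(self, chofx_candidates):
        peaks, _ = make_mixture()
        hits = local_search(
            peaks, chofx_candidates, SearchConfig(mode="targeted", m=3)
        )
        found = hit_formulas(hits)
        assert {"C2H4OX2", "C3H6OX2"} <= found
        assert "CF2X2" not in found

    def test_local_targeted_loosened_finds_cf2(self, chofx_candidates):
        peaks, _ = make_mixture()
        hits = local_search(
            peaks, chofx_candidates, SearchConfig(mode="targeted", m=1)
        )
        assert "CF2X2" in hit_formulas(hits)


class TestScalingShape:
    def test_global_scales_better_with_library_size(self):
        import time

        rng = np.random.default_rng(123)
        mz = np.unique(rng.uniform(100, 1500, 800))
        peaks = PeakList(mz, np.ones(len(mz)))
        libraries = {
            n: [
                UnitCandidate((("C", 1),), float(m), 0, formula_string=f"u{i}")
                for i, m in enumerate(rng.uniform(14, 200, n))
            ]
            for n in (20, 800)
        }
        c = cfg(m=3)
        times = {}
        for name, algo in (("local", local_search), ("global", global_search)):
            for n, lib in libraries.items():
                t0 = time.perf_counter()
                algo(peaks, lib, c)
                times[(name, n)] = time.perf_counter() - t0
        local_ratio = times[("local", 800)] / times[("local", 20)]
        global_ratio = times[("global", 800)] / times[("global", 20)]
        assert global_ratio < local_ratio
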