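"""Segmentation, distal-site identification, and usage quantification."""

import statistics

import numpy as np
import pandas as pd
import pytest

from apakit import (
    assess_sample_integrity,
    global_breakpoint_check,
    identify_distal_site,
    mse_ratio,
    passes_coverage_gate,
    pool_profiles,
    quantify_usage,
    rpm_normalize,
    run_paqr,
    segment_exon,
    tin_score,
)

RNG = np.random.default_rng(20260928)


# ---------------------------------------------------------------------------
# TIN / sample integrity
# ---------------------------------------------------------------------------

class TestSampleIntegrity:
    def test_uniform_coverage_is_100(self):
        assert tin_score(np.full(800, 3.0)) == pytest.approx(100.0)

    def test_single_base_coverage_tends_to_zero(self):
        spike = np.zeros(1000)
        spike[17] = 99.0
        assert tin_score(spike) == pytest.approx(0.1)

    def test_median_gate_is_inclusive_at_threshold(self):
        # three transcripts engineered to straddle the threshold
        flat = np.full(100, 5.0)
        half = np.zeros(100)
        half[:60] = 5.0
        res = assess_sample_integrity({"t1": flat, "t2": half, "t3": half},
                                      "s", min_tin=70.0)
        assert res.median_tin == pytest.approx(60.0)
        assert not res.passed
        res2 = assess_sample_integrity({"t1": flat, "t2": flat, "t3": half}, "s")
        assert res2.passed

    def test_all_zero_transcripts_fail_with_reason(self):
        res = assess_sample_integrity({"t1": np.zeros(50)}, "s")
        assert not res.passed and "nonzero" in res.reason

    def test_zero_transcript_excluded_from_median(self):
        res = assess_sample_integrity({"t1": np.zeros(50),
                                       "t2": np.full(50, 2.0)}, "s")
        assert res.n_transcripts == 1 and res.median_tin == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# MSE ratio
# ---------------------------------------------------------------------------

class TestMseRatio:
    def test_clean_balanced_step(self):
        arr = np.array([10.0] * 200 + [0.0] * 200)
        d = mse_ratio(arr, 200)
        assert d.mse_up == 0.0 and d.mse_down == 0.0
        assert d.mse_total == pytest.approx(25.0)
        assert d.ratio == 0.0 and d.used and d.reason == "used"

    def test_flat_array_rejected_downstream_not_lower(self):
        d = mse_ratio(np.full(400, 7.0), 200)
        assert not d.used and d.reason == "downstream_not_lower"

    def test_short_segment_rejected(self):
        arr = np.array([10.0] * 50 + [0.0] * 350)
        d = mse_ratio(arr, 50)
        assert not d.used and d.reason == "segment_too_short"

    def test_threshold_boundary_inclusive(self):
        # noise-free two-level step plus within-segment variance tuned near 0.5
        up = np.tile([12.0, 8.0], 100)     # mean 10, var 4
        down = np.tile([2.0, -0.0], 100)   # mean 1, var 1
        arr = np.concatenate([up, down])
        d = mse_ratio(arr, 200)
        expected = (4.0 + 1.0) / np.var(arr)
        assert d.ratio == pytest.approx(expected)
        assert d.used == (expected <= 0.5)

    def test_scale_invariance(self):
        arr = RNG.poisson(10.0, 600).astype(float)
        arr[300:] *= 0.3
        base = mse_ratio(arr, 300)
        for c in (0.01, 3.7, 1000.0):
            scaled = mse_ratio(c * arr, 300)
            assert scaled.used == base.used
            if np.isfinite(base.ratio):
                assert scaled.ratio == pytest.approx(base.ratio, rel=1e-9)

    def test_breakpoint_outside_segment_raises(self):
        with pytest.raises(ValueError):
            mse_ratio(np.ones(10), 0)


# ---------------------------------------------------------------------------
# Distal site identification
# ---------------------------------------------------------------------------

def _two_site_values(level1=10.0, level2=4.0, seg=300, ext3=200):
    return np.array([level1] * seg + [level2] * seg + [0.0] * ext3)


class TestDistalSite:
    def test_clean_step_qualifies_last_site(self, exon_factory):
        exon, profs = exon_factory({"s1": _two_site_values()}, [299, 599])
        distal = identify_distal_site(exon, profs["s1"], read_length=100)
        assert distal is exon.sites[-1]

    def test_uniform_coverage_past_sites_disqualifies(self, exon_factory):
        values = np.full(800, 10.0)  # no drop anywhere, incl. the extension
        exon, profs = exon_factory({"s1": values}, [299, 599])
        assert identify_distal_site(exon, profs["s1"], read_length=100) is None

    def test_condition2_requires_low_downstream_vs_exon_start(self, exon_factory):
        # downstream of the last site drops relative to upstream (cond 1) but
        # stays above 10% of the start coverage (cond 2)
        values = np.array([100.0] * 300 + [60.0] * 300 + [30.0] * 200)
        exon, profs = exon_factory({"s1": values}, [299, 599])
        assert identify_distal_site(exon, profs["s1"], read_length=100) is None

    def test_falls_back_to_more_proximal_site(self, exon_factory):
        # the 3'-most site has no step; the middle one does
        values = np.array([10.0] * 300 + [0.0] * 500)
        exon, profs = exon_factory({"s1": values}, [299, 599])
        distal = identify_distal_site(exon, profs["s1"], read_length=100)
        assert distal is exon.sites[0]

    def test_low_coverage_gate(self, exon_factory):
        values = _two_site_values(4.0, 1.6)
        exon, profs = exon_factory({"s1": values}, [299, 599])
        distal = identify_distal_site(exon, profs["s1"], read_length=100)
        ok, reason = passes_coverage_gate(exon, profs["s1"], distal)
        assert not ok and reason == "low_coverage"

    def test_gate_requires_internal_site(self, exon_factory):
        values = np.array([10.0] * 300 + [0.0] * 200)
        exon, profs = exon_factory({"s1": values}, [299])
        distal = identify_distal_site(exon, profs["s1"], read_length=100)
        ok, reason = passes_coverage_gate(exon, profs["s1"], distal)
        assert not ok and reason == "no_internal_site"


# ---------------------------------------------------------------------------
# Recursive segmentation
# ---------------------------------------------------------------------------

def _noisy_steps(levels, seg=300, ext3=200, rng=RNG, sd=0.0):
    parts = [np.full(seg, lv, float) for lv in levels] + [np.zeros(ext3)]
    arr = np.concatenate(parts)
    if sd:
        arr = np.clip(arr + rng.normal(0, sd, arr.size), 0, None)
    return arr


class TestSegmentExon:
    def test_two_planted_steps_recovered_in_two_replicates(self, exon_factory):
        vals = {s: _noisy_steps([10, 6, 0], sd=0.5) for s in ("r1", "r2")}
        exon, profs = exon_factory(vals, [299, 599, 899])
        used, calls = segment_exon(exon, [profs["r1"], profs["r2"]],
                                   exon.sites[-1])
        assert [s.site_id for s in used] == ["exonA_s0", "exonA_s1"]
        for s in used:
            assert all(d.used for d in calls[s.site_id].per_sample)

    def test_step_in_one_of_three_replicates_not_used(self, exon_factory):
        stepped = _noisy_steps([10, 0], sd=0.4)
        flat = _noisy_steps([10, 10], sd=0.4)
        flat[-200:] = 0.0  # both shapes share the post-distal drop
        exon, profs = exon_factory({"r1": stepped, "r2": flat, "r3": flat},
                                   [299, 599])
        used, _ = segment_exon(exon, [profs[s] for s in ("r1", "r2", "r3")],
                               exon.sites[-1])
        assert used == []

    def test_step_in_two_of_three_replicates_used(self, exon_factory):
        stepped = _noisy_steps([10, 0], sd=0.4)
        flat = _noisy_steps([10, 10], sd=0.4)
        flat[-200:] = 0.0
        exon, profs = exon_factory(
            {"r1": stepped, "r2": stepped.copy(), "r3": flat}, [299, 599])
        used, _ = segment_exon(exon, [profs[s] for s in ("r1", "r2", "r3")],
                               exon.sites[-1])
        assert [s.site_id for s in used] == ["exonA_s0"]

    def test_closely_spaced_sites_report_exactly_one(self, exon_factory):
        # two catalog sites 50 nt apart flanking one true step at offset 299
        vals = {s: _noisy_steps([10, 0], sd=0.3) for s in ("r1", "r2")}
        exon, profs = exon_factory(vals, [274, 324, 599])
        used, _ = segment_exon(exon, [profs["r1"], profs["r2"]],
                               exon.sites[-1])
        assert len(used) == 1
        assert used[0].site_id in ("exonA_s0", "exonA_s1")

    def test_zero_coverage_replicate_abstains(self, exon_factory):
        stepped = _noisy_steps([10, 0], sd=0.3)
        silent = np.zeros_like(stepped)
        exon, profs = exon_factory(
            {"r1": stepped, "r2": stepped.copy(), "r3": silent}, [299, 599])
        used, calls = segment_exon(exon, [profs[s] for s in ("r1", "r2", "r3")],
                                   exon.sites[-1])
        assert [s.site_id for s in used] == ["exonA_s0"]
        assert calls["exonA_s0"].support == 2

    def test_scale_invariance_of_calls_and_usage(self, exon_factory):
        base = _noisy_steps([10, 4, 0], sd=0.5)
        for c in (0.5, 20.0):
            exon, profs = exon_factory({"r1": base, "r2": c * base}, [299, 599, 899])
            u1, _ = segment_exon(exon, [profs["r1"]], exon.sites[-1])
            u2, _ = segment_exon(exon, [profs["r2"]], exon.sites[-1])
            assert [s.site_id for s in u1] == [s.site_id for s in u2]
            rows1 = quantify_usage(exon, profs["r1"], u1 + [exon.sites[-1]])
            rows2 = quantify_usage(exon, profs["r2"], u2 + [exon.sites[-1]])
            for a, b in zip(rows1, rows2):
                assert a["relative"] == pytest.approx(b["relative"], abs=1e-12)

    def test_strand_mirror_symmetry(self, exon_factory):
        vals = _noisy_steps([10, 6, 0], sd=0.5)
        exon_f, profs_f = exon_factory({"r1": vals}, [299, 599, 899], strand="+")
        exon_r, profs_r = exon_factory({"r1": vals.copy()}, [299, 599, 899],
                                       strand="-")
        uf, _ = segment_exon(exon_f, [profs_f["r1"]], exon_f.sites[-1])
        ur, _ = segment_exon(exon_r, [profs_r["r1"]], exon_r.sites[-1])
        assert [s.site_id for s in uf] == [s.site_id for s in ur]
        rf = quantify_usage(exon_f, profs_f["r1"], uf + [exon_f.sites[-1]])
        rr = quantify_usage(exon_r, profs_r["r1"], ur + [exon_r.sites[-1]])
        assert [r["relative"] for r in rf] == pytest.approx(
            [r["relative"] for r in rr])


# ---------------------------------------------------------------------------
# Brute-force oracle for the recursive segmentation
# ---------------------------------------------------------------------------

def oracle_segment(arrays, breakpoints, region_end, threshold=0.5,
                   min_segment=100, cluster_span=200):
    """Naive re-implementation of the recursive breakpoint selection.

    Evaluates every candidate by direct slicing, applies the replicate rule,
    chain-clusters closely spaced candidates, and picks the smallest median
    ratio (5'-most on ties) at each step.
    """
    need = 2 if len(arrays) >= 2 else 1
    chosen = []

    def evaluate(arr, lo, hi, bp):
        up, down = arr[lo:bp], arr[bp:hi]
        if len(up) < min_segment or len(down) < min_segment:
            return False, float("inf")
        if not down.mean() < up.mean():
            return False, float("inf")
        total = arr[lo:hi]
        mse_t = ((total - total.mean()) ** 2).mean()
        if mse_t <= 0:
            return False, 1.0
        r = (((up - up.mean()) ** 2).mean()
             + ((down - down.mean()) ** 2).mean()) / mse_t
        return r <= threshold, r

    def step(lo, hi):
        viable = []
        for bp in sorted(b for b in breakpoints if lo < b < hi):
            decs = [evaluate(a, lo, hi, bp) for a in arrays]
            support = sum(ok for ok, _ in decs)
            if support >= need:
                med = statistics.median(r for ok, r in decs if ok)
                viable.append((bp, med))
        if not viable:
            return
        clusters = []
        for bp, med in viable:
            if clusters and bp - clusters[-1][-1][0] <= cluster_span:
                clusters[-1].append((bp, med))
            else:
                clusters.append([(bp, med)])
        reps = [min(cl, key=lambda t: (t[1], t[0])) for cl in clusters]
        best_bp, _ = min(reps, key=lambda t: (t[1], t[0]))
        chosen.append(best_bp)
        step(lo, best_bp)
        step(best_bp, hi)

    step(0, region_end)
    return sorted(chosen)


def _random_case(rng, max_len=2000):
    n_sites = int(rng.integers(2, 6))
    length = int(rng.integers(600, max_len))
    offsets = np.sort(rng.choice(np.arange(50, length - 50), size=n_sites,
                                 replace=False))
    levels = np.sort(rng.uniform(0, 30, n_sites + 1))[::-1]
    arr = np.empty(length + 200)
    bounds = [0] + [int(o) + 1 for o in offsets] + [length]
    for seg_lo, seg_hi, lv in zip(bounds, bounds[1:], levels):
        arr[seg_lo:seg_hi] = lv
    arr[length:] = 0.0
    n_rep = int(rng.integers(1, 4))
    arrays = [np.clip(arr + rng.normal(0, rng.uniform(0.2, 4.0), arr.size),
                      0, None) for _ in range(n_rep)]
    return arrays, [int(o) + 1 for o in offsets[:-1]], int(offsets[-1]) + 1


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_arrays(self, exon_factory):
        rng = np.random.default_rng(42)
        for _ in range(120):
            arrays, cand_bps, region_end = _random_case(rng)
            offsets = [bp - 1 for bp in cand_bps] + [region_end - 1]
            vals = {f"r{i}": a for i, a in enumerate(arrays)}
            exon, profs = exon_factory(vals, offsets)
            used, _ = segment_exon(exon, list(profs.values()), exon.sites[-1])
            got = sorted(profs["r0"].site_index(s) + 1 for s in used)
            expected = oracle_segment(arrays, cand_bps, region_end)
            assert got == expected


# ---------------------------------------------------------------------------
# Global breakpoint validity check
# ---------------------------------------------------------------------------

class TestGlobalCheck:
    def test_clean_planted_steps_pass(self, exon_factory):
        vals = _noisy_steps([10, 4, 0], sd=0.4)
        exon, profs = exon_factory({"r1": vals}, [299, 599, 899])
        used, _ = segment_exon(exon, [profs["r1"]], exon.sites[-1])
        ok, _ = global_breakpoint_check(exon, profs["r1"],
                                        used + [exon.sites[-1]],
                                        exon.sites[-1])
        assert ok

    def test_rogue_uncataloged_step_fails(self, exon_factory):
        # catalog step at 299 plus an extra step at 799, 500 nt from any site
        arr = np.concatenate([np.full(300, 20.0), np.full(500, 12.0),
                              np.full(400, 4.0), np.zeros(200)])
        exon, profs = exon_factory({"r1": arr}, [299, 1199])
        used, _ = segment_exon(exon, [profs["r1"]], exon.sites[-1])
        ok, bps = global_breakpoint_check(exon, profs["r1"],
                                          used + [exon.sites[-1]],
                                          exon.sites[-1])
        assert not ok
        assert any(abs(bp - 800) < 50 for bp in bps)

    def test_breakpoint_within_200_upstream_passes(self, exon_factory):
        # true step 150 nt upstream of the annotated site
        arr = np.concatenate([np.full(300, 10.0), np.full(500, 0.0)])
        exon, profs = exon_factory({"r1": arr}, [449, 599])
        ok, bps = global_breakpoint_check(
            exon, profs["r1"], [exon.sites[0], exon.sites[1]], exon.sites[1])
        assert bps == [300]
        assert ok


# ---------------------------------------------------------------------------
# Usage quantification and RPM
# ---------------------------------------------------------------------------

class TestQuantifyUsage:
    def test_segment_mean_subtraction(self, exon_factory):
        values = _two_site_values(10.0, 4.0)
        exon, profs = exon_factory({"s1": values}, [299, 599])
        rows = quantify_usage(exon, profs["s1"], exon.sites)
        assert [r["raw"] for r in rows] == pytest.approx([6.0, 4.0])
        assert [r["relative"] for r in rows] == pytest.approx([0.6, 0.4])

    def test_zero_rule_for_unsupported_site(self, exon_factory):
        values = np.array([3.0] * 300 + [4.0] * 300 + [0.0] * 200)
        exon, profs = exon_factory({"s1": values}, [299, 599])
        rows = quantify_usage(exon, profs["s1"], exon.sites,
                              support={"exonA_s0": False, "exonA_s1": True})
        assert rows[0]["raw"] == 0.0
        assert rows[1]["relative"] == pytest.approx(1.0)

    def test_single_used_site_normalizes_to_one(self, exon_factory):
        values = np.array([5.0] * 600 + [0.0] * 200)
        exon, profs = exon_factory({"s1": values}, [599])
        (row,) = quantify_usage(exon, profs["s1"], exon.sites)
        assert row["relative"] == pytest.approx(1.0)

    def test_all_zero_usage_emitted_as_missing(self, exon_factory):
        values = np.zeros(800)
        exon, profs = exon_factory({"s1": values}, [299, 599])
        rows = quantify_usage(exon, profs["s1"], exon.sites)
        assert all(np.isnan(r["relative"]) for r in rows)


class TestRpm:
    def test_two_exon_normalization(self):
        df = pd.DataFrame(dict(sample=["s"] * 3, raw=[3.0, 1.0, 4.0]))
        out = rpm_normalize(df)
        assert list(out["rpm"]) == pytest.approx([375000.0, 125000.0, 500000.0])

    def test_single_site_is_full_library(self):
        df = pd.DataFrame(dict(sample=["s"], raw=[1.0]))
        assert rpm_normalize(df)["rpm"].iloc[0] == pytest.approx(1e6)

    def test_rpm_sums_to_million_per_sample(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(dict(sample=list("ab") * 5, raw=rng.uniform(0, 9, 10)))
        out = rpm_normalize(df)
        sums = out.groupby("sample")["rpm"].sum()
        assert np.allclose(sums, 1e6, rtol=1e-9)

    def test_zero_library_errors(self):
        df = pd.DataFrame(dict(sample=["s", "s"], raw=[0.0, 0.0]))
        with pytest.raises(ValueError, match="library"):
            rpm_normalize(df)


class TestPipeline:
    def test_pooled_profile_drives_distal_choice(self, exon_factory):
        weak = _two_site_values(2.0, 0.8)
        strong = _two_site_values(30.0, 12.0)
        exon, profs = exon_factory({"r1": weak, "r2": strong}, [299, 599])
        pooled = pool_profiles([profs["r1"], profs["r2"]])
        assert identify_distal_site(exon, pooled, 100) is exon.sites[-1]
        assert passes_coverage_gate(exon, pooled, exon.sites[-1])[0]

    def test_run_paqr_excludes_low_coverage_exon(self, exon_factory):
        good = {s: _two_site_values(20.0, 8.0) for s in ("r1", "r2")}
        exon_g, profs_g = exon_factory(good, [299, 599], exon_id="good")
        bad = {s: _two_site_values(2.0, 0.8) for s in ("r1", "r2")}
        exon_b, profs_b = exon_factory(bad, [299, 599], exon_id="bad",
                                       start=50_000)
        profiles = {s: {"good": profs_g[s], "bad": profs_b[s]}
                    for s in ("r1", "r2")}
        usage, excl = run_paqr([exon_g, exon_b], profiles, read_length=100)
        assert set(usage["exon_id"]) == {"good"}
        assert ("bad", "*", "low_coverage") in excl
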