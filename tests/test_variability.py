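"""The neq statistic, column classification and region detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saconf.alignment import trivial_msa, project_msla
from saconf.variability import (CHANGE, CONSERVED, HIGH, STRONG, UNDEFINED,
                                VARIABLE, WEAK, ColumnProfile, RegionCriteria,
                                classify, column_profile, detect_regions, neq,
                                profile_set)


class TestNeq:
    def test_single_symbol_is_one(self):
        assert neq([1.0]) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_20_is_20(self):
        assert neq([1 / 20] * 20) == pytest.approx(20.0, rel=1e-12)

    def test_uniform_27_is_27(self):
        assert neq([1 / 27] * 27) == pytest.approx(27.0, rel=1e-12)

    def test_two_symbol_column_matches_hand_evaluation(self):
        expected = math.exp(-(0.9 * math.log(0.9) + 0.1 * math.log(0.1)))
        assert neq([0.9, 0.1]) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.3841, abs=5e-4)

    def test_zero_frequency_contributes_nothing(self):
        assert neq([0.5, 0.5, 0.0]) == pytest.approx(2.0, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            neq([-0.1, 1.1])
        with pytest.raises(ValueError):
            neq([0.4, 0.4])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=27))
def test_neq_bounds_and_uniform_extremes(weights):
    f = np.array(weights) / np.sum(weights)
    value = neq(f)
    assert 1.0 - 1e-9 <= value <= len(f) + 1e-9
    # relabeling invariance
    assert neq(np.random.default_rng(0).permutation(f)) == pytest.approx(value)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=10))
def test_merging_symbols_never_increases_neq(weights):
    f = np.array(weights) / np.sum(weights)
    merged = np.concatenate([[f[0] + f[1]], f[2:]])
    assert neq(merged) <= neq(f) + 1e-9


class TestClassify:
    @pytest.mark.parametrize("value,expected", [
        (1.0, CONSERVED), (1.0 + 5e-13, CONSERVED), (1.2, WEAK),
        (1.5 - 1e-9, WEAK), (1.5, VARIABLE), (2.9, VARIABLE),
        (3.0, HIGH), (4.99, HIGH), (5.0, STRONG), (None, UNDEFINED),
    ])
    def test_threshold_boundaries(self, value, expected):
        assert classify(value) == expected


class TestColumnProfile:
    def test_fully_conserved_column(self, model):
        p = column_profile(["A"] * 10, ["a"] * 10, model)
        assert p.neq_aa == pytest.approx(1.0, abs=1e-12)
        assert p.neq_sl == pytest.approx(1.0, abs=1e-12)
        assert p.aa_class == CONSERVED and p.sl_class == CONSERVED
        assert p.ss_status == "HELIX"

    def test_sl_change_within_helix_category(self, model):
        p = column_profile(["G"] * 10, ["a"] * 5 + ["A"] * 5, model)
        assert p.neq_sl > 1
        assert p.ss_status == "HELIX"

    def test_majority_gapped_column_undefined(self, model):
        p = column_profile(["-"] * 6 + ["A"] * 4, ["-"] * 6 + ["a"] * 4, model)
        assert p.neq_aa is None and p.neq_sl is None
        assert p.aa_class == UNDEFINED and p.sl_class == UNDEFINED
        assert p.missing_frac == pytest.approx(0.6)

    def test_exactly_half_missing_is_undefined(self, model):
        p = column_profile(["-"] * 5 + ["A"] * 5, ["-"] * 5 + ["a"] * 5, model)
        assert p.neq_aa is None

    def test_uniform_four_letters_across_categories(self, model):
        sl = ["a", "B", "C", "D"] * 3  # helix letter + three loop letters
        p = column_profile(["A"] * 12, sl, model)
        assert p.neq_sl == pytest.approx(4.0, rel=1e-12)
        assert p.sl_class == HIGH
        assert p.ss_status == CHANGE

    def test_gaps_excluded_from_frequencies(self, model):
        p = column_profile(["-", "-", "A", "A", "A", "A", "A", "A", "A", "A"],
                           ["-", "-", "a", "a", "a", "a", "a", "a", "a", "a"],
                           model)
        assert p.neq_aa == pytest.approx(1.0, abs=1e-12)
        assert p.missing_frac == pytest.approx(0.2)

    def test_length_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            column_profile(["A"], ["a", "a"], model)


def series_profiles(values):
    out = []
    for i, v in enumerate(values, start=1):
        out.append(ColumnProfile(i, {}, {}, None, v, 0.0, UNDEFINED,
                                 classify(v), "LOOP"))
    return out


def brute_force_regions(values, crit):
    """Exhaustive interval scanner, independent of the detector."""
    n = len(values)

    def defined(i):
        return values[i] is not None

    def var(i):
        return defined(i) and values[i] >= crit.t_var

    def spk(i):
        return defined(i) and values[i] >= crit.t_high

    def admissible(s, e):
        if not (var(s) and var(e)):
            return False
        last = s
        for k in range(s, e + 1):
            if not defined(k):
                return False
            if var(k):
                if k - last - 1 > crit.max_gap:
                    return False
                last = k
        return True

    cands = [(s, e) for s in range(n) for e in range(s, n) if admissible(s, e)]
    maximal = [c for c in cands
               if not any(c != o and o[0] <= c[0] and c[1] <= o[1] for o in cands)]
    out = []
    for s, e in sorted(maximal):
        has_run = any(all(var(k) for k in range(i, i + crit.l))
                      for i in range(s, e - crit.l + 2))
        has_spike = any(spk(k) for k in range(s, e + 1))
        if has_run or has_spike:
            trig = "BOTH" if (has_run and has_spike) else ("RUN" if has_run else "SPIKE")
            out.append((s + 1, e + 1, trig))
    return out


class TestDetectRegions:
    CRIT = RegionCriteria(l=4, t_var=1.5, t_high=4.0, max_gap=0)

    def test_simple_run(self):
        profiles = series_profiles([1, 1, 2, 2, 2, 2, 1, 1])
        regions = detect_regions(profiles, self.CRIT)
        assert [(r.start, r.end, r.trigger) for r in regions] == [(3, 6, "RUN")]
        assert regions[0].mean_neq_sl == pytest.approx(2.0)

    def test_isolated_spike(self):
        profiles = series_profiles([1, 1, 4.5, 1, 1])
        regions = detect_regions(profiles, self.CRIT)
        assert [(r.start, r.end, r.trigger) for r in regions] == [(3, 3, "SPIKE")]

    def test_short_run_without_spike_ignored(self):
        profiles = series_profiles([1, 2, 2, 2, 1])
        assert detect_regions(profiles, self.CRIT) == []

    def test_gap_bridging(self):
        crit = RegionCriteria(l=4, t_var=1.5, t_high=4.0, max_gap=1)
        values = [1, 2, 2, 2, 2, 1, 2, 2, 2, 2, 1]
        regions = detect_regions(series_profiles(values), crit)
        assert [(r.start, r.end) for r in regions] == [(2, 10)]

    def test_undefined_breaks_runs(self):
        crit = RegionCriteria(l=4, t_var=1.5, t_high=4.0, max_gap=1)
        values = [2, 2, 2, 2, None, 2, 2, 2, 2]
        regions = detect_regions(series_profiles(values), crit)
        assert [(r.start, r.end) for r in regions] == [(1, 4), (6, 9)]

    @pytest.mark.parametrize("max_gap", [0, 1, 2])
    def test_matches_brute_force_on_random_series(self, max_gap):
        crit = RegionCriteria(l=4, t_var=1.5, t_high=4.0, max_gap=max_gap)
        rng = np.random.default_rng(17 + max_gap)
        for _ in range(60):
            n = int(rng.integers(1, 31))
            values = [float(rng.choice([1.0, 2.0, 4.5])) for _ in range(n)]
            got = [(r.start, r.end, r.trigger)
                   for r in detect_regions(series_profiles(values), crit)]
            assert got == brute_force_regions(values, crit)


class TestProfileSet:
    def test_identical_chains_fully_conserved(self, model):
        from test_alignment import make_chain
        chains = [make_chain("ACDEFGHIKL", name=f"S00{k}_A") for k in range(2)]
        msa = trivial_msa(chains)
        letters = "DDDDDDD"
        msla = project_msla(msa, {ch.name: letters for ch in chains})
        profiles, summary = profile_set(msa, msla, model)
        assert summary["pct_conserved_aa"] == pytest.approx(100.0)
        assert summary["pct_conserved_sl"] == pytest.approx(100.0)
        assert summary["mean_neq_aa"] == pytest.approx(1.0)
        assert summary["mean_neq_sl"] == pytest.approx(1.0)
        # the three letter-less terminus columns are undefined
        assert summary["n_defined_sl"] == 7

    def test_summary_counts_match_independent_tally(self, model):
        rng = np.random.default_rng(3)
        C, P = 8, 40
        aa_rows = [["A"] * P for _ in range(C)]
        sl_rows = [["D"] * P for _ in range(C)]
        variable_cols = {5, 12, 30}
        for c in variable_cols:
            for r in range(C // 2):
                sl_rows[r][c] = "E"
        profiles = [column_profile([row[c] for row in aa_rows],
                                   [row[c] for row in sl_rows], model,
                                   column=c + 1) for c in range(P)]
        n_conserved = sum(1 for p in profiles
                          if p.neq_sl is not None and abs(p.neq_sl - 1) < 1e-12)
        assert n_conserved == P - len(variable_cols)
        for c in variable_cols:
            assert profiles[c].neq_sl == pytest.approx(2.0, rel=1e-12)


def test_population_sd_in_summary(model):
    from test_alignment import make_chain
    chains = [make_chain("ACDEFGHIKL", name=f"S00{k}_A") for k in range(2)]
    msa = trivial_msa(chains)
    msla = project_msla(msa, {chains[0].name: "DDDDDDD",
                              chains[1].name: "DDDEDDD"})
    profiles, summary = profile_set(msa, msla, model)
    vals = np.array([p.neq_sl for p in profiles if p.neq_sl is not None])
    assert summary["sd_neq_sl"] == pytest.approx(float(vals.std(ddof=0)))
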