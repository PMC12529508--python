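import math
import statistics

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from cysquant.io_formats import ReferenceSiteDB
from cysquant.ligandability import (
    CallConfig,
    call_all,
    call_antiligandable,
    call_site,
    categorize_vs_reference,
    dose_response_table,
    hit_rate_analysis,
    parse_dose_condition,
    screen_totals,
    stereo_compare,
    summarize_compound,
)
from cysquant.quantification import SiteConditionResult
from cysquant.site_mapping import CysteineSiteID

CFG = CallConfig()


def result(reps, site="P1_C3", condition="KB2", call="pending"):
    ratios = [r for _, r in reps]
    return SiteConditionResult(
        site=CysteineSiteID.parse(site),
        condition=condition,
        replicate_ratios=tuple(reps),
        mean_log2=statistics.mean(ratios) if ratios else None,
        sd_log2=statistics.stdev(ratios) if len(ratios) >= 2 else None,
        n_replicates_quantified=len(reps),
        n_psms=len(reps),
        call=call,
    )


def pair(a, b, **kw):
    return result([(1, a), (2, b)], **kw)


def oracle_call(a: float, b: float, cfg: CallConfig = CFG) -> str:
    """Independent transcription of the two-clause rule for a replicate
    pair: mean >= threshold, and both replicates >= threshold when the
    sample SD exceeds the gate (mirror rule for anti-liganded)."""
    mean = (a + b) / 2
    sd = abs(a - b) / math.sqrt(2)
    if mean >= cfg.threshold:
        if sd <= cfg.sd_gate or (a >= cfg.threshold and b >= cfg.threshold):
            return "liganded"
    if mean <= cfg.anti_threshold:
        if sd <= cfg.sd_gate or (a <= cfg.anti_threshold and b <= cfg.anti_threshold):
            return "anti-liganded"
    return "not-liganded"


class TestCallSite:
    def test_liganded_within_sd_gate(self):
        # mean 2.05 >= 2, sd 0.636 <= 2
        assert call_site(pair(2.5, 1.6)) == "liganded"

    def test_sd_gate_blocks(self):
        # mean 2.75 >= 2 but sd 4.5/sqrt(2) = 3.182 > 2 and rep2 < 2
        assert abs(5.0 - 0.5) / math.sqrt(2) > 2
        assert call_site(pair(5.0, 0.5)) == "not-liganded"

    def test_just_under_gate(self):
        # sd = 2.8/sqrt(2) = 1.980 <= 2
        assert abs(4.9 - 2.1) / math.sqrt(2) == pytest.approx(1.9799, abs=1e-4)
        assert call_site(pair(4.9, 2.1)) == "liganded"

    def test_high_sd_but_both_over_threshold(self):
        # sd = 4/sqrt(2) = 2.83 > 2, yet both replicates >= 2
        assert call_site(pair(6.0, 2.0)) == "liganded"

    def test_unquantified_passthrough(self):
        assert call_site(result([(1, 3.0)])) == "unquantified"

    def test_anti_liganded(self):
        assert call_site(pair(-2.5, -2.2)) == "anti-liganded"
        assert call_antiligandable(pair(-2.5, -2.2))

    def test_anti_above_threshold(self):
        assert not call_antiligandable(pair(-1.0, -1.2))

    def test_anti_sd_gate(self):
        assert not call_antiligandable(pair(-5.0, -0.5))
        assert call_site(pair(-5.0, -0.5)) == "not-liganded"

    def test_exhaustive_grid_oracle(self):
        grid = [x / 2 for x in range(-12, 13)]  # -6, -5.5, ..., 6
        assert len(grid) == 25
        for a in grid:
            for b in grid:
                assert call_site(pair(a, b)) == oracle_call(a, b), (a, b)

    def test_sd_gate_breaks_naive_monotonicity(self):
        # The SD gate makes the rule non-monotone in a single replicate:
        # raising one replicate can push the SD over the gate while the
        # other replicate sits below the threshold.
        assert call_site(pair(2.1, 1.95)) == "liganded"
        assert call_site(pair(7.0, 1.95)) == "not-liganded"

    @given(
        a=st.floats(2.0, 8.0),
        delta=st.floats(0, 4),
        b=st.floats(2.0, 8.0),
    )
    def test_monotone_when_both_replicates_over_threshold(self, a, delta, b):
        # With both replicates at/above threshold the SD gate is moot and
        # raising a replicate can never lose the liganded call.
        assert call_site(pair(a, b)) == "liganded"
        assert call_site(pair(a + delta, b)) == "liganded"

    @given(a=st.floats(-8, 8), delta=st.floats(0, 4), b=st.floats(-8, 8))
    def test_raising_never_creates_anti_call(self, a, delta, b):
        if call_site(pair(a, b)) != "anti-liganded":
            assert call_site(pair(a + delta, b + delta)) != "anti-liganded"


class TestSummarizeCompound:
    def test_fraction(self):
        results = [
            pair(3.0, 3.2, site=f"P{i}_C1", call="liganded") for i in range(23)
        ] + [
            pair(0.1, 0.0, site=f"Q{i}_C1", call="not-liganded") for i in range(77)
        ]
        s = summarize_compound(results, CFG)
        assert s.n_identified == 100
        assert s.n_liganded == 23
        assert s.fraction_liganded == pytest.approx(0.23)

    def test_degenerate_empty(self):
        s = summarize_compound(
            [result([(1, 3.0)], call="unquantified")], CFG, condition="KB2"
        )
        assert s.n_identified == 0
        assert s.fraction_liganded == 0.0

    def test_exclusion_flag(self):
        cfg = CallConfig(excluded_compounds=("SO56", "SO59"))
        s = summarize_compound(
            [pair(3.0, 3.0, condition="SO56", call="liganded")], cfg, "SO56"
        )
        assert s.excluded_from_totals

    def test_partition_identified(self):
        results = [
            pair(3.0, 3.1, site="P1_C1", call="liganded"),
            pair(0.0, 0.1, site="P2_C1", call="not-liganded"),
            pair(-3.0, -3.1, site="P3_C1", call="anti-liganded"),
            result([(1, 3.0)], site="P4_C1", call="unquantified"),
        ]
        s = summarize_compound(results, CFG)
        n_by_call = {c: sum(1 for r in results if r.call == c) for c in
                     ("liganded", "not-liganded", "anti-liganded")}
        assert s.n_identified == sum(n_by_call.values())


class TestScreenTotals:
    def test_set_semantics(self):
        results = [
            pair(3.0, 3.1, site="P1_C3", condition="KB2", call="liganded"),
            pair(3.0, 3.1, site="P1_C3", condition="KB7", call="liganded"),
            pair(0.0, 0.1, site="P1_C9", condition="KB2", call="not-liganded"),
        ]
        t = screen_totals(results, CFG)
        assert t.n_unique_sites == 2
        assert t.n_unique_proteins == 1
        assert t.n_liganded_total == 1

    def test_excluded_compound_site_not_counted(self):
        cfg = CallConfig(excluded_compounds=("SO56",))
        results = [
            pair(3.0, 3.1, site="P1_C3", condition="SO56", call="liganded"),
            pair(0.5, 0.4, site="P1_C3", condition="KB2", call="not-liganded"),
        ]
        t = screen_totals(results, cfg)
        assert t.n_unique_sites == 1
        assert t.n_liganded_total == 0

    def test_empty(self):
        t = screen_totals([], CFG)
        assert (t.n_unique_sites, t.n_unique_proteins, t.n_liganded_total) == (0, 0, 0)

    def test_exclusion_invariance_property(self):
        cfg = CallConfig(excluded_compounds=("SO56",))
        base = [
            pair(3.0, 3.1, site="P1_C3", condition="KB2", call="liganded"),
            pair(0.1, 0.2, site="P2_C5", condition="KB2", call="not-liganded"),
        ]
        extra = [
            pair(4.0, 4.1, site="P2_C5", condition="SO56", call="liganded"),
        ]
        with_excl = screen_totals(base + extra, cfg)
        without = screen_totals(base, cfg)
        assert with_excl.n_liganded_total == without.n_liganded_total


class TestReference:
    def make_db(self):
        return ReferenceSiteDB(
            {"P1_C3": (True, True), "P2_C7": (True, False)}
        )

    def test_categorize(self):
        results = [
            pair(3.0, 3.1, site="P1_C3", call="liganded"),
            pair(0.1, 0.2, site="P2_C7", call="not-liganded"),
            pair(3.0, 3.1, site="P3_C9", call="liganded"),
        ]
        cats, counts = categorize_vs_reference(results, self.make_db())
        assert cats == {
            "P1_C3": "known-ligandable",
            "P2_C7": "known-identified-only",
            "P3_C9": "novel",
        }
        assert counts["known-ligandable"] == 1
        assert counts["known-identified-only"] == 1
        assert counts["novel"] == 1
        assert counts["liganded-novel"] == 1

    def test_empty_refdb_all_novel(self):
        results = [pair(0.1, 0.2, site="P1_C3", call="not-liganded")]
        cats, counts = categorize_vs_reference(results, ReferenceSiteDB())
        assert counts["novel"] == 1

    def test_superset_refdb_no_novel(self):
        results = [pair(0.1, 0.2, site="P1_C3", call="not-liganded")]
        cats, counts = categorize_vs_reference(results, self.make_db())
        assert counts["novel"] == 0

    def test_hit_rate(self):
        results = [
            pair(3.0, 3.1, site="P1_C3", condition="KB2", call="liganded"),
            pair(3.0, 3.1, site="P3_C9", condition="KB2", call="liganded"),
            pair(0.1, 0.2, site="P1_C3", condition="KB7", call="not-liganded"),
            pair(3.2, 3.3, site="P1_C3", condition="SO56", call="liganded"),
        ]
        hr = hit_rate_analysis(results, self.make_db())
        assert hr.total_conditions == 3
        assert hr.per_condition["KB2"] == pytest.approx(0.5)
        assert hr.per_condition["KB7"] is None
        assert hr.per_site["P1_C3"] == (2, 3)
        assert hr.per_site["P3_C9"] == (1, 3)


def welch_p_oracle(a, b):
    """Closed-form Welch t-test, written independently of the pipeline."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return 2 * sps.t.sf(abs(t), df)


class TestStereoCompare:
    def test_selective_for_a(self):
        ra = [pair(3.0, 3.2, condition="A")]
        rb = [pair(0.1, -0.1, condition="B")]
        comps, skipped = stereo_compare(ra, rb, min_delta=1.0, alpha=0.05)
        (c,) = comps
        assert c.delta == pytest.approx(3.1)
        assert c.p_value == pytest.approx(welch_p_oracle([3.0, 3.2], [0.1, -0.1]))
        assert c.p_value < 0.05
        assert c.selective_for == "A"

    def test_identity_gives_p_one(self):
        ra = [pair(1.5, 1.5, condition="A")]
        rb = [pair(1.5, 1.5, condition="B")]
        (c,), _ = stereo_compare(ra, rb)
        assert c.delta == 0.0
        assert c.p_value == 1.0
        assert c.selective_for == "none"

    def test_symmetric_cancellation(self):
        ra = [pair(2.0, -2.0, condition="A")]
        rb = [pair(0.0, 0.0, condition="B")]
        (c,), _ = stereo_compare(ra, rb)
        assert c.delta == 0.0
        assert c.selective_for == "none"

    def test_skip_tallies(self):
        ra = [
            pair(3.0, 3.2, site="P1_C3", condition="A"),
            result([(1, 2.0)], site="P2_C5", condition="A"),
        ]
        rb = [
            pair(0.0, 0.1, site="P2_C5", condition="B"),
            pair(0.0, 0.1, site="P9_C9", condition="B"),
        ]
        comps, skipped = stereo_compare(ra, rb)
        assert not comps
        assert skipped == {
            "missing-in-a": 1,
            "missing-in-b": 1,
            "insufficient-replicates": 1,
        }

    def test_antisymmetry_property(self):
        rng = np.random.default_rng(0)
        ra = [
            pair(*rng.normal(1.0, 1.5, 2), site=f"P{i}_C1", condition="A")
            for i in range(20)
        ]
        rb = [
            pair(*rng.normal(0.0, 1.5, 2), site=f"P{i}_C1", condition="B")
            for i in range(20)
        ]
        fwd, _ = stereo_compare(ra, rb)
        rev, _ = stereo_compare(rb, ra)
        swap = {"A": "B", "B": "A", "none": "none"}
        for f, r in zip(fwd, rev):
            assert f.delta == pytest.approx(-r.delta)
            assert f.p_value == pytest.approx(r.p_value)
            assert swap[f.selective_for] == r.selective_for

    def test_bh_adjustment_weakens_significance(self):
        rng = np.random.default_rng(1)
        ra = [
            pair(*rng.normal(0.4, 0.3, 2), site=f"P{i}_C1", condition="A")
            for i in range(30)
        ]
        rb = [
            pair(*rng.normal(0.0, 0.3, 2), site=f"P{i}_C1", condition="B")
            for i in range(30)
        ]
        raw, _ = stereo_compare(ra, rb, min_delta=0.1)
        adj, _ = stereo_compare(ra, rb, min_delta=0.1, adjust="bh")
        n_raw = sum(1 for c in raw if c.selective_for != "none")
        n_adj = sum(1 for c in adj if c.selective_for != "none")
        assert n_adj <= n_raw


class TestDoseResponse:
    def test_condition_grammar(self):
        assert parse_dose_condition("BEH-1-Sa@5uM") == ("BEH-1-Sa", 5.0, "uM")
        assert parse_dose_condition("X@12.5uM")[1] == 12.5
        with pytest.raises(ValueError):
            parse_dose_condition("KB2")

    def test_two_column_matrix(self):
        results = [
            pair(3.0, 3.1, site="P1_C3", condition="BEH-1-Sa@5uM", call="liganded"),
            pair(4.0, 4.1, site="P1_C3", condition="BEH-1-Sa@100uM", call="liganded"),
        ]
        df = dose_response_table(results)
        assert list(df.columns) == ["BEH-1-Sa@5uM", "BEH-1-Sa@100uM"]
        assert df.loc["P1_C3", "BEH-1-Sa@5uM"] == pytest.approx(3.05)

    def test_missing_cell_is_nan(self):
        results = [
            pair(3.0, 3.1, site="P1_C3", condition="Z@100uM", call="liganded"),
            result([(1, 2.0)], site="P1_C3", condition="Z@5uM", call="unquantified"),
            pair(0.1, 0.0, site="P2_C9", condition="Z@5uM", call="not-liganded"),
        ]
        df = dose_response_table(results)
        assert math.isnan(df.loc["P1_C3", "Z@5uM"])
        # rows sorted by max |mean|, strongest first
        assert list(df.index) == ["P1_C3", "P2_C9"]

    def test_single_concentration(self):
        results = [pair(1.0, 1.1, site="P1_C3", condition="Z@5uM")]
        df = dose_response_table(results)
        assert df.shape == (1, 1)


class TestCallAll:
    def test_sets_calls_in_place(self):
        results = [pair(3.0, 3.2), pair(0.0, 0.1), result([(1, 5.0)])]
        call_all(results, CFG)
        assert [r.call for r in results] == [
            "liganded",
            "not-liganded",
            "unquantified",
        ]
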