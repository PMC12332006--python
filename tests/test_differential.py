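import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from misplice import differential as diff
from tests.conftest import make_intron


class TestWelch:
    def test_closed_form_example(self):
        # oracle arithmetic: means 2 vs 5, var 1 each, se^2 = 2/3,
        # t = -3/sqrt(2/3) = -3.6742, df = (2/3)^2 / (2*(1/3)^2/2) = 4
        t, df, p = diff.welch_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0214, abs=2e-4)

    def test_identical_groups(self):
        t, _, p = diff.welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == 1.0

    def test_zero_variance_unequal_means(self):
        t, _, p = diff.welch_t_test([0, 0, 0], [5, 5, 5])
        assert t == -math.inf
        assert p == diff.P_SENTINEL

    def test_zero_variance_equal_means(self):
        t, _, p = diff.welch_t_test([2, 2], [2, 2])
        assert (t, p) == (0.0, 1.0)

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError):
            diff.welch_t_test([1], [2, 3])

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
    )
    def test_matches_scipy(self, a, b):
        if np.var(a) == 0 and np.var(b) == 0:
            return
        t, df, p = diff.welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-9, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)


class TestAudicClaverie:
    def test_p00_equal_libraries(self):
        # direct evaluation: C(0,0) / 2^1 = 0.5
        assert diff.audic_claverie_pmf(0, 0, 10, 10) == pytest.approx(0.5)
        assert diff.audic_claverie_test(0, 0, 10, 10) == pytest.approx(1.0)

    def test_p55_equal_libraries(self):
        # C(10,5)/2^11 = 252/2048
        assert diff.audic_claverie_pmf(5, 5, 100, 100) == pytest.approx(252 / 2048)

    def test_tail_monotone_in_y(self):
        ps = [diff.audic_claverie_test(0, y, 50, 50) for y in range(2, 40)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_tails_match_direct_summation(self):
        # independent oracle: explicit pmf sums over the conditional law
        for x, y, n1, n2 in [(3, 8, 100, 150), (10, 2, 80, 60), (0, 5, 10, 10)]:
            lower = sum(diff.audic_claverie_pmf(j, x, n1, n2) for j in range(y + 1))
            upper = 1.0 - sum(diff.audic_claverie_pmf(j, x, n1, n2) for j in range(y))
            expected = min(1.0, 2 * min(lower, upper))
            assert diff.audic_claverie_test(x, y, n1, n2) == pytest.approx(expected, rel=1e-9)

    def test_library_size_scaling(self):
        # a count that tracks library size is less surprising
        p_prop = diff.audic_claverie_test(10, 20, 100, 200)
        p_flat = diff.audic_claverie_test(10, 20, 100, 100)
        assert p_prop > p_flat

    @given(st.integers(0, 60), st.integers(0, 60))
    def test_near_symmetry(self, x, y):
        # the tail-based two-sided p is symmetric up to endpoint handling
        # (exact symmetry is unattainable for this formula; see the tails)
        p1 = diff.audic_claverie_test(x, y, 100, 100)
        p2 = diff.audic_claverie_test(y, x, 100, 100)
        assert p2 / 2 <= p1 <= min(1.0, 2 * p2) or p1 == p2

    def test_non_integer_errors(self):
        with pytest.raises(ValueError):
            diff.audic_claverie_test(1.5, 2, 10, 10)
        with pytest.raises(ValueError):
            diff.audic_claverie_test(1, 2, 0, 10)


class TestBhFdr:
    def test_hand_example(self):
        # brute force: sorted p * m / rank = [.04,.04,.04,.04], then min-accumulate
        assert diff.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_singleton_identity(self):
        assert diff.bh_fdr([0.5]) == [0.5]

    def test_alignment_to_input_order(self):
        p = [0.04, 0.01, 0.03, 0.02]
        q = diff.bh_fdr(p)
        assert q == pytest.approx([0.04] * 4)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            diff.bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels_and_inflates(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = diff.bh_fdr(pvals)
        expected = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(q, expected)
        assert all(qi >= pi for qi, pi in zip(q, pvals))
        assert all(0 <= qi <= 1 for qi in q)


class TestChiSquare:
    def test_null_fit(self):
        chi2, df, p = diff.chi_square_gof([50, 50], [0.5, 0.5])
        assert chi2 == 0.0
        assert p == 1.0

    def test_hand_arithmetic(self):
        # (10-5)^2/5 + (0-5)^2/5 = 10
        chi2, df, p = diff.chi_square_gof([10, 0], [0.5, 0.5])
        assert chi2 == pytest.approx(10.0)
        assert df == 1

    def test_two_cell_detected_fractions(self):
        # minor/major detected split as expected proportions
        obs = [60, 539]
        props = [599 / 180062, 179463 / 180062]
        total = sum(obs)
        expected = [total * p for p in props]
        by_hand = sum((o - e) ** 2 / e for o, e in zip(obs, expected))
        chi2, _, _ = diff.chi_square_gof(obs, props)
        assert chi2 == pytest.approx(by_hand)

    def test_matches_scipy(self):
        obs = [30, 50, 20]
        props = [0.3, 0.5, 0.2]
        chi2, df, p = diff.chi_square_gof(obs, props)
        ref = stats.chisquare(obs, [sum(obs) * x for x in props])
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_errors(self):
        with pytest.raises(ValueError):
            diff.chi_square_gof([1, 2], [0.6, 0.6])
        with pytest.raises(ValueError):
            diff.chi_square_gof([0, 0], [0.5, 0.5])
        with pytest.raises(ValueError):
            diff.chi_square_gof([5, 5], [1.0, 0.0])


def _precursor_row(intron_id="i1", fdr=0.01, cov_t=True, cov_c=True, mt=0.12, mc=0.05):
    return {
        "intron_id": intron_id,
        "intron_class": "minor",
        "mean_treated": mt,
        "mean_control": mc,
        "delta": mt - mc,
        "t_stat": 0.0,
        "df": 4.0,
        "p_welch": 0.01,
        "p_ac": 0.01,
        "fdr": fdr,
        "coverage_ok_treated": cov_t,
        "coverage_ok_control": cov_c,
    }


class TestRetentionFilter:
    def test_all_rules_pass(self):
        out = diff.call_differential_retention(pd.DataFrame([_precursor_row()]))
        assert out["call"].tolist() == ["retained_in_treated"]

    def test_delta_rule(self):
        out = diff.call_differential_retention(pd.DataFrame([_precursor_row(mt=0.12, mc=0.09)]))
        assert out["call"].tolist() == ["not_significant"]

    def test_fdr_gate(self):
        out = diff.call_differential_retention(pd.DataFrame([_precursor_row(fdr=0.2)]))
        assert out["call"].tolist() == ["not_significant"]

    def test_coverage_gate(self):
        out = diff.call_differential_retention(pd.DataFrame([_precursor_row(cov_t=False)]))
        assert out["call"].tolist() == ["not_significant"]

    def test_ratio_floor(self):
        out = diff.call_differential_retention(
            pd.DataFrame([_precursor_row(mt=0.09, mc=0.01)])
        )
        assert out["call"].tolist() == ["not_significant"]

    def test_mirrored_control_call(self):
        out = diff.call_differential_retention(
            pd.DataFrame([_precursor_row(mt=0.02, mc=0.15)])
        )
        assert out["call"].tolist() == ["retained_in_control"]

    def test_missing_inputs_excluded(self, caplog):
        rows = [_precursor_row("a"), _precursor_row("b")]
        rows[1]["fdr"] = float("nan")
        out = diff.call_differential_retention(pd.DataFrame(rows))
        assert out["intron_id"].tolist() == ["a"]

    def test_brute_force_equivalence_random_tables(self):
        rng = np.random.default_rng(5)
        rules = diff.RetentionRules()
        rows = []
        for i in range(200):
            rows.append(
                _precursor_row(
                    f"i{i}",
                    fdr=float(rng.uniform(0, 0.12)),
                    cov_t=bool(rng.random() < 0.8),
                    cov_c=bool(rng.random() < 0.8),
                    mt=float(rng.uniform(0, 0.3)),
                    mc=float(rng.uniform(0, 0.3)),
                )
            )
        table = pd.DataFrame(rows)
        out = diff.call_differential_retention(table, rules)
        for row in out.itertuples():
            if (
                row.fdr <= 0.05
                and row.coverage_ok_treated
                and row.mean_treated >= 0.10
                and row.mean_treated - row.mean_control >= 0.05
            ):
                expected = "retained_in_treated"
            elif (
                row.fdr <= 0.05
                and row.coverage_ok_control
                and row.mean_control >= 0.10
                and row.mean_control - row.mean_treated >= 0.05
            ):
                expected = "retained_in_control"
            else:
                expected = "not_significant"
            assert row.call == expected


def _quant_rows(intron_id, treated_vals, control_vals, column="msi_ret"):
    rows = []
    for i, v in enumerate(treated_vals):
        rows.append({"intron_id": intron_id, "sample": f"treated_{i+1}", column: v})
    for i, v in enumerate(control_vals):
        rows.append({"intron_id": intron_id, "sample": f"control_{i+1}", column: v})
    return rows


def _design(n=4):
    mapping = {f"treated_{i+1}": "treated" for i in range(n)}
    mapping.update({f"control_{i+1}": "control" for i in range(n)})
    return diff.ConditionDesign("treated", "control", mapping)


class TestMsiCalls:
    def _table(self, ret_t, ret_c, as_t=None, as_c=None):
        n = len(ret_t)
        as_t = as_t or [0.0] * n
        as_c = as_c or [0.0] * n
        rows = []
        for i in range(n):
            rows.append(
                {
                    "intron_id": "i1",
                    "sample": f"treated_{i+1}",
                    "msi_ret": ret_t[i],
                    "msi_as": as_t[i],
                }
            )
            rows.append(
                {
                    "intron_id": "i1",
                    "sample": f"control_{i+1}",
                    "msi_ret": ret_c[i],
                    "msi_as": as_c[i],
                }
            )
        return pd.DataFrame(rows)

    def test_clear_ir_signal(self):
        table = self._table([20, 22, 18, 21], [2, 3, 1, 2])
        out = diff.call_missplicing_msi(table, _design())
        assert out["ir_significant"].tolist() == [True]
        # cross-check against the Welch oracle on the same vectors
        _, _, p = diff.welch_t_test([20, 22, 18, 21], [2, 3, 1, 2])
        assert out["p_ret"].iloc[0] == pytest.approx(p)

    def test_identical_groups_not_significant(self):
        table = self._table([5, 6, 7, 8], [5, 6, 7, 8])
        out = diff.call_missplicing_msi(table, _design())
        assert not out["ir_significant"].iloc[0]

    def test_delta_gate(self):
        table = self._table([10.0, 10.1, 9.9, 10.0], [6.0, 6.1, 5.9, 6.0])
        out = diff.call_missplicing_msi(table, _design())
        assert out["p_ret"].iloc[0] < 0.001
        assert not out["ir_significant"].iloc[0]  # delta 4 < 5

    def test_requires_two_replicates(self):
        design = diff.ConditionDesign(
            "treated", "control", {"treated_1": "treated", "control_1": "control", "control_2": "control"}
        )
        with pytest.raises(ValueError):
            diff.call_missplicing_msi(self._table([1], [1]), design)


class TestGeneCategories:
    def _calls(self, spec_map):
        rows = []
        for intron_id, (ir, as_) in spec_map.items():
            rows.append({"intron_id": intron_id, "ir_significant": ir, "as_significant": as_})
        return pd.DataFrame(rows)

    def _catalog(self):
        recs = []
        for g in range(5):
            recs.append(
                make_intron(
                    start=1000 * g + 100, end=1000 * g + 200, gene_id=f"g{g}", intron_class="minor"
                )
            )
        recs.append(make_intron(start=9000, end=9100, gene_id="g_undetected"))
        return recs

    def test_toy_cohort_counts(self):
        catalog = self._catalog()
        ids = [r.intron_id for r in catalog[:5]]
        calls = self._calls(
            {
                ids[0]: (True, False),
                ids[1]: (True, False),
                ids[2]: (False, True),
                ids[3]: (True, True),
                ids[4]: (False, False),
            }
        )
        cats, counts = diff.categorize_genes(calls, catalog)
        assert counts == {"IR": 2, "AS": 1, "IR_and_AS": 1, "unaffected": 1, "detected": 5}
        by_gene = {c.gene_id: c.category for c in cats}
        assert by_gene["g0"] == "IR"
        assert by_gene["g2"] == "AS"
        assert by_gene["g3"] == "IR_and_AS"
        assert by_gene["g4"] == "unaffected"
        assert by_gene["g_undetected"] == "not_detected"

    def test_counts_sum_to_detected(self):
        catalog = self._catalog()
        ids = [r.intron_id for r in catalog[:5]]
        calls = self._calls({i: (True, False) for i in ids})
        _, counts = diff.categorize_genes(calls, catalog)
        assert (
            counts["IR"] + counts["AS"] + counts["IR_and_AS"] + counts["unaffected"]
            == counts["detected"]
        )


class TestFlankingMajor:
    def _transcript_catalog(self, classes, retained_positions=()):
        # one + strand transcript with evenly spaced introns
        recs = []
        for i, cls in enumerate(classes):
            recs.append(
                make_intron(
                    start=1000 + 500 * i,
                    end=1200 + 500 * i,
                    gene_id="gene1",
                    ordinal=i + 1,
                    intron_class=cls,
                    transcript_ids={"tx1"},
                )
            )
        retained = {recs[i].intron_id for i in retained_positions}
        return recs, retained

    def test_no_retained_minors_empty(self):
        recs, _ = self._transcript_catalog(["major", "minor", "major"])
        table, summary = diff.flanking_major_ir(recs, set())
        assert table.empty
        assert summary["n_retained_major"] == 0

    def test_adjacent_retained_major_reported(self):
        recs, retained = self._transcript_catalog(
            ["major", "minor", "major"], retained_positions=(1, 2)
        )
        table, summary = diff.flanking_major_ir(recs, retained)
        flank_rows = table[table["flank_retained"]]
        assert len(flank_rows) == 1
        assert flank_rows.iloc[0]["flank_intron"] == recs[2].intron_id
        assert summary == {
            "n_retained_major": 1,
            "n_flanking": 1,
            "frac_flanking": 1.0,
            "frac_nonflanking": 0.0,
        }

    def test_distant_retained_major_is_nonflanking(self):
        recs, retained = self._transcript_catalog(
            ["minor", "major", "major", "major"], retained_positions=(0, 3)
        )
        _, summary = diff.flanking_major_ir(recs, retained)
        assert summary["n_retained_major"] == 1
        assert summary["n_flanking"] == 0
        assert summary["frac_nonflanking"] == 1.0

    def test_terminal_minor_reports_absent_flank(self):
        recs, retained = self._transcript_catalog(["minor", "major"], retained_positions=(0,))
        table, _ = diff.flanking_major_ir(recs, retained)
        sides = dict(zip(table["side"], table["flank_class"]))
        assert sides["upstream"] == "absent"
        assert sides["downstream"] == "major"


class TestDesign:
    def test_from_table(self, tmp_path):
        path = tmp_path / "design.tsv"
        path.write_text(
            "sample\tcondition\n"
            + "".join(f"t{i}\tsiRNPC3\n" for i in range(4))
            + "".join(f"c{i}\tsiNT\n" for i in range(4))
        )
        d = diff.ConditionDesign.from_table(path)
        assert d.treated == "siRNPC3"
        assert d.control == "siNT"
        assert len(d.samples("siRNPC3")) == 4

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            diff.ConditionDesign("a", "b", {"s1": "c"})


class TestDiffIrPipeline:
    def test_simulated_retention_called(self, toy_pipeline):
        table = diff.diff_ir_table(
            toy_pipeline["quant_df"], toy_pipeline["design"], catalog=toy_pipeline["introns"]
        )
        called = diff.call_differential_retention(table)
        # rho=0.3 in treated vs 0 in control at depth 80: every intron passes
        assert (called["call"] == "retained_in_treated").all()
        assert set(called["intron_class"]) <= {"minor", "major"}

    def test_no_tiling_fails_coverage_gate(self, tmp_path, sim_config):
        import dataclasses

        from misplice import catalog as cat
        from misplice import quant
        from misplice.simulate import make_toy_reference, simulate_reads

        # introns long enough that boundary reads alone cannot tile the body
        cfg = dataclasses.replace(
            sim_config, tile_retained=False, n_genes=3, seed=21, intron_length=(260, 320)
        )
        ref = make_toy_reference(cfg, tmp_path)
        sams, _ = simulate_reads(ref, cfg, tmp_path)
        introns = cat.build_catalog(ref.gtf, minor_list_path=ref.minor_list)
        qdf = quant.quantify(introns, sams)
        design = diff.ConditionDesign(
            "treated",
            "control",
            {s: ("treated" if s.startswith("treated") else "control") for s in sams},
        )
        table = diff.diff_ir_table(qdf, design, catalog=introns)
        assert not table["coverage_ok_treated"].any()
        called = diff.call_differential_retention(table)
        assert (called["call"] == "not_significant").all()
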