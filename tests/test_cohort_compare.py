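"""Cohort alignment, Ω-stratification, consistency selection, contrast and
zero-GV matrices, and the end-to-end pipeline."""

import numpy as np
import pytest

from gva.cohort_compare import (
    align_cohorts,
    contrast_average,
    contrast_matrices,
    run_gva,
    select_consistent,
    stratify_omega,
    zero_gv_matrices,
)
from gva.gv_core import GVTable
from gva.synthetic import SimConfig, generate_pair, synthetic_panel


def _table(panel, rows, **kw):
    return GVTable.from_counts(panel, rows, **kw)


class TestAlign:
    def test_identical_tables_all_common(self, risk_tables):
        res = align_cohorts(risk_tables["EIRA"], risk_tables["EIRA"])
        assert res.common == risk_tables["EIRA"].gvs()
        assert res.a_only == [] and res.b_only == []

    def test_planted_overlap_recovered(self):
        panel = synthetic_panel(3)
        shared = [(1, 1, 1), (2, 2, 2)]
        a = _table(panel, [(gv, 1, 1) for gv in shared + [(3, 3, 3)]])
        b = _table(panel, [(gv, 2, 2) for gv in shared + [(1, 2, 3), (3, 2, 1)]])
        res = align_cohorts(a, b)
        assert res.common == sorted(shared)
        assert res.a_only == [(3, 3, 3)]
        assert res.b_only == sorted([(1, 2, 3), (3, 2, 1)])
        assert res.n_a_only == 2 and res.n_b_only == 8

    def test_mismatched_panels_error(self, risk_tables):
        other = _table(synthetic_panel(7), [((1,) * 7, 1, 1)])
        with pytest.raises(ValueError, match="panels differ"):
            align_cohorts(risk_tables["EIRA"], other)


class TestStratify:
    @pytest.mark.parametrize(
        "ra, rb, attr",
        [
            (2.0, 3.0, "omega_11"),
            (2.0, 0.5, "omega_12"),
            (0.5, 2.0, "omega_21"),
            (0.5, 0.8, "omega_22"),
            (1.0, 2.0, "omega_21"),  # OR exactly 1 counts as the < 1 side
        ],
    )
    def test_single_gv_placement(self, ra, rb, attr):
        gv = (1, 2)
        part = stratify_omega([gv], {gv: ra}, {gv: rb})
        assert getattr(part, attr) == [gv]
        if ra == 1.0 or rb == 1.0:
            assert part.boundary == [gv]

    def test_partition_is_exact_on_planted_signs(self):
        rng = np.random.default_rng(1)
        gvs = [(int(a), int(b)) for a, b in
               {tuple(rng.integers(1, 4, 2)) for _ in range(30)}]
        or_a = {gv: float(rng.choice([0.5, 2.0])) for gv in gvs}
        or_b = {gv: float(rng.choice([0.5, 2.0])) for gv in gvs}
        part = stratify_omega(gvs, or_a, or_b)
        assert part.all_gvs() == sorted(gvs)
        sets = [set(part.omega_11), set(part.omega_12), set(part.omega_21), set(part.omega_22)]
        assert sum(len(s) for s in sets) == len(gvs)  # disjoint partition
        for gv in part.omega_11:
            assert or_a[gv] > 1 and or_b[gv] > 1
        for gv in part.omega_21:
            assert or_a[gv] < 1 and or_b[gv] > 1

    def test_rejects_nonfinite_or(self):
        gv = (1, 1)
        with pytest.raises(ValueError, match="zero GVs"):
            stratify_omega([gv], {gv: float("inf")}, {gv: 2.0})


class TestSelectConsistent:
    def _tables_with_planted_risk(self):
        """One strong-risk GV (OR ≈ 9, n_t ≈ 40) plus weak background GVs in
        two cohorts of 1000/1500."""
        panel = synthetic_panel(2)
        rows_a = [((1, 1), 5, 35), ((1, 2), 300, 470), ((2, 1), 300, 460), ((2, 2), 395, 535)]
        rows_b = [((1, 1), 6, 38), ((1, 2), 310, 462), ((2, 1), 290, 465), ((2, 2), 394, 535)]
        return _table(panel, rows_a), _table(panel, rows_b)

    def test_planted_strong_risk_gv_selected(self):
        a, b = self._tables_with_planted_risk()
        or_a = {gv: float(e.n_s * (a.N_h - e.n_h)) / (e.n_h * (a.N_s - e.n_s))
                for gv, e in a.entries.items()}
        or_b = {gv: float(e.n_s * (b.N_h - e.n_h)) / (e.n_h * (b.N_s - e.n_s))
                for gv, e in b.entries.items()}
        part = stratify_omega(list(a.entries), or_a, or_b)
        sel = select_consistent(part, a, b, alpha=0.05)
        assert (1, 1) in sel.risk_set
        rec = sel.records_a[(1, 1)]
        assert rec.or_exp > rec.or_upper_tr
        assert rec.p_tail < 0.05
        assert rec.neg_log10_p > 1

    def test_gv_beyond_threshold_in_one_cohort_only_is_excluded(self):
        a, b = self._tables_with_planted_risk()
        # flatten the signal in cohort b: same group size, null composition
        b.entries[(1, 1)].n_h, b.entries[(1, 1)].n_s = 14, 30
        or_a = {gv: 2.0 for gv in a.entries}
        or_b = {gv: 1.5 for gv in b.entries}
        part = stratify_omega(list(a.entries), or_a, or_b)
        sel = select_consistent(part, a, b, alpha=0.05)
        assert (1, 1) not in sel.risk_set

    def test_empty_partition_gives_empty_sets(self, risk_tables):
        part = stratify_omega([], {}, {})
        sel = select_consistent(part, risk_tables["EIRA"], risk_tables["NARAC"])
        assert sel.risk_set == [] and sel.protective_set == []

    def test_selection_monotone_in_alpha(self):
        """Shrinking alpha never adds GVs to either selected set."""
        cfg = SimConfig(seed=21, n_gvs=40, planted_or={3: 4.0, 4: 0.25},
                        planted_freq={3: 0.006, 4: 0.03})
        a, b, truth = generate_pair(cfg)
        from gva.gv_core import build_gv_table
        ta = build_gv_table(a, truth["panel"])
        tb = build_gv_table(b, truth["panel"])
        res = align_cohorts(ta, tb)
        from gva.gv_stats import classify_zero, ZeroGVStatus, odds_ratio
        keep = [gv for gv in res.common
                if classify_zero(ta.entries[gv]) is ZeroGVStatus.NONE
                and classify_zero(tb.entries[gv]) is ZeroGVStatus.NONE]
        or_a = {gv: odds_ratio(ta.entries[gv], ta.N_h, ta.N_s) for gv in keep}
        or_b = {gv: odds_ratio(tb.entries[gv], tb.N_h, tb.N_s) for gv in keep}
        part = stratify_omega(keep, or_a, or_b)
        prev_risk, prev_prot = None, None
        for alpha in (0.2, 0.1, 0.05, 0.01, 0.001):
            sel = select_consistent(part, ta, tb, alpha)
            if prev_risk is not None:
                assert set(sel.risk_set) <= prev_risk
                assert set(sel.protective_set) <= prev_prot
            prev_risk, prev_prot = set(sel.risk_set), set(sel.protective_set)


class TestContrast:
    def test_published_case_cell(self, risk_tables):
        m = contrast_average(risk_tables["EIRA"], risk_tables["EIRA"].gvs(), "s")
        assert m[0, 1] == pytest.approx(0.5735, abs=5e-5)  # rs977003 AA, cases

    def test_published_control_cell(self, protective_tables):
        m = contrast_average(
            protective_tables["EIRA"], protective_tables["EIRA"].gvs(), "h"
        )
        assert m[0, 1] == pytest.approx(0.4921, abs=5e-5)  # rs977003 AA, controls

    def test_single_gv_selection_is_its_index_matrix(self, risk_tables):
        from gva.gv_core import index_matrix

        gv = risk_tables["EIRA"].gvs()[0]
        m = contrast_average(risk_tables["EIRA"], [gv], "s")
        np.testing.assert_array_equal(m, index_matrix(gv))

    def test_columns_sum_to_one_and_diff_to_zero(self, risk_tables):
        cm = contrast_matrices(risk_tables["EIRA"], risk_tables["EIRA"].gvs())
        np.testing.assert_allclose(cm.freq_case.sum(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(cm.freq_ctrl.sum(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(cm.diff.sum(axis=0), 0.0, atol=1e-12)

    def test_empty_selection_errors(self, risk_tables):
        with pytest.raises(ValueError, match="empty"):
            contrast_average(risk_tables["EIRA"], [], "s")


class TestZeroGV:
    def _zero_table(self, panel, extra=()):
        rows = [((1, 2, 3), 0, 6), ((2, 2, 2), 4, 0), ((3, 1, 1), 3, 5), *extra]
        return _table(panel, rows)

    def test_single_ss_gv_gives_its_index_matrix(self):
        from gva.gv_core import index_matrix

        panel = synthetic_panel(3)
        t = self._zero_table(panel)
        za, zb, mask = zero_gv_matrices(t, t)
        np.testing.assert_array_equal(za.c_ss, index_matrix((1, 2, 3)))
        np.testing.assert_array_equal(za.c_sh, index_matrix((2, 2, 2)))
        assert mask.all()  # identical cohorts agree in sign everywhere

    def test_diff_columns_sum_to_zero(self):
        panel = synthetic_panel(3)
        t = self._zero_table(panel, extra=[((1, 1, 1), 0, 2), ((3, 3, 3), 7, 0)])
        za, _, _ = zero_gv_matrices(t, t)
        np.testing.assert_allclose(za.diff.sum(axis=0), 0.0, atol=1e-12)

    def test_planted_all_case_gv_shows_positive_diff(self):
        """A solely-sick GV rich in state 2 at marker 3 must leave a positive
        case-minus-control difference in that cell."""
        panel = synthetic_panel(4)
        t = _table(panel, [((1, 1, 2, 1), 0, 9), ((1, 1, 1, 1), 5, 0), ((2, 2, 2, 2), 3, 3)])
        za, _, _ = zero_gv_matrices(t, t)
        assert za.diff[1, 2] > 0  # state γ=2 at marker index 2

    def test_empty_subset_flagged_as_none(self):
        panel = synthetic_panel(3)
        t = _table(panel, [((3, 1, 1), 3, 5), ((1, 2, 3), 0, 6)])  # no solely-healthy
        za, _, mask = zero_gv_matrices(t, t)
        assert za.c_sh is None and za.diff is None and mask is None


class TestRunGVA:
    def test_self_comparison_puts_planted_risk_in_omega11(self):
        cfg = SimConfig(seed=5, n_gvs=40, planted_or={3: 6.0}, planted_freq={3: 0.005},
                        perturbation_scale=0.0)
        a, _, truth = generate_pair(cfg)
        rep = run_gva(a, a, truth["panel"], alpha=0.05)
        planted = truth["pool"][3]
        assert planted in rep.partition.omega_11
        assert planted in rep.selection.risk_set

    def test_pipeline_on_synthetic_pair_is_deterministic(self):
        cfg = SimConfig(seed=9, n_gvs=50, planted_or={2: 5.0}, planted_freq={2: 0.005},
                        n_zero_sick=2, n_zero_healthy=2)
        a, b, truth = generate_pair(cfg)
        rep1 = run_gva(a, b, truth["panel"])
        rep2 = run_gva(a, b, truth["panel"])
        assert rep1.selection.risk_set == rep2.selection.risk_set
        assert rep1.partition.omega_11 == rep2.partition.omega_11
        if rep1.risk_contrast_a is not None:
            np.testing.assert_array_equal(
                rep1.risk_contrast_a.diff, rep2.risk_contrast_a.diff
            )

    def test_zero_gvs_reported_not_dropped(self):
        cfg = SimConfig(seed=13, n_gvs=30, n_zero_sick=3, n_zero_healthy=2,
                        perturbation_scale=0.0)
        a, b, truth = generate_pair(cfg)
        rep = run_gva(a, b, truth["panel"])
        assert set(truth["zero_sick"]) <= set(rep.zero_a)
        assert set(truth["zero_healthy"]) <= set(rep.zero_a)
        # excluded from stratification...
        assert not set(rep.zero_a) & set(rep.partition.all_gvs())
        # ...but present in the zero-GV analysis
        za, _, _ = rep.zero_matrices
        assert set(truth["zero_sick"]) <= set(za.ss_gvs)

    def test_filtered_totals_are_common_nonzero_sums(self):
        cfg = SimConfig(seed=17, n_gvs=30, n_zero_sick=2)
        a, b, truth = generate_pair(cfg)
        rep = run_gva(a, b, truth["panel"], totals="filtered")
        assert rep.filtered_a.N_h == rep.filtered_a.sum_h
        assert rep.filtered_a.N_s == rep.filtered_a.sum_s
        raw = run_gva(a, b, truth["panel"], totals="raw")
        assert raw.filtered_a.N_h == rep.table_a.N_h

    def test_crop_recompute(self, ra_panel):
        from gva.datasets import risk_contrast_tables

        tabs = risk_contrast_tables()
        # the bundled tables carry full filtered cohort totals; keep them
        rep = run_gva(tabs["EIRA"], tabs["NARAC"], alpha=0.05, totals="raw",
                      crop_keep=[3, 4, 5, 6])
        # all six published contrast GVs clear both cohorts' thresholds
        assert rep.selection.risk_set == tabs["EIRA"].gvs()
        assert rep.cropped is not None
        cm = rep.cropped["risk_a"]
        np.testing.assert_allclose(cm.freq_case.sum(axis=0), 1.0, atol=1e-12)
        assert cm.freq_case.shape == (3, 4)
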