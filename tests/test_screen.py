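import math

import numpy as np
import pandas as pd
import pytest

from mhcscreen.deconvolution import FractionMatrix
from mhcscreen.io import ExpressionMatrix, MhcScreenError, RunConfig, write_screen_report
from mhcscreen.scoring import CorrelationResult, SignatureScores
from mhcscreen.screen import (
    cellline_dual_effector_filter,
    correlation_filter,
    expression_filter,
    intersect_candidates,
    prognostic_filter,
    run_full_screen,
    screen_metrics,
    single_cell_validation,
    til_filter,
)
from mhcscreen.simulate import SimulationConfig, simulate_single_cell
from mhcscreen.survival import GeneCohortScore, PrognosticTable


def scores_for(expr, values):
    return SignatureScores(list(expr.sample_ids), np.asarray(values, float), "gsva", "MHC1")


class TestCorrelationFilter:
    def test_exact_negative_copy_passes(self, run_config):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        expr = ExpressionMatrix(["g"], [f"s{i}" for i in range(30)], -y[None, :])
        passed, detail = correlation_filter(expr, scores_for(expr, y), run_config)
        assert passed == {"g"}
        assert detail["g"].rho == pytest.approx(-1.0)

    def test_boundary_rho_is_inclusive(self):
        cfg = RunConfig()
        table = PrognosticTable(entries={}, genes=[], cohorts=[], risky_threshold=-12)
        # construct a gene achieving rho == -0.15 exactly is brittle with
        # continuous data; check the comparison rule directly instead
        assert (-0.15 <= cfg.rho_signature_max) and not (-0.1499 <= cfg.rho_signature_max)

    def test_shipped_defaults(self):
        cfg = RunConfig()
        assert cfg.rho_signature_max == -0.15
        assert cfg.p_max == 0.05


class TestExpressionFilter:
    def _expr(self, value, n=10):
        return ExpressionMatrix(["g"], [f"s{i}" for i in range(n)],
                                np.full((1, n), value), scale="log2_tpm")

    def test_mean_exactly_at_threshold_passes(self, run_config):
        assert expression_filter(self._expr(1.0), run_config) == {"g"}

    def test_just_below_threshold_fails(self, run_config):
        assert expression_filter(self._expr(0.99), run_config) == set()

    def test_wrong_scale_errors(self, run_config):
        expr = ExpressionMatrix(["g"], ["s1", "s2"], np.ones((1, 2)), scale="counts")
        with pytest.raises(MhcScreenError, match="scale"):
            expression_filter(expr, run_config)


def prognostic_table(scores_by_gene_cohort, risky_threshold=-12.0):
    entries = {}
    genes = sorted({g for g, _ in scores_by_gene_cohort})
    cohorts = sorted({c for _, c in scores_by_gene_cohort})
    for (g, c), score in scores_by_gene_cohort.items():
        entries[(g, c)] = GeneCohortScore(
            gene=g, cohort=c, score=score,
            risky=score is not None and score <= risky_threshold)
    return PrognosticTable(entries=entries, genes=genes, cohorts=cohorts,
                           risky_threshold=risky_threshold)


class TestPrognosticFilter:
    def _table(self, focal_score, n_risky_others):
        scores = {("g", "BRCA"): focal_score}
        for i in range(5):
            scores[("g", f"C{i:02d}")] = -20 if i < n_risky_others else 0
        return prognostic_table(scores)

    def test_score_exactly_minus12_fails_strict(self, run_config):
        table = self._table(-12, 5)
        assert prognostic_filter(table, "BRCA", run_config) == set()

    def test_passing_gene(self, run_config):
        table = self._table(-13, 4)
        assert prognostic_filter(table, "BRCA", run_config) == {"g"}

    def test_risky_in_exactly_three_fails_strict(self, run_config):
        # focal BRCA is risky too (score -13 <= -12), so 3 risky others
        # + BRCA = 4 > 3 passes; with 2 others it is exactly 3 and fails
        table = self._table(-13, 2)
        assert prognostic_filter(table, "BRCA", run_config) == set()

    def test_unavailable_score_excluded(self, run_config):
        table = self._table(None, 5)
        assert prognostic_filter(table, "BRCA", run_config) == set()


class TestIntersect:
    def test_worked_example(self):
        assert intersect_candidates([{"a", "b", "c"}, {"b", "c"}, {"c", "b", "d"}]) == ["b", "c"]

    def test_empty_input_set_gives_empty(self):
        assert intersect_candidates([{"a"}, set()]) == []

    def test_order_independent(self):
        sets = [{"a", "b"}, {"b", "c"}, {"b"}]
        assert (intersect_candidates(sets) == intersect_candidates(sets[::-1])
                == intersect_candidates([sets[1], sets[0], sets[2]]))


def rho_frame(rho_cd8, rho_nk):
    return pd.DataFrame({
        "CD8_T": {"g": CorrelationResult(rho_cd8, 0.01, 100)},
        "NK_activated": {"g": CorrelationResult(rho_nk, 0.01, 100)},
    })


class TestTilFilter:
    def test_requires_both_cell_types(self, run_config):
        assert til_filter(["g"], rho_frame(-0.2, -0.05), run_config) == set()
        assert til_filter(["g"], rho_frame(-0.2, -0.2), run_config) == {"g"}

    def test_boundary_is_strict(self, run_config):
        assert til_filter(["g"], rho_frame(-0.1, -0.3), run_config) == set()

    def test_missing_cell_type_errors(self, run_config):
        frame = pd.DataFrame({"CD8_T": {"g": CorrelationResult(-0.5, 0.01, 100)}})
        with pytest.raises(MhcScreenError):
            til_filter(["g"], frame, run_config)


class TestDualEffectorFilter:
    def test_planted_duals_retained_and_boundary_strict(self, small_panel, run_config):
        from mhcscreen.scoring import ucell_score, zscore_normalize
        from mhcscreen.simulate import MHC1_SIGNATURE
        scores = zscore_normalize(ucell_score(
            small_panel.expression, MHC1_SIGNATURE,
            max_rank=small_panel.expression.n_genes - 1))
        candidates = small_panel.truth.planted_negative
        passed, detail = cellline_dual_effector_filter(candidates, small_panel, scores, run_config)
        assert passed == set(small_panel.truth.planted_dual)
        # boundary: a median of exactly -0.5 must fail the strict rule
        assert not (-0.5 < run_config.dependency_max)

    def test_gene_absent_from_panel_excluded(self, small_panel, run_config):
        from mhcscreen.scoring import ucell_score, zscore_normalize
        from mhcscreen.simulate import MHC1_SIGNATURE
        scores = zscore_normalize(ucell_score(
            small_panel.expression, MHC1_SIGNATURE,
            max_rank=small_panel.expression.n_genes - 1))
        passed, _ = cellline_dual_effector_filter(["not_a_gene"], small_panel, scores, run_config)
        assert passed == set()


class TestSingleCellValidation:
    def test_extreme_tumor_fraction_samples_excluded(self, run_config):
        cfg = SimulationConfig(n_samples=50, n_genes=60, n_planted_negative=4,
                               n_planted_dual=2, n_sc_samples=10,
                               cells_per_sample=150, seed=2)
        samples = simulate_single_cell(cfg)
        high = [s for s in samples if 0.10 <= s.tumor_proportion <= 0.90]
        if len(high) >= 3:
            out = single_cell_validation(samples, cfg_planted(cfg), ["HLA-A", "HLA-B", "B2M"],
                                         run_config)
            assert out["n_samples"].max() <= len(high)

    def test_too_few_surviving_samples_errors(self, run_config):
        cfg = SimulationConfig(n_samples=50, n_genes=60, n_planted_negative=4,
                               n_planted_dual=2, n_sc_samples=5,
                               cells_per_sample=150, seed=3, tumor_prop_range=(0.95, 0.99))
        samples = simulate_single_cell(cfg)
        with pytest.raises(MhcScreenError, match="exclusion"):
            single_cell_validation(samples, cfg_planted(cfg), ["HLA-A"], run_config)


def cfg_planted(cfg):
    return [f"NEG{i + 1:03d}" for i in range(cfg.n_planted_negative)]


class TestFullScreen:
    def test_planted_recovery_on_small_cohort(self, small_cohort, small_panel, run_config):
        result = run_full_screen(small_cohort, run_config, panel=small_panel)
        metrics = screen_metrics(result, small_cohort.truth)
        assert metrics["recall"] >= 0.8
        assert metrics["decoy_pass_rate"] <= 0.05
        assert metrics["recall"] > metrics["decoy_pass_rate"]

    def test_subset_chain(self, small_cohort, small_panel, run_config):
        result = run_full_screen(small_cohort, run_config, panel=small_panel)
        corr = result.stage("signature_correlation").passed
        prog = result.stage("prognostic").passed
        expr = result.stage("expression").passed
        til = result.stage("til_correlation").passed
        assert set(result.candidates) == til
        assert til <= corr & prog & expr
        assert set(result.dual_effectors) <= til

    def test_impossible_threshold_gives_valid_empty_result(self, small_cohort, small_panel):
        cfg = RunConfig(rho_signature_max=-1.0, seed=42)  # nothing reaches rho <= -1
        result = run_full_screen(small_cohort, cfg, panel=small_panel)
        assert result.candidates == []
        assert result.dual_effectors == []

    def test_permissive_thresholds_keep_all_screenable_genes(self, small_cohort, small_panel):
        cfg = RunConfig(rho_signature_max=1.0, p_max=1.0, expr_min=-math.inf,
                        prognostic_max=math.inf, min_risky_cohorts=-1,
                        rho_til_max=1.0, dependency_max=math.inf,
                        cellline_rho_max=1.0, seed=42)
        result = run_full_screen(small_cohort, cfg, panel=small_panel)
        screenable = set(small_cohort.expression.gene_ids) - set(small_cohort.truth.signature_genes)
        assert set(result.candidates) == screenable

    def test_relaxing_a_threshold_never_shrinks_stages(self, small_cohort, small_panel, run_config):
        strict = run_full_screen(small_cohort, run_config, panel=small_panel)
        relaxed_cfg = RunConfig(rho_signature_max=-0.05, seed=42)
        relaxed = run_full_screen(small_cohort, relaxed_cfg, panel=small_panel)
        assert strict.stage("signature_correlation").passed <= relaxed.stage("signature_correlation").passed

    def test_report_byte_identical_across_runs(self, small_cohort, small_panel, run_config, tmp_path):
        r1 = run_full_screen(small_cohort, run_config, panel=small_panel)
        r2 = run_full_screen(small_cohort, run_config, panel=small_panel)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_screen_report(r1, d1)
        write_screen_report(r2, d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()
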