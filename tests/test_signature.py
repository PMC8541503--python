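import numpy as np
import pytest
from scipy import stats

from mmrisk import (
    DataValidationError,
    ExpressionMatrix,
    MMRiskError,
    RiskScores,
    SignatureModel,
    SimulationConfig,
    build_signature,
    compute_risk_score,
    screen_genes,
    simulate_cohort,
)
from mmrisk.signature import GeneScreen, GeneScreenResult, SignatureGene

from .conftest import make_survival


def log_matrix(values, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(gene_ids, sample_ids, values, "log_normalized")


def two_gene_model(score_cutoff=None):
    return SignatureModel(
        genes=[
            SignatureGene("g0", 1.0, 0.8, "poor_when_high", 0.01),
            SignatureGene("g1", 2.0, -0.5, "poor_when_low", 0.02),
        ],
        alpha=0.05,
        score_cutoff=score_cutoff,
        metadata={"space": "log_normalized"},
    )


class TestScreen:
    def test_constant_gene_skipped(self):
        rng = np.random.default_rng(3)
        n = 40
        s = make_survival(rng, n, cens_frac=0.3)
        vals = np.vstack([rng.normal(5, 1, size=n), np.full(n, 2.5)])
        m = log_matrix(vals, sample_ids=s.sample_ids)
        screen = screen_genes(m, s)
        assert "g1" in screen.skipped and "degenerate" in screen.skipped["g1"]
        assert [r.gene_id for r in screen.results] == ["g0"]

    def test_raw_counts_rejected(self):
        rng = np.random.default_rng(0)
        s = make_survival(rng, 10)
        m = ExpressionMatrix(["g"], s.sample_ids, np.ones((1, 10)), "raw_counts")
        with pytest.raises(DataValidationError, match="normalized"):
            screen_genes(m, s)

    def test_misaligned_samples_rejected(self):
        rng = np.random.default_rng(0)
        s = make_survival(rng, 10)
        m = log_matrix(rng.normal(5, 1, size=(2, 10)))  # sample ids s0..s9 match
        other = make_survival(rng, 9)
        with pytest.raises(DataValidationError):
            screen_genes(m, other)

    def test_direction_consistent_with_beta(self, fitted):
        for r in fitted.screen.results:
            assert (r.beta > 0) == (r.direction == "poor_when_high") or r.beta == 0

    def test_null_screen_selects_nothing(self):
        # survival independent of every gene: BH keeps the family clean
        cfg = SimulationConfig(
            seed=99, n_genes=300, n_samples=120, n_prognostic=0
        )
        counts, surv, _ = simulate_cohort(cfg)
        from mmrisk import normalize_pipeline

        screen = screen_genes(normalize_pipeline(counts), surv)
        selected = [r for r in screen.results if r.p_adj < 0.05]
        assert len(selected) <= 2


class TestBuildSignature:
    def _screen(self, p_adjs):
        results = [
            GeneScreenResult(f"g{i}", 1.0, 3.0, p, 0.5, "poor_when_high", p_adj=p)
            for i, p in enumerate(p_adjs)
        ]
        return GeneScreen(results)

    def test_threshold_arithmetic(self):
        model = build_signature(self._screen([0.01, 0.04, 0.06]), alpha=0.05)
        assert len(model.genes) == 2

    def test_alpha_one_keeps_everything(self):
        model = build_signature(self._screen([0.2, 0.9, 0.5]), alpha=1.0)
        assert len(model.genes) == 3

    def test_empty_selection_warns(self):
        with pytest.warns(UserWarning, match="empty signature"):
            model = build_signature(self._screen([0.9]), alpha=0.05)
        assert model.genes == []

    def test_recovered_directions_match_planted(self, cohort, fitted):
        _, _, truth = cohort
        planted = dict(zip(truth.prognostic_gene_ids, truth.directions))
        df = fitted.signature.to_dataframe().set_index("gene_id")
        hits = [g for g in df.index if g in planted]
        assert hits, "no planted gene recovered"
        for g in hits:
            assert df.loc[g, "direction"] == planted[g]


class TestRiskScore:
    def test_forced_arithmetic(self):
        model = two_gene_model()
        m = log_matrix([[1.5], [2.5]], gene_ids=["g0", "g1"])  # above both cutpoints
        scores = compute_risk_score(model, m)
        assert scores.score[0] == pytest.approx(0.8 - 0.5)

    def test_extremal_score_is_sum_abs_beta(self):
        model = two_gene_model()
        # above the adverse-high cutpoint, below the protective-high cutpoint
        m = log_matrix([[1.5], [1.5]], gene_ids=["g0", "g1"])
        scores = compute_risk_score(model, m)
        assert scores.score[0] == pytest.approx(model.max_score) == pytest.approx(1.3)

    def test_flipping_one_gene_changes_score_by_2beta(self):
        model = two_gene_model()
        above = compute_risk_score(model, log_matrix([[1.5], [2.5]], gene_ids=["g0", "g1"]))
        below = compute_risk_score(model, log_matrix([[0.5], [2.5]], gene_ids=["g0", "g1"]))
        assert above.score[0] - below.score[0] == pytest.approx(2 * 0.8)

    def test_at_most_2k_distinct_values_and_zero_beta_inert(self):
        rng = np.random.default_rng(6)
        model = two_gene_model()
        m = log_matrix(rng.uniform(0, 4, size=(2, 200)), gene_ids=["g0", "g1"])
        scores = compute_risk_score(model, m)
        assert len(np.unique(scores.score)) <= 4
        model.genes.append(SignatureGene("g2", 0.0, 0.0, "poor_when_high", 0.01))
        m2 = log_matrix(
            np.vstack([m.values, rng.uniform(0, 4, size=200)]), gene_ids=["g0", "g1", "g2"]
        )
        np.testing.assert_allclose(compute_risk_score(model, m2).score, scores.score)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        model = two_gene_model()
        vals = rng.uniform(0.2, 3.0, size=(2, 50))
        base = compute_risk_score(model, log_matrix(vals, gene_ids=["g0", "g1"]))
        warped_model = SignatureModel(
            genes=[
                SignatureGene("g0", np.exp(1.0), 0.8, "poor_when_high", 0.01),
                SignatureGene("g1", 2.0, -0.5, "poor_when_low", 0.02),
            ],
            metadata={"space": "log_normalized"},
        )
        warped_vals = vals.copy()
        warped_vals[0] = np.exp(vals[0])
        warped = compute_risk_score(
            warped_model, log_matrix(warped_vals, gene_ids=["g0", "g1"])
        )
        np.testing.assert_allclose(warped.score, base.score)

    def test_score_bounded_by_sum_abs_beta(self, fitted):
        assert np.all(np.abs(fitted.scores.score) <= fitted.signature.max_score + 1e-9)

    def test_missing_gene_policy(self):
        model = SignatureModel(
            genes=[
                SignatureGene(f"g{i}", 1.0, 0.1 * (i + 1), "poor_when_high", 0.01)
                for i in range(10)
            ],
            metadata={"space": "log_normalized"},
        )
        m_ok = log_matrix(np.ones((9, 3)) * 2, gene_ids=[f"g{i}" for i in range(9)])
        with pytest.warns(UserWarning, match="absent"):
            scores = compute_risk_score(m=m_ok, model=model)
        assert scores.score[0] == pytest.approx(sum(0.1 * (i + 1) for i in range(9)))
        m_bad = log_matrix(np.ones((5, 3)), gene_ids=[f"g{i}" for i in range(5)])
        with pytest.raises(DataValidationError, match="absent"):
            compute_risk_score(model, m_bad)

    def test_wrong_space_rejected(self):
        model = two_gene_model()
        m = ExpressionMatrix(["g0", "g1"], ["s"], np.ones((2, 1)), "normalized")
        with pytest.raises(DataValidationError, match="space"):
            compute_risk_score(model, m)

    def test_empty_model_errors(self):
        with pytest.raises(MMRiskError, match="empty"):
            compute_risk_score(SignatureModel(genes=[]), log_matrix(np.ones((1, 1))))

    def test_concordance_with_true_risk_group(self, cohort, fitted):
        _, _, truth = cohort
        sc = fitted.scores.score
        hi = truth.true_high_risk
        auc = stats.mannwhitneyu(sc[hi], sc[~hi]).statistic / (hi.sum() * (~hi).sum())
        assert auc > 0.8


class TestSerialization:
    def test_json_round_trip(self, fitted):
        text = fitted.signature.to_json()
        again = SignatureModel.from_json(text)
        assert again.to_json() == text
        assert again.gene_ids == fitted.signature.gene_ids
        assert again.score_cutoff == fitted.signature.score_cutoff

    def test_save_load(self, tmp_path):
        model = two_gene_model(score_cutoff=0.1)
        path = tmp_path / "sig.json"
        model.save(path)
        again = SignatureModel.load(path)
        assert again.to_json() == model.to_json()

    def test_poor_good_partition_counts(self, fitted):
        sig = fitted.signature
        assert sig.n_poor + sig.n_good == len(sig.genes)
        df = sig.to_dataframe()
        assert sig.n_poor == (df["beta"] > 0).sum()
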