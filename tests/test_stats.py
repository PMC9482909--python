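"""Feature-selection statistics: IQR ladder, normalization/scaling,
univariate tests, PLS-DA VIP, the three-way selection rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from exposcreen.msdata import CohortDesign
from exposcreen.stats import (
    ProcessedMatrix,
    iqr_filter,
    ladder_fraction,
    normalize_and_scale,
    plsda_vip,
    select_significant,
    univariate,
)


def make_design(n_pd=10, n_ctrl=10, n_qc=0):
    groups = {f"PD{i}": "PD" for i in range(n_pd)}
    groups.update({f"C{i}": "Ctrl" for i in range(n_ctrl)})
    groups.update({f"QC{i}": "QC" for i in range(n_qc)})
    return CohortDesign(groups)


def matrix_from(array, design, stage="raw", prefix="F"):
    df = pd.DataFrame(
        array, index=[f"{prefix}{i:04d}" for i in range(len(array))], columns=list(design.groups)
    )
    return ProcessedMatrix(df, stage, design)


def simulate(n_features=100, n_spiked=0, fc=4.0, cv=0.2, n=10, seed=0, baseline=1e6):
    rng = np.random.default_rng(seed)
    design = make_design(n, n)
    sigma = np.sqrt(np.log(1 + cv * cv))
    X = baseline * np.exp(sigma * rng.standard_normal((n_features, 2 * n)))
    X[:n_spiked, :n] *= fc
    return matrix_from(X, design), design


class TestIqrFilter:
    def test_ladder(self):
        assert ladder_fraction(100) == 0.0
        assert ladder_fraction(400) == 0.05
        assert ladder_fraction(999) == 0.10
        assert ladder_fraction(1000) == 0.25
        assert ladder_fraction(5000) == 0.40

    def test_small_table_drops_nothing(self):
        m, _ = simulate(100)
        assert len(iqr_filter(m).data) == 100

    def test_identical_iqr_ties_broken_by_feature_id(self):
        design = make_design(3, 3)
        X = np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], (1000, 1))
        m = matrix_from(X, design)
        kept = iqr_filter(m).data.index
        assert len(kept) == 750
        # lexicographically smallest ids dropped first on full tie
        assert "F0000" not in kept and "F0999" in kept

    def test_constant_feature_dropped_first(self):
        design = make_design(3, 3)
        rng = np.random.default_rng(1)
        X = rng.uniform(1, 100, (20, 6))
        X[7] = 5.0  # constant, IQR 0
        m = matrix_from(X, design)
        kept = iqr_filter(m, drop_fraction=0.05).data.index
        assert "F0007" not in kept

    def test_requires_ten_features(self):
        m, _ = simulate(5)
        with pytest.raises(ValueError):
            iqr_filter(m)


class TestNormalizeAndScale:
    def test_sample_totals_equalized(self):
        design = make_design(2, 2)
        m = matrix_from(np.array([[50.0, 100.0, 25.0, 75.0], [50.0, 100.0, 25.0, 75.0]]), design)
        normalized, _ = normalize_and_scale(m)
        totals = normalized.data.sum(axis=0)
        assert np.allclose(totals, totals.iloc[0])

    def test_idempotent(self):
        m, _ = simulate(30)
        n1, _ = normalize_and_scale(m)
        n2, _ = normalize_and_scale(n1)
        assert np.allclose(n1.data.to_numpy(), n2.data.to_numpy())

    def test_pareto_variance_equals_sd(self):
        m, _ = simulate(50, seed=3)
        normalized, scaled = normalize_and_scale(m)
        sd = normalized.data.std(axis=1, ddof=1)
        assert np.allclose(scaled.data.var(axis=1, ddof=1), sd)

    def test_constant_feature_guarded_to_zeros(self):
        # equal column totals keep the constant row constant through
        # normalization; sd 0 must yield a zero row, not NaN
        design = make_design(2, 2)
        X = np.array([[5.0, 5.0, 5.0, 5.0], [3.0, 3.0, 3.0, 3.0]])
        _, scaled = normalize_and_scale(matrix_from(X, design))
        assert np.allclose(scaled.data.to_numpy(), 0.0)

    def test_all_zero_sample_named_in_error(self):
        design = make_design(2, 2)
        X = np.array([[1.0, 0.0, 2.0, 3.0], [1.0, 0.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="PD1"):
            normalize_and_scale(matrix_from(X, design))


class TestUnivariate:
    def test_fold_change_of_means(self):
        # FC is the ratio of group means on the normalized-unscaled matrix
        design = make_design(3, 3)
        X = np.vstack([[20.0, 20, 20, 10, 10, 10], np.full((11, 6), 100.0)])
        normalized = matrix_from(X, design, stage="normalized")
        scaled = matrix_from(X - X.mean(axis=1, keepdims=True), design, stage="scaled")
        uni = univariate(normalized, scaled)
        assert uni.iloc[0]["fold_change"] == pytest.approx(2.0)
        assert np.allclose(uni.iloc[1:]["fold_change"], 1.0)

    def test_identical_groups(self):
        design = make_design(4, 4)
        rng = np.random.default_rng(0)
        row = rng.uniform(10, 20, 4)
        X = np.tile(np.concatenate([row, row]), (12, 1))
        X += rng.normal(0, 1e-9, X.shape)  # break exact degeneracy
        normalized, scaled = normalize_and_scale(matrix_from(X, design))
        uni = univariate(normalized, scaled)
        assert np.allclose(uni["fold_change"], 1.0, atol=1e-6)

    def test_nicotinamide_like_direction(self):
        # control levels ~4.3x the disease group: FC ~ 0.23
        design = make_design(5, 5)
        rng = np.random.default_rng(2)
        X = rng.uniform(900, 1100, (20, 10))
        X[0, :5] = X[0, 5:] * 0.2333
        normalized, scaled = normalize_and_scale(matrix_from(X, design))
        uni = univariate(normalized, scaled)
        assert uni.iloc[0]["fold_change"] == pytest.approx(0.23, abs=0.03)

    def test_group_too_small(self):
        design = make_design(2, 3)
        m, _ = simulate(12, n=3)
        normalized, scaled = normalize_and_scale(m)
        normalized.design = design
        scaled.design = design
        with pytest.raises(ValueError):
            univariate(normalized, scaled)


class TestPlsdaVip:
    def test_vip_squared_sums_to_feature_count(self):
        for orthogonal in (False, True):
            m, _ = simulate(80, n_spiked=5, seed=4)
            _, scaled = normalize_and_scale(m)
            vip = plsda_vip(scaled, orthogonal=orthogonal)
            assert (vip**2).sum() == pytest.approx(len(vip), abs=1e-8)

    def test_single_informative_feature_has_max_vip(self):
        m, _ = simulate(60, n_spiked=1, fc=20.0, cv=0.05, seed=5)
        _, scaled = normalize_and_scale(m)
        vip = plsda_vip(scaled)
        assert vip.idxmax() == "F0000"
        assert vip.max() > 1

    def test_permuted_labels_no_systematic_vip(self):
        rng = np.random.default_rng(6)
        top_counts = {}
        for seed in range(8):
            m, design = simulate(50, n_spiked=1, fc=8.0, seed=seed)
            # permute class labels: reassign group membership randomly
            labels = list(design.groups.values())
            rng.shuffle(labels)
            design.groups = dict(zip(design.groups.keys(), labels))
            _, scaled = normalize_and_scale(m)
            vip = plsda_vip(scaled)
            top_counts[vip.idxmax()] = top_counts.get(vip.idxmax(), 0) + 1
            assert abs(np.median(vip) - 1.0) < 0.5
        assert max(top_counts.values()) < 8  # no feature wins across all seeds

    def test_matches_sklearn_first_component_weights(self):
        """Independent cross-check of the NIPALS predictive component."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        m, _ = simulate(40, n_spiked=3, seed=7)
        _, scaled = normalize_and_scale(m)
        cols = scaled.group_columns("PD") + scaled.group_columns("Ctrl")
        X = scaled.data[cols].T.to_numpy()
        y = np.array([1.0] * 10 + [-1.0] * 10)
        pls = sklearn.PLSRegression(n_components=1, scale=False).fit(X, y)
        w_sklearn = pls.x_weights_[:, 0]
        vip = plsda_vip(scaled, n_components=1)
        # for a 1-component PLS1 model VIP_j = sqrt(p) * |w_j|
        expected = np.sqrt(len(vip)) * np.abs(w_sklearn / np.linalg.norm(w_sklearn))
        assert np.allclose(vip.to_numpy(), expected, atol=1e-8)

    def test_constant_matrix_errors(self):
        design = make_design(3, 3)
        m = matrix_from(np.ones((12, 6)), design, stage="scaled")
        with pytest.raises(ValueError):
            plsda_vip(m)

    def test_null_pvalues_uniform(self):
        """Welch p-values under the null are Uniform(0,1) (KS, alpha=0.01)."""
        m, _ = simulate(1000, n_spiked=0, seed=8)
        normalized, scaled = normalize_and_scale(m)
        uni = univariate(normalized, scaled)
        stat = sps.kstest(uni["p_value"], "uniform")
        assert stat.pvalue > 0.01


class TestSelectSignificant:
    def row(self, fc, p, fid="F1"):
        return pd.DataFrame({"fold_change": [fc], "p_value": [p]}, index=[fid])

    def select_one(self, fc, p, vip):
        res, _ = select_significant(self.row(fc, p), pd.Series([vip], index=["F1"]))
        return res[0]

    def test_passing_case(self):
        r = self.select_one(3.0, 0.05, 1.5)
        assert r.significant and r.direction == "up_in_PD"

    def test_vip_below_one_rejected(self):
        # the published valine case: FC and p pass, VIP 0.7783 fails
        assert not self.select_one(3.0, 0.05, 0.7783).significant

    def test_exhaustive_truth_table(self):
        for p_ok in (True, False):
            for fc_case in ("up", "down", "mid"):
                for vip_ok in (True, False):
                    fc = {"up": 3.0, "down": 0.3, "mid": 1.2}[fc_case]
                    r = self.select_one(fc, 0.05 if p_ok else 0.2, 1.5 if vip_ok else 0.8)
                    assert r.significant == (p_ok and fc_case != "mid" and vip_ok)

    def test_boundaries_strict(self):
        assert not self.select_one(2.0, 0.05, 1.5).significant  # FC > 2 strict
        assert not self.select_one(3.0, 0.1, 1.5).significant  # p < 0.1 strict
        assert not self.select_one(3.0, 0.05, 1.0).significant  # VIP > 1 strict

    def test_volcano_table(self):
        _, volcano = select_significant(self.row(4.0, 0.01), pd.Series([2.0], index=["F1"]))
        assert volcano.loc["F1", "log2_fc"] == pytest.approx(2.0)
        assert volcano.loc["F1", "neg_log10_p"] == pytest.approx(2.0)

    def test_fdr_flag_uses_adjusted_p(self):
        uni = pd.DataFrame(
            {"fold_change": [4.0] * 10, "p_value": [0.08] * 10}, index=[f"F{i}" for i in range(10)]
        )
        vip = pd.Series(2.0, index=uni.index)
        raw, _ = select_significant(uni, vip)
        adj, _ = select_significant(uni, vip, fdr=True)
        assert all(r.significant for r in raw)
        assert all(r.p_value == 0.08 for r in adj)  # BH with equal p keeps 0.08 < 0.1
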