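"""MA/loess normalization and differential-expression statistics."""

import numpy as np
import pandas as pd
import pytest

from _oracles import bh_hand, lowess_hand
from oligochip.array_qc import filter_spots
from oligochip.fixtures import FixtureSpec, generate_two_color_slides
from oligochip.normalize_de import (
    DEGeneList,
    GeneExpressionMatrix,
    bh_adjust,
    build_expression_matrix,
    consensus_lists,
    loess_normalize,
    ma_transform,
    normalize_slide,
    per_gene_linear_fit,
    sam_test,
)


class TestMATransform:
    def test_equal_channels(self):
        v = ma_transform(256.0, 256.0)
        assert (v.M, v.A) == (0.0, 8.0)

    def test_fourfold_ratio(self):
        v = ma_transform(64.0, 16.0)
        assert v.M == pytest.approx(2.0)
        assert v.A == pytest.approx(5.0)

    def test_swap_negates_m_preserves_a(self, rng):
        r, g = rng.uniform(10, 1000, 2)
        a, b = ma_transform(r, g), ma_transform(g, r)
        assert a.M == pytest.approx(-b.M)
        assert a.A == pytest.approx(b.A)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ma_transform(0.0, 10.0)


class TestLoessNormalize:
    def test_constant_trend_removed(self, rng):
        a = rng.uniform(6, 14, 200)
        m = np.full(200, 1.7)
        out = loess_normalize(m, a)
        assert np.max(np.abs(out)) < 1e-6

    def test_matches_hand_local_regression(self, rng):
        a = rng.uniform(6, 14, 150)
        m = 0.4 * np.sin(a) + rng.normal(0, 0.2, 150)
        ours = loess_normalize(m, a, span=0.4, iterations=0)
        hand = m - lowess_hand(a, m, 0.4)
        assert np.max(np.abs(ours - hand)) < 1e-8

    def test_planted_smooth_bias_recovered(self):
        """With a planted dye bias and no DE, per-decile medians of
        normalized M are near zero."""
        spec = FixtureSpec(seed=5, n_spots=2000, dye_bias_amplitude=0.6,
                           n_de_genes=0, m_noise_sd=0.15)
        slides, _, _ = generate_two_color_slides(spec)
        df = normalize_slide(filter_spots(next(iter(slides.values()))))
        deciles = pd.qcut(df["A"], 10)
        med = df.groupby(deciles, observed=True)["M_norm"].median()
        assert np.max(np.abs(med.to_numpy())) < 0.05

    def test_planted_de_gene_survives_normalization(self):
        spec = FixtureSpec(seed=8, n_spots=800, dye_bias_amplitude=0.4,
                           n_de_genes=8, de_log2_fold=1.0, m_noise_sd=0.1)
        slides, truth, layout = generate_two_color_slides(spec)
        sid = layout.loc[layout["orientation"] == "forward", "slide_id"].iloc[0]
        df = normalize_slide(filter_spots(slides[sid])).set_index("ID")
        planted = truth[truth["log2_fold"] == 1.0]["gene_id"]
        got = df.loc[planted, "M_norm"]
        assert np.all(np.abs(got - 1.0) < 0.2)

    def test_normalization_preserves_a(self):
        spec = FixtureSpec(seed=3, n_spots=200)
        slides, _, _ = generate_two_color_slides(spec)
        raw = filter_spots(next(iter(slides.values())))
        df = normalize_slide(raw)
        recomputed = 0.5 * np.log2(
            raw["F_red"].to_numpy() * raw["F_green"].to_numpy()
        )
        assert np.allclose(df["A"], recomputed)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            loess_normalize(rng.normal(size=10), rng.uniform(6, 14, 10))


def _matrix(values, orientations):
    df = pd.DataFrame(
        values, columns=[f"h{i}" for i in range(np.asarray(values).shape[1])]
    )
    df.index = [f"g{i}" for i in range(len(df))]
    return GeneExpressionMatrix(
        values=df,
        dye_orientation={f"h{i}": o for i, o in enumerate(orientations)},
    )


class TestPerGeneLinearFit:
    def test_dye_sign_convention(self):
        mat = _matrix([[1.0, -1.0]], ["forward", "swapped"])
        fit = per_gene_linear_fit(mat)
        assert fit.loc["g0", "estimate"] == pytest.approx(1.0)

    def test_hand_computed_t(self):
        mat = _matrix([[1.0, 1.2, 0.8]], ["forward"] * 3)
        fit = per_gene_linear_fit(mat)
        assert fit.loc["g0", "estimate"] == pytest.approx(1.0)
        assert fit.loc["g0", "t"] == pytest.approx(1.0 / (0.2 / np.sqrt(3)), rel=1e-6)

    def test_degenerate_rows(self):
        mat = _matrix([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0], [0.5, np.nan, np.nan]],
                      ["forward"] * 3)
        fit = per_gene_linear_fit(mat)
        assert fit.loc["g0", "p"] == 1.0
        assert np.isinf(fit.loc["g1", "t"]) and not fit.loc["g1", "testable"]
        assert not fit.loc["g2", "testable"]

    def test_null_pvalues_uniform(self, rng):
        x = rng.normal(0, 0.3, size=(500, 6))
        fit = per_gene_linear_fit(_matrix(x, ["forward"] * 6))
        from scipy.stats import kstest

        assert kstest(fit["p"], "uniform").statistic < 0.06


class TestSAM:
    def test_d_equals_scaled_t_at_s0_zero(self):
        obs = np.array([[0.9, 1.1, 1.3, 0.8, 1.2, 1.0]])
        mat = _matrix(obs, ["forward"] * 6)
        sam = sam_test(mat, n_permutations=20, seed=1, s0=0.0)
        fit = per_gene_linear_fit(mat)
        n = 6
        assert sam.table.loc["g0", "d"] == pytest.approx(
            fit.loc["g0", "t"] / np.sqrt(n), rel=1e-9
        )

    def test_seeded_reproducibility(self, rng):
        x = rng.normal(0, 0.3, size=(100, 6))
        mat = _matrix(x, ["forward", "swapped"] * 3)
        a = sam_test(mat, n_permutations=50, seed=42)
        b = sam_test(mat, n_permutations=50, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.s0 == b.s0

    def test_planted_genes_detected(self, rng):
        x = rng.normal(0, 0.3, size=(400, 6))
        x[:20] += 2.0
        sam = sam_test(_matrix(x, ["forward"] * 6), n_permutations=100, seed=7,
                       fdr_threshold=0.01)
        called = set(np.where(sam.table["fdr"] <= 0.01)[0])
        assert len(called & set(range(20))) >= 18

    def test_fdr_monotone_in_d(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.3, size=(300, 6))
        x[:10] += 1.5
        sam = sam_test(_matrix(x, ["forward"] * 6), n_permutations=60, seed=2)
        t = sam.table.dropna().sort_values("d", key=abs, ascending=False)
        fdr = t["fdr"].to_numpy()
        assert np.all(np.diff(fdr) >= -1e-12)

    def test_too_few_permutations_rejected(self):
        mat = _matrix([[1.0, 2.0]], ["forward"] * 2)
        with pytest.raises(ValueError):
            sam_test(mat, n_permutations=5)


class TestBHAdjust:
    def test_equal_pvalues_unchanged(self):
        assert np.allclose(bh_adjust([0.03] * 5), 0.03)

    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_random_vectors_match_hand_oracle(self, rng):
        for _ in range(10):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), bh_hand(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestConsensus:
    def _dl(self, genes, method="linear_model", comparison="bean_vs_leaf"):
        return DEGeneList(comparison=comparison, genes=frozenset(genes),
                          direction={g: "bean" for g in genes}, method=method,
                          threshold=0.01)

    def test_disjoint_lists_empty(self):
        out = consensus_lists(self._dl({"a", "b"}), self._dl({"c"}, "permutation"))
        assert out.genes == frozenset()

    def test_subset_returned(self):
        out = consensus_lists(self._dl({"a", "b", "c"}), self._dl({"b"}, "permutation"))
        assert out.genes == frozenset({"b"})
        assert out.method == "consensus"

    def test_random_lists_match_set_oracle(self, rng):
        universe = [f"g{i}" for i in range(50)]
        a = {g for g in universe if rng.random() < 0.4}
        b = {g for g in universe if rng.random() < 0.4}
        out = consensus_lists(self._dl(a), self._dl(b, "permutation"))
        assert out.genes == frozenset(a & b)

    def test_mismatched_comparisons_rejected(self):
        with pytest.raises(ValueError):
            consensus_lists(self._dl({"a"}), self._dl({"a"}, comparison="x_vs_y"))


class TestMatrixAssembly:
    def test_build_from_fixture_slides(self):
        spec = FixtureSpec(seed=2, n_spots=150, n_de_genes=10)
        slides, truth, layout = generate_two_color_slides(spec)
        normalized = {sid: normalize_slide(filter_spots(df))
                      for sid, df in slides.items()}
        mat = build_expression_matrix(normalized, layout)
        assert mat.values.shape[1] == 6
        corrected = mat.corrected()
        signs = [1 if o == "forward" else -1
                 for o in layout.set_index("slide_id").loc[mat.values.columns, "orientation"]]
        assert np.allclose(
            corrected.to_numpy(), mat.values.to_numpy() * np.array(signs),
            equal_nan=True,
        )
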