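"""Fixel GLM, streamline connectivity, CFE enhancement and permutation FWE."""

import numpy as np
import pytest
import scipy.sparse as sp
import statsmodels.api as sm

from fixelpipe.cfe import (
    CfeParams, GlmDesign, build_connectivity, cfe_enhance,
    effect_size_percent, fit_fixel_glm, permutation_fwe,
)
from fixelpipe.errors import RankError
from fixelpipe.template import FixelTemplate


def toy_template(streamline_sets, n_fixels=4):
    """Minimal 4-fixel template with prescribed streamlines."""
    voxels = np.array([[i, 0, 0] for i in range(n_fixels)])
    dirs = np.tile([1.0, 0.0, 0.0], (n_fixels, 1))
    tracts = np.array(
        (["CGC_L"] * n_fixels), dtype=object)
    # fill remaining 19 labels with dummy single fixels so validation passes
    return FixelTemplate(
        grid_shape=(max(10, n_fixels), 4, 4), voxel_size_mm=1.0,
        voxels=voxels, directions=dirs, tracts=tracts,
        streamlines=[np.asarray(s, dtype=np.int64) for s in streamline_sets],
    )


class TestFixelGlm:
    def test_two_sample_t_closed_form(self):
        # y = (1,2,3,4), groups (0,0,1,1): pooled two-sample t = 2.828
        y = np.array([[1.0, 2.0, 3.0, 4.0]])
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        t = fit_fixel_glm(y, GlmDesign(X, np.array([0.0, 1.0])))
        assert t[0] == pytest.approx(2.8284271, abs=1e-6)

    def test_matches_statsmodels_ols(self, rng):
        n, F = 40, 12
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n),
                             rng.normal(size=n)])
        Y = rng.normal(size=(F, n))
        t = fit_fixel_glm(Y, GlmDesign(X, np.array([0.0, 1.0, 0.0])))
        for f in range(F):
            ref = sm.OLS(Y[f], X).fit()
            assert t[f] == pytest.approx(ref.tvalues[1], abs=1e-8)

    def test_null_t_centred_at_zero(self, rng):
        n = 30
        X = np.column_stack([np.ones(n),
                             np.repeat([0.0, 1.0], n // 2)])
        Y = rng.normal(size=(4000, n))
        t = fit_fixel_glm(Y, GlmDesign(X, np.array([0.0, 1.0])))
        assert abs(t.mean()) < 0.05
        assert t.std() == pytest.approx(np.sqrt((n - 2) / (n - 4)), abs=0.05)

    def test_zero_contrast_gives_zero_t(self, rng):
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        Y = rng.normal(size=(5, 10))
        t = fit_fixel_glm(Y, GlmDesign(X, np.zeros(2)))
        assert np.all(t == 0)

    def test_zero_residual_variance_sentinel(self):
        X = np.column_stack([np.ones(4), [0, 0, 1, 1.0]])
        Y = np.array([[1.0, 1.0, 2.0, 2.0]])  # exact fit
        with pytest.warns(UserWarning, match="zero residual"):
            t = fit_fixel_glm(Y, GlmDesign(X, np.array([0.0, 1.0])))
        assert np.isinf(t[0]) and t[0] > 0

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(RankError):
            GlmDesign(X, np.array([0.0, 1.0]))


class TestConnectivity:
    def test_always_cotraversed_fixels_fully_connected(self):
        tpl = toy_template([[0, 1], [0, 1], [0, 1]], n_fixels=2)
        c = build_connectivity(tpl).toarray()
        assert c[0, 1] == 1.0 and c[1, 0] == 1.0

    def test_disjoint_bundles_unconnected(self):
        tpl = toy_template([[0, 1], [2, 3]])
        c = build_connectivity(tpl).toarray()
        assert c[0, 2] == 0.0 and c[2, 0] == 0.0

    def test_hand_counted_ratios(self):
        # streamlines {0,1,2}, {0,1}, {1,3}: c_01 = 2/2, c_10 = 2/3,
        # c_13 = 1/3, c_31 = 1/1, c_03 = 0
        tpl = toy_template([[0, 1, 2], [0, 1], [1, 3]])
        c = build_connectivity(tpl).toarray()
        assert c[0, 1] == pytest.approx(1.0)
        assert c[1, 0] == pytest.approx(2 / 3)
        assert c[1, 3] == pytest.approx(1 / 3)
        assert c[3, 1] == pytest.approx(1.0)
        assert c[0, 3] == 0.0
        assert np.all(np.diag(c) == 1.0)

    def test_orphan_fixel_warns_and_self_connects(self):
        tpl = toy_template([[0, 1]])
        with pytest.warns(UserWarning, match="no streamline"):
            c = build_connectivity(tpl).toarray()
        assert c[3, 3] == 1.0 and c[3, :3].sum() == 0.0


class TestEnhance:
    def test_isolated_fixel_direct_summation(self):
        # e = sum_{h=0.1..1.0} 0.1 * h^3 * 1 = 0.3025
        conn = sp.identity(1, format="csr")
        params = CfeParams(dh=0.1, H=3.0, E=2.0, C=0.5, n_permutations=1)
        e = cfe_enhance(np.array([1.0]), conn, params)
        assert e[0] == pytest.approx(0.3025, abs=1e-12)

    def test_nonpositive_t_enhances_to_zero(self):
        conn = sp.identity(5, format="csr")
        e = cfe_enhance(np.array([-1.0, 0.0, -0.5, -3.0, 0.0]), conn,
                        CfeParams())
        assert np.all(e == 0)

    def test_monotone_in_t(self, rng):
        tpl = toy_template([[0, 1, 2], [1, 2, 3], [0, 3]])
        conn = build_connectivity(tpl)
        params = CfeParams()
        t = rng.uniform(0.0, 3.0, 4)
        e = cfe_enhance(t, conn, params)
        for j in range(4):
            t2 = t.copy()
            t2[j] += 0.5
            e2 = cfe_enhance(t2, conn, params)
            assert np.all(e2 >= e - 1e-12)

    def test_identity_connectivity_reduces_to_thresholded_t(self, rng):
        # with c = I, E = 1, H = 0: e = dh * floor(t/dh) ~ t
        conn = sp.identity(6, format="csr")
        params = CfeParams(dh=0.01, E=1.0, H=0.0)
        t = rng.uniform(0.5, 4.0, 6)
        e = cfe_enhance(t, conn, params)
        assert np.allclose(e, params.dh * np.floor(t / params.dh + 1e-9),
                           atol=1e-9)
        assert np.allclose(e, t, atol=params.dh)

    def test_batched_matches_single(self, rng):
        tpl = toy_template([[0, 1, 2], [1, 2, 3], [0, 3]])
        conn = build_connectivity(tpl)
        params = CfeParams()
        T = rng.uniform(-1, 4, (7, 4))
        batched = cfe_enhance(T, conn, params)
        for b in range(7):
            assert np.allclose(batched[b], cfe_enhance(T[b], conn, params))

    def test_wider_support_raises_enhancement(self):
        params = CfeParams()
        t = np.array([2.0, 2.0, 2.0, 2.0])
        sparse_conn = sp.identity(4, format="csr")
        dense_conn = sp.csr_matrix(np.full((4, 4), 1.0))
        e_sparse = cfe_enhance(t, sparse_conn, params)
        e_dense = cfe_enhance(t, dense_conn, params)
        assert np.all(e_dense >= e_sparse)


class TestPermutationFwe:
    def _setup(self, rng, n=16, F=4, effect=0.0):
        tpl = toy_template([[0, 1, 2], [1, 2, 3], [0, 3]])
        group = np.repeat([0.0, 1.0], n // 2)
        X = np.column_stack([np.ones(n), group, rng.normal(size=n)])
        design = GlmDesign(X, np.array([0.0, 1.0, 0.0]))
        Y = rng.normal(size=(F, n)) + effect * group[None, :]
        return tpl, design, Y

    def test_deterministic_given_seed(self, rng):
        tpl, design, Y = self._setup(rng)
        params = CfeParams(n_permutations=50, seed=9)
        r1 = permutation_fwe(Y, design, tpl, params)
        r2 = permutation_fwe(Y, design, tpl, params)
        assert np.array_equal(r1.p_fwe, r2.p_fwe)
        assert np.array_equal(r1.max_null, r2.max_null)

    def test_minimum_p_is_counting_convention(self, rng):
        tpl, design, Y = self._setup(rng, effect=50.0)
        params = CfeParams(n_permutations=99, seed=3)
        res = permutation_fwe(Y, design, tpl, params)
        # huge effect: observed e above every permutation max
        assert res.p_fwe.min() == pytest.approx(1 / 100)

    def test_exhaustive_enumeration_when_requested_too_many(self, rng):
        tpl = toy_template([[0, 1, 2], [1, 2, 3], [0, 3]])
        n = 5
        X = np.column_stack([np.ones(n), [0, 0, 1, 1, 1.0]])
        design = GlmDesign(X, np.array([0.0, 1.0]))
        Y = rng.normal(size=(4, n))
        with pytest.warns(UserWarning, match="exhaustiv"):
            res = permutation_fwe(Y, design, tpl,
                                  CfeParams(n_permutations=10000, seed=0))
        assert res.exhaustive and res.n_permutations == 120

    def test_pvalues_in_unit_interval(self, rng):
        tpl, design, Y = self._setup(rng)
        res = permutation_fwe(Y, design, tpl,
                              CfeParams(n_permutations=60, seed=1))
        assert np.all(res.p_fwe > 0) and np.all(res.p_fwe <= 1)
        assert np.all(res.enhanced >= 0)
        assert np.all(res.enhanced[res.t <= 0] == 0)


class TestEffectSize:
    @pytest.mark.parametrize("g,c,expected", [
        (0.45, 0.50, 10.0), (0.50, 0.50, 0.0),
    ])
    def test_percent_decrease(self, g, c, expected):
        assert effect_size_percent(g, c) == pytest.approx(expected)

    def test_vector_case_elementwise(self, rng):
        g = rng.uniform(0.3, 0.6, 20)
        c = rng.uniform(0.4, 0.7, 20)
        out = effect_size_percent(g, c)
        assert np.allclose(out, [100 * (ci - gi) / ci
                                 for gi, ci in zip(g, c)])

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            effect_size_percent(0.4, 0.0)
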