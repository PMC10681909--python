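import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from regnomics import differential_stats as ds
from regnomics import synthetic_data as sd
from regnomics.errors import ConfigError, InputError
from regnomics.io_formats import ExpressionMatrix


def _matrix(counts, mito=None, doublet=None):
    counts = np.asarray(counts)
    g, c = counts.shape
    meta = pd.DataFrame(
        {
            "condition": ["a"] * c,
            "cluster": ["c0"] * c,
            "mito_fraction": mito if mito is not None else np.zeros(c),
            "doublet_score": doublet if doublet is not None else np.zeros(c),
        },
        index=pd.Index([f"cell{i}" for i in range(c)], name="cell_id"),
    )
    return ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=[f"g{i}" for i in range(g)],
        cell_ids=[f"cell{i}" for i in range(c)],
        metadata=meta,
    )


class TestQCFilter:
    def test_all_pass(self):
        m = _matrix(np.full((2, 4), 500))
        kept, report = ds.qc_filter_cells(m)
        assert kept.n_cells == 4
        assert report["removed"] == {
            "min_umi": 0, "max_umi": 0, "mito": 0, "doublet": 0,
        }

    def test_boundary_499_removed(self):
        counts = np.full((1, 3), 500)
        counts[0, 1] = 499
        kept, report = ds.qc_filter_cells(_matrix(counts))
        assert kept.cell_ids == ["cell0", "cell2"]
        assert report["removed"]["min_umi"] == 1

    def test_boundary_exact_cutoffs_retained(self):
        # 500 and 25000 UMI, mito exactly 0.005, doublet exactly 0.0025 pass
        counts = np.array([[500, 25000]])
        m = _matrix(counts, mito=[0.005, 0.005], doublet=[0.0025, 0.0025])
        kept, _ = ds.qc_filter_cells(m)
        assert kept.n_cells == 2

    def test_first_failing_rule_attribution(self):
        counts = np.array([[499, 26000, 1000, 1000]])
        m = _matrix(counts, mito=[0.9, 0.9, 0.9, 0.0], doublet=[0.9, 0.9, 0.9, 0.9])
        _, report = ds.qc_filter_cells(m)
        assert report["removed"] == {
            "min_umi": 1, "max_umi": 1, "mito": 1, "doublet": 1,
        }

    def test_missing_column_named(self):
        m = _matrix(np.ones((1, 3)))
        m.metadata = m.metadata.drop(columns=["mito_fraction"])
        with pytest.raises(InputError, match="mito_fraction"):
            ds.qc_filter_cells(m)

    def test_matches_per_cell_predicate_loop(self, expression):
        matrix, _ = expression
        params = ds.QCParams()
        kept, report = ds.qc_filter_cells(matrix, params)
        survivors = 0
        for cid in matrix.cell_ids:
            row = matrix.metadata.loc[cid]
            if (
                params.min_umi <= row["umi_total"] <= params.max_umi
                and row["mito_fraction"] <= params.max_mito_fraction
                and row["doublet_score"] <= params.max_doublet_score
            ):
                survivors += 1
        assert kept.n_cells == survivors
        assert report["n_retained"] + sum(report["removed"].values()) == report["n_input"]

    def test_invalid_params(self):
        with pytest.raises(ConfigError):
            ds.QCParams(min_umi=100, max_umi=50)


class TestQCFilterNuclei:
    def test_thresholds(self):
        t = pd.DataFrame(
            {
                "frip": [0.2, 0.14, 0.2, 0.2],
                "fragments": [50_000, 50_000, 29_999, 1_500_001],
            }
        )
        kept, report = ds.qc_filter_nuclei(t)
        assert len(kept) == 1
        assert report["removed"] == {
            "frip": 1, "min_fragments": 1, "max_fragments": 1,
        }


class TestNormalize:
    def test_zero_stays_zero(self):
        norm = ds.normalize_log(_matrix([[0, 1], [1, 1]]))
        assert norm.values[0, 0] == 0.0

    def test_closed_form_single_cell(self):
        norm = ds.normalize_log(_matrix([[9], [1]]), scale=10)
        np.testing.assert_allclose(
            np.asarray(norm.values.todense()).ravel(),
            [np.log(10), np.log(2)],
        )

    def test_brute_force_5x4(self, rng):
        counts = rng.integers(0, 20, size=(5, 4))
        counts[:, 0] += 1  # no zero-total cell
        scale = 1e4
        norm = ds.normalize_log(_matrix(counts), scale=scale)
        totals = counts.sum(axis=0)
        expected = np.log1p(counts * scale / totals)
        np.testing.assert_allclose(
            np.asarray(norm.values.todense()), expected, atol=1e-12
        )

    def test_zero_total_cell_rejected(self):
        with pytest.raises(InputError, match="zero total"):
            ds.normalize_log(_matrix([[1, 0], [1, 0]]))


class TestBHAdjust:
    def test_closed_form(self):
        np.testing.assert_allclose(
            ds.bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ds.bh_adjust(np.array([0.4])), [0.4])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            ds.bh_adjust(np.array([1.5]))

    @staticmethod
    def brute_force(p):
        m = len(p)
        order = np.argsort(p, kind="stable")
        rank_of = np.empty(m, dtype=int)
        rank_of[order] = np.arange(1, m + 1)
        out = np.empty(m)
        for i in range(m):
            candidates = [
                m * p[j] / rank_of[j] for j in range(m) if rank_of[j] >= rank_of[i]
            ]
            out[i] = min(1.0, min(candidates))
        return out

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=1,
            max_size=25,
        )
    )
    def test_matches_brute_force_definition(self, pvals):
        p = np.array(pvals)
        np.testing.assert_allclose(ds.bh_adjust(p), self.brute_force(p), atol=1e-12)


class TestFindMarkers:
    def _norm(self, x1, x2):
        x = np.concatenate([x1, x2], axis=1)
        g, c = x.shape
        return (
            ds.NormalizedMatrix(
                values=sp.csr_matrix(x),
                gene_ids=[f"g{i}" for i in range(g)],
                cell_ids=[f"c{i}" for i in range(c)],
                metadata=pd.DataFrame(index=[f"c{i}" for i in range(c)]),
                scale=1e4,
            ),
            np.arange(x1.shape[1]),
            np.arange(x1.shape[1], c),
        )

    def test_identical_groups_p1_logfc0(self):
        block = np.tile([[1.0, 2.0, 3.0]], (2, 1))
        norm, g1, g2 = self._norm(block, block)
        res = ds.find_markers(norm, g1, g2, min_pct=0.01, logfc_threshold=0.0)
        np.testing.assert_allclose(res["log2_fold_change"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p_value"], 1.0)

    def test_silent_gene_not_tested(self):
        x1 = np.array([[0.0, 0, 0], [1, 2, 3]])
        x2 = np.array([[0.0, 0, 0], [4, 5, 6]])
        norm, g1, g2 = self._norm(x1, x2)
        res = ds.find_markers(norm, g1, g2, min_pct=0.01, logfc_threshold=0.0)
        assert not res.loc[0, "tested"]
        assert res.loc[0, "p_value"] == 1.0
        assert np.isnan(res.loc[0, "adjusted_p"])

    def test_logfc_formula(self, rng):
        x1 = rng.random((3, 5)) * 2
        x2 = rng.random((3, 6))
        norm, g1, g2 = self._norm(np.concatenate([x1], axis=1), x2)
        res = ds.find_markers(norm, g1, g2, min_pct=0.0, logfc_threshold=0.0)
        expected = np.log2(
            (np.expm1(x1).mean(axis=1) + 1) / (np.expm1(x2).mean(axis=1) + 1)
        )
        np.testing.assert_allclose(res["log2_fold_change"], expected, atol=1e-12)

    def test_matches_exact_permutation_oracle_n10(self, rng):
        n = 10
        x1 = rng.normal(0.8, 1.0, size=(1, n))
        x2 = rng.normal(0.0, 1.0, size=(1, n))
        norm, g1, g2 = self._norm(x1, x2)
        res = ds.find_markers(norm, g1, g2, min_pct=0.0, logfc_threshold=0.0)
        p_approx = res.loc[0, "p_value"]

        # exact permutation oracle: all C(20,10) group assignments
        pooled = np.concatenate([x1.ravel(), x2.ravel()])
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        obs = ranks[:n].sum()
        mu = n * (2 * n + 1) / 2.0
        combos = np.array(
            list(itertools.combinations(range(2 * n), n)), dtype=int
        )
        sums = ranks[combos].sum(axis=1)
        p_exact = (np.abs(sums - mu) >= abs(obs - mu) - 1e-12).mean()
        assert abs(p_approx - p_exact) <= 0.1 * p_exact

    def test_invariant_to_gene_and_cell_order(self, rng):
        x1 = rng.random((6, 8))
        x2 = rng.random((6, 9)) * 1.5
        norm, g1, g2 = self._norm(x1, x2)
        res = ds.find_markers(norm, g1, g2, min_pct=0.0, logfc_threshold=0.0)

        gperm = rng.permutation(6)
        cperm1 = rng.permutation(8)
        cperm2 = rng.permutation(9)
        norm2, _, _ = self._norm(x1[np.ix_(gperm, cperm1)], x2[np.ix_(gperm, cperm2)])
        res2 = ds.find_markers(norm2, g1, g2, min_pct=0.0, logfc_threshold=0.0)
        back = res2.set_index("gene_id").loc[
            [f"g{i}" for i in np.argsort(gperm)]
        ]
        np.testing.assert_allclose(
            res["p_value"].to_numpy(), back["p_value"].to_numpy(), atol=1e-12
        )

    def test_empty_group_rejected(self, rng):
        norm, g1, _ = self._norm(rng.random((2, 4)), rng.random((2, 4)))
        with pytest.raises(InputError):
            ds.find_markers(norm, g1, np.array([], dtype=int))


class TestCompositionTest:
    @staticmethod
    def _meta(cluster, condition):
        return pd.DataFrame({"cluster": cluster, "condition": condition})

    def test_identical_composition_zero_logfd(self):
        meta = self._meta(
            ["a", "a", "b", "b"] * 2, ["x"] * 4 + ["y"] * 4
        )
        res = ds.composition_test(meta, n_perm=50, seed=0)
        np.testing.assert_allclose(res["log2_fold_difference"], 0.0, atol=1e-12)

    def test_closed_form_8pct_vs_2pct(self):
        # 8% vs 2% with eps -> 0: log2FD -> 2; with eps = 1/n it is close
        n = 2000
        c1 = ["k"] * 80 + ["other"] * 920
        c2 = ["k"] * 20 + ["other"] * 980
        meta = self._meta(c1 + c2, ["x"] * 1000 + ["y"] * 1000)
        res = ds.composition_test(meta, n_perm=10, seed=0)
        obs = res.set_index("cluster").loc["k", "log2_fold_difference"]
        eps = 1.0 / n
        assert obs == pytest.approx(np.log2((0.08 + eps) / (0.02 + eps)))
        assert obs == pytest.approx(2.0, abs=0.05)

    def test_three_conditions_rejected(self):
        meta = self._meta(["a"] * 3, ["x", "y", "z"])
        with pytest.raises(InputError, match="2 conditions"):
            ds.composition_test(meta, n_perm=10)

    def test_p_in_unit_interval_and_reproducible(self, rng):
        meta = self._meta(
            rng.choice(["a", "b", "c"], size=300),
            rng.choice(["x", "y"], size=300),
        )
        r1 = ds.composition_test(meta, n_perm=200, seed=5)
        r2 = ds.composition_test(meta, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(r1, r2)
        assert ((r1["permutation_p"] > 0) & (r1["permutation_p"] <= 1)).all()

    def test_null_type_i_error_calibrated(self):
        # reduced-size calibration; the full version runs in acceptance
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(60):
            meta = self._meta(
                rng.choice(["a", "b", "c", "d"], size=400),
                rng.choice(["x", "y"], size=400),
            )
            res = ds.composition_test(meta, n_perm=150, seed=int(rng.integers(1 << 31)))
            pvals.extend(res["permutation_p"])
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert frac < 0.10
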