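import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse
from scipy import stats

from scanact.core_io import CellTable, ExpressionPanel
from scanact.gate_pairs import (
    INF,
    andnot_norm,
    inhibitor_pool,
    n_norm,
    normal_coexpression_N,
    or_mod_and,
    or_mod_andnot,
    ts_and,
    ts_and_not,
    ts_and_not_raw,
    tumor_coexpression,
)


def zpanel(rows: dict, columns):
    return ExpressionPanel(
        pd.DataFrame(rows, index=columns).T, unit="zscore"
    )


def panel_from_patterns(pa, pb, names=("a", "b")):
    """High/low boolean patterns -> z-values 2.0 / 0.0."""
    cols = [f"t{i}" for i in range(len(pa))]
    return zpanel(
        {names[0]: [2.0 if x else 0.0 for x in pa],
         names[1]: [2.0 if x else 0.0 for x in pb]},
        cols,
    )


def oracle_or_and(pa, pb):
    d = sum(x and y for x, y in zip(pa, pb))
    b = sum(x and not y for x, y in zip(pa, pb))
    c = sum(y and not x for x, y in zip(pa, pb))
    if d == 0 and b * c == 0:
        return 0.0
    if b * c == 0:
        return INF
    return d / (b * c)


def oracle_or_andnot(pa, pb):
    d = sum(x and y for x, y in zip(pa, pb))
    b = sum(x and not y for x, y in zip(pa, pb))
    return INF if b == 0 else d / b


class TestOrMod:
    @pytest.mark.parametrize(
        "pa,pb,expected",
        [
            # d=0, b=2, c=3 -> 0
            ([1, 1, 0, 0, 0], [0, 0, 1, 1, 1], 0.0),
            # d=0, b=0, c=0 -> 0 by the stated rule
            ([0, 0], [0, 0], 0.0),
            # d=2, b=1, c=1 -> 2
            ([1, 1, 1, 0], [1, 1, 0, 1], 2.0),
        ],
    )
    def test_and_examples(self, pa, pb, expected):
        assert or_mod_and(panel_from_patterns(pa, pb), "a", "b") == expected

    @pytest.mark.parametrize(
        "pa,pb,expected",
        [
            ([0, 0], [0, 0], INF),  # d=0, b=0
            ([1, 1, 1], [1, 1, 1], INF),  # d=3, b=0
            ([1, 1, 0], [0, 0, 0], 0.0),  # d=0, b=2
        ],
    )
    def test_andnot_examples(self, pa, pb, expected):
        assert or_mod_andnot(panel_from_patterns(pa, pb), "a", "b") == expected

    def test_exhaustive_against_enumeration_small_k(self):
        for k in (2, 3, 4):
            for pa in itertools.product([0, 1], repeat=k):
                for pb in itertools.product([0, 1], repeat=k):
                    panel = panel_from_patterns(pa, pb)
                    assert or_mod_and(panel, "a", "b") == oracle_or_and(pa, pb)
                    assert or_mod_andnot(panel, "a", "b") == oracle_or_andnot(pa, pb)

    def test_all_patterns_at_k8_against_enumeration(self):
        # every 8-column pattern for gene a, crossed with shifts and the
        # complement of gene b's pattern
        for pa in itertools.product([0, 1], repeat=8):
            partners = [pa[i:] + pa[:i] for i in (1, 3)] + [
                tuple(1 - x for x in pa)
            ]
            for pb in partners:
                panel = panel_from_patterns(pa, pb)
                assert or_mod_and(panel, "a", "b") == oracle_or_and(pa, pb)
                assert or_mod_andnot(panel, "a", "b") == oracle_or_andnot(pa, pb)


def _bh(pvals):
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        prev = min(prev, p[i] * n / (rank_idx + 1))
        adj[i] = prev
    return adj


def oracle_raw_n(pairs, panels, weights, alpha=0.05):
    """Independent recomputation of the raw co-expression score N."""
    total = {p: 0.0 for p in pairs}
    for tag, (kind, w) in weights.items():
        z = panels[tag].values
        if kind == "corr":
            stats_ = []
            for a, b in pairs:
                r, p = stats.pearsonr(z.loc[a], z.loc[b])
                stats_.append((r, p))
            adj = _bh([p for _, p in stats_])
            for (a, b), (r, _), q in zip(pairs, stats_, adj):
                if q < alpha:
                    total[(a, b)] += w if r < 0 else -w
        else:
            for a, b in pairs:
                om = oracle_or_and(z.loc[a] > 1, z.loc[b] > 1)
                total[(a, b)] += w if om == 0 else -w
    return total


def make_pair_panels(seed=0, n_pairs=6):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(2 * n_pairs)]
    pairs = [(genes[2 * i], genes[2 * i + 1]) for i in range(n_pairs)]
    panels = {}
    for tag, ncols in (
        ("hpa_rna", 8),
        ("gtex_rna", 8),
        ("hpa_ihc", 6),
        ("hpm", 6),
        ("sc", 8),
        ("gtex_prot", 8),
    ):
        vals = rng.normal(0, 1, size=(len(genes), ncols))
        panels[tag] = ExpressionPanel(
            pd.DataFrame(
                vals, index=genes, columns=[f"{tag}{j}" for j in range(ncols)]
            ),
            unit="zscore",
        )
    return pairs, panels


class TestNormalCoexpression:
    def _panels(self, seed=0, n_pairs=6):
        return make_pair_panels(seed, n_pairs)

    def test_raw_n_matches_independent_oracle(self):
        from scanact.gate_pairs import NORMAL_DATASETS

        for seed in range(3):
            pairs, panels = self._panels(seed)
            got = normal_coexpression_N(pairs, panels)
            want = oracle_raw_n(pairs, panels, NORMAL_DATASETS)
            for p in pairs:
                assert got[p] == pytest.approx(want[p])

    def test_absent_genes_contribute_zero(self):
        pairs, panels = self._panels()
        ghost_pairs = [("nope1", "nope2")]
        raw = normal_coexpression_N(ghost_pairs, panels)
        # odds-ratio datasets skip absent genes; correlations too
        assert raw[("nope1", "nope2")] == 0.0

    def test_n_norm_endpoints(self):
        raw = pd.Series(
            [0.0, 5.0, 9.5],
            index=pd.MultiIndex.from_tuples([("a", "b"), ("c", "d"), ("e", "f")]),
        )
        norm = n_norm(raw)
        assert norm[("a", "b")] == 1.0  # pool minimum
        assert norm[("e", "f")] == -1.0  # pool maximum

    def test_degenerate_pool_warns_and_zeroes(self):
        raw = pd.Series(
            [2.0, 2.0], index=pd.MultiIndex.from_tuples([("a", "b"), ("c", "d")])
        )
        with pytest.warns(UserWarning):
            assert (n_norm(raw) == 0).all()


class TestTSAnd:
    def test_formula_and_selection(self):
        rho = pd.Series(
            [0.8, 0.0, 1.0],
            index=pd.MultiIndex.from_tuples([("a", "b"), ("c", "d"), ("e", "f")]),
        )
        nn = pd.Series([-0.5, 0.0, -1.0], index=rho.index)
        out = ts_and(rho, nn)
        assert out["ts"].tolist() == pytest.approx([1.3, 0.0, 2.0])
        assert out["selected"].tolist() == [True, False, True]

    def test_swap_symmetry(self):
        pairs, panels = TestNormalCoexpression()._panels(seed=4)
        fwd = normal_coexpression_N(pairs, panels)
        rev = normal_coexpression_N([(b, a) for a, b in pairs], panels)
        for (a, b) in pairs:
            assert fwd[(a, b)] == pytest.approx(rev[(b, a)])


class TestTSAndNot:
    def test_maximal_raw_score_is_19(self):
        # every dataset rewards, with the inhibitor at or above the
        # activator in every column: raw = (1+1+2+2+1.5+2) * 2 = 19
        cols8 = [f"t{i}" for i in range(8)]
        pattern = np.linspace(-2, 2, 8)
        panels = {}
        for tag in ("hpa_rna", "gtex_rna", "sc", "gtex_prot"):
            panels[tag] = zpanel(
                {"act": pattern, "inh": pattern + 0.5}, cols8
            )
        for tag in ("hpa_ihc", "hpm"):
            panels[tag] = zpanel(
                {"act": pattern, "inh": pattern + 0.5}, cols8
            )
        raw = ts_and_not_raw([("act", "inh")], panels)
        assert raw[("act", "inh")] == pytest.approx(19.0)

    def test_not_swap_symmetric(self):
        cols = [f"t{i}" for i in range(8)]
        pattern = np.linspace(-2, 2, 8)
        panels = {
            tag: zpanel({"act": pattern, "inh": pattern + 0.5}, cols)
            for tag in ("hpa_rna", "gtex_rna", "hpa_ihc", "hpm", "sc", "gtex_prot")
        }
        fwd = ts_and_not_raw([("act", "inh")], panels)[("act", "inh")]
        rev = ts_and_not_raw([("inh", "act")], panels)[("inh", "act")]
        assert fwd != rev

    def test_missing_dataset_contributes_zero(self):
        raw = ts_and_not_raw([("x", "y")], {})
        assert raw[("x", "y")] == 0.0

    def test_norm_endpoints_no_sign_flip(self):
        raw = pd.Series(
            [-4.0, 0.0, 19.0],
            index=pd.MultiIndex.from_tuples([("a", "b"), ("c", "d"), ("e", "f")]),
        )
        norm = andnot_norm(raw)
        assert norm[("a", "b")] == -1.0
        assert norm[("e", "f")] == 1.0


class TestTumorCoexpression:
    def _cells(self, counts, genes):
        cells = [f"c{j}" for j in range(counts.shape[1])]
        return CellTable(
            sample_id="s",
            genes=genes,
            cells=cells,
            counts=scipy.sparse.csr_matrix(counts),
            labels=pd.Series(["tumor"] * len(cells), index=cells),
        )

    def test_self_pair_is_one(self):
        rng = np.random.default_rng(0)
        genes = ["a", "b"]
        table = self._cells(rng.poisson(5, size=(2, 30)), genes)
        rho = tumor_coexpression(table, genes, pairs=[("a", "a"), ("a", "b")])
        assert rho[("a", "a")] == 1.0

    def test_independent_genes_mostly_zeroed_under_null(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(20)]
        table = self._cells(rng.poisson(8, size=(20, 500)), genes)
        rho = tumor_coexpression(table, genes)
        assert (rho == 0).mean() >= 0.95

    def test_planted_pair_retained(self, cohort, layout):
        mask = (cohort.truth == "tumor").to_numpy()
        pair = layout.and_planted_pairs[0]
        rho = tumor_coexpression(
            cohort.cells, list(pair), tumor_mask=mask, pairs=[pair]
        )
        assert rho[pair] > 0

    def test_too_few_cells_rejected(self):
        table = self._cells(np.ones((2, 10)), ["a", "b"])
        with pytest.raises(ValueError, match="20"):
            tumor_coexpression(table, ["a", "b"])


class TestInhibitorPool:
    def test_strict_below_median_and_surfaceome_only(self):
        sc = pd.Series({"a": 0.0, "b": 1.0, "c": 2.0, "d": 3.0, "x": 0.0})
        pool = inhibitor_pool(["a", "b", "c", "d", "x"], {"a", "b", "c", "d"}, sc)
        # median of (0,1,2,3) is 1.5; strictly below keeps a, b; x is not
        # in the surfaceome
        assert pool == ["a", "b"]

    def test_empty_down_set_errors(self):
        with pytest.raises(ValueError):
            inhibitor_pool([], {"a"}, pd.Series(dtype=float))


def test_planted_and_pairs_recovered(cohort, panels, layout):
    """All planted tumor-co-expressed, normal-mutually-exclusive pairs are
    selected and no decoy pair is."""
    mask = (cohort.truth == "tumor").to_numpy()
    pairs = layout.and_pairs
    rho = tumor_coexpression(cohort.cells, layout.and_pool, tumor_mask=mask, pairs=pairs)
    raw = normal_coexpression_N(pairs, panels.z_panels)
    scores = ts_and(rho, n_norm(raw))
    planted = set(layout.and_planted_pairs)
    for p in planted:
        assert scores.loc[p, "selected"], p
    decoys = scores.drop(index=list(planted))
    assert not decoys["selected"].any()


def test_planted_andnot_pairs_top_percentile(panels, layout):
    """Planted activator-shadowing pairs occupy the top 1% of the
    normalized score pool."""
    out = ts_and_not(layout.andnot_pairs, panels.z_panels)
    assert set(out[out["selected"]].index) == set(layout.andnot_planted)
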