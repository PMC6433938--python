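"""CPM filtering, the two-group DE stand-in, Kruskal-Wallis + Dunn,
density correlations and GC content."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sigse.expression_stats import (
    cpm_filter,
    density_correlation,
    flag_de_table,
    gc_content,
    kruskal_dunn,
    simple_de,
)


class TestCpmFilter:
    def _toy(self):
        # 6-gene toy matrix; libraries of 1e6 so CPM == counts
        return pd.DataFrame(
            {
                "s1": [1, 0, 10, 0, 999989, 0],
                "s2": [1, 0, 0, 1, 999998, 0],
                "s3": [1, 0, 0, 0, 999999, 0],
            },
            index=[f"g{i}" for i in range(6)],
        )

    def test_hand_computed_retention(self):
        counts = self._toy()
        retained, cpm_mat = cpm_filter(counts, threshold=0.5, min_samples=2)
        # g0: CPM 1 in all three samples -> kept; g2/g3: above threshold in
        # only one sample -> dropped; g1/g5 all-zero -> dropped; g4 kept
        assert retained == ["g0", "g4"]
        assert np.allclose(cpm_mat.loc["g0"], [1, 1, 1])

    def test_cpm_columns_sum_to_million(self):
        from sigse.expression_stats import cpm

        counts = self._toy()
        assert np.allclose(cpm(counts).sum(axis=0), 1e6)

    def test_zero_total_sample_error_names_it(self):
        counts = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            cpm_filter(counts)


class TestSimpleDe:
    def _cpm(self, a, b, genes=("g1", "g2")):
        cols = {}
        for i in range(3):
            cols[f"t{i}"] = [row[i] for row in a]
            cols[f"r{i}"] = [row[i] for row in b]
        return pd.DataFrame(cols, index=list(genes))

    def test_identical_groups_zero_lfc(self):
        mat = self._cpm([[10, 10, 10], [5, 5, 5]], [[10, 10, 10], [5, 5, 5]])
        groups = {c: ("T" if c.startswith("t") else "R") for c in mat.columns}
        recs = simple_de(mat, groups, ("T", "R"))
        assert all(r.log2fc == 0 for r in recs)

    def test_planted_fourfold_change_recovered(self):
        rng = np.random.default_rng(8)
        treated = 400 * 2 ** rng.normal(0, 0.01, size=(1, 3))
        reference = 100 * 2 ** rng.normal(0, 0.01, size=(1, 3))
        mat = self._cpm(treated.tolist(), reference.tolist(), genes=("g",))
        groups = {c: ("T" if c.startswith("t") else "R") for c in mat.columns}
        [rec] = simple_de(mat, groups, ("T", "R"))
        assert rec.log2fc == pytest.approx(2.0, abs=0.1)
        assert rec.significant

    def test_label_swap_negates_lfc(self):
        rng = np.random.default_rng(12)
        mat = pd.DataFrame(
            rng.uniform(1, 100, size=(20, 6)),
            columns=[f"t{i}" for i in range(3)] + [f"r{i}" for i in range(3)],
            index=[f"g{i}" for i in range(20)],
        )
        groups = {c: ("T" if c.startswith("t") else "R") for c in mat.columns}
        fwd = simple_de(mat, groups, ("T", "R"))
        rev = simple_de(mat, groups, ("R", "T"))
        assert np.allclose([r.log2fc for r in fwd], [-r.log2fc for r in rev])

    def test_flags_recomputed_from_thresholds(self):
        table = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "log2fc": [1.5, 0.5, -2.0, 1.5],
                "ave_expr": [6.0, 6.0, 4.0, 5.0],
                "p_value": [0.01, 0.01, 0.04, 0.2],
            }
        )
        out = flag_de_table(table)
        assert list(out["significant"]) == [True, False, True, False]
        assert list(out["highly_expressed"]) == [True, True, False, False]


def _dunn_oracle(groups):
    """Independently coded rank-based oracle for Kruskal-Wallis + Dunn."""
    labels = list(groups)
    values = []
    owners = []
    for k in labels:
        for v in groups[k]:
            values.append(float(v))
            owners.append(k)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = np.asarray(values)[order]
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2  # average rank, 1-based
        i = j
    n = len(values)
    mean_rank = {k: np.mean([ranks[i] for i in range(n) if owners[i] == k]) for k in labels}
    sizes = {k: sum(1 for o in owners if o == k) for k in labels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    var = n * (n + 1) / 12 - tie_sum / (12 * (n - 1))
    pairs = {}
    m = len(labels) * (len(labels) - 1) // 2
    for a, b in combinations(labels, 2):
        z = (mean_rank[a] - mean_rank[b]) / np.sqrt(var * (1 / sizes[a] + 1 / sizes[b]))
        p = 2 * stats.norm.sf(abs(z))
        pairs[(a, b)] = (z, min(1.0, p * m))
    return pairs


class TestKruskalDunn:
    def test_frozen_hand_computed_example(self):
        # ranks 1..9 split 3/3/3: mean ranks 2, 5, 8; H = 7.2;
        # Dunn z(A,B) = (2-5)/sqrt(7.5*(2/3)) = -1.3416; z(A,C) = -2.6833
        comp = kruskal_dunn({"A": [1, 2, 3], "B": [4, 5, 6], "C": [7, 8, 9]})
        assert comp.kw_stat == pytest.approx(7.2)
        assert comp.pairwise[("A", "B")][0] == pytest.approx(-1.3416407, abs=1e-6)
        assert comp.pairwise[("A", "C")][0] == pytest.approx(-2.6832816, abs=1e-6)

    def test_identical_groups_adjusted_p_one(self):
        comp = kruskal_dunn({"A": [2, 2, 2], "B": [2, 2, 2]})
        assert comp.kw_p == 1.0
        assert comp.pairwise[("A", "B")][2] == 1.0

    def test_matches_independent_oracle_with_ties(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            groups = {
                k: rng.integers(0, 8, size=int(rng.integers(3, 10))).tolist()
                for k in ("A", "B", "C")
            }
            if len({v for vs in groups.values() for v in vs}) == 1:
                continue
            comp = kruskal_dunn(groups)
            oracle = _dunn_oracle(groups)
            for pair, (z, p_adj) in oracle.items():
                assert comp.pairwise[pair][0] == pytest.approx(z, abs=1e-10)
                assert comp.pairwise[pair][2] == pytest.approx(p_adj, abs=1e-10)
            # omnibus H agrees with scipy's tie-corrected statistic
            h, p = stats.kruskal(*groups.values())
            assert comp.kw_stat == pytest.approx(h)
            assert comp.kw_p == pytest.approx(p)

    def test_within_group_permutation_invariance(self):
        groups = {"A": [3, 1, 4, 1], "B": [5, 9, 2, 6]}
        shuffled = {"A": [1, 4, 1, 3], "B": [9, 6, 5, 2]}
        a, b = kruskal_dunn(groups), kruskal_dunn(shuffled)
        assert a.kw_stat == b.kw_stat
        assert a.pairwise[("A", "B")][0] == b.pairwise[("A", "B")][0]


class TestDensityCorrelation:
    def test_exact_linear_relation(self):
        x = [1.0, 2.0, 4.0, 8.0, 16.0]
        df = density_correlation([("lab", x, [2 * v for v in x])])
        assert df.loc[0, "r"] == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(21)
        x, y = rng.uniform(0.1, 50, 30), rng.uniform(0.1, 50, 30)
        r_xy = density_correlation([("a", x, y)]).loc[0, "r"]
        r_yx = density_correlation([("a", y, x)]).loc[0, "r"]
        assert r_xy == pytest.approx(r_yx)

    def test_zero_variance_flagged(self):
        df = density_correlation([("flat", [1.0, 1.0, 1.0], [1.0, 2.0, 3.0])])
        assert not df.loc[0, "defined"]

    def test_zero_densities_floored_not_infinite(self):
        df = density_correlation([("z", [0.0, 1.0, 2.0, 4.0], [0.0, 2.0, 4.0, 8.0])])
        assert np.isfinite(df.loc[0, "r"])

    def test_bonferroni_column(self):
        rng = np.random.default_rng(22)
        pairs = [
            (f"p{i}", rng.uniform(0.1, 5, 20), rng.uniform(0.1, 5, 20))
            for i in range(4)
        ]
        df = density_correlation(pairs)
        assert np.allclose(df["p_bonferroni"], np.minimum(1.0, df["p"] * 4))


class TestGcContent:
    @pytest.mark.parametrize(
        "seq, expected",
        [("GGGG", 1.0), ("ATAT", 0.0), ("ACGT", 0.5), ("ANGC", 2 / 3), ("acgt", 0.5)],
    )
    def test_known_sequences(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_undefined(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")
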