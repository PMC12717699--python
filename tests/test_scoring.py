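import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from senindex.preprocess import ExpressionMatrix
from senindex.scoring import RankConfig, score_by_celltype, score_cells, score_signatures
from senindex.signatures import GeneSignature

from .conftest import ucell_oracle


def make_matrix(values, genes=None, cells=None, layer="log_tpm"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values, genes, cells, layer)


class TestScoreCells:
    def test_top_ranked_up_set_scores_one(self):
        """A signature occupying a cell's top ranks attains the maximal score."""
        m = make_matrix(np.array([[9, 8, 5, 3, 1]], dtype=float).T)
        sig = GeneSignature("S", ("G0", "G1"))
        s = score_cells(m, sig, RankConfig(max_rank=5))
        assert s.iloc[0] == pytest.approx(1.0)

    def test_mirrored_directions_cancel(self):
        """Up and down sets with identical expression profiles combine to 0."""
        vals = np.array([[5, 5, 3, 1, 1]], dtype=float).T
        m = make_matrix(vals, genes=["U1", "D1", "MID", "U2", "D2"])
        s = score_cells(m, GeneSignature("X", ("U1", "U2"), ("D1", "D2")),
                        RankConfig(max_rank=5))
        assert s.iloc[0] == pytest.approx(0.0)

    def test_matches_brute_force_oracle_on_fixed_fixture(self, small_matrix):
        """Scores on the frozen 10x3 integer fixture equal the pair-counting
        rank-sum oracle exactly."""
        sig = GeneSignature("S", ("G0", "G3", "G7"), ("G2", "G9"))
        for max_rank in (5, 8, 15):
            got = score_cells(small_matrix, sig, RankConfig(max_rank=max_rank))
            want = ucell_oracle(small_matrix.dense(), small_matrix.gene_ids,
                                list(sig.up_genes), list(sig.down_genes), max_rank)
            np.testing.assert_allclose(got.to_numpy(), want, atol=1e-12)

    def test_matches_oracle_on_random_matrices(self, rng):
        """Vectorized scores equal the brute-force construction on random
        tie-rich matrices up to 50 genes x 20 cells."""
        for _ in range(25):
            n_g = int(rng.integers(5, 51))
            n_c = int(rng.integers(1, 21))
            vals = rng.integers(0, 6, (n_g, n_c)).astype(float)
            m = make_matrix(vals)
            k_up = int(rng.integers(1, max(2, n_g // 3)))
            k_dn = int(rng.integers(0, max(1, n_g // 3)))
            perm = rng.permutation(n_g)
            up = [f"G{i}" for i in perm[:k_up]]
            dn = [f"G{i}" for i in perm[k_up:k_up + k_dn]]
            max_rank = int(rng.integers(2, n_g + 10))
            got = score_cells(m, GeneSignature("S", tuple(up), tuple(dn)),
                              RankConfig(max_rank=max_rank))
            want = ucell_oracle(vals, m.gene_ids, up, dn, max_rank)
            np.testing.assert_allclose(got.to_numpy(), want, atol=1e-12)

    def test_monotone_transform_invariance(self, rng):
        """Any strictly increasing transform of a cell's expression leaves the
        rank-based score unchanged."""
        vals = rng.random((40, 5))
        m = make_matrix(vals)
        sig = GeneSignature("S", ("G1", "G5", "G9"), ("G20", "G30"))
        base = score_cells(m, sig, RankConfig(max_rank=20))
        for f in (np.exp, np.sqrt, lambda x: 3 * x + 2, lambda x: x ** 3):
            t = score_cells(make_matrix(f(vals)), sig, RankConfig(max_rank=20))
            np.testing.assert_allclose(t.to_numpy(), base.to_numpy(), atol=1e-12)

    def test_up_gene_increase_never_decreases_score(self, rng):
        vals = rng.random((30, 1))
        sig = GeneSignature("S", ("G4",), ("G10",))
        cfg = RankConfig(max_rank=10)
        base = score_cells(make_matrix(vals), sig, cfg).iloc[0]
        bumped = vals.copy()
        bumped[4, 0] += 0.5
        after = score_cells(make_matrix(bumped), sig, cfg).iloc[0]
        assert after >= base - 1e-12

    def test_perfect_separation_effect_size(self, rng):
        """Up-genes top-ranked in senescent cells vs bottom-ranked elsewhere
        yields a score gap of at least 0.5."""
        n_g = 100
        up = [f"G{i}" for i in range(10)]
        sen = np.zeros((n_g, 1))
        sen[:10, 0] = np.arange(10, 0, -1) + 100     # up genes on top
        sen[10:, 0] = rng.random(90)
        other = np.zeros((n_g, 1))
        other[10:, 0] = rng.random(90) + 100          # up genes at the bottom
        sig = GeneSignature("S", tuple(up))
        cfg = RankConfig(max_rank=50)
        s_sen = score_cells(make_matrix(sen), sig, cfg).iloc[0]
        s_oth = score_cells(make_matrix(other), sig, cfg).iloc[0]
        assert s_sen - s_oth >= 0.5

    def test_no_signature_genes_present_raises(self, small_matrix):
        with pytest.raises(ValueError, match="present"):
            score_cells(small_matrix, GeneSignature("S", ("NOPE",)))

    def test_floor_at_zero_option(self):
        vals = np.array([[1, 9.0]], dtype=float).T
        m = make_matrix(vals)
        sig = GeneSignature("S", ("G0",), ("G1",))  # up at bottom, down on top
        raw = score_cells(m, sig, RankConfig(max_rank=2))
        floored = score_cells(m, sig, RankConfig(max_rank=2), floor_at_zero=True)
        assert raw.iloc[0] < 0
        assert floored.iloc[0] == 0.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 50), min_size=8, max_size=8))
def test_score_bounds_property(values):
    """Combined directional scores always stay within [-1, 1]."""
    vals = np.asarray(values, dtype=float)[:, None]
    m = make_matrix(vals)
    sig = GeneSignature("S", ("G0", "G1", "G2"), ("G5", "G6"))
    s = score_cells(m, sig, RankConfig(max_rank=4))
    assert -1.0 <= s.iloc[0] <= 1.0


class TestScoreByCellType:
    @staticmethod
    def _meta(cells, types):
        return pd.DataFrame({"cell_id": cells, "cell_type": types})

    def test_single_cell_type_equals_plain_scoring(self, small_matrix):
        sigs = {"senescence": GeneSignature("S", ("G0", "G1"), ("G8",))}
        meta = self._meta(small_matrix.cell_ids, ["T"] * 3)
        a = score_by_celltype(small_matrix, meta, sigs)
        b = score_signatures(small_matrix, sigs)
        pd.testing.assert_frame_equal(a, b)

    def test_permutation_invariance(self, rng):
        vals = rng.random((20, 8))
        cells = [f"c{i}" for i in range(8)]
        types = ["A", "B"] * 4
        m = make_matrix(vals, cells=cells)
        sigs = {"s": GeneSignature("S", ("G0", "G3"), ("G9",))}
        meta = self._meta(cells, types)
        base = score_by_celltype(m, meta, sigs)
        perm = rng.permutation(8)
        m2 = make_matrix(vals[:, perm], cells=[cells[i] for i in perm])
        shuffled = score_by_celltype(m2, meta, sigs)
        pd.testing.assert_frame_equal(shuffled.loc[base.index], base)

    def test_duplicated_stratum_scores_identically(self, rng):
        """Copying a cell type's cells into a second stratum reproduces the
        same scores: strata are independent."""
        vals = rng.random((15, 4))
        m = make_matrix(np.hstack([vals, vals]),
                        cells=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        meta = self._meta(m.cell_ids, ["T1"] * 4 + ["T2"] * 4)
        sigs = {"s": GeneSignature("S", ("G0", "G5"), ("G10",))}
        out = score_by_celltype(m, meta, sigs)
        np.testing.assert_allclose(out.iloc[:4].to_numpy(), out.iloc[4:].to_numpy())
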