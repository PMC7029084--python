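"""Newick handling, BM covariance construction and the Pagel transform."""

import numpy as np
import pytest

from lhinvar.phylo import (
    bm_covariance,
    check_psd,
    pagel_transform,
    prune_to_taxa,
    read_newick,
    to_correlation,
)
from lhinvar.synthetic_data import simulate_yule_tree

BASIC = "((A:1,B:1):1,C:2);"


class TestRead:
    def test_canonical_parse(self):
        t = read_newick(data=BASIC)
        assert sorted(t.tip_labels) == ["A", "B", "C"]

    def test_missing_semicolon_tolerated(self, caplog):
        t = read_newick(data="((A:1,B:1):1,C:2)")
        assert t.n_tips == 3
        assert "semicolon" in caplog.text or "';'" in caplog.text

    def test_malformed_parentheses_rejected(self):
        with pytest.raises(ValueError, match="parse"):
            read_newick(data="((A:1,B:1:1,C:2);")

    def test_missing_branch_length_named(self):
        with pytest.raises(ValueError, match="branch length"):
            read_newick(data="((A:1,B):1,C:2);")


class TestPrune:
    def test_path_lengths_preserved(self):
        sub, dropped = prune_to_taxa(read_newick(data=BASIC), {"A", "C"})
        assert dropped == []
        cov = bm_covariance(sub)
        i, j = cov.taxa.index("A"), cov.taxa.index("C")
        # A-C patristic distance through the original root is 1 + 1 + 2
        assert cov.V[i, i] + cov.V[j, j] - 2 * cov.V[i, j] == pytest.approx(4.0)

    def test_full_tip_set_is_identity_on_distances(self):
        t = simulate_yule_tree(12, seed=5)
        sub, _ = prune_to_taxa(t, set(t.tip_labels))
        c1 = bm_covariance(t, jitter_singular=False)
        c2 = bm_covariance(sub, jitter_singular=False).restrict(c1.taxa)
        np.testing.assert_allclose(c1.V, c2.V, atol=1e-10)

    def test_single_tip_rejected(self):
        with pytest.raises(ValueError):
            prune_to_taxa(read_newick(data=BASIC), {"A"})

    def test_commutes_with_covariance(self):
        t = simulate_yule_tree(15, seed=9)
        keep = sorted(t.tip_labels)[:8]
        sub, _ = prune_to_taxa(t, keep)
        c_full = bm_covariance(t, jitter_singular=False).restrict(
            bm_covariance(sub, jitter_singular=False).taxa)
        c_sub = bm_covariance(sub, jitter_singular=False)
        np.testing.assert_allclose(c_full.V, c_sub.V, atol=1e-10)


class TestCovariance:
    def test_shared_path_enumeration(self):
        cov = bm_covariance(read_newick(data=BASIC))
        order = [cov.taxa.index(s) for s in "ABC"]
        V = cov.V[np.ix_(order, order)]
        np.testing.assert_allclose(V, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree_is_diagonal(self):
        cov = bm_covariance(read_newick(data="(A:1,B:1,C:1);"))
        np.testing.assert_allclose(cov.V, np.eye(3))

    def test_ultrametric_equal_depths(self):
        cov = bm_covariance(simulate_yule_tree(10, seed=2),
                            jitter_singular=False)
        d = np.diag(cov.V)
        np.testing.assert_allclose(d, d[0], rtol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_psd_on_random_trees(self, seed):
        t = simulate_yule_tree(25, seed=seed, tip_jitter_sd=0.3)
        V = bm_covariance(t).V
        assert np.linalg.eigvalsh(V)[0] >= -1e-8 * np.trace(V)


class TestPagel:
    def setup_method(self):
        self.cov = bm_covariance(read_newick(data=BASIC))

    def test_zero_removes_phylogeny(self):
        out = pagel_transform(self.cov, 0.0).V
        np.testing.assert_allclose(out, np.diag(np.diag(self.cov.V)))

    def test_one_is_identity(self):
        np.testing.assert_allclose(pagel_transform(self.cov, 1.0).V,
                                   self.cov.V)

    def test_half_elementwise(self):
        order = [self.cov.taxa.index(s) for s in "ABC"]
        V = pagel_transform(self.cov, 0.5).V[np.ix_(order, order)]
        np.testing.assert_allclose(V, [[2, .5, 0], [.5, 2, 0], [0, 0, 2]])

    def test_offdiagonal_linear_in_lambda(self):
        t = simulate_yule_tree(8, seed=4)
        cov = bm_covariance(t)
        off = ~np.eye(cov.V.shape[0], dtype=bool)
        v1 = pagel_transform(cov, 0.25).V[off]
        v2 = pagel_transform(cov, 0.75).V[off]
        np.testing.assert_allclose(3 * v1, v2, rtol=1e-12)

    def test_lambda_beyond_psd_bound_rejected(self):
        with pytest.raises(ValueError):
            pagel_transform(self.cov, 50.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            pagel_transform(self.cov, -0.1)


def test_correlation_has_unit_diagonal():
    cov = bm_covariance(simulate_yule_tree(10, seed=1, tip_jitter_sd=0.2))
    R = to_correlation(cov)
    np.testing.assert_allclose(np.diag(R), 1.0)
    check_psd(R)
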