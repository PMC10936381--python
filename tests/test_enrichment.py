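from itertools import combinations

import numpy as np
import pytest

from netqc.enrichment import full_shuffle_score_matrix, net_score_matrix, net_score_pair
from netqc.errors import ValidationError
from netqc.io_tables import CellTable
from netqc.neighborhood import NeighborhoodConfig
from netqc.synthetic import (
    ASYMMETRY_RADIUS,
    generate_asymmetry_scenario,
    generate_attraction_scenario,
    generate_csr_scenario,
)


def _toy_table():
    """1 focal A plus 6 non-A cells (3 B, 3 C); exactly 2 of the 6 lie within d=1."""
    xy = np.array([
        [0.0, 0.0],            # A
        [0.5, 0.0], [5.0, 0.0], [0.0, 5.0],     # B (first inside d=1)
        [0.0, 0.8], [3.0, 3.0], [-4.0, 1.0],    # C (first inside d=1)
    ])
    labels = np.array(["A", "B", "B", "B", "C", "C", "C"], dtype=object)
    ids = np.array([f"c{i}" for i in range(7)], dtype=object)
    return CellTable(ids=ids, xy=xy, labels=labels)


def _two_class_table(rng):
    xy = rng.uniform(0, 100, (40, 2))
    labels = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
    return CellTable(ids=np.array([f"c{i}" for i in range(40)], dtype=object),
                     xy=xy, labels=labels)


class TestConditionalNull:
    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """MC mu/sigma agree with enumeration over all C(6,3) position subsets."""
        table = _toy_table()
        cfg = NeighborhoodConfig(1.0)
        pool = table.xy[1:]
        inside = (np.linalg.norm(pool, axis=1) <= 1.0).astype(int)
        values = [inside[list(idx)].sum() / 1.0 for idx in combinations(range(6), 3)]
        mu_exact = float(np.mean(values))
        sigma_exact = float(np.std(values))  # population sd over equally likely subsets

        res = net_score_pair(table, "A", "B", cfg, n_permutations=5000, seed=0)
        assert abs(res.null.mu - mu_exact) <= 0.02
        assert abs(res.null.sigma - sigma_exact) / sigma_exact <= 0.05

    def test_two_class_pool_is_degenerate(self, rng):
        """With only two classes every replicate re-draws the original B positions."""
        table = _two_class_table(rng)
        res = net_score_pair(table, "A", "B", NeighborhoodConfig(10.0),
                             n_permutations=50, seed=1)
        assert np.isnan(res.score)
        assert res.null.sigma == 0.0
        assert "sigma" in res.reason

        matrix = net_score_matrix(table, NeighborhoodConfig(10.0), 50, seed=1)
        assert np.all(np.isnan(matrix.scores))
        assert ("A", "B") in matrix.notes and ("B", "A") in matrix.notes

    def test_standardization_identity(self):
        table = generate_attraction_scenario(0)
        res = net_score_pair(table, "A", "B", NeighborhoodConfig(50.0), 200, seed=0)
        assert res.score == (res.observed - res.null.mu) / res.null.sigma
        vals = res.null.replicate_values
        assert res.null.mu == float(np.mean(vals))
        assert res.null.sigma == float(np.std(vals, ddof=1))

    def test_same_focal_and_query_rejected(self, rng):
        with pytest.raises(ValidationError):
            net_score_pair(_two_class_table(rng), "A", "A", NeighborhoodConfig(5.0), 10)

    def test_minimum_permutations_enforced(self, rng):
        with pytest.raises(ValidationError):
            net_score_pair(_two_class_table(rng), "A", "B", NeighborhoodConfig(5.0),
                           n_permutations=1)


class TestMatrixContracts:
    def test_seed_determinism_and_sensitivity(self):
        table = generate_csr_scenario(0)
        cfg = NeighborhoodConfig(50.0)
        m1 = net_score_matrix(table, cfg, 100, seed=5)
        m2 = net_score_matrix(table, cfg, 100, seed=5)
        np.testing.assert_array_equal(m1.scores, m2.scores)
        m3 = net_score_matrix(table, cfg, 100, seed=6)
        off = ~np.eye(3, dtype=bool)
        assert not np.array_equal(m1.scores[off], m3.scores[off])

    def test_record_order_invariance(self, rng):
        table = generate_asymmetry_scenario(3)
        perm = rng.permutation(len(table))
        shuffled = CellTable(ids=table.ids[perm], xy=table.xy[perm],
                             labels=table.labels[perm])
        cfg = NeighborhoodConfig(ASYMMETRY_RADIUS)
        m1 = net_score_matrix(table, cfg, 100, seed=7)
        m2 = net_score_matrix(shuffled, cfg, 100, seed=7)
        f1 = full_shuffle_score_matrix(table, cfg, 100, seed=7)
        f2 = full_shuffle_score_matrix(shuffled, cfg, 100, seed=7)
        for a in m1.class_names:
            for b in m1.class_names:
                if a != b:
                    assert m1.score(a, b) == m2.score(a, b)
                    assert f1.score(a, b) == f2.score(a, b)

    def test_monte_carlo_error_shrinks_with_replicates(self):
        table = generate_attraction_scenario(0)
        cfg = NeighborhoodConfig(50.0)
        diffs = {}
        for n_perm, bound in ((100, 2.5), (1000, 0.8), (10000, 0.3)):
            z1 = net_score_pair(table, "A", "B", cfg, n_perm, seed=1).score
            z2 = net_score_pair(table, "A", "B", cfg, n_perm, seed=2).score
            diffs[n_perm] = abs(z1 - z2)
            assert diffs[n_perm] < bound
        assert diffs[10000] < diffs[100]

    def test_asymmetry_is_directional_under_conditional_null(self):
        table = generate_asymmetry_scenario(0)
        m = net_score_matrix(table, NeighborhoodConfig(ASYMMETRY_RADIUS), 500, seed=0)
        z_gt = m.score("Glioma", "TAMM")
        z_tg = m.score("TAMM", "Glioma")
        assert z_gt < -2
        assert abs(z_gt - z_tg) > 2


class TestFullShuffle:
    def test_csr_scores_are_calibrated(self):
        table = generate_csr_scenario(0)
        m = full_shuffle_score_matrix(table, NeighborhoodConfig(50.0), 500, seed=0)
        off = m.scores[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 3)

    def test_matrix_is_exactly_symmetric(self):
        """Shared per-replicate permutations make z[A][B] = z[B][A] up to round-off."""
        table = generate_asymmetry_scenario(1)
        m = full_shuffle_score_matrix(table, NeighborhoodConfig(ASYMMETRY_RADIUS),
                                      300, seed=4)
        np.testing.assert_allclose(m.scores, m.scores.T, atol=1e-9)

    def test_minimal_replicate_run_is_finite(self):
        table = generate_csr_scenario(2)
        m = full_shuffle_score_matrix(table, NeighborhoodConfig(50.0), 2, seed=0)
        off = ~np.eye(3, dtype=bool)
        assert np.all(np.isfinite(m.null_mean[off]))
        assert np.all(m.null_std[off] >= 0)

    def test_diagonal_defined_only_on_request(self):
        table = generate_csr_scenario(1)
        cfg = NeighborhoodConfig(50.0)
        default = full_shuffle_score_matrix(table, cfg, 100, seed=0)
        assert np.all(np.isnan(np.diag(default.scores)))
        included = full_shuffle_score_matrix(table, cfg, 100, seed=0,
                                             diagonal_policy="include")
        assert np.all(np.isfinite(np.diag(included.scores)))
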