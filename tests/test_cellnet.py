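"""The per-cell neighborhood statistic and network construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import bf_counts, bf_neighborhood, closed_form_rho_hat
from lncstage.cellnet import (
    CellNetworkInference,
    DegenerateMarginError,
    NeighborhoodCounts,
    all_cell_networks,
    cell_network,
    neighborhood,
    neighborhood_counts,
    normalized_stat,
)
from lncstage.data_io import ExpressionMatrix, InteractionList


class TestNeighborhood:
    def test_smallest_box_is_self_only(self):
        assert set(neighborhood(np.arange(10.0), k=5, box_fraction=0.1)) == {5}

    def test_two_nearest_by_distance(self):
        values = [1.0, 2.0, 2.1, 5.0, 9.0]
        assert set(neighborhood(values, k=1, box_fraction=0.4)) == {1, 2}

    def test_boundary_ties_all_included(self):
        # n = 3; the third-nearest distance is 1, where cells 1 and 3 tie
        values = [5.0, 4.0, 5.0, 6.0, 9.0]
        assert set(neighborhood(values, k=0, box_fraction=0.6)) == {0, 1, 2, 3}

    def test_all_equal_values_cover_every_cell(self):
        # degenerate input: every cell ties at distance zero
        assert set(neighborhood([2.0] * 10, k=0, box_fraction=0.3)) == set(range(10))

    def test_focal_cell_always_member(self, rng):
        values = rng.standard_normal(30)
        for k in range(30):
            assert k in neighborhood(values, k, 0.1)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_fraction(self, bad):
        with pytest.raises(ValueError):
            neighborhood([1.0, 2.0, 3.0], 0, bad)

    @given(st.integers(min_value=0, max_value=19), st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_brute_force(self, k, data):
        values = data.draw(
            st.lists(
                st.floats(-5, 5, allow_nan=False).map(lambda x: round(x, 1)),
                min_size=20,
                max_size=20,
            )
        )
        frac = data.draw(st.sampled_from([0.1, 0.2, 0.35, 0.5]))
        assert set(neighborhood(values, k, frac)) == bf_neighborhood(values, k, frac)


class TestNeighborhoodCounts:
    def test_identical_vectors_fully_overlap(self, rng):
        u = rng.standard_normal(25)
        c = neighborhood_counts(u, u, k=3, box_fraction=0.2)
        assert c.m_uv == c.m_u == c.m_v

    def test_reversed_vector_example(self):
        u = [1.0, 2.0, 3.0, 4.0, 5.0]
        v = [5.0, 4.0, 3.0, 2.0, 1.0]
        c = neighborhood_counts(u, v, k=2, box_fraction=0.6)
        assert (c.m, c.m_u, c.m_v, c.m_uv) == (5, 3, 3, 3)

    def test_self_membership_forces_overlap(self, rng):
        # neighborhoods disjoint except for the focal cell itself
        u = np.arange(10.0)
        v = np.array([10.0, 20.0, 30.0, 40.0, 0.5, 50.0, 60.0, 70.0, 80.0, 90.0])
        c = neighborhood_counts(u, v, k=4, box_fraction=0.2)
        assert c.m_uv >= 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            neighborhood_counts([1.0, 2.0], [1.0, 2.0, 3.0], 0, 0.5)

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            NeighborhoodCounts(m=10, m_u=3, m_v=3, m_uv=5)  # overlap > margin
        with pytest.raises(ValueError):
            NeighborhoodCounts(m=10, m_u=0, m_v=3, m_uv=0)  # empty margin
        with pytest.raises(ValueError):
            NeighborhoodCounts(m=10, m_u=9, m_v=9, m_uv=2)  # below m_u+m_v-m

    @given(
        st.integers(min_value=0, max_value=29),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_counts_match_brute_force_random_vectors(self, k, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(10, 50))
        k = k % m
        # mix of continuous values and zero-inflation to exercise ties
        u = np.where(rng.random(m) < 0.3, 0.0, rng.standard_normal(m)).round(2)
        v = np.where(rng.random(m) < 0.3, 0.0, rng.standard_normal(m)).round(2)
        c = neighborhood_counts(u, v, k, 0.1)
        assert (c.m, c.m_u, c.m_v, c.m_uv) == bf_counts(u, v, k, 0.1)


class TestNormalizedStat:
    def test_independence_case(self):
        s = normalized_stat(NeighborhoodCounts(100, 10, 10, 1))
        assert s.rho == pytest.approx(0.0, abs=1e-15)
        assert s.rho_hat == pytest.approx(0.0, abs=1e-12)
        assert s.p == pytest.approx(0.5, abs=1e-12)

    def test_full_overlap_worked_value(self):
        s = normalized_stat(NeighborhoodCounts(100, 10, 10, 10))
        assert s.rho_hat == pytest.approx(np.sqrt(99), rel=1e-12)
        assert s.rho_hat == pytest.approx(9.94987, abs=1e-5)

    def test_zero_overlap_worked_value(self):
        s = normalized_stat(NeighborhoodCounts(100, 10, 10, 0))
        assert s.rho_hat == pytest.approx(np.sqrt(99) * (-100) / 900, rel=1e-12)
        assert s.rho_hat == pytest.approx(-1.10554, abs=1e-5)

    def test_degenerate_margin_errors(self):
        with pytest.raises(DegenerateMarginError):
            normalized_stat(NeighborhoodCounts(10, 10, 3, 3))

    def test_two_sided_tail_doubles_upper(self):
        c = NeighborhoodCounts(100, 10, 10, 6)
        up = normalized_stat(c, tail="upper")
        two = normalized_stat(c, tail="two-sided")
        assert two.p == pytest.approx(2 * up.p)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_ratio_equals_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 200))
        m_u = int(rng.integers(1, m))
        m_v = int(rng.integers(1, m))
        lo, hi = max(0, m_u + m_v - m), min(m_u, m_v)
        m_uv = int(rng.integers(lo, hi + 1))
        s = normalized_stat(NeighborhoodCounts(m, m_u, m_v, m_uv))
        assert s.rho_hat == pytest.approx(
            closed_form_rho_hat(m, m_u, m_v, m_uv), abs=1e-10
        )
        assert np.sign(s.rho_hat) == np.sign(s.rho) or s.rho == 0

    def test_symmetric_in_u_v(self):
        a = normalized_stat(NeighborhoodCounts(50, 7, 12, 4))
        b = normalized_stat(NeighborhoodCounts(50, 12, 7, 4))
        assert a.rho_hat == pytest.approx(b.rho_hat, abs=1e-12)

    def test_strictly_increasing_in_overlap(self):
        vals = [
            normalized_stat(NeighborhoodCounts(60, 10, 15, m_uv)).rho_hat
            for m_uv in range(0, 11)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestStatisticInvariance:
    def test_affine_transform_leaves_rho_hat_unchanged(self, rng):
        u = rng.standard_normal(40)
        v = rng.standard_normal(40)
        base = neighborhood_counts(u, v, 7, 0.1)
        for a, b in [(2.0, 3.0), (-1.5, 0.7)]:
            c = neighborhood_counts(a * u + b, v, 7, 0.1)
            assert (c.m_u, c.m_v, c.m_uv) == (base.m_u, base.m_v, base.m_uv)


def _expr_with_planted_pair(m, rho, seed, n_decoys=20):
    """One correlated (LNCP, MRP) pair plus independent decoy pairs."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(m)
    planted = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(m)
    rows = [z, planted]
    names = ["LNCP", "MRP"]
    roles = {"LNCP": "lncRNA", "MRP": "mRNA"}
    for i in range(n_decoys):
        rows += [rng.standard_normal(m), rng.standard_normal(m)]
        names += [f"LNCD{i}", f"MRD{i}"]
        roles[f"LNCD{i}"] = "lncRNA"
        roles[f"MRD{i}"] = "mRNA"
    df = pd.DataFrame(rows, index=names, columns=[f"c{i}" for i in range(m)])
    pairs = InteractionList(
        (("LNCP", "MRP"),)
        + tuple((f"LNCD{i}", f"MRD{i}") for i in range(n_decoys))
    )
    return ExpressionMatrix(df, roles), pairs


class TestCellNetworks:
    def test_alpha_one_keeps_every_pair(self, annotated_matrix, priors):
        net = cell_network(annotated_matrix, priors, k=0, alpha=1.0)
        assert net.edge_set == priors.pair_set

    def test_alpha_near_zero_empties_network(self, annotated_matrix, priors):
        net = cell_network(annotated_matrix, priors, k=0, alpha=1e-300)
        assert net.n_edges == 0

    def test_planted_pair_detected_decoys_near_null(self):
        # m = 276 cells: the scale the 0.1 box fraction is tuned for; the
        # normal approximation is anticonservative for much smaller boxes
        expr, pairs = _expr_with_planted_pair(m=276, rho=0.95, seed=7)
        est = CellNetworkInference().fit(expr, pairs)
        planted_rate = np.mean(
            [("LNCP", "MRP") in n.edge_set for n in est.cell_networks_]
        )
        decoy_p = est.p_[1:]  # pooled over 20 independent decoy pairs
        assert planted_rate > 0.5
        assert (decoy_p < 0.05).mean() < 0.15
        assert 0.1 < np.median(decoy_p) < 0.9

    def test_one_network_per_cell(self, annotated_matrix, priors):
        nets = all_cell_networks(annotated_matrix, priors)
        assert [n.cell_id for n in nets] == annotated_matrix.cells

    def test_permuting_cells_permutes_networks(self, annotated_matrix, priors):
        perm = np.random.default_rng(1).permutation(annotated_matrix.n_cells)
        permuted = ExpressionMatrix(
            annotated_matrix.values.iloc[:, perm], annotated_matrix.gene_role
        )
        base = {n.cell_id: n for n in all_cell_networks(annotated_matrix, priors)}
        for net in all_cell_networks(permuted, priors):
            assert net.edge_set == base[net.cell_id].edge_set

    def test_duplicate_priors_equal_deduplicated(self, annotated_matrix, priors):
        doubled = InteractionList(priors.pairs + priors.pairs)
        a = all_cell_networks(annotated_matrix, priors)
        b = all_cell_networks(annotated_matrix, doubled)
        assert all(x.edge_set == y.edge_set for x, y in zip(a, b))

    def test_missing_genes_skipped_and_empty_prior_errors(self, annotated_matrix):
        mixed = InteractionList((("LNC1", "MR1"), ("LNCX", "MR1"), ("LNC1", "MRX")))
        est = CellNetworkInference().fit(annotated_matrix, mixed)
        assert est.pairs_ == [("LNC1", "MR1")]
        with pytest.raises(ValueError, match="no usable prior"):
            CellNetworkInference().fit(
                annotated_matrix, InteractionList((("NOPE", "NADA"),))
            )

    def test_estimator_params_round_trip(self):
        est = CellNetworkInference(box_fraction=0.2, alpha=0.01, tail="two-sided")
        assert CellNetworkInference(**est.get_params()).get_params() == {
            "box_fraction": 0.2,
            "alpha": 0.01,
            "tail": "two-sided",
        }
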