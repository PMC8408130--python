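"""Niche-model generation, trophic positions and allometry."""

import io

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

import trophicmeta as tm
from trophicmeta.niche_web import read_edgelist, write_edgelist, to_networkx


def nx_trophic_oracle(feeding: np.ndarray) -> np.ndarray:
    """Independent oracle: per-species min shortest-path length to any producer."""
    S = feeding.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(S))
    g.add_edges_from(
        (i, j) for i in range(S) for j in range(S) if feeding[i, j] and i != j
    )
    producers = [i for i in range(S) if g.out_degree(i) == 0 and not feeding[i, i]]
    T = np.empty(S, dtype=int)
    for i in range(S):
        lengths = []
        for p in producers:
            try:
                lengths.append(nx.shortest_path_length(g, i, p))
            except nx.NetworkXNoPath:
                pass
        T[i] = min(lengths)
    return T


class TestTrophicPositions:
    def test_linear_chain(self):
        # species 2 eats 1 eats 0
        feeding = np.zeros((3, 3), dtype=bool)
        feeding[1, 0] = feeding[2, 1] = True
        assert tm.trophic_positions(feeding).tolist() == [0, 1, 2]

    def test_omnivore_takes_shortest_path(self):
        # 2 eats both the producer 0 and the herbivore 1
        feeding = np.zeros((3, 3), dtype=bool)
        feeding[1, 0] = feeding[2, 0] = feeding[2, 1] = True
        assert tm.trophic_positions(feeding).tolist() == [0, 1, 1]

    def test_self_links_ignored(self):
        feeding = np.zeros((2, 2), dtype=bool)
        feeding[1, 0] = feeding[1, 1] = True
        assert tm.trophic_positions(feeding).tolist() == [0, 1]

    def test_no_path_raises(self):
        # 0 and 1 eat only each other: no basal support
        feeding = np.zeros((3, 3), dtype=bool)
        feeding[0, 1] = feeding[1, 0] = True
        with pytest.raises(ValueError):
            tm.trophic_positions(feeding)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bfs_oracle_on_random_webs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            web = tm.generate_niche_web(int(rng.integers(5, 16)), 0.18, rng)
            assert np.array_equal(
                web.trophic_position, nx_trophic_oracle(web.feeding)
            )


class TestAllometry:
    def test_producer_mass_is_one(self, small_web):
        assert np.all(small_web.mass[small_web.producers] == 1.0)
        assert np.all(small_web.turnover[small_web.producers] == 1.0)

    def test_mass_and_turnover_relations_exact(self, small_web):
        assert np.array_equal(small_web.mass, 42.0 ** small_web.trophic_position)
        assert np.array_equal(small_web.turnover, small_web.mass ** (-0.25))

    def test_second_level_consumer(self):
        feeding = np.zeros((3, 3), dtype=bool)
        feeding[1, 0] = feeding[2, 1] = True
        web = tm.FoodWebTopology(
            S=3, C_target=0.2, niche_values=np.array([0.1, 0.5, 0.9]),
            feeding=feeding, trophic_position=tm.trophic_positions(feeding),
        )
        web = tm.assign_allometry(web, R=42.0)
        assert web.mass.tolist() == [1.0, 42.0, 1764.0]
        assert web.turnover[2] == pytest.approx((42.0 ** -0.25) ** 2)

    def test_invalid_ratio_rejected(self, small_web):
        with pytest.raises(ValueError):
            tm.assign_allometry(small_web, R=-1.0)


class TestGeneration:
    def test_invariants_on_retained_webs(self, rng):
        for _ in range(20):
            web = tm.generate_niche_web(15, 0.2, rng)
            assert web.producers.any()
            assert np.all(web.trophic_position >= 0)
            # producer <=> no prey
            assert np.array_equal(web.trophic_position == 0, web.producers)

    def test_preconditions(self, rng):
        with pytest.raises(ValueError):
            tm.generate_niche_web(1, 0.2, rng)
        with pytest.raises(ValueError):
            tm.generate_niche_web(10, 0.6, rng)

    def test_attempt_budget_signals_infeasibility(self, rng):
        from trophicmeta.niche_web import InfeasibleWebError

        # S=2 at tiny connectance essentially never yields a connected web
        with pytest.raises(InfeasibleWebError):
            tm.generate_niche_web(2, 1e-6, rng, max_attempts=5)

    def test_range_fraction_beta_mean(self, rng):
        # at C=0.25 the range fraction is Beta(1, 1), i.e. Uniform(0, 1)
        C = 0.25
        b = 1.0 / (2 * C) - 1.0
        draws = rng.beta(1.0, b, size=100_000)
        assert draws.mean() == pytest.approx(1.0 / (1.0 + b), abs=3e-3)
        assert draws.mean() == pytest.approx(0.5, abs=3e-3)

    def test_feeding_biased_down_niche_axis(self, rng):
        down = total = 0
        for _ in range(50):
            web = tm.generate_niche_web(15, 0.18, rng)
            cons, prey = np.nonzero(web.feeding)
            down += int(
                (web.niche_values[prey] < web.niche_values[cons]).sum()
            )
            total += len(cons)
        assert down / total > 0.5

    def test_cannibalism_flag(self, rng):
        for _ in range(20):
            web = tm.generate_niche_web(15, 0.2, rng, allow_cannibalism=False)
            assert not np.diag(web.feeding).any()

    def test_seeded_reproducibility(self):
        w1 = tm.generate_niche_web(15, 0.2, np.random.default_rng(5))
        w2 = tm.generate_niche_web(15, 0.2, np.random.default_rng(5))
        assert np.array_equal(w1.feeding, w2.feeding)
        assert np.array_equal(w1.niche_values, w2.niche_values)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=15, deadline=None)
def test_generated_webs_satisfy_retention_invariants(seed):
    """Every retained web has basal support and an undirected single component."""
    rng = np.random.default_rng(seed)
    web = tm.generate_niche_web(10, 0.2, rng)
    assert web.producers.any()
    sym = web.feeding | web.feeding.T
    np.fill_diagonal(sym, False)
    g = nx.from_numpy_array(sym)
    assert nx.is_connected(g)
    # trophic positions defined everywhere
    assert np.array_equal(web.trophic_position, nx_trophic_oracle(web.feeding))


def test_edgelist_roundtrip(small_web):
    buf = io.StringIO()
    write_edgelist(small_web, buf)
    buf.seek(0)
    back = read_edgelist(buf)
    assert np.array_equal(back.feeding, small_web.feeding)
    assert np.allclose(back.niche_values, small_web.niche_values)
    assert np.array_equal(back.trophic_position, small_web.trophic_position)
    assert np.array_equal(back.mass, small_web.mass)


def test_networkx_export_matches_links(small_web):
    g = to_networkx(small_web)
    assert g.number_of_edges() == small_web.n_links
    assert g.nodes[0]["mass"] == small_web.mass[0]
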