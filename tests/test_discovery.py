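"""Pathway ranking, permutation p values, signature selection, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sig32.containers import PathwayDB
from sig32.discovery import (
    PathwayRanking,
    bh_adjust,
    overrepresentation_test,
    permutation_fdr,
    rank_pathways,
    select_signature,
)
from sig32.errors import InputError
from sig32.synthetic import SimulationDesign, simulate_pancancer
from sig32.trifactor import Lambdas, TriFactorModel, fit_trifactor


def _toy_model(scores: np.ndarray) -> TriFactorModel:
    n_types, n_pw = scores.shape
    return TriFactorModel(
        U=np.eye(n_types), S=scores, V=np.zeros((4, n_pw)),
        types=[f"t{i}" for i in range(n_types)],
        pathway_names=[f"PW{j + 1:02d}" for j in range(n_pw)],
        lambdas=Lambdas(), objective_trace=np.array([0.0]), converged=True, seed=0,
    )


class TestRanking:
    def test_ties_rank_in_index_order(self):
        model = _toy_model(np.array([[0.5, 0.5, 0.1]]))
        table = rank_pathways(model, "t0").table
        assert list(table["pathway"]) == ["PW01", "PW02", "PW03"]
        assert list(table["rank"]) == [1, 2, 3]

    def test_unknown_type_raises(self):
        model = _toy_model(np.array([[1.0, 0.0]]))
        with pytest.raises(KeyError):
            rank_pathways(model, "nope")

    def test_planted_pathway_ranked_first(self, default_design):
        """A planted pathway tops the target-type ranking across seeds."""
        hits = 0
        for seed in range(5):
            sim = simulate_pancancer(default_design, seed=seed)
            mm = sim.mutations
            model = fit_trifactor(
                mm.values, mm.cancer_type, sim.pathways.membership_matrix(mm.gene_ids),
                sim.network.laplacian, max_iter=300, seed=seed,
                pathway_names=sim.pathways.names,
            )
            top = rank_pathways(model, sim.planted[0]).table.iloc[0]["pathway"]
            hits += top in sim.planted[1]
        assert hits == 5


class TestPermutationFDR:
    def test_all_zero_matrix_gives_p_one(self):
        """When every permuted score ties the observed score, p = 1 exactly."""
        X = np.zeros((12, 10))
        labels = np.repeat(["a", "b"], 6)
        V0 = np.zeros((10, 2))
        V0[:5, 0] = 1
        V0[5:, 1] = 1
        L = np.zeros((10, 10))
        _, table = permutation_fdr(X, labels, V0, L, n_perm=19, seed=0, max_iter=50)
        assert (table["p"] == 1.0).all()

    def test_nperm_zero_rejected(self):
        with pytest.raises(InputError):
            permutation_fdr(np.zeros((4, 4)), ["a", "a", "b", "b"],
                            np.ones((4, 1)), np.zeros((4, 4)), n_perm=0)

    def test_planted_pathways_significant(self, default_pancancer):
        """Planted pathways reach q < 0.05 with the pipeline regularization."""
        mm = default_pancancer.mutations
        _, table = permutation_fdr(
            mm.values, mm.cancer_type,
            default_pancancer.pathways.membership_matrix(mm.gene_ids),
            default_pancancer.network.laplacian, (1.0, 1.0, 10.0),
            n_perm=150, seed=4, max_iter=300, perm_max_iter=120,
            pathway_names=default_pancancer.pathways.names,
        )
        target = default_pancancer.planted[0]
        sub = table[table.cancer_type == target].set_index("pathway")
        planted = sub.loc[default_pancancer.planted[1]]
        assert (planted["p"] == 1 / 151).all()
        # BH within the 20-pathway database: q = (1/151) * 20/3 < 0.05
        assert (planted["q"] < 0.05).all()


class TestSignature:
    def _ranking(self, rows):
        return PathwayRanking("t0", pd.DataFrame(rows))

    def test_disjoint_passing_sets_give_32_genes(self):
        db = PathwayDB(sets={
            "PW01": [f"a{i}" for i in range(10)],
            "PW02": [f"b{i}" for i in range(12)],
            "PW03": [f"c{i}" for i in range(10)],
        })
        ranking = self._ranking([
            {"pathway": "PW01", "score": 3.0, "rank": 1, "q": 0.001},
            {"pathway": "PW02", "score": 2.0, "rank": 2, "q": 0.001},
            {"pathway": "PW03", "score": 1.0, "rank": 3, "q": 0.001},
        ])
        assert len(select_signature(ranking, db)) == 32

    def test_top_n_one_returns_single_set(self):
        db = PathwayDB(sets={"PW01": ["g1", "g2"], "PW02": ["g9"]})
        ranking = self._ranking([
            {"pathway": "PW01", "score": 2.0, "rank": 1, "q": 0.01},
            {"pathway": "PW02", "score": 1.0, "rank": 2, "q": 0.01},
        ])
        assert select_signature(ranking, db, top_n=1) == ["g1", "g2"]

    def test_overlapping_sets_union_ordered(self):
        db = PathwayDB(sets={"P1": ["a", "b", "c"], "P2": ["b", "c", "d"]})
        ranking = self._ranking([
            {"pathway": "P2", "score": 2.0, "rank": 1, "q": 0.01},
            {"pathway": "P1", "score": 1.0, "rank": 2, "q": 0.01},
        ])
        sig = select_signature(ranking, db, top_n=2)
        assert sig == ["b", "c", "d", "a"]
        assert len(sig) == 4

    def test_nothing_passing_warns_and_returns_empty(self):
        db = PathwayDB(sets={"P1": ["a"]})
        ranking = self._ranking([{"pathway": "P1", "score": 1.0, "rank": 1, "q": 0.9}])
        with pytest.warns(UserWarning):
            assert select_signature(ranking, db) == []


class TestOverrepresentation:
    def test_matches_exhaustive_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(20)]
        members = universe[:5]
        gene_list = universe[:4] + universe[5:7]  # overlap 4
        db = PathwayDB(sets={"S": members})
        out = overrepresentation_test(gene_list, db, universe)
        # enumerate P(X >= 4) for X ~ Hypergeom(N=20, K=5, n=6) directly
        from math import comb

        p_exact = sum(
            comb(5, x) * comb(15, 6 - x) for x in range(4, 6)
        ) / comb(20, 6)
        assert out.loc[0, "p"] == pytest.approx(p_exact, rel=1e-12)

    def test_list_equals_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        db = PathwayDB(sets={"A": universe[:3], "B": universe[3:6]})
        out = overrepresentation_test(universe, db, universe)
        assert (out["p"] == 1.0).all()

    def test_empty_universe_rejected(self):
        with pytest.raises(InputError):
            overrepresentation_test([], PathwayDB(sets={"A": ["g"]}), [])


def test_bh_matches_independent_step_up_oracle():
    """BH q values agree with a hand-rolled step-up on 1000 random vectors."""

    def step_up(p):
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        running = 1.0
        for i in range(m - 1, -1, -1):
            running = min(running, p[order[i]] * m / (i + 1))
            q[order[i]] = running
        return q

    rng = np.random.default_rng(8)
    for _ in range(1000):
        m = int(rng.integers(1, 40))
        p = rng.random(m)
        assert np.allclose(bh_adjust(p), step_up(p), atol=1e-12)
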