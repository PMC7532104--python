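"""Composition: path-count weights, recipes, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repcool.composition import (
    CompositionRecipe,
    compose,
    compose_all,
    default_recipes,
)
from repcool.networks import NetworkRole, TypedNetwork, ValidationError

from conftest import brute_force_path_counts, random_primaries


def net(role, name, edges):
    return TypedNetwork.from_edges(role, name, edges)


class TestRecipes:
    def test_default_recipes_structure(self):
        drgn = net(NetworkRole.DRGN, "drgn", [("d1", "g1")])
        digns = [
            net(NetworkRole.DIGN, f"dign{i}", [("s1", "g1")]) for i in range(3)
        ]
        ppin = net(NetworkRole.PPIN, "ppin", [("g1", "g2")])
        gcn = net(NetworkRole.GCN, "gcn", [("g1", "g3")])
        recipes = default_recipes(drgn, digns, ppin, gcn)
        assert [r.recipe_id for r in recipes] == [
            f"Net{i}" for i in range(1, 10)
        ]
        assert [r.length for r in recipes] == [2] * 3 + [3] * 6
        assert all(r.chain[1] is ppin for r in recipes[3:6])
        assert all(r.chain[1] is gcn for r in recipes[6:9])
        # deterministic: second call gives an identical ordered list
        assert recipes == default_recipes(drgn, digns, ppin, gcn)

    def test_wrong_dign_count_rejected(self):
        drgn = net(NetworkRole.DRGN, "drgn", [("d1", "g1")])
        digns = [
            net(NetworkRole.DIGN, f"dign{i}", [("s1", "g1")]) for i in range(2)
        ]
        ppin = net(NetworkRole.PPIN, "ppin", [("g1", "g2")])
        gcn = net(NetworkRole.GCN, "gcn", [("g1", "g3")])
        with pytest.raises(ValidationError, match="3 DIGN"):
            default_recipes(drgn, digns, ppin, gcn)

    def test_bad_chain_rejected(self):
        drgn = net(NetworkRole.DRGN, "drgn", [("d1", "g1")])
        dign = net(NetworkRole.DIGN, "dign", [("s1", "g1")])
        with pytest.raises(ValidationError, match="start with a DRGN"):
            CompositionRecipe("bad", (dign, drgn))
        with pytest.raises(ValidationError, match="middle"):
            CompositionRecipe("bad", (drgn, drgn, dign))


class TestComposeExamples:
    def test_single_shared_gene(self):
        drgn = net(NetworkRole.DRGN, "drgn", [("d1", "g1"), ("d1", "g2")])
        dign = net(NetworkRole.DIGN, "dign", [("s1", "g2"), ("s1", "g3")])
        assert compose(CompositionRecipe("n", (drgn, dign))).weights == {
            ("d1", "s1"): 1
        }

    def test_full_overlap_counts_each_gene(self):
        genes = ["g1", "g2", "g3"]
        drgn = net(NetworkRole.DRGN, "drgn", [("d1", g) for g in genes])
        dign = net(NetworkRole.DIGN, "dign", [("s1", g) for g in genes])
        assert compose(CompositionRecipe("n", (drgn, dign))).weights == {
            ("d1", "s1"): 3
        }

    def test_bridged_path_requires_distinct_genes(self):
        # only d1-g1-g2-s1 counts; the self-hop d1-g1-g1-s1 is excluded
        drgn = net(NetworkRole.DRGN, "drgn", [("d1", "g1")])
        ppin = net(NetworkRole.PPIN, "ppin", [("g1", "g2")])
        dign = net(NetworkRole.DIGN, "dign", [("s1", "g2"), ("s1", "g1")])
        assert compose(
            CompositionRecipe("n", (drgn, ppin, dign))
        ).weights == {("d1", "s1"): 1}

    def test_middle_edge_usable_in_both_directions(self):
        drgn = net(NetworkRole.DRGN, "drgn", [("d1", "g1"), ("d1", "g2")])
        ppin = net(NetworkRole.PPIN, "ppin", [("g1", "g2")])
        dign = net(NetworkRole.DIGN, "dign", [("s1", "g1"), ("s1", "g2")])
        # paths: d1-g1-g2-s1 and d1-g2-g1-s1
        assert compose(
            CompositionRecipe("n", (drgn, ppin, dign))
        ).weights == {("d1", "s1"): 2}

    def test_zero_path_pairs_absent(self):
        drgn = net(NetworkRole.DRGN, "drgn", [("d1", "g1")])
        dign = net(NetworkRole.DIGN, "dign", [("s1", "g2")])
        assert compose(CompositionRecipe("n", (drgn, dign))).weights == {}


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        drgn, digns, ppin, gcn = random_primaries(rng, 10, 30, 10, 0.1)
        for recipe in default_recipes(drgn, digns, ppin, gcn):
            middle = recipe.chain[1] if recipe.length == 3 else None
            expected = brute_force_path_counts(
                recipe.chain[0], recipe.chain[-1], middle
            )
            assert compose(recipe).weights == expected

    @pytest.mark.parametrize("seed", range(3))
    def test_matrix_product_equivalence(self, seed):
        """Weights equal dense A_dg · M · A_gd with zeroed diagonal."""
        rng = np.random.default_rng(100 + seed)
        drgn, digns, ppin, gcn = random_primaries(rng, 8, 20, 8, 0.15)
        drugs = sorted({d for d, _ in drgn.edges})
        genes = [f"g{i}" for i in range(20)]
        for dign, middle in [(digns[0], ppin), (digns[1], gcn)]:
            diseases = sorted({s for s, _ in dign.edges})
            A = np.zeros((len(drugs), len(genes)), dtype=int)
            for d, g in drgn.edges:
                A[drugs.index(d), genes.index(g)] = 1
            M = np.zeros((len(genes), len(genes)), dtype=int)
            for a, b in middle.edges:
                M[genes.index(a), genes.index(b)] = 1
                M[genes.index(b), genes.index(a)] = 1
            np.fill_diagonal(M, 0)
            B = np.zeros((len(genes), len(diseases)), dtype=int)
            for s, g in dign.edges:
                B[genes.index(g), diseases.index(s)] = 1
            W = A @ M @ B
            composed = compose(CompositionRecipe("n", (drgn, middle, dign)))
            for i, d in enumerate(drugs):
                for j, s in enumerate(diseases):
                    assert composed.weight(d, s) == W[i, j]


class TestProperties:
    def test_monotonicity_under_edge_addition(self):
        rng = np.random.default_rng(7)
        drgn, digns, ppin, gcn = random_primaries(rng, 6, 15, 6, 0.1)
        recipe = CompositionRecipe("n", (drgn, ppin, digns[0]))
        before = compose(recipe)
        bigger = TypedNetwork.from_edges(
            NetworkRole.PPIN, "ppin",
            set(ppin.edges) | {("g0", "g7"), ("g2", "g11")},
        )
        after = compose(CompositionRecipe("n", (drgn, bigger, digns[0])))
        for pair, w in before.weights.items():
            assert after.weight(*pair) >= w

    def test_middle_orientation_irrelevant(self):
        # canonical storage already makes orientation immaterial: loading
        # reversed edges yields the identical network, hence weights
        edges = [("g1", "g2"), ("g3", "g2"), ("g4", "g1")]
        fwd = TypedNetwork.from_edges(NetworkRole.PPIN, "p", edges)
        rev = TypedNetwork.from_edges(
            NetworkRole.PPIN, "p", [(b, a) for a, b in edges]
        )
        assert fwd == rev

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_length2_weight_is_shared_gene_count(self, seed):
        """Direct composition weight equals |genes(d) ∩ genes(s)|."""
        rng = np.random.default_rng(seed)
        drgn, digns, *_ = random_primaries(rng, 5, 12, 5, 0.2)
        composed = compose(CompositionRecipe("n", (drgn, digns[0])))
        drug_genes = {}
        for d, g in drgn.edges:
            drug_genes.setdefault(d, set()).add(g)
        dis_genes = {}
        for s, g in digns[0].edges:
            dis_genes.setdefault(s, set()).add(g)
        for d, genes in drug_genes.items():
            for s, sg in dis_genes.items():
                assert composed.weight(d, s) == len(genes & sg)


def test_compose_all_summaries_and_empty_drgn(caplog):
    drgn = net(NetworkRole.DRGN, "drgn", [])
    digns = [
        net(NetworkRole.DIGN, f"dign{i}", [("s1", "g1")]) for i in range(3)
    ]
    ppin = net(NetworkRole.PPIN, "ppin", [("g1", "g2")])
    gcn = net(NetworkRole.GCN, "gcn", [("g1", "g2")])
    import logging

    with caplog.at_level(logging.INFO, logger="repcool.composition"):
        nets = compose_all(default_recipes(drgn, digns, ppin, gcn))
    assert len(nets) == 9
    assert all(len(n) == 0 for n in nets)  # vacuous composition
    assert sum("associations" in r.message for r in caplog.records) == 9
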