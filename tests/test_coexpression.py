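import math

import numpy as np
import pandas as pd
import pytest

from solatlas import (
    build_network,
    family_enrichment,
    mutual_rank,
    pcc_matrix,
    seed_neighborhood,
)
from solatlas.coexpression import NetworkError, resolve_pcc_cutoff
from solatlas.synthetic import SimulationConfig, simulate_modules

from conftest import make_expression


def random_pcc(rng, n):
    """Random symmetric correlation-like matrix with unit diagonal."""
    X = rng.normal(size=(n, max(8, n)))
    corr = np.corrcoef(X)
    ids = [f"g{i:02d}" for i in range(n)]
    return pd.DataFrame(corr, index=ids, columns=ids)


def oracle_mutual_rank(pcc: pd.DataFrame) -> np.ndarray:
    """Exhaustive double-loop MR with descending-PCC, ascending-id ranks."""
    ids = list(pcc.index)
    n = len(ids)
    arr = pcc.to_numpy()
    rank = np.zeros((n, n))
    for a in range(n):
        partners = sorted(
            (h for h in range(n) if h != a),
            key=lambda h: (-arr[a, h], ids[h]),
        )
        for pos, h in enumerate(partners, start=1):
            rank[a, h] = pos
    mr = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a != b:
                mr[a, b] = math.sqrt(rank[a, b] * rank[b, a])
    return mr


class TestPccMatrix:
    def test_affine_partner_has_correlation_one(self):
        base = [1.0, 3.0, 7.0, 15.0, 31.0]
        expr = make_expression(
            {f"s{j}": [base[j], 2 * base[j]] for j in range(5)},
            genes=["A", "B"],
            organs={f"s{j}": "leaf" for j in range(5)},
        )
        pcc = pcc_matrix(expr, transform="none")
        assert pcc.loc["A", "B"] == pytest.approx(1.0)

    def test_negated_partner_has_correlation_minus_one(self):
        base = [1.0, 3.0, 7.0, 15.0, 31.0]
        expr = make_expression(
            {f"s{j}": [base[j], 40.0 - base[j]] for j in range(5)},
            genes=["A", "C"],
            organs={f"s{j}": "root" for j in range(5)},
        )
        pcc = pcc_matrix(expr, transform="none")
        assert pcc.loc["A", "C"] == pytest.approx(-1.0)

    def test_matches_two_pass_covariance_oracle(self, rng):
        X = rng.uniform(0, 100, size=(10, 12))
        frame = pd.DataFrame(
            X, index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(12)],
        )
        pcc = pcc_matrix(frame, transform="none").to_numpy()
        for a in range(10):
            for b in range(10):
                xa, xb = X[a], X[b]
                cov = np.mean((xa - xa.mean()) * (xb - xb.mean()))
                expected = cov / (xa.std() * xb.std())
                assert pcc[a, b] == pytest.approx(expected, abs=1e-10)

    def test_constant_gene_gets_zero_correlations(self):
        expr = make_expression(
            {f"s{j}": [float(j), 5.0] for j in range(4)},
            genes=["A", "flat"],
            organs={f"s{j}": "stem" for j in range(4)},
        )
        pcc = pcc_matrix(expr, transform="none")
        assert pcc.loc["flat", "A"] == 0.0
        assert pcc.loc["flat", "flat"] == 1.0

    def test_too_few_samples_rejected(self):
        expr = make_expression(
            {"s1": [1.0], "s2": [2.0]}, genes=["A"],
            organs={"s1": "root", "s2": "root"},
        )
        with pytest.raises(NetworkError, match="3 samples"):
            pcc_matrix(expr)


class TestMutualRank:
    def test_mutual_top_partners_have_mr_one(self):
        ids = ["a", "b", "c"]
        arr = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
        mr = mutual_rank(pd.DataFrame(arr, index=ids, columns=ids))
        assert mr.loc["a", "b"] == 1.0

    def test_rank_pair_2_8_gives_mr_4(self):
        # direct formula: sqrt(2 × 8) = 4
        assert math.sqrt(2 * 8) == 4.0
        rng = np.random.default_rng(42)
        for _ in range(20):
            pcc = random_pcc(rng, 10)
            mr = mutual_rank(pcc)
            oracle = oracle_mutual_rank(pcc)
            found = np.argwhere(np.isclose(oracle, 4.0))
            for a, b in found:
                assert mr.iloc[a, b] == pytest.approx(4.0)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(5):
            pcc = random_pcc(rng, 8)
            mr = mutual_rank(pcc)
            np.testing.assert_allclose(mr.to_numpy(), oracle_mutual_rank(pcc))

    def test_symmetric_and_at_least_one(self, rng):
        pcc = random_pcc(rng, 12)
        mr = mutual_rank(pcc).to_numpy()
        np.testing.assert_allclose(mr, mr.T)
        off = mr[~np.eye(12, dtype=bool)]
        assert (off >= 1.0).all()

    def test_invariant_under_monotone_pcc_transform(self, rng):
        pcc = random_pcc(rng, 9)
        shrunk = pd.DataFrame(
            np.tanh(2 * pcc.to_numpy()), index=pcc.index, columns=pcc.columns
        )
        np.testing.assert_allclose(
            mutual_rank(pcc).to_numpy(), mutual_rank(shrunk).to_numpy()
        )

    def test_asymmetric_input_rejected(self):
        arr = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(NetworkError, match="symmetric"):
            mutual_rank(pd.DataFrame(arr, index=["a", "b"], columns=["a", "b"]))


def oracle_network(pcc, mr, cutoff, mr_cutoff, top_n):
    """Brute-force edge filter over every pair."""
    ids = list(pcc.index)
    n = len(ids)
    M = mr.to_numpy()
    tops = []
    for g in range(n):
        partners = sorted(
            (h for h in range(n) if h != g), key=lambda h: (M[g, h], ids[h])
        )
        tops.append(set(partners[:top_n]))
    edges = set()
    for a in range(n):
        for b in range(a + 1, n):
            if pcc.iloc[a, b] >= cutoff and (
                b in tops[a] or a in tops[b] or M[a, b] <= mr_cutoff
            ):
                edges.add((ids[a], ids[b]))
    return edges


class TestBuildNetwork:
    def test_clique_retained(self):
        ids = ["a", "b", "c"]
        arr = np.full((3, 3), 0.9)
        np.fill_diagonal(arr, 1.0)
        pcc = pd.DataFrame(arr, index=ids, columns=ids)
        net = build_network(pcc, mutual_rank(pcc), pcc_cutoff=0.57)
        assert len(net) == 3

    def test_pcc_gate_is_conjunctive(self):
        # strong mutual rank cannot rescue a weak correlation
        ids = ["a", "b", "c", "d"]
        arr = np.eye(4)
        arr[0, 1] = arr[1, 0] = 0.4
        arr[2, 3] = arr[3, 2] = 0.9
        pcc = pd.DataFrame(arr, index=ids, columns=ids)
        net = build_network(pcc, mutual_rank(pcc), pcc_cutoff=0.57)
        kept = set(map(tuple, net.edges[["gene_a", "gene_b"]].to_numpy()))
        assert ("a", "b") not in kept
        assert ("c", "d") in kept

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for n in (10, 30, 50):
            pcc = random_pcc(rng, n)
            mr = mutual_rank(pcc)
            cutoff = resolve_pcc_cutoff(pcc, ("quantile", 0.95))
            net = build_network(pcc, mr, pcc_cutoff=cutoff)
            got = set(map(tuple, net.edges[["gene_a", "gene_b"]].to_numpy()))
            assert got == oracle_network(pcc, mr, cutoff, 30, 3)

    def test_monotone_in_cutoffs(self, rng):
        pcc = random_pcc(rng, 25)
        mr = mutual_rank(pcc)
        sizes_pcc = [
            len(build_network(pcc, mr, pcc_cutoff=c))
            for c in (0.0, 0.2, 0.4, 0.6)
        ]
        assert sizes_pcc == sorted(sizes_pcc, reverse=True)
        sizes_mr = [
            len(build_network(pcc, mr, pcc_cutoff=0.1, mr_cutoff=m))
            for m in (1, 5, 15, 30)
        ]
        assert sizes_mr == sorted(sizes_mr)
        sizes_top = [
            len(build_network(pcc, mr, pcc_cutoff=0.1, mr_cutoff=0, top_n=t))
            for t in (1, 3, 6)
        ]
        assert sizes_top == sorted(sizes_top)

    def test_bad_cutoff_spec_rejected(self, rng):
        pcc = random_pcc(rng, 5)
        with pytest.raises(NetworkError, match="cutoff"):
            build_network(pcc, mutual_rank(pcc), pcc_cutoff="high")


class TestSeedNeighborhood:
    def test_isolated_seed_has_no_partners(self, rng):
        pcc = random_pcc(rng, 10)
        seed = pcc.index[0]
        pcc.loc[seed, :] = 0.0
        pcc.loc[:, seed] = 0.0
        pcc.loc[seed, seed] = 1.0
        per_seed, union, _ = seed_neighborhood(pcc, [seed])
        assert per_seed[seed] == frozenset()
        assert union == frozenset()

    def test_shared_partner_counted_once(self):
        ids = ["s1", "s2", "p", "q"]
        arr = np.eye(4)
        arr[0, 2] = arr[2, 0] = 0.95
        arr[1, 2] = arr[2, 1] = 0.94
        arr[0, 1] = arr[1, 0] = 0.05
        pcc = pd.DataFrame(arr, index=ids, columns=ids)
        per_seed, union, thr = seed_neighborhood(pcc, ["s1", "s2"],
                                                 pcc_quantile=0.5)
        assert "p" in per_seed["s1"] and "p" in per_seed["s2"]
        assert union == frozenset({"p"})  # seeds excluded, no double count

    def test_unknown_seed_listed(self, rng):
        pcc = random_pcc(rng, 5)
        with pytest.raises(NetworkError, match="nope"):
            seed_neighborhood(pcc, ["nope"])

    def test_planted_module_recall(self):
        mods = simulate_modules(SimulationConfig(seed=13))
        pcc = pcc_matrix(mods.expression)
        per_seed, union, _ = seed_neighborhood(pcc, mods.seeds)
        module = set(
            mods.truth.to_frame()
            .query("truth_class == 'module_1'")["gene_id"]
        ) - set(mods.seeds)
        recall = len(per_seed[mods.seeds[0]] & module) / len(module)
        assert recall >= 0.95


class TestFamilyEnrichment:
    def test_planted_family_is_top_hit(self):
        mods = simulate_modules(SimulationConfig(seed=13))
        pcc = pcc_matrix(mods.expression)
        _, union, _ = seed_neighborhood(pcc, mods.seeds)
        results = family_enrichment(
            union, mods.families, frozenset(pcc.index)
        )
        assert results[0].term_id == "FAM_planted_1"
        assert results[0].padj < 0.05

    def test_all_partners_in_one_family_matches_enumeration(self):
        from solatlas.expression_io import AnnotationTable

        background = {f"g{i}" for i in range(100)}
        fam_members = {f"g{i}" for i in range(6)}
        families = AnnotationTable({g: frozenset({"F"}) for g in fam_members})
        results = family_enrichment(fam_members, families, background)
        # k = n = K = 6: p = C(6,6)C(94,0)/C(100,6)
        expected = 1 / math.comb(100, 6)
        assert results[0].p == pytest.approx(expected, rel=1e-9)
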