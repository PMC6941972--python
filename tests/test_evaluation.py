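"""Evaluation metrics: similarity, SA filter, scaffolds, NN search, rank test."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from gexmol import evaluation as ev
from gexmol.exceptions import ConfigurationError, ShapeError, SmilesParseError


class TestSimilarity:
    @pytest.mark.parametrize("metric", ["maccs", "morgan", "fraggle"])
    def test_identical_molecules_score_one(self, metric):
        rec = ev.similarity("CCOc1ccccc1", "CCOc1ccccc1", metric)
        assert rec.value == pytest.approx(1.0)

    def test_morgan_parameters(self):
        assert ev.MORGAN_RADIUS == 3 and ev.MORGAN_BITS == 1024

    def test_maccs_matches_hand_counted_tanimoto(self):
        """Independent oracle: count common/total set bits directly."""
        a = MACCSkeys.GenMACCSKeys(Chem.MolFromSmiles("CCO"))
        b = MACCSkeys.GenMACCSKeys(Chem.MolFromSmiles("c1ccccc1"))
        bits_a = set(a.GetOnBits())
        bits_b = set(b.GetOnBits())
        expected = len(bits_a & bits_b) / len(bits_a | bits_b)
        assert ev.similarity("CCO", "c1ccccc1", "maccs").value == pytest.approx(expected)

    @pytest.mark.parametrize("metric", ["maccs", "morgan"])
    def test_fingerprint_similarity_symmetric(self, metric):
        pairs = [("CCO", "CCN"), ("c1ccccc1", "Cc1ccccc1"), ("CC(=O)O", "CCOC")]
        for a, b in pairs:
            assert ev.similarity(a, b, metric).value == pytest.approx(
                ev.similarity(b, a, metric).value
            )

    def test_values_within_unit_interval(self):
        mols = ["CCO", "CCCC", "c1ccncc1", "CC(C)O", "COC"]
        for a, b in itertools.combinations(mols, 2):
            for metric in ("maccs", "morgan"):
                assert 0.0 <= ev.similarity(a, b, metric).value <= 1.0

    def test_unknown_metric_and_bad_smiles_rejected(self):
        with pytest.raises(ConfigurationError):
            ev.similarity("CCO", "CCN", "dice")
        with pytest.raises(SmilesParseError):
            ev.similarity("zzz", "CCN", "maccs")


class TestMaxSimilarityToSet:
    ACTIVES = ["CCO", "CCN", "c1ccccc1", "CC(=O)O", "CCCC"]

    def test_query_in_actives_scores_one(self):
        rec = ev.max_similarity_to_set("CCO", self.ACTIVES, "maccs")
        assert rec.value == pytest.approx(1.0)
        assert rec.reference == "CCO"

    def test_singleton_equals_pairwise(self):
        rec = ev.max_similarity_to_set("CCO", ["CCN"], "morgan")
        assert rec.value == ev.similarity("CCO", "CCN", "morgan").value

    def test_matches_brute_force_maximum(self):
        query = "CCOC"
        best = max(
            (ev.similarity(query, ref, "maccs").value for ref in self.ACTIVES)
        )
        assert ev.max_similarity_to_set(query, self.ACTIVES, "maccs").value == best

    def test_empty_actives_rejected(self):
        with pytest.raises(ConfigurationError):
            ev.max_similarity_to_set("CCO", [])


class TestSaFilter:
    def test_threshold_default(self):
        assert ev.SA_THRESHOLD == 4.5

    def test_empty_list_passes_through(self):
        assert ev.sa_filter([]) == []

    def test_ethanol_retained(self):
        assert ev.sa_score("CCO") < 4.5
        assert ev.sa_filter(["CCO"]) == ["CCO"]

    def test_unparseable_skipped_with_log(self, caplog):
        assert ev.sa_filter(["CCO", "not-a-molecule"]) == ["CCO"]


class TestScaffoldOverlap:
    def test_disjoint_scaffolds_zero(self):
        count, shared = ev.scaffold_overlap(["c1ccccc1"], ["C1CCCCC1C1CCCCC1"])
        assert count == 0 and shared == []

    def test_identical_sets_full_overlap(self):
        mols = ["Cc1ccccc1", "CCc1ccncc1"]
        count, shared = ev.scaffold_overlap(mols, mols)
        assert count == 2

    def test_toluene_ethylbenzene_share_benzene(self):
        count, shared = ev.scaffold_overlap(["Cc1ccccc1"], ["CCc1ccccc1"])
        assert count == 1 and shared == ["c1ccccc1"]

    def test_generic_abstraction_merges_heteroaromatics(self):
        # pyridine and benzene differ as scaffolds but share the generic ring
        count, _ = ev.scaffold_overlap(["c1ccncc1"], ["c1ccccc1"], generic=False)
        generic_count, shared = ev.scaffold_overlap(["c1ccncc1"], ["c1ccccc1"], generic=True)
        assert count == 0 and generic_count == 1
        assert shared == ["C1CCCCC1"]


class TestSignatureNnSearch:
    def test_query_equal_to_library_row_distance_zero(self):
        lib = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        idx, dist = ev.signature_nn_search(lib[1], lib, "euclidean")
        assert idx == 1 and dist == pytest.approx(0.0)

    @pytest.mark.parametrize("metric", ["euclidean", "cosine"])
    def test_matches_exhaustive_scan(self, metric):
        rng = np.random.default_rng(2)
        lib = rng.normal(size=(1000, 8))
        query = rng.normal(size=8)
        idx, dist = ev.signature_nn_search(query, lib, metric)
        if metric == "euclidean":
            all_d = np.linalg.norm(lib - query, axis=1)
        else:
            all_d = 1 - lib @ query / (np.linalg.norm(lib, axis=1) * np.linalg.norm(query))
        assert idx == int(np.argmin(all_d))
        assert dist == pytest.approx(float(all_d.min()))

    def test_euclidean_and_cosine_disagree_on_scaled_vectors(self):
        v = np.array([1.0, 0.0])
        w = np.array([2.0, 0.5])
        lib = np.stack([v, w])
        query = 2.0 * v  # same direction as v, but nearer to w in norm
        idx_cos, _ = ev.signature_nn_search(query, lib, "cosine")
        idx_euc, _ = ev.signature_nn_search(query, lib, "euclidean")
        assert idx_cos == 0 and idx_euc != 0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            ev.signature_nn_search(np.ones(3), np.ones((5, 4)))

    def test_empty_library_rejected(self):
        with pytest.raises(ConfigurationError):
            ev.signature_nn_search(np.ones(3), np.zeros((0, 3)))


def exact_mwu_oracle(a, b):
    """Exhaustive pair counting + permutation enumeration of the U null."""
    a, b = list(a), list(b)
    u = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
    pooled = a + b
    n = len(a)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        sel = set(combo)
        ga = [pooled[i] for i in sel]
        gb = [pooled[i] for i in range(len(pooled)) if i not in sel]
        u_perm = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in ga for y in gb)
        total += 1
        count += u_perm >= u
    return u, count / total


class TestMannWhitney:
    def test_all_pairs_won_u_is_nine(self):
        u, _ = ev.mann_whitney_u_greater([0.9, 0.9, 0.9], [0.1, 0.1, 0.1])
        assert u == 9.0

    @pytest.mark.parametrize("na,nb", [(2, 3), (4, 4), (5, 3), (8, 8), (6, 2)])
    def test_matches_exact_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        a = rng.normal(size=na)
        b = rng.normal(size=nb)
        u, p = ev.mann_whitney_u_greater(a, b)
        u_expected, p_expected = exact_mwu_oracle(a, b)
        assert u == pytest.approx(u_expected)
        assert p == pytest.approx(p_expected, abs=1e-12)

    def test_identical_sets_p_around_half(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=50)
        _, p = ev.mann_whitney_u_greater(scores, scores)
        assert 0.4 < p < 0.6


class TestGenerationReportInvariants:
    def test_count_chain_enforced(self):
        with pytest.raises(ValueError):
            ev.GenerationReport(generated=10, valid=11, unique_valid=5, synthesizable=0)
        with pytest.raises(ValueError):
            ev.GenerationReport(generated=10, valid=5, unique_valid=6, synthesizable=0)
        with pytest.raises(ValueError):
            ev.GenerationReport(generated=10, valid=5, unique_valid=5, synthesizable=6)

    def test_fractions(self):
        rep = ev.GenerationReport(generated=10, valid=5, unique_valid=4, synthesizable=2)
        assert rep.valid_fraction == 0.5
        assert rep.unique_fraction == 0.4
        assert rep.synthesizable_fraction == 0.2
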