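import numpy as np
import pytest

from conkatseq.network import DomainNetwork, NetworkNode
from conkatseq.similarity import (
    ReferenceBGC,
    align_identity,
    best_assignment,
    classify_novelty,
    compare_networks,
    score_network_vs_reference,
    translate_variant,
    validate_network_on_contig,
    DomainMatch,
    SimilarityResult,
)

from _oracles import best_injective_assignment, gotoh_local_score

RNG = np.random.default_rng(2024)

CODON = {
    "M": "ATG", "A": "GCT", "L": "CTG", "K": "AAA", "F": "TTT", "G": "GGT",
    "P": "CCG", "W": "TGG", "D": "GAT", "E": "GAA", "V": "GTT", "S": "TCT",
    "T": "ACT", "Y": "TAT", "H": "CAT", "N": "AAT", "I": "ATT", "R": "CGT",
    "Q": "CAA", "C": "TGT",
}


def encode(protein: str) -> str:
    return "".join(CODON[aa] for aa in protein)


def random_protein(n, rng=RNG) -> str:
    return "".join(rng.choice(list(CODON), n))


def make_net(node_seqs: dict[str, str], domain_type="AD") -> DomainNetwork:
    ids = sorted(node_seqs)
    nodes = {
        vid: NetworkNode(vid, node_seqs[vid], domain_type, frozenset({"s1", "s2", "s3"}), 10)
        for vid in ids
    }
    edges = [(ids[i], ids[i + 1], 1e-8) for i in range(len(ids) - 1)]
    return DomainNetwork(network_id=f"net_{ids[0]}", nodes=nodes, edges=edges)


class TestTranslate:
    def test_frame_zero(self):
        assert translate_variant("ATGGCT", frame=0) == "MA"

    def test_auto_picks_frame_with_fewest_stops(self):
        # encodes RMLTMCNV in frame 1; frames 0 and 2 each hold an internal stop
        nt = "ACGTATGCTGACTATGTGTAATGTT"
        assert translate_variant(nt, frame=0)[:-1].count("*") == 1
        assert translate_variant(nt, frame=2)[:-1].count("*") == 1
        auto = translate_variant(nt, frame="auto")
        assert auto == translate_variant(nt, frame=1) == "RMLTMCNV"
        assert "*" not in auto

    def test_short_input_frame_two(self):
        assert len(translate_variant("ATGCC", frame=2)) == 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            translate_variant("AT", frame=0)


class TestAlignIdentity:
    def test_exact_substring(self):
        target = random_protein(120)
        query = target[30:70]
        m = align_identity(query, target)
        assert m.identity == pytest.approx(1.0)
        assert m.query_coverage == pytest.approx(1.0)
        assert m.target_interval == (30, 70)

    def test_low_coverage_returns_none(self):
        target = random_protein(80)
        # half the query matches, half is an unrelated tail
        query = target[10:30] + "W" * 20
        m = align_identity(query, target, min_cov=0.80)
        if m is not None:
            assert m.query_coverage >= 0.80  # contract: never under threshold

    def test_score_matches_affine_dp_oracle(self):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(9)
        for _ in range(10):
            q = random_protein(15, rng)
            t = random_protein(40, rng)
            from conkatseq.similarity import _protein_aligner

            score = _protein_aligner().align(q, t).score
            assert score == pytest.approx(gotoh_local_score(q, t, blosum))


class TestBestAssignment:
    def test_matches_exhaustive_injective_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n_nodes, n_pos = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            node_hits = {}
            weights = {}
            for ni in range(n_nodes):
                hits = []
                for pi in range(n_pos):
                    if rng.random() < 0.6:
                        ident = float(np.round(rng.random(), 3))
                        if ident > 0:
                            hits.append(
                                DomainMatch(
                                    node=f"n{ni}",
                                    target_protein=f"p{pi}",
                                    target_interval=(0, 100),
                                    identity=ident,
                                    query_coverage=1.0,
                                )
                            )
                            weights[(f"n{ni}", f"p{pi}")] = ident
                node_hits[f"n{ni}"] = hits
            assignment = best_assignment(node_hits)
            total = sum(m.identity for m in assignment.values())
            assert total == pytest.approx(best_injective_assignment(weights))

    def test_overlapping_intervals_form_one_position(self):
        # two nodes hitting the same region of one protein cannot both match
        hits = {
            "a": [DomainMatch("a", "p", (0, 100), 0.9, 1.0)],
            "b": [DomainMatch("b", "p", (10, 110), 0.8, 1.0)],
        }
        assignment = best_assignment(hits)
        assert list(assignment) == ["a"]

    def test_distant_intervals_are_independent(self):
        hits = {
            "a": [DomainMatch("a", "p", (0, 100), 0.9, 1.0)],
            "b": [DomainMatch("b", "p", (200, 300), 0.8, 1.0)],
        }
        assignment = best_assignment(hits)
        assert sorted(assignment) == ["a", "b"]


class TestScoreNetwork:
    def _four_domain_net(self):
        proteins = [random_protein(40) for _ in range(4)]
        return make_net({f"d{i}": encode(p) for i, p in enumerate(proteins)}), proteins

    def test_perfect_match_scores_100(self):
        net, proteins = self._four_domain_net()
        ref = ReferenceBGC(
            "ref1", [(f"p{i}", "".join(RNG.choice(list(CODON), 10)) + p + "".join(RNG.choice(list(CODON), 10))) for i, p in enumerate(proteins)]
        )
        res = score_network_vs_reference(net, ref)
        assert res.classification == "related"
        assert res.matched_fraction == pytest.approx(1.0)
        assert res.score == pytest.approx(100.0)

    def test_half_matched_median_includes_zeros(self):
        # two domains match two reference proteins, two match nothing:
        # median of {0, 0, id1, id2}
        net, proteins = self._four_domain_net()
        ref = ReferenceBGC("ref1", [("p0", proteins[0]), ("p1", proteins[1])])
        res = score_network_vs_reference(net, ref)
        assert res.classification == "related"
        assert res.matched_fraction == pytest.approx(0.5)
        assert res.score == pytest.approx((100.0 + 0.0) / 2)

    def test_quarter_matched_is_unrelated(self):
        net, proteins = self._four_domain_net()
        ref = ReferenceBGC("ref1", [("p0", proteins[0])])
        res = score_network_vs_reference(net, ref)
        assert res.classification == "unrelated"
        assert res.matched_fraction == pytest.approx(0.25)
        assert res.score is None

    def test_score_invariant_to_duplicate_reference_proteins(self):
        net, proteins = self._four_domain_net()
        ref = ReferenceBGC("r", [(f"p{i}", p) for i, p in enumerate(proteins)])
        dup = ReferenceBGC(
            "r2", [(f"p{i}", p) for i, p in enumerate(proteins + proteins)]
        )
        a = score_network_vs_reference(net, ref)
        b = score_network_vs_reference(net, dup)
        assert a.score == pytest.approx(b.score)
        assert a.matched_fraction == pytest.approx(b.matched_fraction)


class TestClassification:
    def _result(self, score, classification="related"):
        return SimilarityResult("n", "t", 1.0, score, classification)

    @pytest.mark.parametrize(
        "score,expected", [(80.0, "known"), (75.0, "known"), (70.0, "novel")]
    )
    def test_threshold_step(self, score, expected):
        assert classify_novelty([self._result(score)]) == expected

    def test_no_related_results_is_novel(self):
        assert classify_novelty([]) == "novel"
        assert classify_novelty([SimilarityResult("n", "t", 0.2, None, "unrelated")]) == "novel"


class TestCompareNetworks:
    def test_identical_networks_related(self):
        net, _ = TestScoreNetwork()._four_domain_net()
        assert compare_networks(net, net) is True

    def test_boundary_half_shared(self):
        proteins = [random_protein(40) for _ in range(4)]
        net_a = make_net({f"a{i}": encode(p) for i, p in enumerate(proteins)})
        others = [random_protein(40) for _ in range(2)]
        net_b = make_net(
            {
                "b0": encode(proteins[0]),
                "b1": encode(proteins[1]),
                "b2": encode(others[0]),
                "b3": encode(others[1]),
            }
        )
        assert compare_networks(net_a, net_b) is True  # exactly 50% at >=90%

    def test_all_distant_unrelated(self):
        net_a = make_net({f"a{i}": encode(random_protein(40)) for i in range(4)})
        net_b = make_net({f"b{i}": encode(random_protein(40)) for i in range(4)})
        assert compare_networks(net_a, net_b) is False


class TestValidateOnContig:
    def _contig_with(self, seqs, rng):
        spacer = lambda: "".join(rng.choice(list("ACGT"), 200))
        return spacer() + spacer().join(seqs) + spacer()

    def test_all_embedded(self):
        rng = np.random.default_rng(15)
        seqs = ["".join(rng.choice(list("ACGT"), 120)) for _ in range(5)]
        net = make_net({f"d{i}": s for i, s in enumerate(seqs)})
        contig = self._contig_with(seqs, rng)
        assert validate_network_on_contig(net, contig) == (5, 0)

    def test_one_absent(self):
        rng = np.random.default_rng(16)
        seqs = ["".join(rng.choice(list("ACGT"), 120)) for _ in range(5)]
        net = make_net({f"d{i}": s for i, s in enumerate(seqs)})
        contig = self._contig_with(seqs[:4], rng)
        assert validate_network_on_contig(net, contig) == (4, 1)

    def test_reverse_strand_found(self):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), 120))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        net = make_net({"d0": seq, "d1": seq[:60] + seq[60:], "d2": seq})
        contig = self._contig_with([rc], rng)
        ok, bad = validate_network_on_contig(net, contig)
        assert ok == 3

    def test_mutated_beyond_threshold_is_false(self):
        rng = np.random.default_rng(18)
        seq = "".join(rng.choice(list("ACGT"), 200))
        pos = rng.choice(200, size=20, replace=False)  # 10% mutated
        mutated = list(seq)
        for p in pos:
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        net = make_net({"d0": "".join(mutated), "d1": seq, "d2": seq})
        contig = self._contig_with([seq], rng)
        ok, bad = validate_network_on_contig(net, contig, id_threshold=0.93)
        assert (ok, bad) == (2, 1)

    def test_counts_always_sum_to_nodes(self):
        rng = np.random.default_rng(19)
        net = make_net({f"d{i}": "".join(rng.choice(list("ACGT"), 90)) for i in range(4)})
        ok, bad = validate_network_on_contig(net, "".join(rng.choice(list("ACGT"), 500)))
        assert ok + bad == 4
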