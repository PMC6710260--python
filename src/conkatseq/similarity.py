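"""Scoring domain networks against reference BGCs, other networks and contigs.

A domain network is compared to a reference biosynthetic gene cluster by
translating each node's centroid, locally aligning it against the reference
proteins (BLOSUM62, affine gaps, query coverage >= 80%), and finding the best
combination of matches: an assignment of nodes to *independent* reference
positions — intervals that do not substantially overlap — maximizing total
identity.  If at least half the network's domains are matched, the network is
"related" to that reference and receives a similarity score: the median
percent identity over ALL of its domains, with unmatched domains entering as
zero.  A network is "known" when it relates to some reference at >= 75%
identity, otherwise novel; two networks from different samples are closely
related when >= 50% of one's domains match the other at >= 90% identity.
Networks are validated against assembled clone/contig sequences at the
nucleotide level with a 93% identity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import linear_sum_assignment

from .network import DomainNetwork

__all__ = [
    "ReferenceBGC",
    "DomainMatch",
    "SimilarityResult",
    "translate_variant",
    "align_identity",
    "score_network_vs_reference",
    "classify_novelty",
    "compare_networks",
    "validate_network_on_contig",
    "read_reference_fasta",
]

DEFAULT_MIN_COV = 0.80
DEFAULT_MIN_MATCH_FRAC = 0.5
DEFAULT_KNOWN_IDENTITY = 75.0
DEFAULT_CROSS_IDENTITY = 90.0
DEFAULT_CONTIG_IDENTITY = 0.93
# Two reference intervals conflict (are the same "position") when they overlap
# by more than this fraction of both intervals.
RECIPROCAL_OVERLAP = 0.25

_CODON_TABLE_ID = 1  # the standard genetic code


@dataclass(frozen=True)
class ReferenceBGC:
    """A reference gene cluster: a set of protein sequences under one id."""

    bgc_id: str
    proteins: list[tuple[str, str]]  # (protein_id, amino-acid sequence)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError("reference BGC must contain at least one protein")


@dataclass(frozen=True)
class DomainMatch:
    node: str
    target_protein: str
    target_interval: tuple[int, int]  # [start, end) in aa coordinates
    identity: float
    query_coverage: float


@dataclass(frozen=True)
class SimilarityResult:
    network_id: str
    target_id: str
    matched_fraction: float
    score: Optional[float]  # median percent identity; None when unrelated
    classification: str  # "related" | "unrelated"


def translate_variant(centroid: str, frame: Union[int, str] = "auto") -> str:
    """Translate a nucleotide centroid in a fixed or automatic reading frame.

    ``frame="auto"`` picks the frame with the fewest internal stop codons
    (ties to the lowest frame index); internal stops are retained as ``*``
    symbols so they penalize downstream alignment rather than truncating it.
    """
    from Bio.Seq import Seq

    def _translate(offset: int) -> str:
        sub = centroid[offset:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            raise ValueError("sequence too short to translate")
        return str(Seq(sub).translate(table=_CODON_TABLE_ID))

    if frame == "auto":
        best: Optional[tuple[int, int, str]] = None
        for offset in range(3):
            try:
                prot = _translate(offset)
            except ValueError:
                continue
            internal_stops = prot[:-1].count("*")
            if best is None or internal_stops < best[0]:
                best = (internal_stops, offset, prot)
        if best is None:
            raise ValueError("sequence too short to translate")
        return best[2]
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1, 2 or 'auto'")
    return _translate(frame)


_PROTEIN_ALIGNER = None
_NT_ALIGNER = None


def _protein_aligner():
    global _PROTEIN_ALIGNER
    if _PROTEIN_ALIGNER is None:
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        _PROTEIN_ALIGNER = aligner
    return _PROTEIN_ALIGNER


def _nt_local_aligner():
    global _NT_ALIGNER
    if _NT_ALIGNER is None:
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        _NT_ALIGNER = aligner
    return _NT_ALIGNER


def _alignment_stats(alignment, query_len: int):
    """(identity, query_coverage, target_interval) of a local alignment."""
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / columns if columns else 0.0
    query_spans, target_spans = alignment.aligned  # align(query, target) order
    covered = int(sum(end - start for start, end in query_spans))
    interval = (int(target_spans[0][0]), int(target_spans[-1][1]))
    return identity, covered / query_len, interval


def align_identity(
    query: str, target: str, min_cov: float = DEFAULT_MIN_COV, node: str = ""
) -> Optional[DomainMatch]:
    """Best local protein alignment of ``query`` against ``target``.

    BLOSUM62 with affine gaps (-11/-1); identity is identical columns over
    alignment columns and coverage is the fraction of query residues aligned.
    Returns None when no alignment reaches ``min_cov`` query coverage.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    alignments = _protein_aligner().align(query, target)
    try:
        best = alignments[0]
    except IndexError:
        return None
    if best.score <= 0:
        return None
    identity, coverage, interval = _alignment_stats(best, len(query))
    if coverage < min_cov:
        return None
    return DomainMatch(
        node=node,
        target_protein="",
        target_interval=interval,
        identity=identity,
        query_coverage=coverage,
    )


def _intervals_conflict(a: tuple[int, int], b: tuple[int, int]) -> bool:
    overlap = min(a[1], b[1]) - max(a[0], b[0])
    if overlap <= 0:
        return False
    len_a, len_b = a[1] - a[0], b[1] - b[0]
    return overlap > RECIPROCAL_OVERLAP * len_a and overlap > RECIPROCAL_OVERLAP * len_b


def _group_positions(hits: list[DomainMatch]) -> list[int]:
    """Single-linkage grouping of hits into independent reference positions.

    Hits on the same protein whose intervals conflict (reciprocal overlap
    above the threshold) belong to the same position; returns one group index
    per hit.
    """
    n = len(hits)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if hits[i].target_protein != hits[j].target_protein:
                continue
            if _intervals_conflict(hits[i].target_interval, hits[j].target_interval):
                parent[find(i)] = find(j)
    roots = {}
    groups = []
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        groups.append(roots[r])
    return groups


def best_assignment(
    node_hits: dict[str, list[DomainMatch]]
) -> dict[str, DomainMatch]:
    """Best combination of matches: nodes to independent reference positions.

    All hits are grouped into positions; each node's weight toward a position
    is its best hit identity there.  The assignment maximizing total identity
    is solved exactly (Hungarian algorithm); zero-weight pairings count as
    unmatched.
    """
    nodes = sorted(node_hits)
    all_hits = [h for n in nodes for h in node_hits[n]]
    if not all_hits:
        return {}
    groups = _group_positions(all_hits)
    n_positions = max(groups) + 1
    weight = np.zeros((len(nodes), n_positions))
    best_hit: dict[tuple[int, int], DomainMatch] = {}
    offset = 0
    for ni, node in enumerate(nodes):
        for h in node_hits[node]:
            g = groups[offset]
            if h.identity > weight[ni, g]:
                weight[ni, g] = h.identity
                best_hit[(ni, g)] = h
            offset += 1
    row, col = linear_sum_assignment(weight, maximize=True)
    assignment = {}
    for ni, g in zip(row, col):
        if weight[ni, g] > 0:
            assignment[nodes[ni]] = best_hit[(ni, g)]
    return assignment


def _translated_nodes(net: DomainNetwork) -> dict[str, str]:
    proteins = {}
    for vid in net.node_ids():
        centroid = net.nodes[vid].centroid
        if not centroid:
            raise ValueError(f"node {vid} has no centroid sequence")
        proteins[vid] = translate_variant(centroid, frame="auto")
    return proteins


def score_network_vs_reference(
    net: DomainNetwork,
    ref: ReferenceBGC,
    min_match_frac: float = DEFAULT_MIN_MATCH_FRAC,
    min_cov: float = DEFAULT_MIN_COV,
    include_unmatched: bool = True,
) -> SimilarityResult:
    """Similarity of a domain network to one reference BGC.

    The score is the median percent identity over the network's domains under
    the best combination of matches to independent reference positions; with
    ``include_unmatched`` (the default) domains without a match enter the
    median as 0, so a network where half the domains match perfectly scores
    well below 100.  Networks with fewer than ``min_match_frac`` of domains
    matched are classified unrelated and receive no score.
    """
    proteins = _translated_nodes(net)
    node_hits: dict[str, list[DomainMatch]] = {vid: [] for vid in proteins}
    for vid, query in proteins.items():
        for protein_id, target in ref.proteins:
            m = align_identity(query, target, min_cov=min_cov, node=vid)
            if m is not None:
                node_hits[vid].append(
                    DomainMatch(
                        node=vid,
                        target_protein=protein_id,
                        target_interval=m.target_interval,
                        identity=m.identity,
                        query_coverage=m.query_coverage,
                    )
                )
    assignment = best_assignment(node_hits)
    n_nodes = net.n_nodes
    matched_fraction = len(assignment) / n_nodes if n_nodes else 0.0
    if matched_fraction >= min_match_frac and n_nodes:
        identities = [
            100.0 * assignment[vid].identity if vid in assignment else 0.0
            for vid in net.node_ids()
        ]
        if not include_unmatched:
            identities = [x for x in identities if x > 0]
        score = float(np.median(identities))
        classification = "related"
    else:
        score = None
        classification = "unrelated"
    return SimilarityResult(
        network_id=net.network_id,
        target_id=ref.bgc_id,
        matched_fraction=matched_fraction,
        score=score,
        classification=classification,
    )


def classify_novelty(
    results: Iterable[SimilarityResult], known_identity: float = DEFAULT_KNOWN_IDENTITY
) -> str:
    """"known" if any related reference scores >= ``known_identity``, else "novel"."""
    for r in results:
        if r.classification == "related" and r.score is not None and r.score >= known_identity:
            return "known"
    return "novel"


def compare_networks(
    net_a: DomainNetwork,
    net_b: DomainNetwork,
    min_match_frac: float = DEFAULT_MIN_MATCH_FRAC,
    min_identity: float = DEFAULT_CROSS_IDENTITY,
    min_cov: float = DEFAULT_MIN_COV,
) -> bool:
    """Whether ``net_a`` is closely related to ``net_b`` (asymmetric).

    ``net_b``'s translated domains act as the reference: each is an
    independent target, and ``net_a`` is closely related when at least
    ``min_match_frac`` of its domains are assigned a match at or above
    ``min_identity`` percent identity.
    """
    targets = _translated_nodes(net_b)
    proteins = _translated_nodes(net_a)
    node_hits: dict[str, list[DomainMatch]] = {vid: [] for vid in proteins}
    for vid, query in proteins.items():
        for target_id, target in targets.items():
            m = align_identity(query, target, min_cov=min_cov, node=vid)
            if m is not None:
                node_hits[vid].append(
                    DomainMatch(
                        node=vid,
                        target_protein=target_id,
                        target_interval=(0, len(target)),
                        identity=m.identity,
                        query_coverage=m.query_coverage,
                    )
                )
    assignment = best_assignment(node_hits)
    n_nodes = net_a.n_nodes
    if not n_nodes:
        return False
    strong = sum(1 for m in assignment.values() if 100.0 * m.identity >= min_identity)
    return strong / n_nodes >= min_match_frac


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def validate_network_on_contig(
    net: DomainNetwork,
    contig: str,
    id_threshold: float = DEFAULT_CONTIG_IDENTITY,
    min_cov: float = DEFAULT_MIN_COV,
) -> tuple[int, int]:
    """Count validated vs false clustering predictions against a contig.

    Each node centroid is locally aligned against both strands of the contig;
    a node is a validated prediction when its best full-coverage hit reaches
    ``id_threshold`` nucleotide identity, otherwise a false one.  The two
    counts always sum to the node count.
    """
    if not contig:
        raise ValueError("contig must be non-empty")
    aligner = _nt_local_aligner()
    validated = 0
    for vid in net.node_ids():
        centroid = net.nodes[vid].centroid
        best_identity = 0.0
        for strand in (contig, _revcomp(contig)):
            alignments = aligner.align(centroid, strand)
            try:
                top = alignments[0]
            except IndexError:
                continue
            if top.score <= 0:
                continue
            identity, coverage, _ = _alignment_stats(top, len(centroid))
            if coverage >= min_cov:
                best_identity = max(best_identity, identity)
        if best_identity >= id_threshold:
            validated += 1
    return validated, net.n_nodes - validated


def read_reference_fasta(path: Union[str, Path], source: str = "") -> list[ReferenceBGC]:
    """Load reference BGC proteins from FASTA with ``>bgc_id|protein_id`` headers."""
    from Bio import SeqIO

    grouped: dict[str, list[tuple[str, str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"header {rec.id!r} is not of the form bgc_id|protein_id")
        bgc_id, protein_id = rec.id.split("|", 1)
        grouped.setdefault(bgc_id, []).append((protein_id, str(rec.seq).upper()))
    return [
        ReferenceBGC(bgc_id=bgc, proteins=prots, source=source)
        for bgc, prots in sorted(grouped.items())
    ]
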