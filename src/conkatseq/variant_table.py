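"""Dereplication, 95%-identity clustering and the variant x subpool matrix.

Trimmed subpool reads are collapsed to unique (sequence, subpool) records with
counts, pooled across subpools, and greedily clustered at 95% global identity
into *domain variants* — the operational unit of one biosynthetic-domain
observation.  Three filters then remove low-evidence records: an absolute
read-count floor, a 5% floor relative to the cluster centroid's count, and a
requirement that each cluster span at least three distinct library wells
(fewer carries no co-occurrence information).  The surviving clusters become
a boolean occurrence matrix over the full subpool universe, the substrate of
all downstream statistics.

Identity here is ``--iddef 1`` style: identical aligned columns divided by
total alignment columns, gaps counted as columns, from a global end-to-end
alignment under match +1 / mismatch -1 / gap -2.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .debarcode import SubpoolReadSet

__all__ = [
    "UniqueSeq",
    "DomainVariant",
    "OccurrenceMatrix",
    "dereplicate",
    "pairwise_identity",
    "greedy_cluster",
    "filter_clusters",
    "build_occurrence_matrix",
    "merge_tables",
    "uniques_from_demux",
]

# Global-alignment scoring used for all nucleotide identity computations.
MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2

DEFAULT_ID_THRESHOLD = 0.95
DEFAULT_MIN_READS = 2
DEFAULT_REL_FRAC = 0.05
DEFAULT_MIN_WELLS = 3


@dataclass(frozen=True)
class UniqueSeq:
    """A dereplicated read: one distinct sequence in one subpool, with count."""

    seq: str
    subpool_id: Hashable
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not self.seq:
            raise ValueError("sequence must be non-empty")


@dataclass
class DomainVariant:
    """A 95%-identity amplicon cluster: one domain variant.

    ``centroid_count`` is the read count of the founding (most abundant)
    dereplicated record; the relative-abundance filter is taken against it.
    """

    variant_id: str
    centroid: str
    domain_type: str
    members: list[UniqueSeq]
    centroid_count: int

    @property
    def subpool_counts(self) -> dict[Hashable, int]:
        counts: Counter = Counter()
        for m in self.members:
            counts[m.subpool_id] += m.count
        return dict(counts)

    @property
    def subpools(self) -> set:
        return {m.subpool_id for m in self.members}

    @property
    def total_reads(self) -> int:
        return sum(m.count for m in self.members)


def dereplicate(reads: SubpoolReadSet) -> list[UniqueSeq]:
    """Collapse a subpool's reads to unique sequences with propagated counts.

    Output is sorted by count (descending), ties by sequence, and conserves
    the total read count.
    """
    counts = Counter(reads.reads)
    return [
        UniqueSeq(seq=s, subpool_id=reads.subpool_id, count=c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def uniques_from_demux(result, subpool_ids: Optional[dict] = None) -> list[UniqueSeq]:
    """Dereplicate every subpool of a demultiplexing result into one pooled list.

    ``subpool_ids`` optionally remaps (plate, row, col) addresses to other
    identifiers (e.g. the integer subpool indices of a simulation).
    """
    uniques: list[UniqueSeq] = []
    for sp_id, readset in result.subpools.items():
        mapped = subpool_ids[sp_id] if subpool_ids is not None else sp_id
        for u in dereplicate(readset):
            uniques.append(UniqueSeq(seq=u.seq, subpool_id=mapped, count=u.count))
    return uniques


_ALIGNER = None


def _global_aligner():
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = MATCH_SCORE
        aligner.mismatch_score = MISMATCH_SCORE
        aligner.open_gap_score = GAP_SCORE
        aligner.extend_gap_score = GAP_SCORE
        _ALIGNER = aligner
    return _ALIGNER


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the optimal global alignment of a, b.

    End gaps are penalized and counted as alignment columns, so e.g.
    ACGT vs ACG aligns over four columns and scores 0.75.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0
    alignment = _global_aligner().align(a, b)[0]
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / columns


def _hamming_identity_matrix(seq: str, encoded: np.ndarray) -> np.ndarray:
    """Ungapped identity of ``seq`` against each row of an equal-length byte matrix."""
    query = np.frombuffer(seq.encode(), dtype=np.uint8)
    matches = (encoded == query).sum(axis=1)
    return matches / encoded.shape[1]


class _CentroidIndex:
    """Centroids grouped by length for vectorized ungapped-identity screening."""

    def __init__(self) -> None:
        self.order: list[tuple[int, str]] = []  # (cluster index, centroid seq)
        self._by_len: dict[int, tuple[list[int], list[np.ndarray]]] = {}

    def add(self, cluster_idx: int, seq: str) -> None:
        self.order.append((cluster_idx, seq))
        idxs, rows = self._by_len.setdefault(len(seq), ([], []))
        idxs.append(cluster_idx)
        rows.append(np.frombuffer(seq.encode(), dtype=np.uint8))

    def hamming_identities(self, seq: str) -> dict[int, float]:
        group = self._by_len.get(len(seq))
        if group is None:
            return {}
        idxs, rows = group
        ids = _hamming_identity_matrix(seq, np.vstack(rows))
        return dict(zip(idxs, ids))


def greedy_cluster(
    uniques: Iterable[UniqueSeq],
    id_threshold: float = DEFAULT_ID_THRESHOLD,
    domain_type: str = "dom",
    prescreen_band: Optional[float] = 0.10,
) -> list[DomainVariant]:
    """Single-pass greedy centroid clustering of pooled dereplicated records.

    Records are sorted by abundance (descending; ties lexicographic by
    sequence); each joins the first existing centroid whose global identity
    is at or above ``id_threshold``, otherwise it founds a new cluster and
    becomes its (static) centroid.

    For equal-length sequences the ungapped identity is a lower bound on the
    aligned identity under the match/mismatch/gap scoring used here, so a
    centroid passing the ungapped test is accepted without alignment; the
    exact global alignment is computed only for centroids whose ungapped
    identity falls within ``prescreen_band`` below the threshold (or whose
    length differs).  Set ``prescreen_band=None`` to align against every
    length-compatible centroid.
    """
    if not 0 < id_threshold <= 1:
        raise ValueError("id_threshold must be in (0, 1]")
    records = sorted(uniques, key=lambda u: (-u.count, u.seq, str(u.subpool_id)))
    clusters: list[DomainVariant] = []
    index = _CentroidIndex()
    cache: dict[str, int] = {}  # seq -> cluster index (or -1: founded its own)

    for rec in records:
        target = cache.get(rec.seq)
        if target is None:
            target = _scan_centroids(rec.seq, index, id_threshold, prescreen_band)
            cache[rec.seq] = target if target is not None else -1
        elif target == -1:
            target = None
        if target is None:
            cluster_idx = len(clusters)
            clusters.append(
                DomainVariant(
                    variant_id=f"{domain_type}_{cluster_idx:05d}",
                    centroid=rec.seq,
                    domain_type=domain_type,
                    members=[rec],
                    centroid_count=rec.count,
                )
            )
            index.add(cluster_idx, rec.seq)
            cache[rec.seq] = cluster_idx
        else:
            clusters[target].members.append(rec)
    return clusters


def _scan_centroids(
    seq: str,
    index: _CentroidIndex,
    id_threshold: float,
    prescreen_band: Optional[float],
) -> Optional[int]:
    """First centroid (creation order) with aligned identity >= threshold."""
    ham = index.hamming_identities(seq)
    for cluster_idx, centroid in index.order:
        h = ham.get(cluster_idx)
        if h is not None:
            if h >= id_threshold:
                return cluster_idx  # ungapped identity is a lower bound
            if prescreen_band is not None and h < id_threshold - prescreen_band:
                continue
        else:
            # identity <= shorter/longer length; skip hopeless length ratios
            lo, hi = sorted((len(seq), len(centroid)))
            if lo / hi < id_threshold:
                continue
        if pairwise_identity(seq, centroid) >= id_threshold:
            return cluster_idx
    return None


def filter_clusters(
    clusters: Sequence[DomainVariant],
    min_reads: int = DEFAULT_MIN_READS,
    rel_frac: float = DEFAULT_REL_FRAC,
    min_wells: int = DEFAULT_MIN_WELLS,
) -> list[DomainVariant]:
    """Apply the three evidence filters to clustered variants.

    (i) members with fewer than ``min_reads`` reads are removed; (ii) members
    with fewer than ``rel_frac`` times the centroid record's read count are
    removed (the centroid record itself is exempt); (iii) clusters whose
    surviving members span fewer than ``min_wells`` distinct subpools are
    dropped entirely.
    """
    kept: list[DomainVariant] = []
    for cluster in clusters:
        floor = rel_frac * cluster.centroid_count
        survivors = [
            m
            for m in cluster.members
            if m.count >= min_reads
            and (
                m.count >= floor
                or (m.seq == cluster.centroid and m.count == cluster.centroid_count)
            )
        ]
        wells = {m.subpool_id for m in survivors}
        if len(wells) < min_wells:
            continue
        kept.append(
            DomainVariant(
                variant_id=cluster.variant_id,
                centroid=cluster.centroid,
                domain_type=cluster.domain_type,
                members=survivors,
                centroid_count=cluster.centroid_count,
            )
        )
    return kept


class OccurrenceMatrix:
    """Boolean domain-variant x subpool presence table over the full library.

    Wraps a read-count DataFrame (rows = variants, columns = every subpool in
    the library, including subpools where nothing was detected — the total
    subpool number is the Fisher-test population size) plus per-variant
    metadata (domain_type, centroid).  Construction asserts that every
    retained variant is present in at least ``min_wells`` subpools.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        meta: pd.DataFrame,
        min_wells: int = DEFAULT_MIN_WELLS,
    ) -> None:
        if not counts.index.equals(meta.index):
            raise ValueError("counts and meta must share the variant index")
        if counts.index.has_duplicates:
            raise ValueError("duplicate variant_id in matrix")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate subpool_id in matrix")
        prevalence = (counts > 0).sum(axis=1)
        low = prevalence[prevalence < min_wells]
        if len(low):
            raise ValueError(
                f"{len(low)} variant(s) present in fewer than {min_wells} subpools: "
                f"{list(low.index[:5])}"
            )
        self.counts = counts
        self.meta = meta
        self.min_wells = min_wells

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    @property
    def variants(self) -> list:
        return list(self.counts.index)

    @property
    def subpools(self) -> list:
        return list(self.counts.columns)

    @property
    def n_subpools(self) -> int:
        return self.counts.shape[1]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[0]

    def presence_array(self) -> np.ndarray:
        return self.counts.to_numpy() > 0

    def subpool_set(self, variant_id) -> set:
        row = self.counts.loc[variant_id]
        return set(row.index[row > 0])

    def to_tsv(self, path: Union[str, Path]) -> None:
        df = self.counts.copy()
        df.insert(0, "domain_type", self.meta["domain_type"])
        df.insert(1, "centroid", self.meta["centroid"])
        df.to_csv(path, sep="\t", index_label="variant_id")

    @classmethod
    def from_tsv(cls, path: Union[str, Path], min_wells: int = DEFAULT_MIN_WELLS) -> "OccurrenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="variant_id")
        meta = df[["domain_type", "centroid"]]
        counts = df.drop(columns=["domain_type", "centroid"])
        return cls(counts, meta, min_wells=min_wells)


def build_occurrence_matrix(
    clusters: Sequence[DomainVariant],
    subpools: Sequence[Hashable],
    min_wells: int = DEFAULT_MIN_WELLS,
) -> OccurrenceMatrix:
    """Assemble filtered clusters into an OccurrenceMatrix over ``subpools``.

    ``subpools`` is the full subpool universe of the library (not only those
    with detections).  Clusters spanning fewer than ``min_wells`` subpools are
    dropped, keeping the matrix invariant valid even on unfiltered input.
    """
    subpools = list(subpools)
    if len(set(subpools)) != len(subpools):
        raise ValueError("duplicate subpool ids")
    keep = [c for c in clusters if len(c.subpools) >= min_wells]
    counts = pd.DataFrame(
        0, index=[c.variant_id for c in keep], columns=subpools, dtype=np.int64
    )
    for c in keep:
        for sp, n in c.subpool_counts.items():
            if sp not in counts.columns:
                raise ValueError(f"cluster {c.variant_id} references unknown subpool {sp!r}")
            counts.at[c.variant_id, sp] = n
    meta = pd.DataFrame(
        {
            "domain_type": [c.domain_type for c in keep],
            "centroid": [c.centroid for c in keep],
        },
        index=counts.index,
    )
    return OccurrenceMatrix(counts, meta, min_wells=min_wells)


def merge_tables(tables: Sequence[OccurrenceMatrix]) -> OccurrenceMatrix:
    """Row-wise union of per-domain occurrence tables sharing one subpool universe.

    Variant ids are namespaced by domain type so tables from different primer
    systems can never collide; subpool ordering follows the first table.
    """
    if not tables:
        raise ValueError("no tables to merge")
    universe = set(tables[0].subpools)
    for t in tables[1:]:
        if set(t.subpools) != universe:
            raise ValueError("subpool universes differ between tables")
    order = tables[0].subpools
    counts_parts, meta_parts = [], []
    for t in tables:
        counts = t.counts.reindex(columns=order)
        namespaced = [
            vid if str(vid).startswith(f"{dt}:") else f"{dt}:{vid}"
            for vid, dt in zip(t.counts.index, t.meta["domain_type"])
        ]
        counts.index = pd.Index(namespaced)
        meta = t.meta.copy()
        meta.index = counts.index
        counts_parts.append(counts)
        meta_parts.append(meta)
    merged_counts = pd.concat(counts_parts)
    merged_meta = pd.concat(meta_parts)
    if merged_counts.index.has_duplicates:
        raise ValueError("duplicate variant ids after namespacing")
    min_wells = min(t.min_wells for t in tables)
    return OccurrenceMatrix(merged_counts, merged_meta, min_wells=min_wells)
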