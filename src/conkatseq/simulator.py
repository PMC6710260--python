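"""Synthetic partitioned cosmid libraries with known clustered-domain truth.

The generator instantiates the physical model behind co-occurrence linkage:
a community of genomes with strongly skewed (log-normal) abundances, each
carrying one or more biosynthetic gene clusters whose conserved domains sit a
few kilobases apart; a library of ~38 kb inserts sampled from the community
in proportion to abundance; and an arraying of those clones into equal-sized
subpools.  Two loci ``d`` bp apart land on the same insert of length ``L``
with probability ``(L - d)/L``, so clustered domains co-occur across subpools
far above chance — the signal the statistical pipeline detects.

Observations can be emitted at two levels: *direct* mode yields the
variant x subpool occurrence matrix after per-(domain, subpool) amplification
dropout, and *read* mode emits barcoded paired-end reads (with per-base
substitution errors) plus the barcode scheme, exercising the full
demultiplex/cluster/filter front end.  The ground truth (domain sequences,
clone table, true co-resident pairs) supports precision/recall scoring of
any downstream prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .debarcode import ReadPair, SubpoolScheme
from .linkage import LinkSet
from .network import DomainNetwork
from .variant_table import OccurrenceMatrix

__all__ = [
    "SimParams",
    "PRESETS",
    "Community",
    "SimulatedTruth",
    "SimulationRun",
    "RecoveryScore",
    "simulate_community",
    "simulate_library",
    "simulate_run",
    "cocapture_probability",
    "empirical_cocapture",
    "score_recovery",
    "count_recovered_bgcs",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Study-condition parameters of one simulated library.

    Defaults describe a desk-scale analogue of a large arrayed soil library:
    20 genomes of 10 Mbp under a log-normal abundance law (sigma 1.5), one
    4-domain BGC per genome with 2-8 kb between domain starts, ~38 kb inserts
    (truncated normal, 20-45 kb), 384 subpools of 1000 clones, 10%
    per-(domain, subpool) amplification dropout and error-free reads.
    """

    n_genomes: int = 20
    abundance_sigma: float = 1.5
    genome_length: int = 10_000_000
    n_bgcs_per_genome: int = 1
    domains_per_bgc: tuple[int, int] = (4, 4)
    inter_domain_spacing: tuple[int, int] = (2000, 8000)
    domain_length: int = 230
    n_subpools: int = 384
    clones_per_subpool: int = 1000
    insert_mean: float = 38_000.0
    insert_sd: float = 4_000.0
    insert_min: int = 20_000
    insert_max: int = 45_000
    dropout: float = 0.1
    error_rate: float = 0.0
    reads_per_detection: tuple[int, int] = (5, 15)
    partition: str = "deal"  # "deal" (exact arraying) or "poisson"
    domain_type: str = "AD"
    barcode_len: int = 8
    primer_len: int = 12
    seed: int = 0

    @property
    def n_clones(self) -> int:
        return self.n_subpools * self.clones_per_subpool

    def __post_init__(self) -> None:
        if min(
            self.n_genomes,
            self.genome_length,
            self.n_bgcs_per_genome,
            self.n_subpools,
            self.clones_per_subpool,
            self.domain_length,
        ) <= 0:
            raise ValueError("all size parameters must be positive")
        if not (0 <= self.dropout < 1 and 0 <= self.error_rate < 1):
            raise ValueError("dropout and error_rate must lie in [0, 1)")
        if self.partition not in ("deal", "poisson"):
            raise ValueError("partition must be 'deal' or 'poisson'")
        lo, hi = self.domains_per_bgc
        # worst-case BGC span must fit in the genome
        span = hi * self.domain_length + (hi - 1) * self.inter_domain_spacing[1]
        if span > self.genome_length:
            raise ValueError("BGC span exceeds genome length (infeasible spacing)")


PRESETS: dict[str, SimParams] = {
    # the large arrayed-library layout: 2304 subpools x ~5000 cosmids
    "arizona": SimParams(n_subpools=2304, clones_per_subpool=5000),
    # desk-scale layout used throughout the test suite
    "small": SimParams(n_subpools=384, clones_per_subpool=1000),
    # read-mode scale: one partial plate, suitable for full-pipeline runs
    "tiny": SimParams(
        n_genomes=8,
        abundance_sigma=0.8,
        genome_length=2_000_000,
        n_subpools=96,
        clones_per_subpool=200,
    ),
}


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


@dataclass
class Community:
    """Genomes as coordinate systems; sequence exists only around domains."""

    abundances: np.ndarray  # sums to 1
    genome_length: int
    domains: pd.DataFrame  # domain_id, genome, bgc_id, position
    domain_seqs: dict[str, str]
    bgc_membership: dict[str, list[str]]

    @property
    def n_genomes(self) -> int:
        return len(self.abundances)

    @property
    def domain_ids(self) -> list[str]:
        return list(self.domains["domain_id"])


@dataclass
class SimulatedTruth:
    """Ground truth grounding recovery metrics."""

    community: Community
    clone_table: pd.DataFrame  # clone_id, genome, start, length, subpool
    true_pairs: set[frozenset]  # pairs co-resident on >= 1 clone
    cocapture_subpools: dict[frozenset, int]  # pair -> distinct subpools with a co-clone

    def detectable_pairs(self, min_shared: int = 3) -> set[frozenset]:
        """True pairs co-captured in at least ``min_shared`` distinct subpools."""
        return {p for p, n in self.cocapture_subpools.items() if n >= min_shared}


def simulate_community(params: SimParams, rng: np.random.Generator) -> Community:
    """Draw genome abundances and place BGC domains on circular genomes.

    Domain sequences are independent random DNA, which keeps every pair far
    below the 85% identity ceiling the variant clustering assumes.
    """
    raw = rng.lognormal(mean=0.0, sigma=params.abundance_sigma, size=params.n_genomes)
    abundances = raw / raw.sum()

    lo_d, hi_d = params.domains_per_bgc
    lo_s, hi_s = params.inter_domain_spacing
    records = []
    domain_seqs: dict[str, str] = {}
    bgc_membership: dict[str, list[str]] = {}
    for g in range(params.n_genomes):
        for b in range(params.n_bgcs_per_genome):
            bgc_id = f"g{g:03d}_bgc{b}"
            n_dom = int(rng.integers(lo_d, hi_d + 1))
            start = int(rng.integers(0, params.genome_length))
            pos = start
            members = []
            for k in range(n_dom):
                if k:
                    pos += params.domain_length + int(rng.integers(lo_s, hi_s + 1))
                domain_id = f"{bgc_id}_d{k}"
                records.append(
                    {
                        "domain_id": domain_id,
                        "genome": g,
                        "bgc_id": bgc_id,
                        "position": pos % params.genome_length,
                    }
                )
                domain_seqs[domain_id] = _random_dna(rng, params.domain_length)
                members.append(domain_id)
            bgc_membership[bgc_id] = members
    return Community(
        abundances=abundances,
        genome_length=params.genome_length,
        domains=pd.DataFrame.from_records(records),
        domain_seqs=domain_seqs,
        bgc_membership=bgc_membership,
    )


def simulate_library(
    community: Community, params: SimParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample clones (genome, start, insert length) and array them into subpools.

    Genomes are sampled proportionally to abundance, insert starts uniformly
    on the (circular) genome, and insert lengths from a truncated normal.
    The default partitioning deals clones round-robin over a random
    permutation, giving subpool sizes within one clone of each other;
    ``partition="poisson"`` assigns each clone an independent uniform subpool.
    """
    n = params.n_clones
    genome = rng.choice(community.n_genomes, size=n, p=community.abundances)
    start = rng.integers(0, community.genome_length, size=n)
    length = rng.normal(params.insert_mean, params.insert_sd, size=n)
    bad = (length < params.insert_min) | (length > params.insert_max)
    while np.any(bad):
        length[bad] = rng.normal(params.insert_mean, params.insert_sd, size=int(bad.sum()))
        bad = (length < params.insert_min) | (length > params.insert_max)
    length = length.astype(np.int64)

    if params.partition == "deal":
        order = rng.permutation(n)
        subpool = np.empty(n, dtype=np.int64)
        subpool[order] = np.arange(n) % params.n_subpools
    else:
        subpool = rng.integers(0, params.n_subpools, size=n)

    return pd.DataFrame(
        {
            "clone_id": np.arange(n),
            "genome": genome.astype(np.int64),
            "start": start,
            "length": length,
            "subpool": subpool,
        }
    )


def cocapture_probability(d: float, L: float) -> float:
    """Probability an insert of length L covering one locus also covers a locus d bp away."""
    if d < 0 or L <= 0:
        raise ValueError("require d >= 0 and L > 0")
    return max(0.0, (L - d) / L)


def empirical_cocapture(
    d: float, L: float, n_trials: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo co-capture frequency over inserts covering a focal locus."""
    # insert start uniform over the window that covers the focal locus at 0
    starts = rng.uniform(-L, 0.0, size=n_trials)
    return float(np.mean(starts + L > d))


@dataclass
class SimulationRun:
    """One seeded simulation: community, clones, capture and detection state."""

    params: SimParams
    community: Community
    clone_table: pd.DataFrame
    truth: SimulatedTruth
    capture: np.ndarray  # bool, n_domains x n_subpools: >=1 clone carries the domain
    detection: np.ndarray  # bool, capture AND amplification succeeded
    _read_seed: int = 0

    @property
    def domain_ids(self) -> list[str]:
        return self.community.domain_ids

    def occurrence_matrix(self, min_wells: int = 3) -> OccurrenceMatrix:
        """Direct-mode occurrence matrix (one row per sufficiently seen domain)."""
        counts = pd.DataFrame(
            self.detection.astype(np.int64),
            index=self.domain_ids,
            columns=list(range(self.params.n_subpools)),
        )
        keep = counts.sum(axis=1) >= min_wells
        counts = counts.loc[keep]
        meta = pd.DataFrame(
            {
                "domain_type": self.params.domain_type,
                "centroid": [self.community.domain_seqs[d] for d in counts.index],
            },
            index=counts.index,
        )
        return OccurrenceMatrix(counts, meta, min_wells=min_wells)

    def scheme(self) -> SubpoolScheme:
        """Barcode scheme used by read mode (requires <= 384 subpools)."""
        if self.params.n_subpools > 384:
            raise ValueError("read mode supports at most one 384-subpool plate")
        rng = np.random.default_rng(self._read_seed)
        columns = _draw_barcodes(rng, 24, self.params.barcode_len)
        rows = _draw_barcodes(rng, 16, self.params.barcode_len)
        return SubpoolScheme(
            plate_id="SIM",
            column_barcodes={b: i for i, b in enumerate(columns)},
            row_barcodes={b: i for i, b in enumerate(rows)},
            primer_len=self.params.primer_len,
            total_len=self.params.primer_len + self.params.domain_length,
            spacer=0,
            domain_type=self.params.domain_type,
        )

    def reads(self) -> tuple[list[ReadPair], SubpoolScheme]:
        """Read-mode output: barcoded read pairs for every detection event.

        Each detected (domain, subpool) yields ``reads_per_detection`` read
        pairs of the domain sequence with i.i.d. per-base substitution errors,
        prefixed by the subpool's column (forward) and row (reverse) barcodes
        and a fixed spacer+primer filler consumed by trimming.  At
        ``error_rate=0`` the demultiplex/cluster pipeline reconstructs the
        direct-mode matrix exactly.
        """
        scheme = self.scheme()
        rng = np.random.default_rng(self._read_seed + 1)
        filler = _random_dna(rng, self.params.primer_len)
        col_by_idx = {i: b for b, i in scheme.column_barcodes.items()}
        row_by_idx = {i: b for b, i in scheme.row_barcodes.items()}
        lo, hi = self.params.reads_per_detection
        pairs: list[ReadPair] = []
        dom_idx, pool_idx = np.nonzero(self.detection)
        for d_i, s_i in zip(dom_idx, pool_idx):
            domain_id = self.domain_ids[d_i]
            seq = self.community.domain_seqs[domain_id]
            row_bc = row_by_idx[int(s_i) // 24]
            col_bc = col_by_idx[int(s_i) % 24]
            for r in range(int(rng.integers(lo, hi + 1))):
                err = _mutate(seq, self.params.error_rate, rng)
                pairs.append(
                    ReadPair(
                        id=f"{domain_id}|pool{s_i}|r{r}",
                        fwd_seq=col_bc + filler + err,
                        rev_seq=row_bc + filler + _revcomp(err),
                    )
                )
        return pairs, scheme

    def subpool_universe(self) -> list:
        return list(range(self.params.n_subpools))

    def read_mode_subpool_ids(self) -> dict:
        """Map (plate, row, col) subpool ids back to integer subpool indices."""
        return {("SIM", s // 24, s % 24): s for s in range(self.params.n_subpools)}


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.shape[0]) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _draw_barcodes(
    rng: np.random.Generator, n: int, length: int, min_dist: int = 3
) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= min_dist."""
    out: list[np.ndarray] = []
    while len(out) < n:
        cand = rng.integers(0, 4, length)
        if all(np.sum(cand != prev) >= min_dist for prev in out):
            out.append(cand)
    return [_BASES[c].tobytes().decode() for c in out]


def simulate_run(params: SimParams) -> SimulationRun:
    """Full seeded simulation: community, library, capture, detections, truth."""
    ss = np.random.SeedSequence(params.seed)
    rng_comm, rng_lib, rng_det, rng_reads = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    community = simulate_community(params, rng_comm)
    clone_table = simulate_library(community, params, rng_lib)

    n_domains = len(community.domains)
    capture = np.zeros((n_domains, params.n_subpools), dtype=bool)
    true_pairs: set[frozenset] = set()
    cocapture: dict[frozenset, int] = {}

    genomes = clone_table["genome"].to_numpy()
    starts = clone_table["start"].to_numpy()
    lengths = clone_table["length"].to_numpy()
    subpools = clone_table["subpool"].to_numpy()
    G = params.genome_length

    dom = community.domains
    for g, group in dom.groupby("genome"):
        clone_sel = np.nonzero(genomes == g)[0]
        if clone_sel.size == 0:
            continue
        c_start = starts[clone_sel]
        c_len = lengths[clone_sel]
        c_pool = subpools[clone_sel]
        covered = {}
        for row in group.itertuples():
            offset = (row.position - c_start) % G
            cov = offset <= (c_len - params.domain_length)
            covered[row.Index] = cov
            if np.any(cov):
                capture[row.Index, np.unique(c_pool[cov])] = True
        idxs = list(group.index)
        for i, a in enumerate(idxs):
            for b in idxs[i + 1 :]:
                both = covered[a] & covered[b]
                if np.any(both):
                    pair = frozenset(
                        (dom.at[a, "domain_id"], dom.at[b, "domain_id"])
                    )
                    true_pairs.add(pair)
                    cocapture[pair] = int(np.unique(c_pool[both]).size)

    detection = capture & (rng_det.random(capture.shape) >= params.dropout)
    truth = SimulatedTruth(
        community=community,
        clone_table=clone_table,
        true_pairs=true_pairs,
        cocapture_subpools=cocapture,
    )
    return SimulationRun(
        params=params,
        community=community,
        clone_table=clone_table,
        truth=truth,
        capture=capture,
        detection=detection,
        _read_seed=int(rng_reads.integers(0, 2**31 - 1)),
    )


@dataclass(frozen=True)
class RecoveryScore:
    precision: float
    recall: float
    n_predicted: int
    n_true_detectable: int
    n_unknown_variants: int
    zero_support: bool  # precision reported as 1.0 with no predictions


def _map_variants_to_domains(
    centroids: dict[str, str], truth: SimulatedTruth, id_threshold: float = 0.95
) -> dict[str, Optional[str]]:
    """Variant -> true domain by sequence identity (ungapped on equal lengths)."""
    domain_items = list(truth.community.domain_seqs.items())
    mapping: dict[str, Optional[str]] = {}
    for vid, centroid in centroids.items():
        best_id, best_dom = 0.0, None
        q = np.frombuffer(centroid.encode(), dtype=np.uint8)
        for dom_id, seq in domain_items:
            if len(seq) != len(centroid):
                continue
            t = np.frombuffer(seq.encode(), dtype=np.uint8)
            ident = float(np.mean(q == t))
            if ident > best_id:
                best_id, best_dom = ident, dom_id
        mapping[vid] = best_dom if best_id >= id_threshold else None
    return mapping


def _predicted_variant_pairs(
    predicted: Union[LinkSet, Sequence[DomainNetwork]]
) -> tuple[set[frozenset], dict[str, str]]:
    """Significant variant pairs and variant->centroid from links or networks."""
    pairs: set[frozenset] = set()
    centroids: dict[str, str] = {}
    if isinstance(predicted, LinkSet):
        for t in predicted.significant_links():
            pairs.add(frozenset((t.variant_a, t.variant_b)))
    else:
        for net in predicted:
            for a, b, _ in net.edges:
                pairs.add(frozenset((a, b)))
            for vid, node in net.nodes.items():
                if node.centroid:
                    centroids[vid] = node.centroid
    return pairs, centroids


def score_recovery(
    predicted: Union[LinkSet, Sequence[DomainNetwork]],
    truth: SimulatedTruth,
    centroids: Optional[dict[str, str]] = None,
    min_shared: int = 3,
) -> RecoveryScore:
    """Precision/recall of predicted links against the simulated truth.

    Precision is measured over all predicted pairs whose variants map to true
    domains (identity >= 0.95); unmappable variants are excluded and counted.
    Recall is detectability-limited: its denominator is the set of true pairs
    co-captured in at least ``min_shared`` distinct subpools, since pairs
    below that floor are statistically invisible by design.  With zero
    predictions precision is reported as 1.0 with ``zero_support`` set.
    """
    pairs, net_centroids = _predicted_variant_pairs(predicted)
    centroids = centroids if centroids is not None else net_centroids
    variant_ids = {v for p in pairs for v in p}
    known_domains = set(truth.community.domain_seqs)
    mapping: dict[str, Optional[str]] = {}
    direct = variant_ids & known_domains  # direct mode: variant ids ARE domain ids
    for vid in direct:
        mapping[vid] = vid
    remaining = {v: centroids[v] for v in variant_ids - direct if v in centroids}
    mapping.update(_map_variants_to_domains(remaining, truth))
    n_unknown = sum(1 for v in variant_ids if mapping.get(v) is None)

    mapped_pairs = set()
    for p in pairs:
        a, b = tuple(p)
        da, db = mapping.get(a), mapping.get(b)
        if da is not None and db is not None and da != db:
            mapped_pairs.add(frozenset((da, db)))

    detectable = truth.detectable_pairs(min_shared)
    if mapped_pairs:
        precision = len(mapped_pairs & truth.true_pairs) / len(mapped_pairs)
        zero_support = False
    else:
        precision, zero_support = 1.0, True
    recall = (
        len(mapped_pairs & detectable) / len(detectable) if detectable else 0.0
    )
    return RecoveryScore(
        precision=precision,
        recall=recall,
        n_predicted=len(mapped_pairs),
        n_true_detectable=len(detectable),
        n_unknown_variants=n_unknown,
        zero_support=zero_support,
    )


def count_recovered_bgcs(
    networks: Sequence[DomainNetwork],
    truth: SimulatedTruth,
    min_nodes: int = 3,
) -> int:
    """Number of true BGCs represented by >= ``min_nodes`` domains in one network."""
    known_domains = set(truth.community.domain_seqs)
    recovered = 0
    for bgc_id, members in truth.community.bgc_membership.items():
        members = set(members)
        for net in networks:
            mapped = set()
            for vid, node in net.nodes.items():
                if vid in known_domains:
                    mapped.add(vid)
                elif node.centroid:
                    dom = _map_variants_to_domains(
                        {vid: node.centroid}, truth
                    )[vid]
                    if dom is not None:
                        mapped.add(dom)
            if len(mapped & members) >= min_nodes:
                recovered += 1
                break
    return recovered


def write_truth(truth: SimulatedTruth, out_dir: Union[str, Path], include_clones: bool = True) -> None:
    """Write ground-truth TSVs (domains, BGC membership, true pairs, clones)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dom = truth.community.domains.copy()
    dom["sequence"] = [truth.community.domain_seqs[d] for d in dom["domain_id"]]
    dom.to_csv(out_dir / "domains.tsv", sep="\t", index=False)
    with open(out_dir / "true_pairs.tsv", "w") as fh:
        fh.write("domain_a\tdomain_b\tcocapture_subpools\n")
        for pair in sorted(truth.true_pairs, key=sorted):
            a, b = sorted(pair)
            fh.write(f"{a}\t{b}\t{truth.cocapture_subpools[pair]}\n")
    if include_clones:
        truth.clone_table.to_csv(out_dir / "clones.tsv", sep="\t", index=False)
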