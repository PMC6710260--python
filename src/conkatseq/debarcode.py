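"""Demultiplexing of barcoded paired-end amplicon reads into library subpools.

Each PCR plate amplifies one biosynthetic domain from 384 library subpools
using 24 column-barcoded forward primers crossed with 16 row-barcoded reverse
primers.  The forward read therefore starts with a column barcode, followed by
a spacer and the degenerate primer, followed by the amplified domain; the
reverse read starts with a row barcode.  Demultiplexing matches the barcode
prefixes (Hamming distance), strips the column barcode from the forward read,
and trims the remainder to a fixed, primer-free domain sequence.  Only the
forward read is carried downstream; the reverse read exists solely to supply
the row barcode.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pandas as pd

__all__ = [
    "SubpoolScheme",
    "ReadPair",
    "SubpoolReadSet",
    "Unassigned",
    "UnassignedReason",
    "SchemeError",
    "parse_scheme",
    "write_scheme",
    "assign_subpool",
    "trim_read",
    "demultiplex",
]

N_COLUMNS = 24
N_ROWS = 16

_DNA = set("ACGTN")


class SchemeError(ValueError):
    """Raised for malformed subpool barcode schemes."""


class UnassignedReason(str, enum.Enum):
    NO_COLUMN = "no_column"
    NO_ROW = "no_row"
    AMBIGUOUS = "ambiguous"
    TOO_SHORT = "too_short"  # assigned a subpool but forward read too short to trim


@dataclass(frozen=True)
class Unassigned:
    """Sentinel result for a read pair that could not be placed in a subpool."""

    reason: UnassignedReason

    def __bool__(self) -> bool:  # allows `if assign_subpool(...)` idiom
        return False


SubpoolId = tuple[str, int, int]  # (plate, row, column)


@dataclass(frozen=True)
class SubpoolScheme:
    """Barcode layout of one 384-subpool PCR plate.

    ``column_barcodes`` and ``row_barcodes`` map barcode sequence to column /
    row index.  ``primer_len`` is the number of bases (spacer + degenerate
    primer) stripped from the forward read *after* barcode removal, and
    ``total_len`` the length the barcode-free forward read is truncated to
    before stripping, so every retained read is ``total_len - primer_len`` nt.
    """

    plate_id: str
    column_barcodes: dict[str, int]
    row_barcodes: dict[str, int]
    primer_len: int
    total_len: int
    spacer: int
    domain_type: str

    def __post_init__(self) -> None:
        for name, barcodes, expected in (
            ("column", self.column_barcodes, N_COLUMNS),
            ("row", self.row_barcodes, N_ROWS),
        ):
            if len(barcodes) != expected:
                raise SchemeError(
                    f"expected {expected} {name} barcodes, got {len(barcodes)}"
                )
            lengths = {len(b) for b in barcodes}
            if len(lengths) != 1:
                raise SchemeError(f"{name} barcodes have mixed lengths: {lengths}")
            if sorted(barcodes.values()) != list(range(expected)):
                raise SchemeError(f"{name} indices must be 0..{expected - 1}")
            bad = [b for b in barcodes if not set(b) <= set("ACGT")]
            if bad:
                raise SchemeError(f"non-ACGT {name} barcode(s): {bad}")
        if not 0 <= self.primer_len < self.total_len:
            raise SchemeError("require 0 <= primer_len < total_len")

    @property
    def column_barcode_len(self) -> int:
        return len(next(iter(self.column_barcodes)))

    @property
    def row_barcode_len(self) -> int:
        return len(next(iter(self.row_barcodes)))

    @property
    def read_len(self) -> int:
        """Length of every trimmed forward read."""
        return self.total_len - self.primer_len

    @property
    def n_subpools(self) -> int:
        return N_COLUMNS * N_ROWS

    def subpool_ids(self) -> list[SubpoolId]:
        """All addressable subpools in row-major order."""
        return [
            (self.plate_id, r, c) for r in range(N_ROWS) for c in range(N_COLUMNS)
        ]


@dataclass(frozen=True)
class ReadPair:
    id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: Optional[str] = None
    rev_qual: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.fwd_seq or not self.rev_seq:
            raise ValueError("read sequences must be non-empty")
        if not (set(self.fwd_seq) <= _DNA and set(self.rev_seq) <= _DNA):
            raise ValueError(f"read {self.id}: alphabet must be A/C/G/T/N")


@dataclass
class SubpoolReadSet:
    """Trimmed forward reads of one subpool; all reads have equal length."""

    subpool_id: SubpoolId
    reads: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len({len(r) for r in self.reads}) > 1:
            raise ValueError("all trimmed reads in a subpool must have equal length")


def parse_scheme(scheme_file: Union[str, Path]) -> SubpoolScheme:
    """Parse a subpool barcode scheme TSV.

    The format holds header key/value lines (``#key<TAB>value``) for plate_id,
    primer_len, total_len, spacer and domain_type, then a ``barcode  axis
    index`` table with 24 ``column`` and 16 ``row`` entries.  Duplicate
    barcodes within an axis are rejected; the column and row sets are
    independent, so a barcode may legally appear once under each axis.
    """
    meta: dict[str, str] = {}
    rows: list[tuple[str, str, int]] = []
    header_seen = False
    with open(scheme_file) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                try:
                    key, value = line[1:].split("\t", 1)
                except ValueError as exc:
                    raise SchemeError(f"line {line_no}: malformed header line") from exc
                meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if fields[0] == "barcode":
                header_seen = True
                continue
            if len(fields) != 3:
                raise SchemeError(f"line {line_no}: expected 3 columns, got {len(fields)}")
            barcode, axis, index = fields
            if axis not in ("row", "column"):
                raise SchemeError(f"line {line_no}: axis must be 'row' or 'column'")
            rows.append((barcode.upper(), axis, int(index)))
    if not header_seen:
        raise SchemeError("missing 'barcode\taxis\tindex' table header")
    for key in ("plate_id", "primer_len", "total_len", "spacer", "domain_type"):
        if key not in meta:
            raise SchemeError(f"missing header key '{key}'")

    columns: dict[str, int] = {}
    row_bc: dict[str, int] = {}
    for barcode, axis, index in rows:
        target = columns if axis == "column" else row_bc
        if barcode in target:
            raise SchemeError(f"duplicate {axis} barcode {barcode}")
        target[barcode] = index

    return SubpoolScheme(
        plate_id=meta["plate_id"],
        column_barcodes=columns,
        row_barcodes=row_bc,
        primer_len=int(meta["primer_len"]),
        total_len=int(meta["total_len"]),
        spacer=int(meta["spacer"]),
        domain_type=meta["domain_type"],
    )


def write_scheme(scheme: SubpoolScheme, path: Union[str, Path]) -> None:
    """Write a scheme in the TSV format understood by :func:`parse_scheme`."""
    with open(path, "w") as fh:
        fh.write(f"#plate_id\t{scheme.plate_id}\n")
        fh.write(f"#primer_len\t{scheme.primer_len}\n")
        fh.write(f"#total_len\t{scheme.total_len}\n")
        fh.write(f"#spacer\t{scheme.spacer}\n")
        fh.write(f"#domain_type\t{scheme.domain_type}\n")
        fh.write("barcode\taxis\tindex\n")
        for barcode, idx in sorted(scheme.column_barcodes.items(), key=lambda kv: kv[1]):
            fh.write(f"{barcode}\tcolumn\t{idx}\n")
        for barcode, idx in sorted(scheme.row_barcodes.items(), key=lambda kv: kv[1]):
            fh.write(f"{barcode}\trow\t{idx}\n")


def _hamming(a: str, b: str) -> int:
    # N never matches: it counts as a mismatch against every base.
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def _match_barcode(
    prefix_source: str, barcodes: dict[str, int], max_mismatch: int
) -> Optional[int]:
    """Index of the unique best barcode within max_mismatch, else None.

    Returns -1 to signal an ambiguous tie at the best distance.
    """
    bc_len = len(next(iter(barcodes)))
    if len(prefix_source) < bc_len:
        return None
    prefix = prefix_source[:bc_len]
    best_d, best_idx, tied = max_mismatch + 1, None, False
    for barcode, idx in barcodes.items():
        d = _hamming(prefix, barcode)
        if d < best_d:
            best_d, best_idx, tied = d, idx, False
        elif d == best_d and best_idx is not None:
            tied = True
    if best_idx is None or best_d > max_mismatch:
        return None
    return -1 if tied else best_idx


def assign_subpool(
    pair: ReadPair, scheme: SubpoolScheme, max_mismatch: int = 0
) -> Union[SubpoolId, Unassigned]:
    """Assign a read pair to a subpool from its column/row barcode prefixes.

    The forward read prefix is matched against the 24 column barcodes and the
    reverse read prefix against the 16 row barcodes, each within
    ``max_mismatch`` Hamming distance; a unique best match is required on both
    axes.  Unassignable pairs are data, not errors: an :class:`Unassigned`
    carrying the failure category is returned.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    col = _match_barcode(pair.fwd_seq, scheme.column_barcodes, max_mismatch)
    if col is None:
        return Unassigned(UnassignedReason.NO_COLUMN)
    row = _match_barcode(pair.rev_seq, scheme.row_barcodes, max_mismatch)
    if row is None:
        return Unassigned(UnassignedReason.NO_ROW)
    if col == -1 or row == -1:
        return Unassigned(UnassignedReason.AMBIGUOUS)
    return (scheme.plate_id, row, col)


def trim_read(seq: str, primer_len: int, total_len: int) -> Optional[str]:
    """Truncate to ``total_len`` then strip the first ``primer_len`` bases.

    Mirrors fixed-length amplicon trimming (truncate, strip-left): reads
    shorter than ``total_len`` carry ragged 3' ends and are discarded (None).
    """
    if not 0 <= primer_len < total_len:
        raise ValueError("require 0 <= primer_len < total_len")
    if len(seq) < total_len:
        return None
    return seq[primer_len:total_len]


@dataclass
class DemuxResult:
    """Per-subpool trimmed reads plus assignment accounting."""

    scheme: SubpoolScheme
    subpools: dict[SubpoolId, SubpoolReadSet]
    unassigned: Counter  # UnassignedReason -> count
    n_input: int

    @property
    def n_assigned(self) -> int:
        return sum(len(s.reads) for s in self.subpools.values())

    def report(self) -> pd.DataFrame:
        """Tidy demultiplexing report: one row per subpool plus unassigned rows."""
        records = [
            {
                "category": "subpool",
                "subpool_id": f"{p}_{r}_{c}",
                "n_reads": len(readset.reads),
            }
            for (p, r, c), readset in sorted(self.subpools.items())
        ]
        for reason in UnassignedReason:
            records.append(
                {
                    "category": "unassigned",
                    "subpool_id": reason.value,
                    "n_reads": self.unassigned.get(reason, 0),
                }
            )
        return pd.DataFrame.from_records(records)


def demultiplex(
    pairs: Iterable[ReadPair], scheme: SubpoolScheme, max_mismatch: int = 0
) -> DemuxResult:
    """Assign read pairs to subpools and trim forward reads to domain sequences.

    The column barcode is removed from the forward read first; the
    spacer+primer region is then stripped by :func:`trim_read` applied to the
    remainder.  Pairs whose forward remainder is shorter than ``total_len``
    are dropped and counted under ``too_short``.
    """
    subpools: dict[SubpoolId, SubpoolReadSet] = {}
    unassigned: Counter = Counter()
    n_input = 0
    bc_len = scheme.column_barcode_len
    for pair in pairs:
        n_input += 1
        result = assign_subpool(pair, scheme, max_mismatch)
        if isinstance(result, Unassigned):
            unassigned[result.reason] += 1
            continue
        trimmed = trim_read(pair.fwd_seq[bc_len:], scheme.primer_len, scheme.total_len)
        if trimmed is None:
            unassigned[UnassignedReason.TOO_SHORT] += 1
            continue
        subpools.setdefault(result, SubpoolReadSet(result)).reads.append(trimmed)
    return DemuxResult(scheme=scheme, subpools=subpools, unassigned=unassigned, n_input=n_input)


def read_fastq_pairs(
    r1_path: Union[str, Path], r2_path: Union[str, Path]
) -> Iterator[ReadPair]:
    """Stream read pairs from two (optionally gzipped) FASTQ files."""
    import gzip

    from Bio import SeqIO

    def _open(path: Union[str, Path]):
        path = str(path)
        return gzip.open(path, "rt") if path.endswith(".gz") else open(path)

    with _open(r1_path) as fh1, _open(r2_path) as fh2:
        for rec1, rec2 in zip(
            SeqIO.parse(fh1, "fastq"), SeqIO.parse(fh2, "fastq"), strict=True
        ):
            yield ReadPair(id=rec1.id, fwd_seq=str(rec1.seq).upper(), rev_seq=str(rec2.seq).upper())


def write_subpool_fastas(result: DemuxResult, out_dir: Union[str, Path]) -> list[Path]:
    """One FASTA per subpool, named <plate>_<row>_<col>.fasta."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (plate, row, col), readset in sorted(result.subpools.items()):
        path = out_dir / f"{plate}_{row}_{col}.fasta"
        with open(path, "w") as fh:
            for i, seq in enumerate(readset.reads):
                fh.write(f">{plate}_{row}_{col}.{i}\n{seq}\n")
        paths.append(path)
    return paths
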