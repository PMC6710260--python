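"""Sequencing-output and genome-frequency extrapolation from shallow coverage.

Given the mean depth of coverage a contig attained in a shallow untargeted
sequencing run of the pooled library, two extrapolations follow directly from
proportionality of depth and output: the total sequencing output that would
be needed to bring the contig to a target depth, and the frequency of the
contig's source genome in the library (assuming a fixed genome size, default
10 Mbp = 0.01 Gbp).  With the default 15.5 Gbp run, a contig at 0.31x depth
needs 15.5 / 0.31 * 20 = 1000 Gbp for 20x coverage, and a contig at 15.5x
depth implies a source-genome frequency of 1%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

__all__ = [
    "CoverageObservation",
    "required_output",
    "genome_frequency",
    "extrapolate_table",
]

DEFAULT_SEQUENCED_OUTPUT_GBP = 15.5
DEFAULT_GENOME_SIZE_GBP = 0.01  # a 10 Mbp soil-bacterium genome
DEFAULT_TARGET_DEPTH = 20.0


@dataclass(frozen=True)
class CoverageObservation:
    contig_id: str
    mean_depth: float
    sequenced_output: float = DEFAULT_SEQUENCED_OUTPUT_GBP
    genome_size: float = DEFAULT_GENOME_SIZE_GBP
    target_depth: float = DEFAULT_TARGET_DEPTH

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if min(self.sequenced_output, self.genome_size, self.target_depth) <= 0:
            raise ValueError("all parameters must be positive")


def required_output(obs: CoverageObservation) -> float:
    """Gbp of sequencing needed to reach the target depth on this contig.

    required = sequenced_output / mean_depth * target_depth, so that
    required * mean_depth == sequenced_output * target_depth exactly.
    """
    return obs.sequenced_output / obs.mean_depth * obs.target_depth


def genome_frequency(obs: CoverageObservation) -> float:
    """Estimated frequency of the contig's source genome in the library.

    frequency = 1 / ((sequenced_output / genome_size) / mean_depth), i.e. the
    attained depth relative to the depth a genome comprising the whole
    library would attain.
    """
    return obs.mean_depth * obs.genome_size / obs.sequenced_output


def extrapolate_table(
    depth_table: Union[str, Path, pd.DataFrame],
    sequenced_output: float = DEFAULT_SEQUENCED_OUTPUT_GBP,
    genome_size: float = DEFAULT_GENOME_SIZE_GBP,
    target_depth: float = DEFAULT_TARGET_DEPTH,
) -> pd.DataFrame:
    """Apply both extrapolations to a contig depth table.

    Input: TSV or DataFrame with columns ``contig_id`` and ``mean_depth``;
    output adds ``required_output_gbp`` and ``est_frequency``.
    """
    if not isinstance(depth_table, pd.DataFrame):
        depth_table = pd.read_csv(depth_table, sep="\t")
    missing = {"contig_id", "mean_depth"} - set(depth_table.columns)
    if missing:
        raise ValueError(f"depth table missing column(s): {sorted(missing)}")
    out = depth_table.copy()
    rows = [
        CoverageObservation(
            contig_id=str(r.contig_id),
            mean_depth=float(r.mean_depth),
            sequenced_output=sequenced_output,
            genome_size=genome_size,
            target_depth=target_depth,
        )
        for r in out.itertuples()
    ]
    out["required_output_gbp"] = [required_output(o) for o in rows]
    out["est_frequency"] = [genome_frequency(o) for o in rows]
    return out
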