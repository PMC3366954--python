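"""Domain records and the probeset-to-gene curation step.

Microarray platforms assay many genes with more than one probeset. A
positional clustering scan is sensitive to this redundancy: two probesets
for one dysregulated gene would be double-counted inside a window and
inflate the binomial tail. Before scanning, each gene is therefore
represented by its single best probeset (the one with the lowest nominal
P-value), and all other probesets for that gene are dropped.

Coordinates are 1-based inclusive on input. The representative position
used for window membership is the span midpoint, ``floor((start+end)/2)``;
strand is ignored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    """One gene's genomic placement.

    Parameters
    ----------
    gene_id : str
        Unique gene identifier.
    chrom : str
        Chromosome name; must be non-empty.
    start, end : int
        Genomic span in bp, 1-based inclusive, ``start <= end``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.chrom:
            raise ValueError(f"gene {self.gene_id!r}: chrom must be non-empty")
        if self.start < 1:
            raise ValueError(
                f"gene {self.gene_id!r}: start must be >= 1 (got {self.start})"
            )
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: start ({self.start}) > end ({self.end})"
            )

    @property
    def rep_point(self) -> int:
        """Representative bp position for window binning (span midpoint)."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ProbesetStat:
    """Differential-expression summary for one probeset (pre-curation)."""

    probeset_id: str
    gene_id: Optional[str]
    p_value: float
    t_stat: float = 0.0
    log_fc: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.probeset_id:
            raise ValueError("probeset_id must be non-empty")
        if not (
            math.isfinite(self.p_value) and 0.0 < self.p_value <= 1.0
        ):
            raise ValueError(
                f"probeset {self.probeset_id!r}: p_value must be in (0, 1], "
                f"got {self.p_value!r}"
            )
        if not math.isfinite(self.t_stat):
            raise ValueError(
                f"probeset {self.probeset_id!r}: t_stat must be finite"
            )


@dataclass(frozen=True)
class GeneStat:
    """Gene-level differential-expression summary after curation.

    ``dysregulated`` is True when the nominal P-value is at or below the
    configured per-gene threshold (0.01 by default downstream).
    """

    gene_id: str
    p_value: float
    t_stat: float
    dysregulated: bool

    def __post_init__(self) -> None:
        if not (math.isfinite(self.p_value) and 0.0 < self.p_value <= 1.0):
            raise ValueError(
                f"gene {self.gene_id!r}: p_value must be in (0, 1], "
                f"got {self.p_value!r}"
            )


def dedupe_probesets(
    table: Sequence[ProbesetStat], alpha_gene: float = 0.01
) -> list[GeneStat]:
    """Collapse probesets to one record per gene by minimum P-value.

    For each gene the probeset with the lowest nominal P-value is
    retained and all other probesets for that gene are deleted. Ties on
    P-value are broken by larger ``|t_stat|``, then by lexicographically
    smallest probeset_id, so the result is deterministic. Probesets with
    no gene assignment are excluded (counted in a log message).

    Parameters
    ----------
    table : sequence of ProbesetStat
    alpha_gene : float
        Per-gene nominal significance threshold used to set the
        ``dysregulated`` flag (comparison is ``<=``).

    Returns
    -------
    list of GeneStat
        Exactly one record per distinct gene_id, sorted by gene_id.
    """
    if not 0.0 < alpha_gene < 1.0:
        raise ValueError(f"alpha_gene must be in (0, 1), got {alpha_gene}")
    n_unassigned = 0
    best: dict[str, ProbesetStat] = {}
    for rec in table:
        if not (math.isfinite(rec.p_value) and 0.0 < rec.p_value <= 1.0):
            raise ValueError(
                f"probeset {rec.probeset_id!r}: p_value must be in (0, 1], "
                f"got {rec.p_value!r}"
            )
        if rec.gene_id is None or rec.gene_id == "":
            n_unassigned += 1
            continue
        cur = best.get(rec.gene_id)
        if cur is None or _dedupe_key(rec) < _dedupe_key(cur):
            best[rec.gene_id] = rec
    if n_unassigned:
        logger.info(
            "dedupe_probesets: dropped %d probeset(s) without a gene assignment",
            n_unassigned,
        )
    return [
        GeneStat(
            gene_id=g,
            p_value=r.p_value,
            t_stat=r.t_stat,
            dysregulated=r.p_value <= alpha_gene,
        )
        for g, r in sorted(best.items())
    ]


def _dedupe_key(rec: ProbesetStat) -> tuple[float, float, str]:
    # smallest p, then largest |t|, then smallest probeset_id
    return (rec.p_value, -abs(rec.t_stat), rec.probeset_id)


def join_annotation(
    stats: Iterable[GeneStat], annotation: Iterable[GeneRecord]
) -> pd.DataFrame:
    """Inner-join gene statistics onto genomic positions.

    Genes present on only one side are counted and logged, never
    silently invented. Duplicate gene_ids in the annotation (e.g. a gene
    with two genomic placements) are rejected.

    Returns
    -------
    pandas.DataFrame
        Columns ``gene_id, chrom, start, end, rep_point, p_value,
        t_stat, dysregulated``, sorted by ``(chrom, rep_point, gene_id)``.
    """
    ann = list(annotation)
    seen: set[str] = set()
    for rec in ann:
        if rec.gene_id in seen:
            raise ValueError(
                f"duplicate gene_id {rec.gene_id!r} in annotation "
                "(multi-placement genes are not supported)"
            )
        seen.add(rec.gene_id)

    ann_df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in ann],
            "chrom": [r.chrom for r in ann],
            "start": [r.start for r in ann],
            "end": [r.end for r in ann],
            "rep_point": [r.rep_point for r in ann],
        }
    )
    stats = list(stats)
    stat_df = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in stats],
            "p_value": [s.p_value for s in stats],
            "t_stat": [s.t_stat for s in stats],
            "dysregulated": [s.dysregulated for s in stats],
        }
    )
    if ann_df.empty or stat_df.empty:
        joined = pd.DataFrame(
            columns=[
                "gene_id", "chrom", "start", "end", "rep_point",
                "p_value", "t_stat", "dysregulated",
            ]
        )
    else:
        joined = ann_df.merge(stat_df, on="gene_id", how="inner")
    n_unmapped_stats = len(stat_df) - len(joined)
    n_unused_ann = len(ann_df) - len(joined)
    if n_unmapped_stats or n_unused_ann:
        logger.info(
            "join_annotation: %d gene(s) with statistics but no annotation; "
            "%d annotated gene(s) without statistics",
            n_unmapped_stats,
            n_unused_ann,
        )
    joined = joined.sort_values(
        ["chrom", "rep_point", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    joined["dysregulated"] = joined["dysregulated"].astype(bool)
    return joined
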