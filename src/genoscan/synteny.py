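"""Overlap of enriched murine intervals with mouse-to-human homology blocks.

Shared synteny — a conserved clustering of orthologous genes — lets an
enriched interval on the mouse genome be mapped onto the human region it
corresponds to (e.g. a murine 5qF cluster onto human 12q24). Given a
user-supplied table of homology blocks (murine interval plus a human
cytoband label), this module reports, for each enriched region, every
block it overlaps and by how many bp; regions overlapping no block are
reported as unmatched, like the predicted-gene cluster on the X
chromosome with no obvious human orthology.

Both inputs must be on the same murine assembly; no liftover is done.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from genoscan.scan import Region


@dataclass(frozen=True)
class HomologyBlock:
    """One homology-map row: murine interval -> human region label.

    Coordinates are 1-based inclusive bp.
    """

    m_chrom: str
    m_start: int
    m_end: int
    h_label: str

    def __post_init__(self) -> None:
        if not self.m_chrom:
            raise ValueError("m_chrom must be non-empty")
        if self.m_start < 1 or self.m_end < self.m_start:
            raise ValueError(
                f"block {self.h_label!r}: invalid interval "
                f"[{self.m_start}, {self.m_end}]"
            )
        if not self.h_label:
            raise ValueError(
                f"block on {self.m_chrom}:{self.m_start}-{self.m_end}: "
                "h_label must be non-empty"
            )


def overlap_length(
    a_start: int, a_end: int, b_start: int, b_end: int
) -> int:
    """Overlap in bp between two 1-based inclusive intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def overlap_regions(
    regions: Sequence[Region],
    blocks: Sequence[HomologyBlock],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Intersect enriched regions with homology blocks.

    Region spans are half-open ``[start, end)`` as produced by
    :func:`genoscan.scan.significant_regions`; they are compared against
    the blocks' inclusive coordinates as the inclusive interval
    ``[max(start, 1), end - 1]``. Any overlap of at least ``min_overlap``
    bp is reported (the default, 1 bp, imposes no threshold).

    Returns
    -------
    pandas.DataFrame
        Columns ``region_id, chrom, region_start, region_end, h_label,
        overlap_bp``; one row per (region, overlapping block), plus one
        row with ``h_label='.'`` and ``overlap_bp=0`` for each unmatched
        region.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    rows: list[dict] = []
    for reg in regions:
        rid = f"{reg.chrom}:{reg.start}-{reg.end}"
        r_start = max(reg.start, 1)
        r_end = reg.end - 1  # half-open -> inclusive
        matched = False
        for blk in blocks:
            if blk.m_chrom != reg.chrom:
                continue
            ov = overlap_length(r_start, r_end, blk.m_start, blk.m_end)
            if ov >= min_overlap:
                matched = True
                rows.append(
                    {
                        "region_id": rid,
                        "chrom": reg.chrom,
                        "region_start": reg.start,
                        "region_end": reg.end,
                        "h_label": blk.h_label,
                        "overlap_bp": ov,
                    }
                )
        if not matched:
            rows.append(
                {
                    "region_id": rid,
                    "chrom": reg.chrom,
                    "region_start": reg.start,
                    "region_end": reg.end,
                    "h_label": ".",
                    "overlap_bp": 0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "chrom",
            "region_start",
            "region_end",
            "h_label",
            "overlap_bp",
        ],
    )
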