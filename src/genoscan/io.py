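"""TSV readers/writers, run configuration, and the full pipeline.

All tables are tab-delimited UTF-8 with a required header row; '.' or an
empty field means missing. Floats are serialized at full precision
(repr-style) so a write-then-read round-trip reproduces the in-memory
values exactly. Annotation coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from genoscan.core import (
    GeneRecord,
    GeneStat,
    ProbesetStat,
    dedupe_probesets,
    join_annotation,
)
from genoscan.scan import (
    Region,
    ScanParams,
    ScanResult,
    chrom_sort_key,
    scan_genome,
    significant_regions,
)
from genoscan.synteny import HomologyBlock, overlap_regions

logger = logging.getLogger(__name__)


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def _to_float(df: pd.DataFrame, col: str, path: str | Path) -> np.ndarray:
    # row-wise float() rather than pd.to_numeric: the latter's fast
    # parser is not correctly rounded and breaks exact round-trips
    raw = df[col].to_numpy()
    vals = np.empty(len(raw))
    for i, s in enumerate(raw):
        if s in (".", ""):
            vals[i] = np.nan
            continue
        try:
            vals[i] = float(s)
        except ValueError:
            raise ValueError(
                f"{path}: cannot parse {col}={s!r} on line {i + 2}"
            ) from None
    return vals


def _to_int(df: pd.DataFrame, col: str, path: str | Path) -> np.ndarray:
    vals = _to_float(df, col, path)
    if np.any(vals != np.floor(vals)):
        i = int(np.argmax(vals != np.floor(vals)))
        raise ValueError(f"{path}: non-integer {col} on line {i + 2}")
    return vals.astype(np.int64)


def read_de_table(path: str | Path) -> list[ProbesetStat]:
    """Read a differential-expression table.

    Required columns: ``probeset_id, gene_id, p_value, t_stat``;
    optional ``log_fc``. Missing gene_id is '.' or empty.
    """
    df = _read_tsv(path, ["probeset_id", "gene_id", "p_value", "t_stat"])
    p = _to_float(df, "p_value", path)
    t = _to_float(df, "t_stat", path)
    lfc = _to_float(df, "log_fc", path) if "log_fc" in df.columns else None
    out: list[ProbesetStat] = []
    for i in range(len(df)):
        gid = df["gene_id"].iat[i]
        out.append(
            ProbesetStat(
                probeset_id=df["probeset_id"].iat[i],
                gene_id=None if gid in (".", "") else gid,
                p_value=float(p[i]),
                t_stat=float(t[i]),
                log_fc=None
                if lfc is None or not np.isfinite(lfc[i])
                else float(lfc[i]),
            )
        )
    return out


def read_annotation(path: str | Path) -> list[GeneRecord]:
    """Read a BED-like gene annotation (1-based inclusive coordinates).

    Required columns: ``chrom, start, end, gene_id``. Duplicate gene_ids
    are rejected.
    """
    df = _read_tsv(path, ["chrom", "start", "end", "gene_id"])
    start = _to_int(df, "start", path)
    end = _to_int(df, "end", path)
    out: list[GeneRecord] = []
    seen: set[str] = set()
    for i in range(len(df)):
        gid = df["gene_id"].iat[i]
        if gid in seen:
            raise ValueError(f"{path}: duplicate gene_id {gid!r} on line {i + 2}")
        seen.add(gid)
        out.append(
            GeneRecord(
                gene_id=gid,
                chrom=df["chrom"].iat[i],
                start=int(start[i]),
                end=int(end[i]),
            )
        )
    return out


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom, length`` TSV."""
    df = _read_tsv(path, ["chrom", "length"])
    length = _to_int(df, "length", path)
    out: dict[str, int] = {}
    for i in range(len(df)):
        chrom = df["chrom"].iat[i]
        if chrom in out:
            raise ValueError(f"{path}: duplicate chromosome {chrom!r}")
        out[chrom] = int(length[i])
    return out


def read_blocks(path: str | Path) -> list[HomologyBlock]:
    """Read a homology-block table: ``m_chrom, m_start, m_end, h_label``."""
    df = _read_tsv(path, ["m_chrom", "m_start", "m_end", "h_label"])
    start = _to_int(df, "m_start", path)
    end = _to_int(df, "m_end", path)
    return [
        HomologyBlock(
            m_chrom=df["m_chrom"].iat[i],
            m_start=int(start[i]),
            m_end=int(end[i]),
            h_label=df["h_label"].iat[i],
        )
        for i in range(len(df))
    ]


def read_scan_tsv(path: str | Path) -> pd.DataFrame:
    """Read a scan output table written by :func:`write_scan_tsv`."""
    df = _read_tsv(
        path,
        [
            "chrom", "center_bp", "window_start", "window_end",
            "n_assayed", "k_dysregulated", "raw_p", "corrected_p",
            "score", "tested",
        ],
    )
    for col in ("center_bp", "window_start", "window_end", "n_assayed",
                "k_dysregulated", "tested"):
        df[col] = _to_int(df, col, path)
    for col in ("raw_p", "corrected_p", "score"):
        df[col] = _to_float(df, col, path)
    return df


def read_regions_tsv(path: str | Path) -> list[Region]:
    """Read a regions table written by :func:`write_regions_tsv`."""
    df = _read_tsv(
        path,
        ["chrom", "start", "end", "peak_center", "peak_score",
         "n_windows_merged"],
    )
    start = _to_int(df, "start", path)
    end = _to_int(df, "end", path)
    peak_center = _to_int(df, "peak_center", path)
    peak_score = _to_float(df, "peak_score", path)
    n_win = _to_int(df, "n_windows_merged", path)
    return [
        Region(
            chrom=df["chrom"].iat[i],
            start=int(start[i]),
            end=int(end[i]),
            peak_center=int(peak_center[i]),
            peak_score=float(peak_score[i]),
            n_windows=int(n_win[i]),
        )
        for i in range(len(df))
    ]


def read_values(path: str | Path) -> np.ndarray:
    """Read one numeric value per line (behavioral measurements)."""
    vals: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                vals.append(float(s))
            except ValueError:
                raise ValueError(
                    f"{path}: cannot parse value {s!r} on line {lineno}"
                ) from None
    return np.asarray(vals, dtype=float)


def infer_chrom_lengths(annotation: Sequence[GeneRecord]) -> dict[str, int]:
    """Fallback chromosome lengths: max(end) per chromosome (logged)."""
    out: dict[str, int] = {}
    for rec in annotation:
        out[rec.chrom] = max(out.get(rec.chrom, 0), rec.end)
    logger.info(
        "chromosome lengths inferred from annotation (max end per chromosome)"
    )
    return out


def write_scan_tsv(result: ScanResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_regions_tsv(regions: Sequence[Region], path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "peak_center": [r.peak_center for r in regions],
            "peak_score": [r.peak_score for r in regions],
            "n_windows_merged": [r.n_windows for r in regions],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_annotation_tsv(
    annotation: Sequence[GeneRecord], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "chrom": [r.chrom for r in annotation],
            "start": [r.start for r in annotation],
            "end": [r.end for r in annotation],
            "gene_id": [r.gene_id for r in annotation],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_de_tsv(stats: Sequence[GeneStat], path: str | Path) -> None:
    """Write gene-level statistics as a DE table (probeset_id = gene_id)."""
    pd.DataFrame(
        {
            "probeset_id": [s.gene_id for s in stats],
            "gene_id": [s.gene_id for s in stats],
            "p_value": [s.p_value for s in stats],
            "t_stat": [s.t_stat for s in stats],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """Inputs, parameters, and outputs of one full pipeline run."""

    de_table: Path
    annotation: Path
    out_dir: Path
    chrom_lengths: Optional[Path] = None
    blocks: Optional[Path] = None
    params: ScanParams = field(default_factory=ScanParams)
    threshold: float = 3.0
    min_overlap: int = 1
    seed: int = 0


def run_pipeline(config: RunConfig) -> dict:
    """Execute dedupe -> join -> scan -> regions -> (optional) synteny.

    Writes ``scan.tsv``, ``regions.tsv``, optionally ``synteny.tsv``,
    and a ``manifest.json`` recording parameters, seed, the Bonferroni
    multiplier M, and stage counts. Returns the manifest dict.
    """
    from genoscan import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name: str, fn):
        try:
            return fn()
        except ValueError as exc:
            raise ValueError(f"{name}: {exc}") from exc

    probesets = _stage("read_de_table", lambda: read_de_table(config.de_table))
    annotation = _stage(
        "read_annotation", lambda: read_annotation(config.annotation)
    )
    stats = _stage(
        "dedupe",
        lambda: dedupe_probesets(probesets, alpha_gene=config.params.alpha_gene),
    )
    genes = _stage("join", lambda: join_annotation(stats, annotation))
    if config.chrom_lengths is not None:
        lengths = _stage(
            "read_chrom_lengths",
            lambda: read_chrom_lengths(config.chrom_lengths),
        )
    else:
        lengths = infer_chrom_lengths(annotation)
    result = _stage(
        "scan", lambda: scan_genome(genes, lengths, config.params)
    )
    regions = _stage(
        "regions", lambda: significant_regions(result, config.threshold)
    )
    write_scan_tsv(result, out / "scan.tsv")
    write_regions_tsv(regions, out / "regions.tsv")

    synteny_rows = None
    if config.blocks is not None:
        blocks = _stage("read_blocks", lambda: read_blocks(config.blocks))
        report = _stage(
            "synteny",
            lambda: overlap_regions(regions, blocks, config.min_overlap),
        )
        report.to_csv(out / "synteny.tsv", sep="\t", index=False, float_format="%.17g")
        synteny_rows = int(len(report))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "params": {
            "step_bp": config.params.step_bp,
            "radius_bp": config.params.radius_bp,
            "alpha_gene": config.params.alpha_gene,
            "success_prob": config.params.success_prob,
            "score_cap": config.params.score_cap,
            "min_genes": config.params.min_genes,
            "use_empirical_rate": config.params.use_empirical_rate,
        },
        "threshold": config.threshold,
        "n_probesets": len(probesets),
        "n_genes_total": result.n_genes_total,
        "n_dysregulated_total": result.n_dysregulated_total,
        "M": result.M,
        "n_windows": len(result.windows),
        "n_regions": len(regions),
        "n_synteny_rows": synteny_rows,
        "chromosomes": sorted(lengths, key=chrom_sort_key),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
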