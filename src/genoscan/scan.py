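"""Staggered sliding-window binomial enrichment scan.

The scan walks each chromosome at ``step_bp`` intervals (1.25 Mb by
default, just under 2.5 cM in the mouse) and, at each window center,
counts the genes whose representative position falls within
``radius_bp`` of the center. With ``radius_bp == step_bp`` the windows
are staggered — each window overlaps its neighbors by 50%, so every
genomic position is covered by exactly two windows and a gene cluster
straddling one window's breakpoint lies in the interior of the next.

Under the null hypothesis of no positional enrichment, the number of
dysregulated genes (nominal P <= ``alpha_gene``) among the ``n`` genes
of a window is Binomial(n, ``success_prob``). Each tested window gets
the exact upper-tail probability P(X >= k), Bonferroni-corrected by the
number of tested windows genome-wide, and reported as the score
``min(score_cap, log10(1 / corrected_p))``. A score of 3 means a
corrected probability of 1 in 1,000 — the positional analogue of the
LOD-3 linkage cutoff.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special as sc

logger = logging.getLogger(__name__)

# floor for probabilities before taking log10, keeps corrected_p in (0, 1]
# even when the exact tail underflows double precision
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class ScanParams:
    """All constants of the enrichment scan.

    Parameters
    ----------
    step_bp : int
        Spacing of window centers along a chromosome (default 1.25 Mb).
    radius_bp : int
        Window half-width; a gene belongs to the window when its
        representative point lies in ``[center - radius, center + radius)``.
        Must be >= ``step_bp`` so consecutive windows overlap (staggered).
    alpha_gene : float
        Per-gene nominal P-value threshold for calling a gene
        dysregulated (comparison is ``<=``).
    success_prob : float
        Per-gene success probability of the binomial null.
    score_cap : float
        Scores are collapsed to this maximum (default 9, i.e. corrected
        probabilities below 1e-9 are collapsed to 1e-9).
    min_genes : int
        Minimum number of assayed genes for a window to be tested.
    use_empirical_rate : bool
        If True, replace ``success_prob`` by the observed genome-wide
        dysregulated fraction (sensitivity analysis; default off).
    """

    step_bp: int = 1_250_000
    radius_bp: int = 1_250_000
    alpha_gene: float = 0.01
    success_prob: float = 0.01
    score_cap: float = 9.0
    min_genes: int = 1
    use_empirical_rate: bool = False

    def __post_init__(self) -> None:
        if self.step_bp <= 0:
            raise ValueError(f"step_bp must be > 0, got {self.step_bp}")
        if self.radius_bp < self.step_bp:
            raise ValueError(
                f"radius_bp ({self.radius_bp}) must be >= step_bp "
                f"({self.step_bp}) to keep windows staggered"
            )
        if not 0.0 < self.alpha_gene < 1.0:
            raise ValueError(f"alpha_gene must be in (0, 1), got {self.alpha_gene}")
        if not 0.0 < self.success_prob < 1.0:
            raise ValueError(
                f"success_prob must be in (0, 1), got {self.success_prob}"
            )
        if self.score_cap <= 0:
            raise ValueError(f"score_cap must be > 0, got {self.score_cap}")
        if self.min_genes < 1:
            raise ValueError(f"min_genes must be >= 1, got {self.min_genes}")


@dataclass(frozen=True)
class WindowResult:
    """One window's counts and probabilities."""

    chrom: str
    center_bp: int
    n_assayed: int
    k_dysregulated: int
    raw_p: float
    corrected_p: float
    score: float
    tested: bool


@dataclass(frozen=True)
class Region:
    """A maximal run of significant windows, merged into one interval."""

    chrom: str
    start: int
    end: int
    peak_center: int
    peak_score: float
    n_windows: int


@dataclass(frozen=True)
class ScanResult:
    """Genome-wide scan output."""

    windows: tuple[WindowResult, ...]
    M: int
    params: ScanParams
    n_genes_total: int
    n_dysregulated_total: int

    def to_frame(self) -> pd.DataFrame:
        """Tabular view, one row per window, deterministic order."""
        p = self.params
        return pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "center_bp": [w.center_bp for w in self.windows],
                "window_start": [w.center_bp - p.radius_bp for w in self.windows],
                "window_end": [w.center_bp + p.radius_bp for w in self.windows],
                "n_assayed": [w.n_assayed for w in self.windows],
                "k_dysregulated": [w.k_dysregulated for w in self.windows],
                "raw_p": [w.raw_p for w in self.windows],
                "corrected_p": [w.corrected_p for w in self.windows],
                "score": [w.score for w in self.windows],
                "tested": [int(w.tested) for w in self.windows],
            }
        )


def chrom_sort_key(chrom: str) -> tuple:
    """Natural sort key so chr2 precedes chr10."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def window_centers(chrom_length: int, params: ScanParams) -> np.ndarray:
    """Window centers for one chromosome.

    Centers sit at integer multiples of ``step_bp`` starting at 0; a
    center is emitted while its window still reaches into the
    chromosome, i.e. while ``center - radius_bp < chrom_length``.
    """
    if chrom_length <= 0:
        raise ValueError(f"chrom_length must be > 0, got {chrom_length}")
    step, radius = params.step_bp, params.radius_bp
    # number of i >= 0 with i*step - radius < L  ==  ceil((L + radius)/step)
    n = -((chrom_length + radius) // -step)
    return np.arange(n, dtype=np.int64) * step


def bin_genes(
    genes: pd.DataFrame, center: int, params: ScanParams
) -> tuple[int, int]:
    """Count (assayed, dysregulated) genes in one window.

    A gene is a member iff ``center - radius <= rep_point < center + radius``
    (half-open on the right). ``genes`` must be sorted by ``rep_point``.
    """
    rep = genes["rep_point"].to_numpy(dtype=np.int64)
    lo = int(np.searchsorted(rep, center - params.radius_bp, side="left"))
    hi = int(np.searchsorted(rep, center + params.radius_bp, side="left"))
    n = hi - lo
    k = int(genes["dysregulated"].to_numpy()[lo:hi].sum())
    return n, k


# below this value scipy's sf loses relative accuracy (its internal
# computation underflows around 1e-275); switch to exact arithmetic
_SF_EXACT_BELOW = 1e-240


def _exact_tail(n: int, k: int, p: float) -> float:
    # exact big-integer tail: p = a/c with c a power of two, so
    # P(X >= k) = sum_{j>=k} C(n,j) a^j (c-a)^(n-j) / c^n, correctly
    # rounded by integer true division. The term recurrence
    # T_{j+1} = T_j (n-j) a / ((j+1) b) is exactly divisible; once terms
    # decrease, the neglected remainder is < 2^-60 of the sum, far below
    # double rounding.
    a, c = p.as_integer_ratio()
    b = c - a
    term = math.comb(n, k) * a**k * b ** (n - k)
    s = 0
    for j in range(k, n + 1):
        s += term
        if j == n:
            break
        term = term * ((n - j) * a) // ((j + 1) * b)
        if (n - j - 1) * a <= (j + 2) * b and (n - j) * term < (s >> 60):
            s += term
            break
    return s / c**n


def binomial_tail(n: int, k: int, p: float) -> float:
    """Binomial upper tail P(X >= k), X ~ Binomial(n, p).

    Returns a value in (0, 1]; k = 0 gives 1 (the whole mass). Computed
    through the regularized incomplete beta identity
    P(X >= k) = I_p(k, n - k + 1), with an exact integer-arithmetic
    fallback in the extreme tail where double-precision special
    functions lose relative accuracy; results are floored at 1e-300 so
    the value stays positive.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if k == 0:
        return 1.0
    tail = float(sc.betainc(k, n - k + 1, p))
    if tail < _SF_EXACT_BELOW:
        tail = _exact_tail(n, k, p)
    return float(min(max(tail, _P_FLOOR), 1.0))


def score_transform(corrected_p: float, params: ScanParams) -> float:
    """Capped log-inverse-probability score.

    ``min(score_cap, log10(1 / corrected_p))``: a corrected probability
    of 0.001 maps to 3; anything at or below ``10**-score_cap`` is
    collapsed to the cap (9 by default).
    """
    if not corrected_p > 0:
        raise ValueError(f"corrected_p must be > 0, got {corrected_p}")
    if corrected_p > 1:
        raise ValueError(f"corrected_p must be <= 1, got {corrected_p}")
    return float(min(params.score_cap, math.log10(1.0 / corrected_p)))


def scan_genome(
    genes: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    params: ScanParams = ScanParams(),
) -> ScanResult:
    """Run the staggered-window binomial scan over the whole genome.

    Parameters
    ----------
    genes : pandas.DataFrame
        Positioned gene table from :func:`genoscan.core.join_annotation`
        (columns ``gene_id, chrom, rep_point, dysregulated`` at least).
    chrom_lengths : mapping chrom -> length in bp
        Must cover every chromosome present in ``genes``.
    params : ScanParams

    Returns
    -------
    ScanResult
        Windows sorted by (chrom, center); the Bonferroni multiplier M
        is the number of windows with at least ``min_genes`` assayed
        genes, and ``corrected_p = min(1, raw_p * M)``. Windows below
        ``min_genes`` are reported untested with raw_p = corrected_p = 1
        and score 0 (their counts are still recorded).
    """
    missing = sorted(set(genes["chrom"]) - set(chrom_lengths))
    if missing:
        raise ValueError(
            f"chromosome(s) {missing} present in gene table but absent "
            "from chrom_lengths"
        )
    n_total = int(len(genes))
    n_dys_total = int(genes["dysregulated"].sum()) if n_total else 0

    p_success = params.success_prob
    if params.use_empirical_rate and n_total > 0:
        p_success = max(n_dys_total / n_total, 1e-12)
        logger.info("scan_genome: using empirical success rate %.4g", p_success)

    chroms = sorted(chrom_lengths, key=chrom_sort_key)
    per_chrom: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
    for chrom in chroms:
        centers = window_centers(int(chrom_lengths[chrom]), params)
        sub = genes[genes["chrom"] == chrom]
        rep = np.sort(sub["rep_point"].to_numpy(dtype=np.int64))
        order = np.argsort(sub["rep_point"].to_numpy(dtype=np.int64), kind="stable")
        dys = sub["dysregulated"].to_numpy()[order].astype(np.int64)
        cdys = np.concatenate([[0], np.cumsum(dys)])
        lo = np.searchsorted(rep, centers - params.radius_bp, side="left")
        hi = np.searchsorted(rep, centers + params.radius_bp, side="left")
        n = (hi - lo).astype(np.int64)
        k = cdys[hi] - cdys[lo]
        per_chrom.append((chrom, centers, n, k))

    M = int(sum(int((n >= params.min_genes).sum()) for _, _, n, _ in per_chrom))

    windows: list[WindowResult] = []
    for chrom, centers, n, k in per_chrom:
        tested = n >= params.min_genes
        raw = np.ones_like(centers, dtype=float)
        if tested.any():
            kt = k[tested]
            nt = n[tested]
            vals = np.ones(len(kt))
            pos = kt >= 1
            vals[pos] = sc.betainc(kt[pos], nt[pos] - kt[pos] + 1, p_success)
            raw[tested] = vals
            # extreme tails: scipy underflows, redo exactly (rare)
            deep = tested & (raw < _SF_EXACT_BELOW)
            for i in np.flatnonzero(deep):
                raw[i] = binomial_tail(int(n[i]), int(k[i]), p_success)
        raw = np.clip(raw, _P_FLOOR, 1.0)
        corrected = np.clip(raw * M, _P_FLOOR, 1.0)
        corrected[~tested] = 1.0
        raw[~tested] = 1.0
        score = np.minimum(params.score_cap, np.log10(1.0 / corrected))
        score = np.maximum(score, 0.0)
        for i in range(len(centers)):
            windows.append(
                WindowResult(
                    chrom=chrom,
                    center_bp=int(centers[i]),
                    n_assayed=int(n[i]),
                    k_dysregulated=int(k[i]),
                    raw_p=float(raw[i]),
                    corrected_p=float(corrected[i]),
                    score=float(score[i]),
                    tested=bool(tested[i]),
                )
            )

    return ScanResult(
        windows=tuple(windows),
        M=M,
        params=params,
        n_genes_total=n_total,
        n_dysregulated_total=n_dys_total,
    )


def significant_regions(
    result: ScanResult, threshold: float = 3.0
) -> list[Region]:
    """Merge significant windows into maximal enriched intervals.

    Windows with ``score >= threshold`` whose spans
    ``[center - radius, center + radius)`` overlap or touch on one
    chromosome are merged; each merged region reports its peak score and
    the center where the peak occurs.
    """
    radius = result.params.radius_bp
    regions: list[Region] = []
    cur: dict | None = None
    for w in result.windows:
        if w.score < threshold:
            continue
        w_start, w_end = w.center_bp - radius, w.center_bp + radius
        if cur is not None and cur["chrom"] == w.chrom and w_start <= cur["end"]:
            cur["end"] = max(cur["end"], w_end)
            cur["n"] += 1
            if w.score > cur["peak_score"]:
                cur["peak_score"] = w.score
                cur["peak_center"] = w.center_bp
        else:
            if cur is not None:
                regions.append(_close_region(cur))
            cur = {
                "chrom": w.chrom,
                "start": w_start,
                "end": w_end,
                "peak_center": w.center_bp,
                "peak_score": w.score,
                "n": 1,
            }
    if cur is not None:
        regions.append(_close_region(cur))
    return regions


def regions_from_scan_frame(
    df: pd.DataFrame, threshold: float = 3.0
) -> list[Region]:
    """Merge significant windows of a tabular scan (see ScanResult.to_frame).

    Same merge rule as :func:`significant_regions`, operating on the
    ``window_start``/``window_end`` columns so it can run on a scan
    table read back from disk.
    """
    regions: list[Region] = []
    cur: dict | None = None
    df = df.sort_values(["chrom", "center_bp"], kind="mergesort")
    for row in df.itertuples(index=False):
        if row.score < threshold:
            continue
        if (
            cur is not None
            and cur["chrom"] == row.chrom
            and row.window_start <= cur["end"]
        ):
            cur["end"] = max(cur["end"], row.window_end)
            cur["n"] += 1
            if row.score > cur["peak_score"]:
                cur["peak_score"] = row.score
                cur["peak_center"] = row.center_bp
        else:
            if cur is not None:
                regions.append(_close_region(cur))
            cur = {
                "chrom": row.chrom,
                "start": row.window_start,
                "end": row.window_end,
                "peak_center": row.center_bp,
                "peak_score": row.score,
                "n": 1,
            }
    if cur is not None:
        regions.append(_close_region(cur))
    return regions


def _close_region(cur: dict) -> Region:
    return Region(
        chrom=cur["chrom"],
        start=int(cur["start"]),
        end=int(cur["end"]),
        peak_center=int(cur["peak_center"]),
        peak_score=float(cur["peak_score"]),
        n_windows=int(cur["n"]),
    )
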