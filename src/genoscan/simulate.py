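"""Seeded synthetic-data generators with known ground truth.

Everything the scan and the permutation test consume can be simulated
here: gene annotations on a multi-chromosome genome, null
differential-expression tables (uniform P-values), planted windows with
an excess of sub-threshold P-values, and two-group behavioral samples
where one group is a bimodal location mixture — the statistical
structure of an inbred strain whose activity phenotype cycles between
two states, compared against a unimodal outbred control.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from genoscan.core import GeneRecord, GeneStat

_DEFAULT_N_CHROM = 20
_DEFAULT_CHROM_LEN = 100_000_000
_DEFAULT_N_GENES = 20_000


@dataclass(frozen=True)
class PlantedCluster:
    """A ground-truth enriched interval to plant into a null table.

    ``n_planted`` genes whose representative point lies in
    ``[start_bp, end_bp]`` (1-based inclusive) get their P-values
    resampled uniformly on ``(0, p_max]``.
    """

    chrom: str
    start_bp: int
    end_bp: int
    n_planted: int
    p_max: float

    def __post_init__(self) -> None:
        if self.start_bp < 1 or self.end_bp < self.start_bp:
            raise ValueError(
                f"planted interval [{self.start_bp}, {self.end_bp}] is invalid"
            )
        if self.n_planted < 0:
            raise ValueError(f"n_planted must be >= 0, got {self.n_planted}")
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError(f"p_max must be in (0, 1], got {self.p_max}")


@dataclass(frozen=True)
class FixtureSpec:
    """Configuration of one synthetic genome.

    Defaults emulate a mammalian-scale design: 20 chromosomes of 100 Mb
    and 20,000 assayed genes — the order of magnitude of a genome-wide
    expression platform — while staying fast enough for simulation
    studies.
    """

    n_chrom: int = _DEFAULT_N_CHROM
    chrom_lengths: tuple[int, ...] = field(
        default_factory=lambda: (_DEFAULT_CHROM_LEN,) * _DEFAULT_N_CHROM
    )
    n_genes: int = _DEFAULT_N_GENES
    placement: str = "uniform"
    planted: tuple[PlantedCluster, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chrom < 1:
            raise ValueError(f"n_chrom must be >= 1, got {self.n_chrom}")
        if len(self.chrom_lengths) != self.n_chrom:
            raise ValueError(
                f"chrom_lengths has {len(self.chrom_lengths)} entries for "
                f"n_chrom={self.n_chrom}"
            )
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.n_genes < 0:
            raise ValueError(f"n_genes must be >= 0, got {self.n_genes}")
        if self.placement not in ("uniform", "clustered"):
            raise ValueError(
                f"placement must be 'uniform' or 'clustered', got {self.placement!r}"
            )
        lengths = dict(zip(self.chrom_names(), self.chrom_lengths))
        for pc in self.planted:
            if pc.chrom not in lengths:
                raise ValueError(f"planted interval on unknown chrom {pc.chrom!r}")
            if pc.end_bp > lengths[pc.chrom]:
                raise ValueError(
                    f"planted interval [{pc.start_bp}, {pc.end_bp}] exceeds "
                    f"{pc.chrom} length {lengths[pc.chrom]}"
                )

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def chrom_length_map(self) -> dict[str, int]:
        return dict(zip(self.chrom_names(), self.chrom_lengths))


def simulate_annotation(spec: FixtureSpec) -> list[GeneRecord]:
    """Place ``spec.n_genes`` genes on the synthetic genome.

    ``uniform`` placement scatters genes genome-wide with probability
    proportional to chromosome length; ``clustered`` placement draws half
    of the genes around a few per-chromosome hotspots (normal with
    300 kb sd), mimicking the uneven gene density of real genomes. Gene
    lengths are uniform on 1-50 kb, clipped to the chromosome.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.chrom_names()
    lengths = np.asarray(spec.chrom_lengths, dtype=np.int64)
    if spec.n_genes == 0:
        return []

    chrom_idx = rng.choice(
        spec.n_chrom, size=spec.n_genes, p=lengths / lengths.sum()
    )
    gene_len = rng.integers(1_000, 50_001, size=spec.n_genes)
    chrom_len = lengths[chrom_idx]
    gene_len = np.minimum(gene_len, chrom_len)

    if spec.placement == "uniform":
        start = 1 + np.floor(
            rng.random(spec.n_genes) * (chrom_len - gene_len + 1)
        ).astype(np.int64)
    else:
        n_hot = 3
        hot = 1 + np.floor(
            rng.random((spec.n_chrom, n_hot)) * lengths[:, None]
        ).astype(np.int64)
        use_hot = rng.random(spec.n_genes) < 0.5
        which = rng.integers(0, n_hot, size=spec.n_genes)
        center = hot[chrom_idx, which]
        jitter = rng.normal(0.0, 300_000.0, size=spec.n_genes)
        start = np.where(
            use_hot,
            np.rint(center + jitter).astype(np.int64),
            1
            + np.floor(
                rng.random(spec.n_genes) * (chrom_len - gene_len + 1)
            ).astype(np.int64),
        )
        start = np.clip(start, 1, chrom_len - gene_len + 1)

    end = start + gene_len - 1
    records = [
        GeneRecord(
            gene_id=f"G{i:06d}",
            chrom=names[int(chrom_idx[i])],
            start=int(start[i]),
            end=int(end[i]),
        )
        for i in range(spec.n_genes)
    ]
    records.sort(key=lambda r: (r.chrom, r.rep_point, r.gene_id))
    return records


def simulate_null_pvalues(
    annotation: Sequence[GeneRecord],
    seed: int = 0,
    alpha_gene: float = 0.01,
) -> list[GeneStat]:
    """Draw i.i.d. uniform(0, 1] null P-values, one per annotated gene.

    Under this null the expected dysregulated fraction at
    ``alpha_gene = 0.01`` is exactly 0.01, matching the binomial model
    the scan assumes.
    """
    n = len(annotation)
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    p = 1.0 - rng.random(n)  # uniform on (0, 1]
    t = rng.standard_normal(n)
    return [
        GeneStat(
            gene_id=rec.gene_id,
            p_value=float(p[i]),
            t_stat=float(t[i]),
            dysregulated=bool(p[i] <= alpha_gene),
        )
        for i, rec in enumerate(annotation)
    ]


def plant_cluster(
    stats: Sequence[GeneStat],
    annotation: Sequence[GeneRecord],
    interval: tuple[str, int, int],
    n_planted: int,
    p_max: float,
    seed: int = 0,
    alpha_gene: float = 0.01,
) -> list[GeneStat]:
    """Resample ``n_planted`` genes inside ``interval`` to P in (0, p_max].

    ``interval`` is (chrom, start_bp, end_bp), 1-based inclusive on the
    genes' representative points. P-values are resampled uniformly on
    (0, p_max] rather than set to a constant, avoiding degenerate ties.
    All other genes are untouched.
    """
    if not 0.0 < p_max <= 1.0:
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    if n_planted < 0:
        raise ValueError(f"n_planted must be >= 0, got {n_planted}")
    if n_planted == 0:
        return list(stats)

    chrom, start_bp, end_bp = interval
    pos = {rec.gene_id: rec for rec in annotation}
    eligible = [
        i
        for i, s in enumerate(stats)
        if s.gene_id in pos
        and pos[s.gene_id].chrom == chrom
        and start_bp <= pos[s.gene_id].rep_point <= end_bp
    ]
    if len(eligible) < n_planted:
        raise ValueError(
            f"interval {chrom}:{start_bp}-{end_bp} holds {len(eligible)} "
            f"gene(s); cannot plant {n_planted} "
            f"(short by {n_planted - len(eligible)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_planted, replace=False)
    new_p = p_max * (1.0 - rng.random(n_planted))  # uniform on (0, p_max]

    out = list(stats)
    for j, ci in enumerate(chosen):
        i = eligible[int(ci)]
        s = out[i]
        out[i] = GeneStat(
            gene_id=s.gene_id,
            p_value=float(new_p[j]),
            t_stat=s.t_stat,
            dysregulated=bool(new_p[j] <= alpha_gene),
        )
    return out


def simulate_behavior(
    n_a: int,
    n_b: int,
    model: str = "bimodal",
    seed: int = 0,
    means: tuple[float, float] = (5.0, 15.0),
    sds: tuple[float, float] = (1.0, 1.0),
    weight: float = 0.5,
    control_mean: float = 5.0,
    control_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate two-group behavioral measurements.

    Group A is drawn from a two-component normal location mixture
    (bimodal — e.g. an animal cycling between low- and high-activity
    states); group B from a single normal (unimodal control). With
    ``model='null'`` both groups share the control distribution, giving
    exchangeable data for calibration checks.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError(f"each group needs >= 2 samples (got {n_a} and {n_b})")
    if model not in ("bimodal", "null"):
        raise ValueError(f"model must be 'bimodal' or 'null', got {model!r}")
    if not 0.0 < weight < 1.0:
        raise ValueError(f"mixture weight must be in (0, 1), got {weight}")
    if min(sds) <= 0 or control_sd <= 0:
        raise ValueError("standard deviations must be positive")

    rng = np.random.default_rng(seed)
    if model == "bimodal":
        comp = rng.random(n_a) < weight
        a = np.where(
            comp,
            rng.normal(means[0], sds[0], size=n_a),
            rng.normal(means[1], sds[1], size=n_a),
        )
    else:
        a = rng.normal(control_mean, control_sd, size=n_a)
    b = rng.normal(control_mean, control_sd, size=n_b)
    return a, b
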