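from __future__ import annotations

import numpy as np
import pytest

from genoscan import (
    FixtureSpec,
    PlantedCluster,
    simulate_annotation,
    simulate_null_pvalues,
)
from genoscan.core import join_annotation
from genoscan.io import write_annotation_tsv, write_de_tsv
from genoscan.simulate import plant_cluster

# small planted fixture reused across tests: 5 x 50 Mb chromosomes,
# 5,000 genes (20 genes/Mb), 10 genes planted in a 2 Mb interval that
# lies entirely inside the window centered at 11.25 Mb
PLANTED_INTERVAL = ("chr1", 10_200_000, 12_200_000)
N_PLANTED = 10
P_MAX = 0.009


def make_planted_spec(seed: int) -> FixtureSpec:
    return FixtureSpec(
        n_chrom=5,
        chrom_lengths=(50_000_000,) * 5,
        n_genes=5_000,
        planted=(
            PlantedCluster(
                chrom=PLANTED_INTERVAL[0],
                start_bp=PLANTED_INTERVAL[1],
                end_bp=PLANTED_INTERVAL[2],
                n_planted=N_PLANTED,
                p_max=P_MAX,
            ),
        ),
        seed=seed,
    )


def make_planted_genes(seed: int):
    """(positioned gene table, chrom length map) with the cluster planted."""
    spec = make_planted_spec(seed)
    ann = simulate_annotation(spec)
    stats = simulate_null_pvalues(ann, seed=seed + 1)
    stats = plant_cluster(
        stats, ann, PLANTED_INTERVAL, N_PLANTED, P_MAX, seed=seed + 2
    )
    return join_annotation(stats, ann), spec.chrom_length_map()


@pytest.fixture
def planted_genes():
    return make_planted_genes(seed=101)


@pytest.fixture
def pipeline_inputs(tmp_path):
    """On-disk DE table + annotation + chrom lengths for a planted fixture."""
    spec = make_planted_spec(seed=2024)
    ann = simulate_annotation(spec)
    stats = simulate_null_pvalues(ann, seed=2025)
    stats = plant_cluster(
        stats, ann, PLANTED_INTERVAL, N_PLANTED, P_MAX, seed=2026
    )
    de_path = tmp_path / "de.tsv"
    ann_path = tmp_path / "annotation.tsv"
    len_path = tmp_path / "chrom_lengths.tsv"
    write_de_tsv(stats, de_path)
    write_annotation_tsv(ann, ann_path)
    lengths = spec.chrom_length_map()
    with open(len_path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    return {
        "de": de_path,
        "annotation": ann_path,
        "lengths": len_path,
        "spec": spec,
        "tmp": tmp_path,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
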