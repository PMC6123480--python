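"""End-to-end convenience: samples → sketches → similarity → identification."""

from __future__ import annotations

import pandas as pd

from . import sketch as sk
from .identify import CohortMap, identify_all
from .sketch import KmerSketch, SequenceSample, SimilarityMatrix


def sketch_cohort(
    samples: list[SequenceSample],
    k: int = sk.DEFAULT_K,
    n: int = sk.DEFAULT_N,
    s_bases: int | None = None,
    abundance_cutoff: int = sk.DEFAULT_ABUNDANCE_CUTOFF,
    hash_seed: int = sk.DEFAULT_HASH_SEED,
    seed: int = 0,
) -> list[KmerSketch]:
    """Sketch every sample with shared parameters.

    Each sample's down-sampling stream is derived from ``seed`` and the
    sample index so runs are reproducible but samples are independent.
    """
    return [
        sk.sketch_sample(
            s,
            k=k,
            n=n,
            s_bases=s_bases,
            abundance_cutoff=abundance_cutoff,
            hash_seed=hash_seed,
            seed=seed + i,
        )
        for i, s in enumerate(samples)
    ]


def cohort_similarity(
    samples: list[SequenceSample],
    k: int = sk.DEFAULT_K,
    n: int = sk.DEFAULT_N,
    s_bases: int | None = None,
    abundance_cutoff: int = sk.DEFAULT_ABUNDANCE_CUTOFF,
    hash_seed: int = sk.DEFAULT_HASH_SEED,
    seed: int = 0,
) -> SimilarityMatrix:
    """All-vs-all estimated Jaccard matrix for a list of samples."""
    sketches = sketch_cohort(
        samples,
        k=k,
        n=n,
        s_bases=s_bases,
        abundance_cutoff=abundance_cutoff,
        hash_seed=hash_seed,
        seed=seed,
    )
    matrix = sk.pairwise_similarity(sketches)
    matrix.parameters["s_bases"] = s_bases
    return matrix


def run_identification(
    matrix: SimilarityMatrix,
    cohort: CohortMap,
    p_cut: float = 0.001,
    q_cut: float = 0.001,
    sim_cut: float = 0.0,
    family: str = "beta",
    min_fit: int = 30,
    correct_global: bool = False,
) -> tuple["pd.DataFrame", object]:
    """Run the directed identification test; returns (table, network)."""
    network, table = identify_all(
        matrix,
        cohort,
        p_cut=p_cut,
        q_cut=q_cut,
        sim_cut=sim_cut,
        family=family,
        min_fit=min_fit,
        correct_global=correct_global,
    )
    return table, network
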