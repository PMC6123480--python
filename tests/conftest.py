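import itertools

import numpy as np
import pytest

from gepmi import CohortMap, SimilarityMatrix


def brute_force_canonical_kmers(reads, k):
    """Independent pure-Python canonical k-mer counter (test oracle)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    counts = {}
    for read in reads:
        for i in range(len(read) - k + 1):
            window = read[i : i + k]
            if any(c not in comp for c in window):
                continue
            rc = "".join(comp[c] for c in reversed(window))
            canon = min(window, rc)
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def brute_force_jaccard(a, b):
    """Exact Jaccard of two sets (test oracle)."""
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


def brute_force_by(p):
    """Independent Benjamini–Yekutieli step-up (test oracle)."""
    p = list(p)
    m = len(p)
    c_m = sum(1.0 / j for j in range(1, m + 1))
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m * c_m / rank)
        q[i] = min(1.0, running)
    return q


@pytest.fixture
def toy_cohort():
    """4 individuals x 3 samples with well-separated intra/inter similarity."""
    rng = np.random.default_rng(7)
    individuals = [f"P{i}" for i in range(4)]
    ids = [f"{p}_V{v}" for p in individuals for v in range(3)]
    entries = {s: s.split("_")[0] for s in ids}
    m = len(ids)
    values = np.ones((m, m))
    for i, j in itertools.combinations(range(m), 2):
        same = entries[ids[i]] == entries[ids[j]]
        sim = rng.uniform(0.85, 0.95) if same else rng.beta(2, 50)
        values[i, j] = values[j, i] = sim
    matrix = SimilarityMatrix(sample_ids=ids, values=values)
    cohort = CohortMap(entries=entries)
    return matrix, cohort
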