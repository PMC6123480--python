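"""Directed query→target identification with FDR control.

Every sample in the cohort gets a null distribution fitted on its
similarities to samples from *other* individuals.  Testing query a against
target b evaluates b's null at the observed similarity; testing b against a
uses a's null, so the test — and the resulting network — is directed.
p-values are corrected per query with the Benjamini–Yekutieli step-up
(valid under arbitrary dependence), and edges are kept when all configured
thresholds pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nullmodel
from .errors import DegenerateDataError, InsufficientDataError
from .nullmodel import NullDistribution
from .sketch import SimilarityMatrix

logger = logging.getLogger(__name__)

DEFAULT_P_CUT = 0.001
DEFAULT_Q_CUT = 0.001
DEFAULT_SIM_CUT = 0.0


@dataclass
class CohortMap:
    """sample_id → individual_id mapping, with optional visit labels."""

    entries: dict[str, str]
    visits: dict[str, str] | None = None

    def individual(self, sample_id: str) -> str:
        return self.entries[sample_id]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "individual_id"}
        if not required.issubset(df.columns):
            raise ValueError(f"cohort TSV must have columns {sorted(required)}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in cohort TSV")
        entries = dict(zip(df["sample_id"], df["individual_id"]))
        visits = (
            dict(zip(df["sample_id"], df["visit"])) if "visit" in df.columns else None
        )
        return cls(entries=entries, visits=visits)

    def to_tsv(self, path: str | Path) -> None:
        rows = {"sample_id": list(self.entries), "individual_id": list(self.entries.values())}
        if self.visits is not None:
            rows["visit"] = [self.visits.get(s, "") for s in self.entries]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class TestResult:
    """One directed query→target test."""

    __test__ = False  # not a pytest class, despite the name

    query_id: str
    target_id: str
    similarity: float
    p_value: float
    q_value: float = float("nan")


@dataclass
class IdentificationNetwork:
    """Thresholded identification network (directed unless noted)."""

    nodes: list[str]
    edges: list[TestResult]
    threshold_spec: dict[str, float]
    directed: bool = True

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.query_id, e.target_id) for e in self.edges}

    def to_edge_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [
                {
                    "query_id": e.query_id,
                    "target_id": e.target_id,
                    "similarity": e.similarity,
                    "p_value": e.p_value,
                    "q_value": e.q_value,
                }
                for e in self.edges
            ]
        )
        df.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.query_id,
                e.target_id,
                similarity=e.similarity,
                p_value=e.p_value,
                q_value=e.q_value,
            )
        nx.write_graphml(g, str(path))


def inter_individual_values(
    target_id: str, matrix: SimilarityMatrix, cohort: CohortMap
) -> np.ndarray:
    """Similarities between the target and samples of other individuals."""
    if target_id not in matrix.sample_ids:
        raise KeyError(f"target {target_id!r} not in similarity matrix")
    if target_id not in cohort.entries:
        raise KeyError(f"target {target_id!r} not in cohort map")
    own = cohort.individual(target_id)
    i = matrix.sample_ids.index(target_id)
    values = [
        float(matrix.values[i, j])
        for j, other in enumerate(matrix.sample_ids)
        if other != target_id and cohort.individual(other) != own
    ]
    return np.asarray(values, dtype=float)


def build_null_for_target(
    target_id: str,
    matrix: SimilarityMatrix,
    cohort: CohortMap,
    family: str = "beta",
    min_fit: int = nullmodel.DEFAULT_MIN_FIT,
) -> NullDistribution:
    """Fit the target's inter-individual null.

    Uses exactly the similarities between the target and every sample whose
    individual differs from the target's (self and same-individual samples
    excluded).  ``family='auto'`` selects the best family by KS statistic;
    the default fits a beta directly.
    """
    values = inter_individual_values(target_id, matrix, cohort)
    if values.size < min_fit:
        raise InsufficientDataError(
            f"target {target_id!r}: {values.size} inter-individual values "
            f"< minimum fit size {min_fit}"
        )
    if family == "auto":
        return nullmodel.select_family(
            values, min_fit=min_fit, target_sample_id=target_id
        )
    return nullmodel.fit_distribution(
        values, family=family, min_fit=min_fit, target_sample_id=target_id
    )


def test_query(
    query_id: str,
    target_id: str,
    matrix: SimilarityMatrix,
    nulls: dict[str, NullDistribution],
) -> TestResult:
    """Directed test of a query against a target's null (p only; q deferred)."""
    if target_id not in nulls:
        raise KeyError(f"no fitted null for target {target_id!r}")
    sim = matrix.get(query_id, target_id)
    p = nullmodel.p_value(sim, nulls[target_id])
    return TestResult(query_id=query_id, target_id=target_id, similarity=sim, p_value=p)


def by_correction(p_values) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted q-values, in input order.

    With sorted p(1) <= ... <= p(m) and c(m) = sum_{j=1}^{m} 1/j, the raw
    adjusted value is p(i) * m * c(m) / i; q(i) = min(1, min_{j>=i} raw(j)).
    The harmonic factor makes the control valid under arbitrary dependence
    between the tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    ranks = np.arange(1, m + 1)
    raw = p[order] * m * c_m / ranks
    q_sorted = np.minimum(1.0, np.minimum.accumulate(raw[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def _passes(value: float, cut: float, greater: bool) -> bool:
    if cut == 0:
        return True  # a zero cutoff disables the criterion (mirrors "-s 0")
    if not greater and cut >= 1:
        return True  # p/q <= 1 always, so a cutoff of 1 filters nothing
    return value > cut if greater else value < cut


def identify_all(
    matrix: SimilarityMatrix,
    cohort: CohortMap,
    p_cut: float = DEFAULT_P_CUT,
    q_cut: float = DEFAULT_Q_CUT,
    sim_cut: float = DEFAULT_SIM_CUT,
    family: str = "beta",
    min_fit: int = nullmodel.DEFAULT_MIN_FIT,
    correct_global: bool = False,
) -> tuple[IdentificationNetwork, pd.DataFrame]:
    """Test every ordered (query, target) pair and threshold the network.

    BY correction is applied per query over that query's testable targets
    (``correct_global=True`` corrects across the whole directed table
    instead).  p/q thresholds use strict ``< cutoff``; the similarity
    threshold uses strict ``> cutoff``; a cutoff of 0 disables the p/q
    criterion and makes the similarity criterion vacuous.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    ids = matrix.sample_ids
    nulls: dict[str, NullDistribution] = {}
    for sid in ids:
        try:
            nulls[sid] = build_null_for_target(
                sid, matrix, cohort, family=family, min_fit=min_fit
            )
        except (InsufficientDataError, DegenerateDataError) as exc:
            logger.warning("skipping untestable target %s: %s", sid, exc)
    rows: list[TestResult] = []
    for query in ids:
        per_query: list[TestResult] = []
        for target in ids:
            if target == query or target not in nulls:
                continue
            per_query.append(test_query(query, target, matrix, nulls))
        if not per_query:
            continue
        if not correct_global:
            qvals = by_correction([r.p_value for r in per_query])
            for r, qv in zip(per_query, qvals):
                r.q_value = float(qv)
        rows.extend(per_query)
    if correct_global and rows:
        qvals = by_correction([r.p_value for r in rows])
        for r, qv in zip(rows, qvals):
            r.q_value = float(qv)

    spec = {"p": p_cut, "q": q_cut, "similarity": sim_cut}
    edges = [
        r
        for r in rows
        if _passes(r.p_value, p_cut, greater=False)
        and _passes(r.q_value, q_cut, greater=False)
        and _passes(r.similarity, sim_cut, greater=True)
    ]
    network = IdentificationNetwork(
        nodes=list(ids), edges=edges, threshold_spec=spec, directed=True
    )
    table = pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "target_id": r.target_id,
                "similarity": r.similarity,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "pass": (r.query_id, r.target_id) in network.edge_set(),
            }
            for r in rows
        ]
    )
    return network, table


def similarity_threshold_network(
    matrix: SimilarityMatrix, sim_cut: float
) -> IdentificationNetwork:
    """Undirected baseline: connect pairs whose similarity exceeds sim_cut."""
    ids = matrix.sample_ids
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            sim = float(matrix.values[i, j])
            if sim > sim_cut:
                edges.append(
                    TestResult(
                        query_id=ids[i],
                        target_id=ids[j],
                        similarity=sim,
                        p_value=float("nan"),
                    )
                )
    return IdentificationNetwork(
        nodes=list(ids),
        edges=edges,
        threshold_spec={"similarity": sim_cut},
        directed=False,
    )
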