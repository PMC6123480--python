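"""Scoring identification performance against ground-truth labels.

Given a table of directed query→target results and the true
sample→individual mapping, this module computes ROC and precision–recall
curves for any of the three scores (raw MinHash similarity, p-value,
q-value), observed false discovery rates along a cutoff grid, and the
combinatorial edge accounting used to judge identification networks
(each individual with n samples contributes n(n-1) directed intra edges).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .errors import EvaluationError
from .identify import CohortMap, IdentificationNetwork


@dataclass
class LabeledScoreSet:
    """Directed pair scores with same-individual labels.

    ``score_kind`` fixes the orientation: similarities are larger for
    same-individual pairs, while p and q values are smaller.
    """

    records: pd.DataFrame  # columns: query_id, target_id, score, label
    score_kind: str  # one of {"similarity", "p", "q"}

    def __post_init__(self) -> None:
        if self.score_kind not in ("similarity", "p", "q"):
            raise ValueError(f"unknown score_kind {self.score_kind!r}")

    @classmethod
    def from_results(
        cls, results: pd.DataFrame, cohort: CohortMap, score_kind: str
    ) -> "LabeledScoreSet":
        """Label a results table (as emitted by ``identify_all``)."""
        column = {"similarity": "similarity", "p": "p_value", "q": "q_value"}[score_kind]
        labels = [
            int(cohort.individual(q) == cohort.individual(t))
            for q, t in zip(results["query_id"], results["target_id"])
        ]
        df = pd.DataFrame(
            {
                "query_id": results["query_id"],
                "target_id": results["target_id"],
                "score": results[column].astype(float),
                "label": labels,
            }
        )
        return cls(records=df, score_kind=score_kind)

    def oriented_scores(self) -> np.ndarray:
        """Scores flipped so that larger always means 'same individual'."""
        s = self.records["score"].to_numpy(dtype=float)
        return s if self.score_kind == "similarity" else -s

    def labels(self) -> np.ndarray:
        return self.records["label"].to_numpy(dtype=int)


def roc_auc(scores: LabeledScoreSet) -> tuple[pd.DataFrame, float]:
    """ROC curve points and area under it."""
    y = scores.labels()
    if len(np.unique(y)) < 2:
        raise EvaluationError("ROC needs both classes present")
    s = scores.oriented_scores()
    fpr, tpr, thresholds = _skm.roc_curve(y, s)
    area = float(_skm.auc(fpr, tpr))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return curve, area


def pr_auc(scores: LabeledScoreSet) -> tuple[pd.DataFrame, float]:
    """Precision–recall curve points and step-wise area (average precision).

    The area uses the step-wise sum Σ (R_i − R_{i−1})·P_i, avoiding the
    optimistic bias of linear interpolation between operating points.
    """
    y = scores.labels()
    if y.sum() == 0:
        raise EvaluationError("precision-recall needs positive labels")
    s = scores.oriented_scores()
    precision, recall, thresholds = _skm.precision_recall_curve(y, s)
    area = float(_skm.average_precision_score(y, s))
    curve = pd.DataFrame(
        {
            "precision": precision[:-1],
            "recall": recall[:-1],
            "threshold": thresholds,
        }
    )
    return curve, area


def empirical_fdr_curve(
    scores: LabeledScoreSet, cutoffs
) -> list[tuple[float, float]]:
    """Observed FDR (false calls / all calls) at each p/q cutoff.

    A call is a pair whose score is strictly below the cutoff; with no
    calls the observed FDR is reported as 0.
    """
    if scores.score_kind not in ("p", "q"):
        raise ValueError("empirical FDR is defined for p or q scores")
    s = scores.records["score"].to_numpy(dtype=float)
    y = scores.labels()
    out = []
    for cut in cutoffs:
        called = s < cut
        n_called = int(called.sum())
        if n_called == 0:
            out.append((float(cut), 0.0))
        else:
            false_calls = int((called & (y == 0)).sum())
            out.append((float(cut), false_calls / n_called))
    return out


def expected_intra_edge_count(cohort: CohortMap, extra_groups=None) -> int:
    """Directed same-individual pair count: Σ_i n_i(n_i − 1).

    ``extra_groups`` adds ordered pairs within explicitly related sample
    groups (e.g. samples sharing a stool donor): Σ_j g_j(g_j − 1).  A pair
    counted twice — by two groups, or by a group and the individual
    structure — raises an error.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    counted: set[tuple[str, str]] = set()
    by_individual: dict[str, list[str]] = {}
    for sid, ind in cohort.entries.items():
        by_individual.setdefault(ind, []).append(sid)
    for members in by_individual.values():
        for a in members:
            for b in members:
                if a != b:
                    counted.add((a, b))
    total = len(counted)
    for group in extra_groups or []:
        group = list(group)
        for a in group:
            for b in group:
                if a == b:
                    continue
                if (a, b) in counted:
                    raise ValueError(
                        f"pair ({a!r}, {b!r}) double-counted by extra groups"
                    )
                counted.add((a, b))
                total += 1
    return total


class EdgeAccuracy(NamedTuple):
    true_edges_found: int
    expected_intra_edges: int
    false_positive_edges: int
    accuracy: float


def network_edge_accuracy(
    network: IdentificationNetwork, cohort: CohortMap, extra_groups=None
) -> EdgeAccuracy:
    """Fraction of expected intra-individual directed edges recovered.

    False positives are edges joining samples of different individuals
    (and outside any extra group).  For an undirected network each edge
    counts in both directions.
    """
    expected = expected_intra_edge_count(cohort, extra_groups=extra_groups)
    related: set[tuple[str, str]] = set()
    by_individual: dict[str, list[str]] = {}
    for sid, ind in cohort.entries.items():
        by_individual.setdefault(ind, []).append(sid)
    for members in by_individual.values():
        for a in members:
            for b in members:
                if a != b:
                    related.add((a, b))
    for group in extra_groups or []:
        group = list(group)
        for a in group:
            for b in group:
                if a != b:
                    related.add((a, b))
    edges = set(network.edge_set())
    if not network.directed:
        edges |= {(b, a) for a, b in edges}
    found = sum(1 for e in edges if e in related)
    false_pos = len(edges) - found
    accuracy = found / expected if expected else 0.0
    return EdgeAccuracy(found, expected, false_pos, accuracy)
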