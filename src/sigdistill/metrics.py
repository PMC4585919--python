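"""External cluster-validation indices: the Rand index and the clustering
F-measure (F-value).

Both indices compare a clustering V against a ground-truth partition U of the
same elements and lie in [0, 1], reaching 1 exactly when the two partitions
are identical up to class names.

Rand index
    The fraction of element pairs on which the two partitions agree — pairs
    co-clustered in both or separated in both, out of all C(n, 2) pairs.

Clustering F-measure
    For each truth class U_i and cluster V_j, precision p = |U_i∩V_j|/|V_j|
    and recall r = |U_i∩V_j|/|U_i| give F(U_i, V_j) = 2pr/(p+r) (0 when the
    intersection is empty).  Each truth class takes its best-matching cluster,
    F(U_i) = max_j F(U_i, V_j), and the overall F-value is the class-size
    weighted mean  F = Σ_i (|U_i|/n)·F(U_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .partition import Partition, check_same_elements

__all__ = ["ValidationScore", "rand_index", "f_value", "score_partitions"]


@dataclass(frozen=True)
class ValidationScore:
    """Rand index and F-value of one clustering against ground truth."""

    rand: float
    f_value: float
    per_class_f: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "rand": self.rand,
            "f_value": self.f_value,
            "per_class_f": dict(self.per_class_f),
        }


def _contingency(u: Partition, v: Partition) -> tuple[np.ndarray, tuple[str, ...]]:
    """Class-by-cluster intersection counts N_ij (rows = U classes, cols = V
    classes) and the row (U-class) labels."""
    check_same_elements(u, v)
    n = len(u)
    if n < 2:
        raise ValueError(f"need at least 2 elements, got {n}")
    iu = {lab: i for i, lab in enumerate(u.labels)}
    iv = {lab: j for j, lab in enumerate(v.labels)}
    cu = np.fromiter((iu[u.class_of[e]] for e in u.element_ids), dtype=np.intp, count=n)
    cv = np.fromiter((iv[v.class_of[e]] for e in u.element_ids), dtype=np.intp, count=n)
    table = np.zeros((len(iu), len(iv)), dtype=np.int64)
    np.add.at(table, (cu, cv), 1)
    return table, u.labels


def rand_index(u: Partition, v: Partition) -> float:
    """Rand index between two partitions of the same element set.

    Computed from the contingency table with integer pair counts, so the
    result is exact: (a + d) / C(n, 2) where a counts pairs co-clustered in
    both partitions and d pairs separated in both.
    """
    table, _ = _contingency(u, v)
    n = int(table.sum())

    def pairs(x: np.ndarray) -> int:
        return int((x * (x - 1) // 2).sum())

    total = n * (n - 1) // 2
    a = pairs(table)  # co-clustered in both
    same_u = pairs(table.sum(axis=1))
    same_v = pairs(table.sum(axis=0))
    # separated in both = total - (same in U only) - (same in V only) - a
    d = total - same_u - same_v + a
    return (a + d) / total


def f_value(u: Partition, v: Partition) -> tuple[float, dict[str, float]]:
    """Clustering F-measure of V against truth U.

    Returns the overall class-size-weighted F-value and the per-class
    best-match F scores.
    """
    table, u_labels = _contingency(u, v)
    n = int(table.sum())
    u_sizes = table.sum(axis=1, keepdims=True)  # |U_i|
    v_sizes = table.sum(axis=0, keepdims=True)  # |V_j|
    with np.errstate(invalid="ignore", divide="ignore"):
        p = table / v_sizes
        r = table / u_sizes
        f = np.where(table > 0, 2.0 * p * r / (p + r), 0.0)
    best = f.max(axis=1)
    per_class = {lab: float(b) for lab, b in zip(u_labels, best)}
    overall = float((u_sizes[:, 0] / n * best).sum())
    return overall, per_class


def score_partitions(truth: Partition, clustered: Partition) -> ValidationScore:
    """Convenience wrapper computing both indices at once."""
    overall_f, per_class = f_value(truth, clustered)
    return ValidationScore(
        rand=rand_index(truth, clustered), f_value=overall_f, per_class_f=per_class
    )
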