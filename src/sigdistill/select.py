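"""Cohesiveness-guided signature distillation.

The core two-step procedure reduces a candidate gene panel (or one panel per
subtype) to a compact signature:

1.  For every class C_r of candidate genes, measure its *cohesiveness*
    Co(C_r) = 1 / d̄(C_r), the inverse of the mean pairwise Euclidean
    distance between the class's gene expression vectors.  The number of
    representatives the class needs is

        N(C_r) = clamp(round(K · d̄(C_r)), 1, |C_r|)

    where K > 0 is the *cohesive strength*, shared by all classes: diverse
    classes (low cohesiveness) get more representatives, tight ones fewer,
    and every class keeps at least one gene.

2.  Partition the class's genes into N(C_r) subclasses by average-linkage
    hierarchical clustering and take from each subclass the gene nearest to
    the subclass's mean expression vector (the nearest-to-center principle).

K itself is chosen by sweeping a grid and maximizing the clustering F-value
obtained when samples are re-clustered using only the candidate signature;
ties prefer the smaller signature, then the smaller K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .clustering import average_linkage, cut, euclidean_distances, standardize
from .metrics import ValidationScore, score_partitions
from .panels import GenePanel, union_panels
from .partition import Partition

__all__ = [
    "ClassCohesion",
    "ClassSelection",
    "SweepPoint",
    "SelectionResult",
    "cohesiveness",
    "feature_count",
    "subclass_partition",
    "nearest_to_center",
    "default_k_grid",
    "sweep_K",
    "select_signature",
    "evaluate_signature",
]


@dataclass(frozen=True)
class ClassCohesion:
    """Within-class tightness of a gene class.

    ``cohesiveness`` is ``math.inf`` exactly when the class is a singleton or
    all its gene vectors coincide (zero mean pairwise distance).
    """

    class_label: str
    member_genes: GenePanel
    mean_pairwise_distance: float
    cohesiveness: float


@dataclass(frozen=True)
class ClassSelection:
    """Per-class outcome of the distillation at the chosen K."""

    cohesion: ClassCohesion
    chosen_K: float
    n_features: int
    subclasses: Partition
    representatives: GenePanel


@dataclass(frozen=True)
class SweepPoint:
    K: float
    signature_size: int
    f_value: float
    class_label: str | None = None  # None for a shared-K sweep


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a K sweep: the signature and how it was arrived at."""

    mode: str
    chosen_K: float | None  # None when each class swept its own K
    per_class: dict[str, ClassSelection]
    signature: GenePanel
    score: ValidationScore
    sweep_trace: tuple[SweepPoint, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "chosen_K": self.chosen_K,
            "per_class": {
                label: {
                    "cohesiveness": sel.cohesion.cohesiveness,
                    "mean_pairwise_distance": sel.cohesion.mean_pairwise_distance,
                    "class_size": len(sel.cohesion.member_genes),
                    "chosen_K": sel.chosen_K,
                    "n_features": sel.n_features,
                    "representatives": list(sel.representatives),
                }
                for label, sel in self.per_class.items()
            },
            "signature": list(self.signature),
            "score": self.score.as_dict(),
            "sweep_trace": [
                {
                    "K": p.K,
                    "signature_size": p.signature_size,
                    "f_value": p.f_value,
                    "class": p.class_label,
                }
                for p in self.sweep_trace
            ],
        }


def _gene_vectors(genes: GenePanel, expr: pd.DataFrame) -> pd.DataFrame:
    unknown = [g for g in genes if g not in expr.index]
    if unknown:
        raise KeyError(f"gene IDs absent from the expression matrix: {unknown}")
    return expr.loc[list(genes)]


def cohesiveness(genes: GenePanel, expr: pd.DataFrame, class_label: str | None = None) -> ClassCohesion:
    """Inverse mean pairwise Euclidean distance between a class's gene vectors.

    Tighter classes (more similar expression profiles) score higher; a
    singleton or zero-diameter class gets the +infinity sentinel.
    """
    if len(genes) < 1:
        raise ValueError("class must contain at least one gene")
    vectors = _gene_vectors(genes, expr)
    if len(genes) == 1:
        mean_d = 0.0
    else:
        mean_d = float(pdist(vectors.to_numpy(dtype=float), metric="euclidean").mean())
    co = math.inf if mean_d == 0.0 else 1.0 / mean_d
    return ClassCohesion(
        class_label=class_label or genes.name,
        member_genes=genes,
        mean_pairwise_distance=mean_d,
        cohesiveness=co,
    )


def feature_count(cohesion: ClassCohesion, K: float) -> int:
    """N(C_r) = clamp(round(K · d̄), 1, |C_r|): representatives needed at strength K.

    Rounding is half-up so the count is a deterministic, monotone step
    function of K.  An infinitely cohesive class always needs exactly one.
    """
    if K <= 0:
        raise ValueError(f"cohesive strength K must be > 0, got {K}")
    m = len(cohesion.member_genes)
    if not math.isfinite(cohesion.cohesiveness):
        return 1
    raw = int(math.floor(K * cohesion.mean_pairwise_distance + 0.5))
    return max(1, min(raw, m))


def subclass_partition(genes: GenePanel, expr: pd.DataFrame, n_subclasses: int) -> Partition:
    """Split a gene class into n_subclasses by UPGMA over gene expression vectors."""
    if not 1 <= n_subclasses <= len(genes):
        raise ValueError(
            f"n_subclasses must be in [1, {len(genes)}], got {n_subclasses}"
        )
    vectors = _gene_vectors(genes, expr)
    if len(genes) == 1:
        return Partition.from_clusters({"C1": list(genes)})
    dm = euclidean_distances(vectors, axis="genes")
    return cut(average_linkage(dm), n_subclasses)


def nearest_to_center(genes: GenePanel | Sequence[str], expr: pd.DataFrame) -> str:
    """The subclass member closest (Euclidean) to the subclass's mean vector.

    Ties go to the lexicographically smallest gene ID.
    """
    ids = list(genes)
    if not ids:
        raise ValueError("subclass is empty")
    # contiguous copy: summation order (hence exact ties) must not depend on
    # how the DataFrame happens to be laid out in memory
    vectors = np.ascontiguousarray(expr.loc[ids].to_numpy(dtype=float))
    center = vectors.mean(axis=0)
    dist = np.sqrt(((vectors - center) ** 2).sum(axis=1))
    best = min(range(len(ids)), key=lambda i: (dist[i], ids[i]))
    return ids[best]


def default_k_grid(cohesions: Sequence[ClassCohesion], n_points: int = 40) -> tuple[float, ...]:
    """Log-spaced K grid guaranteed to visit both the N = 1 and N = |C_r| regimes.

    The lower end makes round(K·d̄) clamp to 1 for every class; the upper end
    pushes every finite-cohesion class to its full size.
    """
    finite = [c.mean_pairwise_distance for c in cohesions if c.mean_pairwise_distance > 0]
    if not finite:
        return (1.0,)
    k_lo = 0.5 / max(finite)
    k_hi = max(len(c.member_genes) for c in cohesions) / min(finite)
    if k_hi <= k_lo:
        k_hi = 2 * k_lo
    return tuple(np.geomspace(k_lo, k_hi, n_points))


def _representatives_at(
    cohesion: ClassCohesion, expr: pd.DataFrame, n: int
) -> tuple[Partition, GenePanel]:
    part = subclass_partition(cohesion.member_genes, expr, n)
    reps = [
        nearest_to_center(members, expr) for members in part.classes.values()
    ]
    return part, GenePanel(f"{cohesion.class_label}-representatives", tuple(reps))


def evaluate_signature(
    expr: pd.DataFrame,
    labels: pd.Series,
    signature: GenePanel,
    *,
    standardized: pd.DataFrame | None = None,
) -> ValidationScore:
    """Score a signature: cluster samples on it and compare with the labeling.

    Samples are clustered with average linkage on Euclidean distances over
    the (per-gene standardized) signature rows and the dendrogram is cut at
    the number of distinct subtype labels.
    """
    z = standardized if standardized is not None else standardize(expr)
    # sort rows by gene ID so the score is numerically independent of the
    # order classes contributed their representatives
    sub = z.loc[sorted(signature), list(labels.index)]
    dm = euclidean_distances(sub, axis="samples")
    clustered = cut(average_linkage(dm), labels.nunique())
    return score_partitions(Partition.from_labels(labels), clustered)


def sweep_K(
    expr: pd.DataFrame,
    labels: pd.Series,
    panels: Mapping[str, GenePanel],
    K_grid: Sequence[float] | None = None,
    *,
    mode_label: str = "pooled",
) -> SelectionResult:
    """Shared-K sweep over one or more gene classes.

    For every K in the grid: compute each class's feature count, partition it
    into subclasses, pick nearest-to-center representatives, form the
    deduplicated signature, and score it by re-clustering the samples.  The
    result reported is for the F-value-maximizing K; ties prefer the smaller
    signature, then the smaller K.
    """
    if not panels:
        raise ValueError("no gene classes supplied")
    for label, panel in panels.items():
        if len(panel) == 0:
            raise ValueError(f"class {label!r} has an empty panel")
    cohesions = {
        label: cohesiveness(panel, expr, class_label=label)
        for label, panel in panels.items()
    }
    if K_grid is None:
        K_grid = default_k_grid(list(cohesions.values()))
    K_grid = tuple(float(k) for k in K_grid)
    if not K_grid:
        raise ValueError("K grid is empty")
    if any(k <= 0 for k in K_grid):
        raise ValueError("K grid values must be > 0")

    z = standardize(expr)
    rep_cache: dict[tuple[str, int], tuple[Partition, GenePanel]] = {}
    trace: list[SweepPoint] = []
    best: tuple[float, int, float] | None = None  # (-f, size, K) minimized
    best_state: tuple[float, dict[str, ClassSelection], GenePanel, ValidationScore] | None = None

    for K in K_grid:
        selections: dict[str, ClassSelection] = {}
        for label, coh in cohesions.items():
            n = feature_count(coh, K)
            if (label, n) not in rep_cache:
                rep_cache[(label, n)] = _representatives_at(coh, expr, n)
            part, reps = rep_cache[(label, n)]
            selections[label] = ClassSelection(
                cohesion=coh, chosen_K=K, n_features=n, subclasses=part, representatives=reps
            )
        signature = union_panels(
            (sel.representatives for sel in selections.values()), name="signature"
        )
        score = evaluate_signature(expr, labels, signature, standardized=z)
        trace.append(SweepPoint(K=K, signature_size=len(signature), f_value=score.f_value))
        key = (-score.f_value, len(signature), K)
        if best is None or key < best:
            best = key
            best_state = (K, selections, signature, score)

    assert best_state is not None
    chosen_K, selections, signature, score = best_state
    return SelectionResult(
        mode=mode_label,
        chosen_K=chosen_K,
        per_class=selections,
        signature=signature,
        score=score,
        sweep_trace=tuple(trace),
    )


def select_signature(
    expr: pd.DataFrame,
    labels: pd.Series,
    panels: Mapping[str, GenePanel] | GenePanel,
    mode: str = "pooled",
    K_grid: Sequence[float] | None = None,
) -> SelectionResult:
    """Distill a signature from candidate panels.

    ``mode="pooled"`` optimizes one shared cohesive strength K across all
    supplied classes (a single panel is treated as one class).
    ``mode="per_subtype"`` requires one panel per subtype label, sweeps K
    independently for each, and unifies the chosen representatives into one
    deduplicated signature, which is then scored as a whole.
    """
    if isinstance(panels, GenePanel):
        panels = {panels.name: panels}
    if mode == "pooled":
        return sweep_K(expr, labels, panels, K_grid, mode_label="pooled")
    if mode != "per_subtype":
        raise ValueError(f"mode must be 'pooled' or 'per_subtype', got {mode!r}")

    subtype_labels = set(labels.unique())
    missing = subtype_labels - set(panels)
    if missing:
        raise ValueError(f"per_subtype mode needs a panel for every subtype; missing: {sorted(missing)}")

    per_class: dict[str, ClassSelection] = {}
    trace: list[SweepPoint] = []
    for label in panels:
        single = sweep_K(expr, labels, {label: panels[label]}, K_grid, mode_label="per_subtype")
        per_class[label] = single.per_class[label]
        trace.extend(
            SweepPoint(p.K, p.signature_size, p.f_value, class_label=label)
            for p in single.sweep_trace
        )
    signature = union_panels(
        (sel.representatives for sel in per_class.values()), name="unified-signature"
    )
    score = evaluate_signature(expr, labels, signature)
    return SelectionResult(
        mode="per_subtype",
        chosen_K=None,
        per_class=per_class,
        signature=signature,
        score=score,
        sweep_trace=tuple(trace),
    )
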