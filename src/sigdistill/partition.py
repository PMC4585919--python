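"""Partitions of a finite element set into named, non-empty classes.

Used for both the ground-truth subtype labeling U and the clustering result V
when computing external validation indices, and for gene subclass assignments
during signature selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd


@dataclass(frozen=True)
class Partition:
    """An assignment of every element to exactly one named class."""

    element_ids: tuple[str, ...]
    class_of: dict[str, str]

    _classes: dict[str, tuple[str, ...]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = tuple(str(e) for e in self.element_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate element IDs in partition")
        missing = [e for e in ids if e not in self.class_of]
        if missing:
            raise ValueError(f"elements without a class: {missing}")
        extra = set(self.class_of) - set(ids)
        if extra:
            raise ValueError(f"class assignments for unknown elements: {sorted(extra)}")
        object.__setattr__(self, "element_ids", ids)
        classes: dict[str, list[str]] = {}
        for e in ids:
            classes.setdefault(str(self.class_of[e]), []).append(e)
        object.__setattr__(
            self, "_classes", {lab: tuple(members) for lab, members in classes.items()}
        )

    @property
    def classes(self) -> dict[str, tuple[str, ...]]:
        """Map class label -> members, in element order; insertion order = first occurrence."""
        return dict(self._classes)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._classes)

    @property
    def n_classes(self) -> int:
        return len(self._classes)

    def __len__(self) -> int:
        return len(self.element_ids)

    @classmethod
    def from_labels(cls, labels: Mapping[str, str] | pd.Series) -> "Partition":
        """Build from an element -> class mapping (e.g. a sample labeling)."""
        if isinstance(labels, pd.Series):
            labels = {str(k): str(v) for k, v in labels.items()}
        return cls(tuple(labels), dict(labels))

    @classmethod
    def from_clusters(cls, clusters: Mapping[str, Iterable[str]]) -> "Partition":
        """Build from a class -> members mapping."""
        class_of: dict[str, str] = {}
        order: list[str] = []
        for lab, members in clusters.items():
            for m in members:
                m = str(m)
                if m in class_of:
                    raise ValueError(f"element {m!r} assigned to more than one class")
                class_of[m] = str(lab)
                order.append(m)
        return cls(tuple(order), class_of)

    def relabeled(self, mapping: Mapping[str, str]) -> "Partition":
        """Rename classes; class structure unchanged."""
        return Partition(
            self.element_ids, {e: str(mapping.get(c, c)) for e, c in self.class_of.items()}
        )

    def to_series(self) -> pd.Series:
        return pd.Series(
            [self.class_of[e] for e in self.element_ids],
            index=list(self.element_ids),
            name="class",
        )


def check_same_elements(u: Partition, v: Partition) -> None:
    """Raise if the two partitions do not cover the identical element set."""
    su, sv = set(u.element_ids), set(v.element_ids)
    if su != sv:
        diff = sorted(su.symmetric_difference(sv))
        raise ValueError(f"partitions cover different element sets; symmetric difference: {diff}")
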