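"""Gene panels: named, ordered, duplicate-free collections of gene IDs.

A panel is the unit of currency throughout the pipeline: the input
differential-gene lists, the per-subtype candidate sets, and the distilled
signature are all :class:`GenePanel` objects.  Order is preserved (it is the
order genes appeared in the source list) and set operations are order-stable
with respect to the left operand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


@dataclass(frozen=True)
class GenePanel:
    """A named ordered set of gene identifiers.

    Parameters
    ----------
    name
        Human-readable panel label (e.g. ``"diff-genes"``, ``"signature"``).
    genes
        Gene IDs in order; duplicates are rejected.
    """

    name: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.genes)
        seen: set[str] = set()
        dups = [g for g in genes if g in seen or seen.add(g)]  # type: ignore[func-returns-value]
        if dups:
            raise ValueError(f"panel {self.name!r} has duplicate gene IDs: {sorted(set(dups))}")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in set(self.genes)

    def intersection(self, other: "GenePanel", name: str | None = None) -> "GenePanel":
        """Order-stable intersection: keeps this panel's gene order."""
        other_set = set(other.genes)
        return GenePanel(
            name or f"{self.name}&{other.name}",
            tuple(g for g in self.genes if g in other_set),
        )

    def union(self, other: "GenePanel", name: str | None = None) -> "GenePanel":
        """Order-stable union: this panel's genes first, then new ones from `other`."""
        mine = set(self.genes)
        return GenePanel(
            name or f"{self.name}|{other.name}",
            self.genes + tuple(g for g in other.genes if g not in mine),
        )

    def restrict_to(self, available: Iterable[str], name: str | None = None) -> "GenePanel":
        """Drop genes not present in `available`, preserving order."""
        avail = set(available)
        return GenePanel(name or self.name, tuple(g for g in self.genes if g in avail))

    def write(self, path: str | Path) -> None:
        """Write one gene ID per line."""
        Path(path).write_text("".join(f"{g}\n" for g in self.genes), encoding="utf-8")

    @classmethod
    def read(cls, path: str | Path, name: str | None = None) -> "GenePanel":
        """Read a panel file: one gene ID per line, ``#`` comments and blanks skipped."""
        path = Path(path)
        genes = []
        for line in path.read_text(encoding="utf-8").splitlines():
            entry = line.split("#", 1)[0].strip()
            if entry:
                genes.append(entry)
        return cls(name or path.stem, tuple(genes))


def union_panels(panels: Iterable[GenePanel], name: str = "pooled") -> GenePanel:
    """Deduplicated, order-stable union of several panels (first occurrence wins)."""
    out: list[str] = []
    seen: set[str] = set()
    for panel in panels:
        for g in panel:
            if g not in seen:
                seen.add(g)
                out.append(g)
    return GenePanel(name, tuple(out))


def panel_overlap(a: GenePanel, b: GenePanel) -> GenePanel:
    """Order-stable intersection of two panels (order follows `a`)."""
    return a.intersection(b)
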