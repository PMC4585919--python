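"""Synthetic expression matrices with planted subtype structure.

The generator emulates the shape of log-scale tumor expression data grouped
into immunohistochemistry-defined subtypes: for each subtype a number of
*blocks* of redundant informative genes is planted, whose members are
mean-shifted in that subtype's samples and correlated with one another
through a shared per-sample latent factor; the remaining genes are pure
Gaussian noise.  The planted structure (which genes are informative for which
subtype, and their block membership) is returned as ground truth so that
signature-recovery experiments can be scored.

Block correlation construction: with target correlation ρ and latent factor
f_s ~ N(0,1) per (block, sample), a member gene takes the value

    x_gs = noise_sd · (√ρ·f_s + √(1−ρ)·ε_gs) + shift·1[s in subtype]

with ε_gs ~ N(0,1) i.i.d., giving Var = noise_sd² and exact pairwise
correlation ρ within the block.  The mean shift is ``effect_size`` expressed
in noise-SD units, i.e. shift = effect_size · noise_sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panels import GenePanel, union_panels

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_layer",
    "truth_panels",
    "pooled_panel",
    "default_subtype_names",
]


def default_subtype_names(n: int) -> tuple[str, ...]:
    """Receptor-status style subtype labels for the 2- and 4-class schemes."""
    if n == 2:
        return ("ER+", "ER-")
    if n == 4:
        return ("ER+PR+HER2-", "ER+PR+HER2+", "ER-PR-HER2+", "ER-PR-HER2-")
    return tuple(f"subtype{i + 1}" for i in range(n))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic expression layer.

    effect_size is the mean shift of an informative gene in its own subtype,
    in units of noise_sd; within_block_correlation is the exact pairwise
    correlation of genes sharing a block.
    """

    n_subtypes: int = 4
    samples_per_subtype: tuple[int, ...] | int = 15
    blocks_per_subtype: int = 2
    block_size: int = 8
    effect_size: float = 3.0
    within_block_correlation: float = 0.85
    n_noise_genes: int = 300
    noise_sd: float = 1.0
    layer_name: str = "mRNA"
    seed: int = 0
    subtype_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_subtypes < 1:
            raise ValueError(f"n_subtypes must be >= 1, got {self.n_subtypes}")
        sps = self.samples_per_subtype
        if isinstance(sps, int):
            sps = (sps,) * self.n_subtypes
        sps = tuple(int(x) for x in sps)
        if len(sps) != self.n_subtypes:
            raise ValueError(
                f"samples_per_subtype has {len(sps)} entries for {self.n_subtypes} subtypes"
            )
        if any(x < 1 for x in sps):
            raise ValueError(f"samples_per_subtype entries must be >= 1, got {sps}")
        object.__setattr__(self, "samples_per_subtype", sps)
        for name in ("blocks_per_subtype", "block_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_noise_genes < 0:
            raise ValueError(f"n_noise_genes must be >= 0, got {self.n_noise_genes}")
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if not 0 <= self.within_block_correlation < 1:
            raise ValueError(
                "within_block_correlation must be in [0, 1), "
                f"got {self.within_block_correlation}"
            )
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        names = self.subtype_names or default_subtype_names(self.n_subtypes)
        names = tuple(str(x) for x in names)
        if len(names) != self.n_subtypes:
            raise ValueError(
                f"subtype_names has {len(names)} entries for {self.n_subtypes} subtypes"
            )
        object.__setattr__(self, "subtype_names", names)

    @property
    def n_informative_genes(self) -> int:
        return self.n_subtypes * self.blocks_per_subtype * self.block_size

    @property
    def n_genes(self) -> int:
        return self.n_informative_genes + self.n_noise_genes

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_subtype))


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure of a simulated layer."""

    informative_genes: dict[str, tuple[str, ...]]  # subtype -> gene IDs
    block_membership: dict[str, tuple[str, int]]  # gene ID -> (subtype, block index)
    noise_genes: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "informative_genes": {k: list(v) for k, v in self.informative_genes.items()},
            "block_membership": {g: list(sb) for g, sb in self.block_membership.items()},
            "noise_genes": list(self.noise_genes),
        }


def simulate_layer(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Draw one labeled expression layer.

    Returns the genes × samples matrix, the sample -> subtype labeling, and
    the planted ground truth.  Identical configs (including seed) produce
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    layer = config.layer_name
    subtypes = config.subtype_names

    sample_ids: list[str] = []
    labels: list[str] = []
    for s, name in enumerate(subtypes):
        for i in range(config.samples_per_subtype[s]):
            sample_ids.append(f"{layer}_T{s + 1}S{i + 1}")
            labels.append(name)
    labeling = pd.Series(labels, index=sample_ids, name="subtype")
    n_samples = len(sample_ids)

    sample_of_subtype = {
        name: np.array([j for j, lab in enumerate(labels) if lab == name])
        for name in subtypes
    }

    rho = config.within_block_correlation
    shift = config.effect_size * config.noise_sd
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    informative: dict[str, list[str]] = {name: [] for name in subtypes}
    membership: dict[str, tuple[str, int]] = {}
    for s, name in enumerate(subtypes):
        for b in range(config.blocks_per_subtype):
            factor = rng.standard_normal(n_samples)
            for g in range(config.block_size):
                gid = f"{layer}_S{s + 1}B{b + 1}G{g + 1}"
                eps = rng.standard_normal(n_samples)
                x = config.noise_sd * (np.sqrt(rho) * factor + np.sqrt(1 - rho) * eps)
                x[sample_of_subtype[name]] += shift
                gene_ids.append(gid)
                rows.append(x)
                informative[name].append(gid)
                membership[gid] = (name, b)
    noise_ids = [f"{layer}_NOISE{i + 1}" for i in range(config.n_noise_genes)]
    for gid in noise_ids:
        gene_ids.append(gid)
        rows.append(config.noise_sd * rng.standard_normal(n_samples))

    expr = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=sample_ids)
    truth = SyntheticTruth(
        informative_genes={k: tuple(v) for k, v in informative.items()},
        block_membership=membership,
        noise_genes=tuple(noise_ids),
    )
    return expr, labeling, truth


def truth_panels(truth: SyntheticTruth) -> dict[str, GenePanel]:
    """One candidate panel per subtype, holding exactly its planted informative genes."""
    return {
        subtype: GenePanel(subtype, genes)
        for subtype, genes in truth.informative_genes.items()
    }


def pooled_panel(truth: SyntheticTruth, name: str = "pooled") -> GenePanel:
    """Union of all subtype panels (the synthetic analogue of a pooled diff-gene list)."""
    return union_panels(truth_panels(truth).values(), name=name)
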