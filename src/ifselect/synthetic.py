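"""Synthetic labeled expression matrices with planted class markers.

The generator emulates the structure of a log-normalized scRNA-seq matrix
annotated with a smoking-status label per cell: a handful of planted marker
genes carry class-dependent mean shifts on top of a common baseline, the
remaining genes are class-independent noise, and Bernoulli dropout zeroes
entries to mimic scRNA-seq sparsity. Every downstream stage is tested
against this known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import LabeledExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_CLASS_NAMES = ("active", "former", "never")

# Cohort compositions (active / former / never cells) of the four lung cell
# compartments the generator's imbalance presets reproduce.
_PRESET_COUNTS: dict[str, tuple[int, int, int]] = {
    "endothelial": (6521, 7189, 29829),
    "epithelial": (37905, 47945, 148499),
    "immune": (41801, 34853, 113189),
    "stromal": (3415, 2342, 10274),
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``planted_genes`` maps gene index -> per-class mean shift vector
    (length L). Non-planted genes are noise around ``baseline_mean``.
    """

    n_cells_per_class: tuple[int, ...]
    n_genes: int
    planted_genes: list[tuple[int, tuple[float, ...]]] = field(default_factory=list)
    baseline_mean: float = 1.0
    noise_sd: float = 0.5
    dropout_rate: float = 0.0
    seed: int = 0
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.n_cells_per_class) < 2:
            raise ValueError("n_cells_per_class: need at least 2 classes")
        if any(int(n) <= 0 for n in self.n_cells_per_class):
            raise ValueError("n_cells_per_class: all counts must be positive")
        if int(self.n_genes) <= 0:
            raise ValueError("n_genes: must be a positive integer")
        if self.baseline_mean < 0:
            raise ValueError("baseline_mean: must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd: must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate: must be in [0, 1)")
        if len(self.class_names) != len(self.n_cells_per_class):
            raise ValueError("class_names: length must match n_cells_per_class")
        L = len(self.n_cells_per_class)
        seen: set[int] = set()
        for g, shifts in self.planted_genes:
            if not (0 <= g < self.n_genes):
                raise ValueError(f"planted_genes: index {g} out of range [0, {self.n_genes})")
            if g in seen:
                raise ValueError(f"planted_genes: duplicate gene index {g}")
            seen.add(g)
            if len(shifts) != L:
                raise ValueError(
                    f"planted_genes: shift vector for gene {g} has length "
                    f"{len(shifts)}, expected {L}"
                )
        if self.planted_genes and not any(
            len(set(shifts)) > 1 for _, shifts in self.planted_genes
        ):
            raise ValueError(
                "planted_genes: at least one planted gene must have two "
                "unequal class means"
            )

    @property
    def n_classes(self) -> int:
        return len(self.n_cells_per_class)

    @property
    def marker_gene_indices(self) -> list[int]:
        return sorted(g for g, _ in self.planted_genes)


def make_gene_ids(n_genes: int) -> list[str]:
    """Zero-padded ENSG-style identifiers for synthetic genes."""
    return [f"ENSG{i:011d}" for i in range(n_genes)]


def generate_dataset(config: SimulationConfig) -> LabeledExpressionMatrix:
    """Draw one labeled matrix from ``config``.

    Each entry is max(0, N(mu, noise_sd)) with mu = baseline_mean plus the
    planted per-class shift where applicable, then zeroed independently with
    probability ``dropout_rate``. Bit-identical for identical configs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_cells = int(sum(config.n_cells_per_class))
    labels = np.concatenate(
        [
            np.full(int(n), name, dtype=object)
            for n, name in zip(config.n_cells_per_class, config.class_names)
        ]
    )
    class_index = np.concatenate(
        [np.full(int(n), i) for i, n in enumerate(config.n_cells_per_class)]
    )

    mu = np.full((n_cells, config.n_genes), float(config.baseline_mean))
    for g, shifts in config.planted_genes:
        mu[:, g] += np.asarray(shifts, dtype=float)[class_index]

    values = mu + rng.normal(0.0, config.noise_sd, size=mu.shape)
    np.maximum(values, 0.0, out=values)
    if config.dropout_rate > 0:
        values[rng.random(values.shape) < config.dropout_rate] = 0.0

    logger.info(
        "synthetic.generate_dataset cells=%d genes=%d markers=%d seed=%d",
        n_cells, config.n_genes, len(config.planted_genes), config.seed,
    )
    return LabeledExpressionMatrix(
        values=values,
        gene_ids=make_gene_ids(config.n_genes),
        labels=labels,
        class_names=list(config.class_names),
    )


def scale_counts(counts: tuple[int, ...], total: int) -> tuple[int, ...]:
    """Rescale class counts to sum to ``total``, preserving proportions.

    Largest-remainder rounding; every class keeps at least one cell.
    """
    if total < len(counts):
        raise ValueError(f"total {total} smaller than number of classes {len(counts)}")
    weights = np.asarray(counts, dtype=float) / float(sum(counts))
    raw = weights * total
    base = np.floor(raw).astype(int)
    base = np.maximum(base, 1)
    remainder = raw - np.floor(raw)
    deficit = total - int(base.sum())
    if deficit > 0:
        for i in np.argsort(-remainder)[:deficit]:
            base[i] += 1
    elif deficit < 0:
        for i in np.argsort(remainder):
            if -deficit == 0:
                break
            if base[i] > 1:
                base[i] -= 1
                deficit += 1
    return tuple(int(b) for b in base)


def default_planted_markers(
    n_genes: int,
    n_markers: int = 15,
    shift: float = 1.5,
    n_classes: int = 3,
) -> list[tuple[int, tuple[float, ...]]]:
    """Evenly spaced marker genes, each elevated in one class in rotation.

    With the default 15 markers and 3 classes, five markers are up-shifted
    in each class, which separates every pair of classes.
    """
    if n_markers > n_genes:
        raise ValueError("more markers than genes")
    stride = max(1, n_genes // max(n_markers, 1))
    planted = []
    for j in range(n_markers):
        idx = (j * stride) % n_genes
        shifts = [0.0] * n_classes
        shifts[j % n_classes] = float(shift)
        planted.append((idx, tuple(shifts)))
    return planted


def imbalance_preset(
    cell_type_name: str,
    total: int = 1500,
    n_genes: int = 2000,
    n_markers: int = 15,
    shift_in_sd: float = 3.0,
    noise_sd: float = 0.5,
    baseline_mean: float = 1.0,
    dropout_rate: float = 0.3,
    seed: int = 0,
) -> SimulationConfig:
    """A SimulationConfig whose class proportions match one of the four lung
    cell compartments (active/former/never smoker cells), scaled down to
    ``total`` cells with total-preserving rounding.
    """
    key = cell_type_name.lower()
    if key not in _PRESET_COUNTS:
        raise ValueError(
            f"unknown cell type {cell_type_name!r}; valid names: "
            f"{sorted(_PRESET_COUNTS)}"
        )
    counts = scale_counts(_PRESET_COUNTS[key], total)
    planted = default_planted_markers(
        n_genes, n_markers=n_markers, shift=shift_in_sd * noise_sd, n_classes=3
    ) if n_markers else []
    return SimulationConfig(
        n_cells_per_class=counts,
        n_genes=n_genes,
        planted_genes=planted,
        baseline_mean=baseline_mean,
        noise_sd=noise_sd,
        dropout_rate=dropout_rate,
        seed=seed,
    )
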