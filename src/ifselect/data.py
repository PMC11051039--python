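"""Core container: a labeled cells-by-genes expression matrix."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LabeledExpressionMatrix:
    """Dense cells × genes matrix of nonnegative expression values with one
    class label per cell.

    Values are on a log-normalized scale (continuous, nonnegative). Gene
    identifiers are unique strings; labels are drawn from ``class_names``.
    """

    values: np.ndarray
    gene_ids: list[str]
    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.gene_ids = [str(g) for g in self.gene_ids]
        if not self.class_names:
            self.class_names = sorted(set(self.labels.tolist()))
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells × genes array")
        n_cells, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != n_genes {n_genes}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if len(self.labels) != n_cells:
            raise ValueError(
                f"labels length {len(self.labels)} != n_cells {n_cells}"
            )
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries")
        if (self.values < 0).any():
            raise ValueError("values must be nonnegative")
        known = set(self.class_names)
        bad = sorted({l for l in self.labels.tolist() if l not in known})
        if bad:
            raise ValueError(f"labels not in class_names: {bad}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict[str, int]:
        counts = pd.Series(self.labels).value_counts()
        return {c: int(counts.get(c, 0)) for c in self.class_names}

    def gene_index(self, gene_ids: list[str]) -> np.ndarray:
        """Column indices for a sequence of gene ids; unknown ids error."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_genes(self, gene_ids: list[str]) -> "LabeledExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return LabeledExpressionMatrix(
            values=self.values[:, idx],
            gene_ids=list(gene_ids),
            labels=self.labels.copy(),
            class_names=list(self.class_names),
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.gene_ids)
        df[label_column] = self.labels
        return df
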