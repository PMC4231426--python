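"""Container for single-knockout steady-state expression compendia.

The experimental design assumed throughout the package: every gene of an
n-gene system is knocked out once, and steady-state expression of all genes
is measured in the wild type and in each mutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ExpressionDataset:
    """Wild-type vector plus knockout matrix for an n-gene system.

    Parameters
    ----------
    gene_ids:
        Ordered, unique gene identifiers. The order fixes both the column
        order of all matrices and the row order of ``ko`` (row i is the
        experiment in which ``gene_ids[i]`` was knocked out).
    wt:
        Length-n wild-type expression vector (arbitrary units, >= 0).
    ko:
        n-by-n matrix; ``ko[i, j]`` is the expression of gene j measured
        after knockout of gene i.
    """

    gene_ids: list[str]
    wt: np.ndarray
    ko: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.wt = np.ascontiguousarray(self.wt, dtype=float).reshape(-1)
        # fixed memory layout keeps reductions bit-reproducible regardless
        # of how the caller sliced the input
        self.ko = np.ascontiguousarray(self.ko, dtype=float)
        n = len(self.gene_ids)
        if n < 2:
            raise ValueError("need at least two genes")
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene identifiers must be unique")
        if self.wt.shape != (n,):
            raise ValueError(
                f"wild-type vector has length {self.wt.shape[0]}, expected {n}"
            )
        if self.ko.shape != (n, n):
            raise ValueError(
                f"knockout matrix has shape {self.ko.shape}, expected {(n, n)}"
            )
        if not (np.isfinite(self.wt).all() and np.isfinite(self.ko).all()):
            raise ValueError("expression values must be finite")

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def stacked(self) -> np.ndarray:
        """All measurements as an (n+1)-by-n matrix: wild type first, then
        the n knockout rows in gene order."""
        return np.vstack([self.wt[np.newaxis, :], self.ko])
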