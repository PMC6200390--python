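"""Labelled relationship kernels.

A :class:`Kernel` is a symmetric positive semidefinite matrix of relationship
coefficients among named individuals/samples — the pedigree numerator
relationship matrix A and the microbial relationship matrix M are both held
in this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Kernel:
    """Symmetric relationship matrix with row/column labels."""

    labels: list[str]
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kernel shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kernel matrix is not symmetric")
        # enforce exact symmetry for downstream linear algebra
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, ids) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([pos[str(i)] for i in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"id {e.args[0]!r} not present in kernel {self.name!r}")

    def subset(self, ids) -> "Kernel":
        """Restrict to the given ids, in the given order."""
        idx = self.index_of(ids)
        return Kernel([self.labels[i] for i in idx],
                      self.values[np.ix_(idx, idx)], name=self.name)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, name: str = "") -> "Kernel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), name=name)
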