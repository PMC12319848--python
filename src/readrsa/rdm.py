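"""Representational dissimilarity matrices (RDMs) and their shared conventions.

An RDM is a square, symmetric, zero-diagonal matrix of pairwise stimulus
dissimilarities over an ordered item list.  All analyses in this package
compare RDMs through their vectorised lower triangle (diagonal excluded,
row-major), so every producer and consumer shares one ordering convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MEASURES = ("visual", "orthographic", "phonological", "semantic", "articulatory")

__all__ = ["MEASURES", "ModelRDM", "rdm_vectorize"]


@dataclass(frozen=True)
class ModelRDM:
    """A hypothesis (or neural) dissimilarity matrix over an ordered word list."""

    items: tuple[str, ...]
    matrix: np.ndarray
    measure: str = "unspecified"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.items)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} items")
        if not np.all(np.isfinite(m)):
            raise ValueError("RDM entries must be finite")
        if np.any(m < -1e-12):
            raise ValueError("RDM entries must be non-negative")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "items", tuple(self.items))

    @property
    def n_items(self) -> int:
        return len(self.items)

    def vectorize(self) -> np.ndarray:
        return rdm_vectorize(self.matrix)

    def reorder(self, items: list[str]) -> "ModelRDM":
        """Return the same RDM over a permuted item list."""
        if sorted(items) != sorted(self.items):
            raise ValueError("items are not a permutation of the RDM's item list")
        idx = [self.items.index(w) for w in items]
        return ModelRDM(tuple(items), self.matrix[np.ix_(idx, idx)], self.measure)

    # ------------------------------------------------------------------ I/O

    def save(self, path: str | Path) -> None:
        """Write as a TSV square matrix with item-name header plus JSON sidecar."""
        path = Path(path)
        pd.DataFrame(self.matrix, index=self.items, columns=self.items).to_csv(
            path, sep="\t"
        )
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"measure": self.measure, "items": list(self.items)}))

    @classmethod
    def load(cls, path: str | Path) -> "ModelRDM":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", index_col=0)
        measure = "unspecified"
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            measure = json.loads(sidecar.read_text())["measure"]
        return cls(tuple(frame.index), frame.to_numpy(float), measure)


def rdm_vectorize(rdm: np.ndarray) -> np.ndarray:
    """Lower triangle of a symmetric zero-diagonal matrix, diagonal excluded.

    Entries are returned in row-major order: (d21, d31, d32, d41, ...), giving
    a vector of length n(n-1)/2.  Raises on asymmetric input because the two
    triangles would then disagree.
    """
    if isinstance(rdm, ModelRDM):
        rdm = rdm.matrix
    m = np.asarray(rdm, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("RDM must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("RDM must be symmetric")
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]
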