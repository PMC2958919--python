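"""Hard cluster assignments shared by the three delimitation methods."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["Partition", "partition_distance"]


@dataclass
class Partition:
    """Assignment of specimens to clusters; label 0 is reserved for noise.

    Cluster labels are contiguous ``1..k``; ``labels[i] == 0`` marks specimen
    ``i`` as unassigned (noise component).
    """

    labels: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if (self.labels < 0).any():
            raise ValueError("labels must be >= 0 (0 = noise)")
        used = sorted(set(self.labels.tolist()) - {0})
        if used != list(range(1, len(used) + 1)):
            # renumber to contiguous 1..k preserving first-appearance order
            remap: dict[int, int] = {}
            new = np.zeros_like(self.labels)
            for i, lab in enumerate(self.labels):
                if lab == 0:
                    continue
                if lab not in remap:
                    remap[lab] = len(remap) + 1
                new[i] = remap[lab]
            self.labels = new
        if self.ids is not None and len(self.ids) != len(self.labels):
            raise ValueError("ids length mismatch")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def n_noise(self) -> int:
        return int((self.labels == 0).sum())

    def clusters(self) -> list[np.ndarray]:
        """Member indices per cluster label 1..k."""
        return [np.flatnonzero(self.labels == c) for c in range(1, self.n_clusters + 1)]

    @classmethod
    def from_labels(cls, labels: Sequence[int], ids: Sequence[str] | None = None) -> "Partition":
        return cls(np.asarray(list(labels)), list(ids) if ids is not None else None)


def partition_distance(a: Partition | np.ndarray, b: Partition | np.ndarray) -> int:
    """Minimum number of elements to reassign to turn one partition into the
    other: n minus the maximum-weight matching of cluster overlaps."""
    la = a.labels if isinstance(a, Partition) else np.asarray(a)
    lb = b.labels if isinstance(b, Partition) else np.asarray(b)
    if len(la) != len(lb):
        raise ValueError("partitions must cover the same elements")
    ua, ub = np.unique(la), np.unique(lb)
    overlap = np.zeros((len(ua), len(ub)), dtype=int)
    for i, x in enumerate(ua):
        for j, y in enumerate(ub):
            overlap[i, j] = int(((la == x) & (lb == y)).sum())
    rows, cols = linear_sum_assignment(-overlap)
    return int(len(la) - overlap[rows, cols].sum())
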