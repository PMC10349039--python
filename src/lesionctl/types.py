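"""Core containers: the labeled weighted connectome and preprocessing report."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

SYMMETRY_TOL = 1e-9


@dataclass
class Connectome:
    """A weighted undirected structural connectome.

    Nodes are labeled gray-matter regions with a hemisphere tag, a region
    volume (mm^3) and a lesioned-tissue fraction in [0, 1].  The adjacency
    holds corrected probabilistic-streamline counts: symmetric, nonnegative,
    zero diagonal.
    """

    node_ids: list[str]
    hemisphere: np.ndarray  # array of 'L'/'R'
    adjacency: np.ndarray
    region_volume: np.ndarray
    region_lesion_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.region_volume = np.asarray(self.region_volume, dtype=float)
        self.region_lesion_fraction = np.asarray(
            self.region_lesion_fraction, dtype=float
        )
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise ValueError("node_ids contains duplicates")
        if self.adjacency.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"{n} node labels"
            )
        for name, arr in (
            ("hemisphere", self.hemisphere),
            ("region_volume", self.region_volume),
            ("region_lesion_fraction", self.region_lesion_fraction),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != n_nodes {n}")
        if not set(self.hemisphere) <= {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")
        if np.any(~np.isfinite(self.adjacency)):
            i, j = np.argwhere(~np.isfinite(self.adjacency))[0]
            raise ValueError(
                f"non-finite adjacency entry at ({self.node_ids[i]}, {self.node_ids[j]})"
            )
        if np.any(self.adjacency < 0):
            i, j = np.argwhere(self.adjacency < 0)[0]
            raise ValueError(
                f"negative weight at ({self.node_ids[i]}, {self.node_ids[j]})"
            )
        if np.max(np.abs(self.adjacency - self.adjacency.T), initial=0.0) > SYMMETRY_TOL:
            raise ValueError("adjacency is not symmetric within 1e-9")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be exactly zero")
        if np.any(self.region_volume <= 0):
            raise ValueError("region volumes must be positive")
        if np.any((self.region_lesion_fraction < 0) | (self.region_lesion_fraction > 1)):
            raise ValueError("lesion fractions must lie in [0, 1]")

    # -- convenience views ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, label: str) -> int:
        try:
            return self.node_ids.index(label)
        except ValueError:
            raise KeyError(f"unknown region label: {label!r}") from None

    def degrees(self) -> np.ndarray:
        """Unweighted degree: count of nonzero off-diagonal entries per row."""
        return np.count_nonzero(self.adjacency, axis=1)

    def strengths(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def left_mask(self) -> np.ndarray:
        return self.hemisphere == "L"

    def with_adjacency(self, adjacency: np.ndarray) -> "Connectome":
        return replace(self, adjacency=np.asarray(adjacency, dtype=float))

    def subset(self, keep: Sequence[int]) -> "Connectome":
        keep = np.asarray(keep, dtype=int)
        return Connectome(
            node_ids=[self.node_ids[i] for i in keep],
            hemisphere=self.hemisphere[keep],
            adjacency=self.adjacency[np.ix_(keep, keep)],
            region_volume=self.region_volume[keep],
            region_lesion_fraction=self.region_lesion_fraction[keep],
        )


@dataclass
class PrepReport:
    """Ledger of what preprocessing did to one connectome."""

    removed_nodes: list[tuple[str, int]] = field(default_factory=list)
    n_links_before: int = 0
    n_links_after: int = 0
    threshold_value: float | None = None
    right_hemisphere_link_count: int | None = None

    def __post_init__(self) -> None:
        rounds = [r for _, r in self.removed_nodes]
        if rounds != sorted(rounds) or len(set(rounds)) != len(rounds):
            raise ValueError("removal rounds must be strictly increasing")
        if self.n_links_after > self.n_links_before:
            raise ValueError("link count cannot grow during preprocessing")

    def to_dict(self) -> dict:
        return {
            "removed_nodes": [[lbl, rnd] for lbl, rnd in self.removed_nodes],
            "n_links_before": self.n_links_before,
            "n_links_after": self.n_links_after,
            "threshold_value": self.threshold_value,
            "right_hemisphere_link_count": self.right_hemisphere_link_count,
        }


def link_count(adjacency: np.ndarray) -> int:
    """Number of undirected links (nonzero strictly-upper-triangle entries)."""
    return int(np.count_nonzero(np.triu(adjacency, k=1)))
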