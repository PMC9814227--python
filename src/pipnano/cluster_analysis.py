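"""PI(4,5)P2 cluster detection under periodic boundaries.

Two lipids of the selected species are adjacent when any pair of their
selected beads lies within the contact cutoff under the minimum-image
convention (in-plane by default: clusters are leaflet-lateral objects).
Clusters are the connected components of that adjacency graph; the
headline statistic is the average cluster size per frame, with both
number- and mass-weighted variants since either convention is defensible
for a cluster-size time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .membrane_model import Box, Frame, Trajectory

__all__ = [
    "ClusterPartition",
    "ClusterSizeSeries",
    "EmptySelectionError",
    "detect_clusters",
    "average_cluster_size",
    "cluster_timeseries",
]


class EmptySelectionError(ValueError):
    """The requested species selects no lipids."""


@dataclass
class ClusterPartition:
    """Disjoint clusters of lipid indices for one frame.

    Invariants: clusters are disjoint and their union is exactly the set of
    selected lipids (monomers appear as singletons).
    """

    clusters: list[frozenset[int]]
    cutoff: float
    bead_selection: str
    species: str
    frame_time: float = 0.0

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for c in self.clusters:
            if seen & c:
                raise ValueError("clusters must be disjoint")
            seen |= c

    @property
    def sizes(self) -> np.ndarray:
        return np.array(sorted((len(c) for c in self.clusters), reverse=True))

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_lipids(self) -> int:
        return int(sum(len(c) for c in self.clusters))

    def as_sets(self) -> set[frozenset[int]]:
        """Order-free view, convenient for comparing partitions."""
        return set(self.clusters)


@dataclass
class ClusterSizeSeries:
    """Per-frame cluster statistics over a trajectory."""

    times: np.ndarray
    mean_size: np.ndarray
    n_clusters: np.ndarray
    largest_size: np.ndarray
    weighting: str
    histograms: list[np.ndarray] | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ps": self.times,
                "n_clusters": self.n_clusters,
                "mean_size": self.mean_size,
                "largest_size": self.largest_size,
            }
        )


def _contact_positions(
    frame: Frame, lipids: np.ndarray, bead_selection: str
) -> tuple[np.ndarray, np.ndarray]:
    """Selected bead positions and their owning lipid ordinals (0..n-1)."""
    pos_chunks: list[np.ndarray] = []
    owner_chunks: list[np.ndarray] = []
    lipid_ordinal = {int(l): k for k, l in enumerate(lipids)}
    wanted = set(int(l) for l in lipids)
    if bead_selection == "all":
        mask = np.isin(frame.lipid_index, lipids)
        pos_chunks.append(frame.positions[mask])
        owner_chunks.append(
            np.array([lipid_ordinal[int(l)] for l in frame.lipid_index[mask]])
        )
    elif bead_selection == "headgroup":
        contact_by_species = {
            sp: set(frame.topology[sp].contact_beads)
            for sp in np.unique(frame.species[lipids].astype(str))
        }
        mask = np.isin(frame.lipid_index, lipids)
        idx = np.flatnonzero(mask)
        keep = [
            i
            for i in idx
            if str(frame.bead_names[i])
            in contact_by_species[str(frame.species[frame.lipid_index[i]])]
        ]
        keep = np.array(keep, dtype=int)
        pos_chunks.append(frame.positions[keep])
        owner_chunks.append(
            np.array([lipid_ordinal[int(l)] for l in frame.lipid_index[keep]])
        )
    else:
        raise ValueError("bead_selection must be 'headgroup' or 'all'")
    return np.concatenate(pos_chunks), np.concatenate(owner_chunks)


class _DSU:
    """Union-find over n elements."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def detect_clusters(
    frame: Frame,
    species: str = "PIP2",
    cutoff: float = 0.6,
    bead_selection: Literal["headgroup", "all"] = "headgroup",
    in_plane: bool = True,
) -> ClusterPartition:
    """Connected-component clusters of the selected species.

    Adjacency: any selected-bead pair of two lipids within ``cutoff`` nm
    under minimum image (distances taken in the x,y plane when ``in_plane``).
    Calcium or other non-lipid beads never enter the adjacency definition;
    clustering is purely lipid-lipid.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lipids = frame.lipids_matching(species)
    if len(lipids) == 0:
        raise EmptySelectionError(f"no lipids match species {species!r}")
    pos, owner = _contact_positions(frame, lipids, bead_selection)
    box = frame.box
    if in_plane:
        coords = np.mod(pos[:, :2], [box.Lx, box.Ly])
        boxsize = [box.Lx, box.Ly]
    else:
        coords = np.mod(pos, box.lengths)
        boxsize = box.lengths
    # guard against x == L after the mod (cKDTree requires [0, L))
    coords = np.where(coords >= np.asarray(boxsize), 0.0, coords)

    tree = cKDTree(coords, boxsize=boxsize)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")

    dsu = _DSU(len(lipids))
    for i, j in pairs:
        oi, oj = int(owner[i]), int(owner[j])
        if oi != oj:
            dsu.union(oi, oj)
    groups: dict[int, set[int]] = {}
    for k, lipid in enumerate(lipids):
        groups.setdefault(dsu.find(k), set()).add(int(lipid))
    return ClusterPartition(
        clusters=[frozenset(g) for g in groups.values()],
        cutoff=cutoff,
        bead_selection=bead_selection,
        species=species,
        frame_time=frame.time,
    )


def average_cluster_size(
    partition: ClusterPartition, weighting: Literal["number", "mass"] = "number"
) -> float:
    """Average cluster size in lipids, monomers included.

    number weighting: (sum of sizes) / (number of clusters).
    mass weighting:   (sum of sizes^2) / (sum of sizes).
    """
    sizes = np.array([len(c) for c in partition.clusters], dtype=float)
    if len(sizes) == 0:
        raise ValueError("average of an empty partition is undefined")
    if weighting == "number":
        return float(sizes.mean())
    if weighting == "mass":
        return float((sizes**2).sum() / sizes.sum())
    raise ValueError("weighting must be 'number' or 'mass'")


def cluster_timeseries(
    traj: Trajectory,
    species: str = "PIP2",
    cutoff: float = 0.6,
    bead_selection: Literal["headgroup", "all"] = "headgroup",
    in_plane: bool = True,
    weighting: Literal["number", "mass"] = "number",
    keep_histograms: bool = False,
) -> ClusterSizeSeries:
    """Per-frame cluster detection and average size over a trajectory.

    The per-frame conservation invariant (cluster sizes sum to the species
    count) is checked on every frame; frame-level failures are re-raised
    with the frame index.
    """
    if len(traj) == 0:
        raise ValueError("trajectory has no frames")
    times, means, ncl, largest = [], [], [], []
    hists: list[np.ndarray] = []
    for k, frame in enumerate(traj):
        try:
            part = detect_clusters(
                frame,
                species=species,
                cutoff=cutoff,
                bead_selection=bead_selection,
                in_plane=in_plane,
            )
            n_species = len(frame.lipids_matching(species))
            if part.n_lipids != n_species:
                raise AssertionError(
                    f"cluster sizes sum to {part.n_lipids}, expected {n_species}"
                )
            means.append(average_cluster_size(part, weighting))
        except Exception as exc:
            raise type(exc)(f"frame {k}: {exc}") from exc
        times.append(frame.time)
        ncl.append(part.n_clusters)
        largest.append(int(part.sizes[0]))
        if keep_histograms:
            hists.append(part.sizes.copy())
    return ClusterSizeSeries(
        times=np.array(times),
        mean_size=np.array(means),
        n_clusters=np.array(ncl),
        largest_size=np.array(largest),
        weighting=weighting,
        histograms=hists if keep_histograms else None,
    )
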