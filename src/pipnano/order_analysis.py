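"""Acyl-chain order parameters and hexagonal-lattice detection.

The S-value order parameter of a chain bond is the second Legendre
polynomial of the angle between the bond and the bilayer normal,
``S = (3 <cos^2 theta> - 1) / 2``: 1 for bonds parallel to the normal,
-0.5 for in-plane bonds, 0 for isotropic orientations.  The normal is the
global z axis (+z for the upper leaflet, -z for the lower, which leaves S
leaflet-symmetric since only cos^2 enters).

Hexagonality detects the six-fold lateral packing that is the hallmark of
a gel phase: an acyl chain (reduced to its in-plane centroid) is counted
as part of a hexagonal lattice when it has at least six neighbours within
the neighbour cutoff and its six nearest neighbours, sorted by azimuth,
are spaced 60 degrees apart within an angular tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .membrane_model import Frame, Trajectory

__all__ = [
    "OrderProfile",
    "DistanceResolvedOrder",
    "HexagonalityResult",
    "bond_s_value",
    "order_profile",
    "distance_resolved_order",
    "hexagonality",
    "hexagonality_vs_temperature",
]


def bond_s_value(
    bond_vectors: np.ndarray, normal: Sequence[float] = (0.0, 0.0, 1.0)
) -> float:
    """S = (3<cos^2 theta> - 1)/2 over a sample of bond vectors.

    ``theta`` is the angle between each bond and *normal*; the average runs
    over the supplied sample.  Zero-length bonds are a geometry error.
    """
    v = np.atleast_2d(np.asarray(bond_vectors, dtype=float))
    if v.shape[0] == 0:
        raise ValueError("need at least one bond vector")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length bond vector")
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    cos2 = (v @ n) ** 2 / norms**2
    return float((3.0 * cos2.mean() - 1.0) / 2.0)


@dataclass
class OrderProfile:
    """Per-bond S-values along one acyl chain of a species.

    Bond ``k`` joins beads ``k`` and ``k+1`` of the chain definition,
    indexed from the glycerol end.
    """

    species: str
    chain: int
    s_values: np.ndarray
    standard_errors: np.ndarray
    n_samples: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.s_values < -0.5 - 1e-9) or np.any(self.s_values > 1.0 + 1e-9):
            raise ValueError("S-values must lie in [-0.5, 1.0]")

    @property
    def n_bonds(self) -> int:
        return len(self.s_values)


def _chain_cos2(
    frame: Frame, lipids: np.ndarray, species: str, chain: int
) -> np.ndarray:
    """cos^2(theta) per bond per lipid, shape (n_lipids, n_bonds)."""
    top = frame.topology[species]
    if chain >= len(top.chains):
        raise ValueError(f"{species} has no chain {chain}")
    beads = top.chains[chain]
    if len(beads) < 2:
        raise ValueError(f"{species} chain {chain} has fewer than 2 beads")
    pos = np.stack(
        [frame.positions_by_bead(lipids, b) for b in beads], axis=1
    )  # (n_lipids, n_beads, 3)
    bonds = np.diff(pos, axis=1)
    norms = np.linalg.norm(bonds, axis=2)
    if np.any(norms == 0):
        raise ValueError("zero-length chain bond")
    return bonds[:, :, 2] ** 2 / norms**2


def order_profile(
    traj: Trajectory | Frame,
    species: str,
    chain: int = 0,
    leaflet: str | None = None,
) -> OrderProfile:
    """Per-bond S aggregated over lipids and frames.

    Standard errors propagate the sample variance of cos^2 theta through
    the Legendre form (SE_S = 1.5 * SE_<cos^2>).
    """
    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    samples: list[np.ndarray] = []
    for frame in frames:
        sp_lipids = [
            int(l)
            for l in frame.lipids_matching(species)
            if str(frame.species[l]) == species
            or str(frame.species[l]).startswith(species)
        ]
        lipids = np.array(
            [
                l
                for l in sp_lipids
                if leaflet is None or str(frame.leaflet[l]) == leaflet
            ],
            dtype=int,
        )
        if len(lipids) == 0:
            continue
        # the species argument may be a prefix; resolve per concrete species
        for concrete in np.unique(frame.species[lipids].astype(str)):
            sel = lipids[frame.species[lipids].astype(str) == concrete]
            samples.append(_chain_cos2(frame, sel, str(concrete), chain))
    if not samples:
        raise ValueError(f"no {species} lipids found in the requested leaflet")
    cos2 = np.concatenate(samples, axis=0)
    n = cos2.shape[0]
    s = (3.0 * cos2.mean(axis=0) - 1.0) / 2.0
    se = 1.5 * cos2.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(s)
    return OrderProfile(
        species=species,
        chain=chain,
        s_values=s,
        standard_errors=se,
        n_samples=np.full(cos2.shape[1], n),
    )


@dataclass
class DistanceResolvedOrder:
    """First-chain-bond S of a probe species binned by in-plane distance to
    the nearest reference-species molecule."""

    bin_edges: np.ndarray  # half-open [lo, hi) bins, nm
    s_values: np.ndarray  # NaN where a bin holds no samples
    counts: np.ndarray  # probe lipids per bin
    n_sampled: int
    probe_species: str
    reference_species: str

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def distance_resolved_order(
    traj: Trajectory | Frame,
    probe_species: str = "POPC",
    reference_species: str = "PIP2",
    bin_width: float = 0.2,
    max_distance: float = 3.0,
    leaflet: str | None = None,
) -> DistanceResolvedOrder:
    """Order of the probe's first acyl-chain bonds versus distance to the
    nearest reference molecule.

    Each probe lipid is located by its glycerol-proximal anchor bead; its
    distance is the in-plane minimum-image distance to the nearest bead of
    any reference-species lipid *in the same leaflet* (molecule-level
    nearest).  The first bond of every chain of the probe contributes a
    cos^2 sample to the lipid's bin.  Probe lipids farther than
    ``max_distance`` are not sampled; empty bins are reported as NaN.
    """
    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    edges = np.arange(0.0, max_distance + bin_width / 2, bin_width)
    if len(edges) < 2:
        raise ValueError("max_distance must cover at least one bin")
    n_bins = len(edges) - 1
    cos2_sums = np.zeros(n_bins)
    cos2_counts = np.zeros(n_bins, dtype=int)  # bond samples
    lipid_counts = np.zeros(n_bins, dtype=int)  # probe lipids
    n_sampled = 0
    saw_reference = False

    for frame in frames:
        box = frame.box
        leaflets = (
            [leaflet]
            if leaflet is not None
            else sorted(set(frame.leaflet.astype(str)) - {"unassigned"}) or [None]
        )
        for leaf in leaflets:
            probe = np.array(
                [
                    int(l)
                    for l in frame.lipids_matching(probe_species)
                    if leaf is None or str(frame.leaflet[l]) == leaf
                ]
            )
            ref = np.array(
                [
                    int(l)
                    for l in frame.lipids_matching(reference_species)
                    if leaf is None or str(frame.leaflet[l]) == leaf
                ]
            )
            if len(ref) == 0 or len(probe) == 0:
                continue
            saw_reference = True
            ref_mask = np.isin(frame.lipid_index, ref)
            ref_xy = np.mod(frame.positions[ref_mask, :2], [box.Lx, box.Ly])
            ref_xy = np.where(ref_xy >= [box.Lx, box.Ly], 0.0, ref_xy)
            tree = cKDTree(ref_xy, boxsize=[box.Lx, box.Ly])

            anchors = np.empty((len(probe), 2))
            for k, l in enumerate(probe):
                sp = str(frame.species[l])
                anchors[k] = frame.bead_position(l, frame.topology[sp].anchor_bead)[:2]
            anchors = np.mod(anchors, [box.Lx, box.Ly])
            anchors = np.where(anchors >= [box.Lx, box.Ly], 0.0, anchors)
            dists, _ = tree.query(anchors)

            for concrete in np.unique(frame.species[probe].astype(str)):
                sel_mask = frame.species[probe].astype(str) == concrete
                sel = probe[sel_mask]
                d_sel = dists[sel_mask]
                top = frame.topology[str(concrete)]
                first_cos2 = np.column_stack(
                    [
                        _chain_cos2(frame, sel, str(concrete), ci)[:, 0]
                        for ci in range(len(top.chains))
                    ]
                )  # (n_sel, n_chains)
                inside = d_sel < max_distance
                bins = np.minimum(
                    (d_sel[inside] / bin_width).astype(int), n_bins - 1
                )
                for b, row in zip(bins, first_cos2[inside]):
                    cos2_sums[b] += row.sum()
                    cos2_counts[b] += len(row)
                    lipid_counts[b] += 1
                n_sampled += int(inside.sum())

    if not saw_reference:
        raise ValueError(
            f"reference species {reference_species!r} absent from every "
            "analyzed leaflet"
        )
    with np.errstate(invalid="ignore"):
        mean_cos2 = np.where(cos2_counts > 0, cos2_sums / np.maximum(cos2_counts, 1), np.nan)
    s = np.where(cos2_counts > 0, (3.0 * mean_cos2 - 1.0) / 2.0, np.nan)
    return DistanceResolvedOrder(
        bin_edges=edges,
        s_values=s,
        counts=lipid_counts,
        n_sampled=n_sampled,
        probe_species=probe_species,
        reference_species=reference_species,
    )


@dataclass
class HexagonalityResult:
    """Count and fraction of acyl chains sitting in hexagonal lattices."""

    n_chains_total: int
    n_chains_hexagonal: int
    neighbor_cutoff: float
    angle_tolerance: float
    min_neighbors: int
    hexagonal_flags: np.ndarray | None = None

    @property
    def fraction(self) -> float:
        return (
            self.n_chains_hexagonal / self.n_chains_total
            if self.n_chains_total
            else 0.0
        )


def _chain_centroids(
    frame: Frame, species: str | None, leaflet: str | None
) -> np.ndarray:
    """In-plane centroids of every acyl chain in the selection."""
    cents: list[np.ndarray] = []
    sp_arr = frame.species.astype(str)
    for concrete in np.unique(sp_arr):
        if species is not None and not (
            concrete == species or concrete.startswith(species)
        ):
            continue
        sel = np.flatnonzero(sp_arr == concrete)
        if leaflet is not None:
            sel = sel[frame.leaflet[sel].astype(str) == leaflet]
        if len(sel) == 0:
            continue
        top = frame.topology[concrete]
        for chain in top.chains:
            pos = np.stack(
                [frame.positions_by_bead(sel, b) for b in chain], axis=1
            )  # (n_sel, n_beads, 3)
            cents.append(pos[:, :, :2].mean(axis=1))
    if not cents:
        raise ValueError("selection contains no acyl chains")
    return np.concatenate(cents, axis=0)


def hexagonality(
    frame: Frame,
    species: str | None = None,
    leaflet: str | None = None,
    neighbor_cutoff: float = 0.55,
    angle_tolerance: float = 15.0,
    min_neighbors: int = 6,
    return_flags: bool = False,
) -> HexagonalityResult:
    """Classify acyl chains as members of a hexagonal lattice.

    A chain (in-plane centroid) is hexagonal iff it has at least
    ``min_neighbors`` centroids within ``neighbor_cutoff`` nm (minimum
    image) and the azimuths of the six nearest of these, sorted, are spaced
    60 +/- ``angle_tolerance`` degrees apart (including the wrap-around
    gap).  The default cutoff of 0.55 nm sits between the gel lattice
    spacing (0.48 nm per chain) and typical fluid chain spacings.
    """
    cents = _chain_centroids(frame, species, leaflet)
    box = frame.box
    L = np.array([box.Lx, box.Ly])
    wrapped = np.mod(cents, L)
    wrapped = np.where(wrapped >= L, 0.0, wrapped)
    tree = cKDTree(wrapped, boxsize=L)
    neighbors = tree.query_ball_point(wrapped, r=neighbor_cutoff)

    flags = np.zeros(len(cents), dtype=bool)
    lo, hi = 60.0 - angle_tolerance, 60.0 + angle_tolerance
    for i, nbrs in enumerate(neighbors):
        nbrs = [j for j in nbrs if j != i]
        if len(nbrs) < min_neighbors:
            continue
        d = wrapped[nbrs] - wrapped[i]
        d -= L * np.round(d / L)
        dist = np.hypot(d[:, 0], d[:, 1])
        six = np.argsort(dist)[:6]
        ang = np.degrees(np.arctan2(d[six, 1], d[six, 0]))
        ang.sort()
        gaps = np.diff(np.concatenate([ang, [ang[0] + 360.0]]))
        if np.all((gaps >= lo) & (gaps <= hi)):
            flags[i] = True
    return HexagonalityResult(
        n_chains_total=len(cents),
        n_chains_hexagonal=int(flags.sum()),
        neighbor_cutoff=neighbor_cutoff,
        angle_tolerance=angle_tolerance,
        min_neighbors=min_neighbors,
        hexagonal_flags=flags if return_flags else None,
    )


def hexagonality_vs_temperature(
    labeled_frames: Sequence[tuple[float, Frame]],
    **hex_kwargs,
) -> tuple[pd.DataFrame, float]:
    """Hexagonality per temperature label plus a Spearman trend statistic.

    Duplicate labels are merged (counts summed) with a warning.  Returns the
    per-label table and the Spearman rank correlation of the hexagonal
    fraction with temperature (a descriptive monotone-trend statistic, not a
    test).
    """
    if len(labeled_frames) < 2:
        raise ValueError("need at least two labeled frames")
    by_label: dict[float, list[Frame]] = {}
    for label, frame in labeled_frames:
        by_label.setdefault(float(label), []).append(frame)
    if any(len(v) > 1 for v in by_label.values()):
        warnings.warn("duplicate temperature labels merged", stacklevel=2)
    if len(by_label) < 2:
        raise ValueError("need at least two distinct temperature labels")
    rows = []
    for label in sorted(by_label):
        tot = hexed = 0
        for frame in by_label[label]:
            res = hexagonality(frame, **hex_kwargs)
            tot += res.n_chains_total
            hexed += res.n_chains_hexagonal
        rows.append(
            {
                "temperature": label,
                "n_chains_total": tot,
                "n_chains_hexagonal": hexed,
                "fraction": hexed / tot if tot else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    if df["fraction"].nunique() <= 1:
        rho = 0.0
    else:
        rho = float(spearmanr(df["temperature"], df["fraction"]).statistic)
    return df, rho
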