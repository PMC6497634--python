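"""Minimum-distance, binding, contact-matrix and geometric descriptors.

All criteria use strict inequality at the cutoff ("less than"), so a pair at
exactly the cutoff distance is a non-contact.  Distances are plain Euclidean
(inputs are assumed unwrapped; no periodic minimum image).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import AtomSet, Trajectory
from .synthetic import PDB_CODE_TO_SUGAR

__all__ = [
    "DistanceSeries", "ContactMatrix",
    "min_distance_series", "com_distance_series", "bound_glycan_count",
    "residue_binding_indicators", "residue_min_distance_summary",
    "residue_sugar_matrix", "ca_matrices", "matrix_difference",
    "end_to_end_series",
]

SUGAR_COLUMN_ORDER = ["Neu", "Gal'", "GalNAc", "Gal", "Glc", "Ligand"]


@dataclass
class DistanceSeries:
    """Per-frame distance (Angstrom) between two named atom groups."""

    values: np.ndarray
    label_a: str
    label_b: str
    kind: str = "min"  # "min" | "com" | "end_to_end"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distances")

    def mean(self) -> float:
        """Average over frames: sum(x_i) / N."""
        return float(self.values.mean())


@dataclass
class ContactMatrix:
    """Labelled residue-pair matrix of mean distances, contact frequencies, or differences."""

    values: np.ndarray
    row_labels: list
    col_labels: list
    statistic: str                      # mean_distance | contact_frequency | difference
    source_tags: tuple[str, str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match labels")
        if self.statistic == "contact_frequency":
            if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1:
                raise ValueError("contact frequencies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels,
                            columns=self.col_labels)

    def to_long_tsv(self, path) -> None:
        df = self.to_frame().stack().reset_index()
        df.columns = ["row_label", "col_label", "value"]
        df.to_csv(path, sep="\t", index=False)


def _group_coords(traj: Trajectory, group: AtomSet) -> np.ndarray:
    if len(group) == 0:
        raise ValueError("empty atom group")
    return traj.coords[:, group.indices, :]


def min_distance_series(traj: Trajectory, group_a: AtomSet,
                        group_b: AtomSet) -> DistanceSeries:
    """Per-frame minimum pairwise distance between two atom groups."""
    a = _group_coords(traj, group_a)
    b = _group_coords(traj, group_b)
    vals = np.array([cdist(a[f], b[f]).min() for f in range(traj.n_frames)])
    return DistanceSeries(vals, group_a.descriptor or "group_a",
                          group_b.descriptor or "group_b", kind="min")


def com_distance_series(traj: Trajectory, group_a: AtomSet, group_b: AtomSet,
                        masses: np.ndarray | None = None) -> DistanceSeries:
    """Per-frame distance between group centers of mass.

    With ``masses`` omitted, unit weights are used (equal-weight centroid over
    the atoms supplied -- pass a heavy-atom selection to reproduce
    "non-hydrogen atoms were considered").
    """
    a = _group_coords(traj, group_a)
    b = _group_coords(traj, group_b)
    if masses is None:
        com_a = a.mean(axis=1)
        com_b = b.mean(axis=1)
    else:
        masses = np.asarray(masses, dtype=float)
        wa = masses[group_a.indices]
        wb = masses[group_b.indices]
        com_a = (a * wa[None, :, None]).sum(axis=1) / wa.sum()
        com_b = (b * wb[None, :, None]).sum(axis=1) / wb.sum()
    vals = np.linalg.norm(com_a - com_b, axis=1)
    return DistanceSeries(vals, group_a.descriptor or "group_a",
                          group_b.descriptor or "group_b", kind="com")


def bound_glycan_count(traj: Trajectory, peptide: AtomSet,
                       glycans: list[AtomSet], cutoff: float) -> np.ndarray:
    """Per-frame count of glycans whose minimum distance to the peptide is < cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not glycans:
        raise ValueError("empty glycan list")
    pep = _group_coords(traj, peptide)
    counts = np.zeros(traj.n_frames, dtype=int)
    for g in glycans:
        gc = _group_coords(traj, g)
        for f in range(traj.n_frames):
            if cdist(pep[f], gc[f]).min() < cutoff:
                counts[f] += 1
    return counts


def residue_binding_indicators(traj: Trajectory, residues: np.ndarray,
                               cluster: AtomSet, cutoff: float,
                               heavy_only: bool = True) -> np.ndarray:
    """0/1 matrix (n_frames, n_residues): residue bound iff min heavy-atom distance < cutoff.

    ``residues`` are topology residue indices; this is the Y_j indicator that
    feeds the binding-helix cross-correlation.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = traj.topology
    clus = _group_coords(traj, cluster)
    out = np.zeros((traj.n_frames, len(residues)), dtype=int)
    for j, r in enumerate(residues):
        idx = top.residue_atoms(int(r))
        if heavy_only:
            idx = idx[top.elements[idx] != "H"]
        if len(idx) == 0:
            raise ValueError(f"residue index {r} has no (heavy) atoms")
        rc = traj.coords[:, idx, :]
        for f in range(traj.n_frames):
            out[f, j] = 1 if cdist(rc[f], clus[f]).min() < cutoff else 0
    return out


def residue_min_distance_summary(traj: Trajectory, residues: np.ndarray,
                                 cluster: AtomSet,
                                 heavy_only: bool = True) -> pd.DataFrame:
    """Boxplot-style summary of each residue's per-frame minimum distance to the cluster.

    Columns: min, q1, median, q3, max, mean; one row per residue (label =
    residue number).  Quartiles use linear interpolation of the empirical
    distribution; ``mean`` is the average minimum distance sum(x_i)/N.
    """
    top = traj.topology
    clus = _group_coords(traj, cluster)
    rows = []
    for r in residues:
        idx = top.residue_atoms(int(r))
        if heavy_only:
            idx = idx[top.elements[idx] != "H"]
        rc = traj.coords[:, idx, :]
        series = np.array([cdist(rc[f], clus[f]).min()
                           for f in range(traj.n_frames)])
        q1, med, q3 = np.percentile(series, [25, 50, 75])
        rows.append({
            "residue": int(top.res_numbers[r]), "min": series.min(), "q1": q1,
            "median": med, "q3": q3, "max": series.max(),
            "mean": series.mean(),
        })
    return pd.DataFrame(rows).set_index("residue")


def residue_sugar_matrix(traj: Trajectory, amino_residues: np.ndarray,
                         sugar_columns: list[str] | None = None,
                         pool: str = "min",
                         heavy_only: bool = True) -> ContactMatrix:
    """Average minimum distance between each amino-acid residue and each sugar type.

    For each frame, the distance from a residue to sugar type ``s`` is the
    minimum over all copies of that sugar across the glycan units
    (``pool="min"``, the default) or the mean over copies (``pool="mean"``);
    the matrix entry is the time average sum(x_i)/N.  Columns default to the
    glycan head-group order Neu, Gal', GalNAc, Gal, Glc, Ligand.
    """
    if pool not in ("min", "mean"):
        raise ValueError("pool must be 'min' or 'mean'")
    top = traj.topology
    sugar_columns = sugar_columns or SUGAR_COLUMN_ORDER
    # atoms per sugar type per glycan copy
    copies: dict[str, list[np.ndarray]] = {s: [] for s in sugar_columns}
    for unit in top.glycan_units:
        for r in unit:
            label = PDB_CODE_TO_SUGAR.get(top.res_names[r], top.res_names[r])
            if label in copies:
                idx = top.residue_atoms(int(r))
                if heavy_only:
                    idx = idx[top.elements[idx] != "H"]
                copies[label].append(idx)
    for s in sugar_columns:
        if not copies[s]:
            raise ValueError(f"no glycan residue of sugar type {s!r} in topology")

    values = np.empty((len(amino_residues), len(sugar_columns)))
    for i, r in enumerate(amino_residues):
        idx = top.residue_atoms(int(r))
        if heavy_only:
            idx = idx[top.elements[idx] != "H"]
        rc = traj.coords[:, idx, :]
        for j, s in enumerate(sugar_columns):
            per_frame = np.empty(traj.n_frames)
            for f in range(traj.n_frames):
                d_copies = [cdist(rc[f], traj.coords[f, c, :]).min()
                            for c in copies[s]]
                per_frame[f] = (min(d_copies) if pool == "min"
                                else float(np.mean(d_copies)))
            values[i, j] = per_frame.mean()
    rows = [int(top.res_numbers[r]) for r in amino_residues]
    return ContactMatrix(values, rows, list(sugar_columns), "mean_distance")


def ca_matrices(traj: Trajectory, peptide_residues: np.ndarray,
                cutoff: float = 8.0) -> tuple[ContactMatrix, ContactMatrix]:
    """Mean CA-CA distance matrix and CA contact-frequency matrix.

    A contact is formed when the CA-CA distance is strictly less than
    ``cutoff`` (default 8.0 A).  Diagonal: distance 0, frequency 1.
    """
    top = traj.topology
    ca_idx = []
    for r in peptide_residues:
        idx = top.residue_atoms(int(r))
        ca = idx[top.atom_names[idx] == "CA"]
        if len(ca) != 1:
            raise ValueError(
                f"residue {top.res_numbers[r]} has {len(ca)} CA atoms")
        ca_idx.append(ca[0])
    ca_idx = np.array(ca_idx)
    xyz = traj.coords[:, ca_idx, :]
    diff = xyz[:, :, None, :] - xyz[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)            # (frames, n, n)
    mean_dist = dist.mean(axis=0)
    freq = (dist < cutoff).mean(axis=0)
    labels = [int(top.res_numbers[r]) for r in peptide_residues]
    return (ContactMatrix(mean_dist, labels, labels, "mean_distance"),
            ContactMatrix(freq, labels, labels, "contact_frequency"))


def matrix_difference(with_glycan: ContactMatrix,
                      only_ab: ContactMatrix) -> ContactMatrix:
    """Difference(i,j) = <x_ij^with-glycan> - <x_ij^only-peptide>, elementwise."""
    if (with_glycan.row_labels != only_ab.row_labels
            or with_glycan.col_labels != only_ab.col_labels):
        raise ValueError("matrix labels do not match")
    if with_glycan.statistic != only_ab.statistic:
        raise ValueError("matrix statistics do not match")
    return ContactMatrix(
        with_glycan.values - only_ab.values,
        with_glycan.row_labels, with_glycan.col_labels, "difference",
        source_tags=(with_glycan.statistic, only_ab.statistic),
    )


def end_to_end_series(traj: Trajectory, chain: AtomSet) -> DistanceSeries:
    """Per-frame distance between the first and last atoms of an ordered chain."""
    if len(chain) < 2:
        raise ValueError("chain needs at least 2 atoms")
    first = traj.coords[:, chain.indices[0], :]
    last = traj.coords[:, chain.indices[-1], :]
    vals = np.linalg.norm(last - first, axis=1)
    return DistanceSeries(vals, chain.descriptor or "chain_start",
                          chain.descriptor or "chain_end", kind="end_to_end")
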