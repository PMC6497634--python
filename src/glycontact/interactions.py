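"""Hydrogen-bond detection and per-residue interaction-energy profiles.

A hydrogen bond is declared when the acceptor-donor heavy-atom distance
X_AD < 3.5 A and the A-H-D angle theta_AHD > 135 deg (both strict).

Interaction energies are direct-sum pairwise Coulomb plus 12-6 Lennard-Jones
over all inter-group atom pairs (no cutoff by default), an approximation of a
force-field energy decomposition:

    E_elec = k_e * q_i q_j / r,            k_e = 332.0636 kcal A / (mol e^2)
    E_vdw  = eps_ij [ (rmin_ij / r)^12 - 2 (rmin_ij / r)^6 ]

with eps_ij = sqrt(eps_i eps_j) and rmin_ij = (rmin/2)_i + (rmin/2)_j
(Lorentz-Berthelot-style combination on the r_min convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._geometry import angle
from .io import AtomSet, Trajectory
from .statcorr import mean_se

__all__ = ["HBondCriteria", "EnergyProfile", "detect_hbonds",
           "hbond_count_profile", "interaction_energy_profile", "COULOMB_K"]

COULOMB_K = 332.0636  # kcal*A/(mol*e^2)

DONOR_ACCEPTOR_ELEMENTS = ("N", "O")  # sulfur deliberately excluded


@dataclass
class HBondCriteria:
    max_AD_distance: float = 3.5    # A, strict upper bound on X_AD
    min_AHD_angle: float = 135.0    # deg, strict lower bound on theta_AHD
    donor_acceptor_elements: tuple[str, ...] = DONOR_ACCEPTOR_ELEMENTS

    def __post_init__(self):
        if self.max_AD_distance <= 0:
            raise ValueError("max_AD_distance must be positive")
        if not 0.0 < self.min_AHD_angle <= 180.0:
            raise ValueError("min_AHD_angle must be in (0, 180]")


@dataclass
class EnergyProfile:
    """Per-residue mean H-bond count and interaction energies with jackknife errors."""

    residues: np.ndarray
    n_hb: np.ndarray
    n_hb_se: np.ndarray
    e_elec: np.ndarray
    e_elec_se: np.ndarray
    e_vdw: np.ndarray
    e_vdw_se: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": self.residues,
            "n_hb": self.n_hb, "n_hb_se": self.n_hb_se,
            "e_elec": self.e_elec, "e_elec_se": self.e_elec_se,
            "e_vdw": self.e_vdw, "e_vdw_se": self.e_vdw_se,
        }).set_index("residue")


def detect_hbonds(coords: np.ndarray,
                  donors: list[tuple[int, int]],
                  acceptors: np.ndarray | list[int],
                  criteria: HBondCriteria | None = None) -> list[tuple[int, int, int]]:
    """Hydrogen bonds in one frame: (donor D, hydrogen H, acceptor A) triples.

    ``donors`` are (D, H) atom-index pairs with H covalently bonded to D
    (enforced: H within 1.3 A of D); ``acceptors`` are candidate heavy-atom
    indices.  A bond is reported iff dist(A, D) < max_AD_distance and
    angle(A, H, D) > min_AHD_angle, both strict.
    """
    criteria = criteria or HBondCriteria()
    coords = np.asarray(coords, dtype=float)
    acceptors = np.asarray(acceptors, dtype=int)
    out = []
    for d, h in donors:
        if np.linalg.norm(coords[h] - coords[d]) > 1.3:
            raise ValueError(
                f"hydrogen {h} is not within 1.3 A of its declared donor {d}")
        for a in acceptors:
            if a == d or a == h:
                continue
            if np.linalg.norm(coords[a] - coords[d]) < criteria.max_AD_distance \
                    and angle(coords[a], coords[h], coords[d]) > criteria.min_AHD_angle:
                out.append((d, h, int(a)))
    return out


def _donors_acceptors(traj: Trajectory, atoms: np.ndarray,
                      criteria: HBondCriteria, frame0: np.ndarray):
    """Split an atom set into (D, H) donor pairs and acceptor indices.

    Donor pairing is geometric on the first frame: each hydrogen is assigned
    to the nearest N/O within 1.3 A (covalent bonding is not read from the
    file format).
    """
    top = traj.topology
    elems = top.elements[atoms]
    polar = atoms[np.isin(elems, criteria.donor_acceptor_elements)]
    hydros = atoms[elems == "H"]
    donors = []
    if len(polar) and len(hydros):
        d = cdist(frame0[hydros], frame0[polar])
        for k, h in enumerate(hydros):
            j = int(np.argmin(d[k]))
            if d[k, j] <= 1.3:
                donors.append((int(polar[j]), int(h)))
    return donors, polar


def hbond_count_profile(traj: Trajectory, peptide_residues: np.ndarray,
                        cluster: AtomSet,
                        criteria: HBondCriteria | None = None) -> pd.DataFrame:
    """Time-averaged hydrogen-bond count between each residue and the cluster.

    Counts bonds in both directions (residue donor -> cluster acceptor and
    cluster donor -> residue acceptor).  Returns a DataFrame indexed by
    residue number with columns ``n_hb`` (mean per frame) and per-frame
    counts accessible via :func:`per_frame_hbond_counts`.
    """
    counts = per_frame_hbond_counts(traj, peptide_residues, cluster, criteria)
    top = traj.topology
    return pd.DataFrame(
        {"n_hb": counts.mean(axis=0)},
        index=pd.Index([int(top.res_numbers[r]) for r in peptide_residues],
                       name="residue"),
    )


def per_frame_hbond_counts(traj: Trajectory, peptide_residues: np.ndarray,
                           cluster: AtomSet,
                           criteria: HBondCriteria | None = None) -> np.ndarray:
    """(n_frames, n_residues) hydrogen-bond counts between residues and the cluster."""
    criteria = criteria or HBondCriteria()
    top = traj.topology
    clus_atoms = cluster.indices
    out = np.zeros((traj.n_frames, len(peptide_residues)), dtype=int)
    frame0 = traj.coords[0]
    clus_donors, clus_acc = _donors_acceptors(traj, clus_atoms, criteria, frame0)
    for j, r in enumerate(peptide_residues):
        res_atoms = top.residue_atoms(int(r))
        res_donors, res_acc = _donors_acceptors(traj, res_atoms, criteria, frame0)
        for f in range(traj.n_frames):
            c = traj.coords[f]
            n = len(detect_hbonds(c, res_donors, clus_acc, criteria))
            n += len(detect_hbonds(c, clus_donors, res_acc, criteria))
            out[f, j] = n
    return out


def _pair_energies(coords: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
                   q: np.ndarray, eps: np.ndarray, rmin_half: np.ndarray,
                   cutoff: float | None) -> tuple[float, float]:
    r = cdist(coords[idx_a], coords[idx_b])
    if cutoff is not None:
        mask = r < cutoff
    else:
        mask = np.ones_like(r, dtype=bool)
    qq = np.outer(q[idx_a], q[idx_b])
    e_elec = float((COULOMB_K * qq[mask] / r[mask]).sum())
    eps_ij = np.sqrt(np.outer(eps[idx_a], eps[idx_b]))
    rmin_ij = rmin_half[idx_a][:, None] + rmin_half[idx_b][None, :]
    sr6 = (rmin_ij[mask] / r[mask]) ** 6
    e_vdw = float((eps_ij[mask] * (sr6 ** 2 - 2 * sr6)).sum())
    return e_elec, e_vdw


def interaction_energy_profile(traj: Trajectory, peptide_residues: np.ndarray,
                               cluster: AtomSet, cutoff: float | None = None,
                               criteria: HBondCriteria | None = None,
                               n_blocks: int = 5) -> EnergyProfile:
    """Per-residue mean electrostatic and VDW energies (and H-bond counts) vs the cluster.

    All residue-cluster atom pairs are summed per frame (direct sum, no
    cutoff unless given); means and jackknife standard errors are taken over
    frames with ``n_blocks`` equal blocks.  The topology must carry charges
    and LJ parameters for every atom involved.
    """
    top = traj.topology
    missing = []
    for name, arr in (("charge", top.charges), ("epsilon", top.lj_epsilon),
                      ("rmin_half", top.lj_rmin_half)):
        if arr is None:
            missing.append(name)
    if missing:
        raise ValueError(f"topology lacks per-atom parameters: {missing}")

    q, eps, rmh = top.charges, top.lj_epsilon, top.lj_rmin_half
    clus = cluster.indices
    n_res = len(peptide_residues)
    e_elec = np.zeros((traj.n_frames, n_res))
    e_vdw = np.zeros((traj.n_frames, n_res))
    for j, r in enumerate(peptide_residues):
        idx = top.residue_atoms(int(r))
        for f in range(traj.n_frames):
            e_elec[f, j], e_vdw[f, j] = _pair_energies(
                traj.coords[f], idx, clus, q, eps, rmh, cutoff)
    nhb = per_frame_hbond_counts(traj, peptide_residues, cluster, criteria)

    stats = [np.array([mean_se(m[:, j], n_blocks=n_blocks)
                       for j in range(n_res)])
             for m in (nhb.astype(float), e_elec, e_vdw)]
    residues = np.array([int(top.res_numbers[r]) for r in peptide_residues])
    return EnergyProfile(
        residues=residues,
        n_hb=stats[0][:, 0], n_hb_se=stats[0][:, 1],
        e_elec=stats[1][:, 0], e_elec_se=stats[1][:, 1],
        e_vdw=stats[2][:, 0], e_vdw_se=stats[2][:, 1],
    )
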