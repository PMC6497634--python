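"""DSSP-style secondary-structure assignment and per-residue propensities.

Assignment follows the Kabsch-Sander scheme: backbone hydrogen bonds are
scored with the electrostatic model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol

and declared when E < -0.5 kcal/mol.  n-turns (n = 3, 4, 5) arise from
CO(i)...HN(i+n) bonds; two consecutive n-turns make a minimal 3-10 (G),
alpha (H) or pi (I) helix; parallel/antiparallel bridge patterns give
isolated bridges (B) and extended strands in ladders (E); isolated turns give
T; a bend (S) is flagged when the angle between CA(i)-CA(i-2) and
CA(i+2)-CA(i) exceeds 70 degrees.  Label priority: H > E > B > G > I > T > S,
everything else coil (C).

Amide hydrogens are reconstructed when absent: H is placed 1.01 A from N in
the C(i-1)-N-CA plane along the external bisector, so stripped or generated
backbones assign identically to protonated ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import angle
from .io import Trajectory
from .statcorr import HELIX_CLASS, mean_se

__all__ = ["SSAssignment", "ks_hbond_energy", "assign", "propensities",
           "SS_CLASSES"]

_KS_Q = 0.084 * 332.0          # kcal/mol * A, coupling constant
_KS_CUTOFF = -0.5              # kcal/mol, bond threshold
_MIN_DIST = 0.5                # A, singularity clamp
_BEND_ANGLE = 70.0             # deg

# reported classes: helix pools {H,G,I}; the rest are separate
SS_CLASSES = {"helix": {"H", "G", "I"}, "E": {"E"}, "B": {"B"},
              "T": {"T"}, "S": {"S"}, "C": {"C"}}


@dataclass
class SSAssignment:
    """Per-frame per-residue labels over the peptide residues of a trajectory."""

    labels: np.ndarray          # (n_frames, n_residues) of 'H','G','I','E','B','T','S','C'
    residue_numbers: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


def ks_hbond_energy(C: np.ndarray, O: np.ndarray, N: np.ndarray,
                    H: np.ndarray) -> float:
    """Kabsch-Sander electrostatic hydrogen-bond energy (kcal/mol).

    C, O belong to the acceptor carbonyl; N, H to the donor amide.  Distances
    below 0.5 A are clamped to 0.5 (singularity guard); exactly coincident
    atoms raise.
    """
    dists = {
        "ON": np.linalg.norm(O - N), "CH": np.linalg.norm(C - H),
        "OH": np.linalg.norm(O - H), "CN": np.linalg.norm(C - N),
    }
    for k, v in dists.items():
        if v == 0.0:
            raise ValueError(f"coincident atoms in K-S energy (r_{k} = 0)")
    r = {k: max(v, _MIN_DIST) for k, v in dists.items()}
    return float(_KS_Q * (1 / r["ON"] + 1 / r["CH"] - 1 / r["OH"] - 1 / r["CN"]))


def _backbone_arrays(traj: Trajectory):
    """Extract N/CA/C/O coordinates per peptide residue; NaN where missing."""
    top = traj.topology
    pep = np.nonzero(top.res_roles == "peptide")[0]
    n_res = len(pep)
    idx = np.full((n_res, 5), -1, dtype=int)      # N, CA, C, O, H
    names = {"N": 0, "CA": 1, "C": 2, "O": 3, "H": 4, "HN": 4}
    for k, r in enumerate(pep):
        for a in top.residue_atoms(int(r)):
            slot = names.get(top.atom_names[a])
            if slot is not None and idx[k, slot] == -1:
                idx[k, slot] = a
    chains = top.res_chains[pep]
    numbers = top.res_numbers[pep]
    return pep, idx, chains, numbers


def _reconstruct_h(bb: np.ndarray, idx: np.ndarray, same_chain_prev: np.ndarray):
    """Amide H per residue; NaN for residues without one (chain starts)."""
    n_res = idx.shape[0]
    H = np.full((n_res, 3), np.nan)
    for i in range(n_res):
        if idx[i, 4] != -1:
            H[i] = bb[i, 4]
            continue
        if not same_chain_prev[i] or idx[i, 0] == -1 or idx[i, 1] == -1 \
                or idx[i - 1, 2] == -1:
            continue
        N = bb[i, 0]
        u = N - bb[i - 1, 2]                     # from previous C
        v = N - bb[i, 1]                         # from own CA
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        b = u + v
        nb = np.linalg.norm(b)
        if nb < 1e-8:
            continue
        H[i] = N + 1.01 * b / nb
    return H


def _assign_frame(coords: np.ndarray, idx: np.ndarray,
                  chains: np.ndarray) -> np.ndarray:
    n_res = idx.shape[0]
    labels = np.array(["C"] * n_res, dtype="U1")
    bb = np.full((n_res, 5, 3), np.nan)
    for i in range(n_res):
        for s in range(5):
            if idx[i, s] != -1:
                bb[i, s] = coords[idx[i, s]]
    same_chain_prev = np.zeros(n_res, dtype=bool)
    same_chain_prev[1:] = chains[1:] == chains[:-1]
    H = _reconstruct_h(bb, idx, same_chain_prev)

    has_bb = ~np.isnan(bb[:, :4].reshape(n_res, -1)).any(axis=1)
    can_accept = has_bb
    can_donate = has_bb & ~np.isnan(H).any(axis=1)

    # hbond[i, j]: CO of residue i accepts from NH of residue j
    hbond = np.zeros((n_res, n_res), dtype=bool)
    for i in range(n_res):
        if not can_accept[i]:
            continue
        C, O = bb[i, 2], bb[i, 3]
        for j in range(n_res):
            if j == i or abs(j - i) < 2 or not can_donate[j]:
                continue
            e = _KS_Q * (
                1 / max(np.linalg.norm(O - bb[j, 0]), _MIN_DIST)
                + 1 / max(np.linalg.norm(C - H[j]), _MIN_DIST)
                - 1 / max(np.linalg.norm(O - H[j]), _MIN_DIST)
                - 1 / max(np.linalg.norm(C - bb[j, 0]), _MIN_DIST)
            )
            hbond[i, j] = e < _KS_CUTOFF

    def contiguous(a: int, b: int) -> bool:
        return 0 <= a and b < n_res and np.all(chains[a:b + 1] == chains[a])

    # n-turns: turn[n][i] iff CO(i)...HN(i+n)
    turn = {n: np.zeros(n_res, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(n_res - n):
            if contiguous(i, i + n) and hbond[i, i + n]:
                turn[n][i] = True

    # helices from two consecutive turns; collect before priority resolution
    helix_mask = {n: np.zeros(n_res, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(1, n_res - n):
            if turn[n][i - 1] and turn[n][i]:
                helix_mask[n][i:i + n] = True

    # bridges
    par = np.zeros((n_res, n_res), dtype=bool)
    anti = np.zeros((n_res, n_res), dtype=bool)
    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            if (hbond[i - 1, j] and hbond[j, i + 1]) or \
               (hbond[j - 1, i] and hbond[i, j + 1]):
                par[i, j] = par[j, i] = True
            if (hbond[i, j] and hbond[j, i]) or \
               (hbond[i - 1, j + 1] and hbond[j - 1, i + 1]):
                anti[i, j] = anti[j, i] = True
    bridge_partner = (par | anti).any(axis=1)
    # ladder: two same-type bridges on consecutive residues -> E; lone bridge -> B
    extended = np.zeros(n_res, dtype=bool)
    for mat in (par, anti):
        pset = {tuple(p) for p in np.argwhere(mat)}
        for i, j in pset:
            if any((i + di, j + dj) in pset
                   for di in (-1, 1) for dj in (-1, 1)):
                extended[i] = True
    isolated_b = bridge_partner & ~extended

    # turn label T: inside any n-turn span
    t_mask = np.zeros(n_res, dtype=bool)
    for n in (3, 4, 5):
        for i in np.nonzero(turn[n])[0]:
            t_mask[i + 1:i + n] = True

    # bend S
    s_mask = np.zeros(n_res, dtype=bool)
    for i in range(2, n_res - 2):
        if contiguous(i - 2, i + 2) and has_bb[i - 2] and has_bb[i] \
                and has_bb[i + 2]:
            ca_m, ca, ca_p = bb[i - 2, 1], bb[i, 1], bb[i + 2, 1]
            kink = 180.0 - angle(ca_m, ca, ca_p)
            if kink > _BEND_ANGLE:
                s_mask[i] = True

    # priority: H > E > B > G > I > T > S > C
    labels[s_mask] = "S"
    labels[t_mask] = "T"
    labels[helix_mask[5]] = "I"
    labels[helix_mask[3]] = "G"
    labels[isolated_b] = "B"
    labels[extended] = "E"
    labels[helix_mask[4]] = "H"
    labels[~has_bb] = "C"
    return labels


def assign(traj: Trajectory) -> SSAssignment:
    """Assign DSSP labels to every peptide residue in every frame.

    Residues missing a backbone atom are labeled C with a warning; terminal
    residues lacking the neighbours a pattern needs default to C.
    """
    pep, idx, chains, numbers = _backbone_arrays(traj)
    if len(pep) == 0:
        raise ValueError("trajectory has no peptide residues")
    missing = numbers[(idx[:, :4] == -1).any(axis=1)]
    if len(missing):
        warnings.warn(
            f"residues {list(missing)} lack backbone atoms; labeled C",
            stacklevel=2)
    labels = np.empty((traj.n_frames, len(pep)), dtype="U1")
    for f in range(traj.n_frames):
        labels[f] = _assign_frame(traj.coords[f], idx, chains)
    return SSAssignment(labels=labels, residue_numbers=numbers.astype(int))


def propensities(assignment: SSAssignment,
                 class_def: set[str] | frozenset[str] = HELIX_CLASS,
                 n_blocks: int = 5,
                 boundaries: np.ndarray | None = None) -> pd.DataFrame:
    """Fraction of frames each residue spends in a label class, with jackknife SE.

    ``class_def`` is a set of DSSP letters (default the helix pool {H, G, I}).
    Errors use the delete-one-block jackknife over frames, blocked either by
    explicit trajectory ``boundaries`` or into ``n_blocks`` equal blocks.
    """
    if not class_def:
        raise ValueError("empty class set")
    ind = np.isin(assignment.labels, list(class_def)).astype(float)
    rows = []
    for k, resnum in enumerate(assignment.residue_numbers):
        m, se = mean_se(ind[:, k], n_blocks=n_blocks, boundaries=boundaries)
        rows.append({"residue": int(resnum), "mean": m, "stderr": se})
    return pd.DataFrame(rows).set_index("residue")
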