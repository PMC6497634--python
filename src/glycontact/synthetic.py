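"""Synthetic peptide + pseudo-glycan-cluster trajectories with known ground truth.

The generator emulates the statistical structure of a 40-residue amyloid
peptide interacting with a rigid cluster of glycan chains:

* a two-state (bound/unbound) Markov chain governs binding frame to frame;
* when bound, a designated anchor glycan is placed in contact (< 3 A) with the
  ``contact_residues`` and the peptide center of mass sits near a configurable
  bound distance from the cluster center; when unbound the peptide is >= 45 A
  away;
* a helix segment (default residues 31-37) adopts ideal alpha-helical backbone
  torsions (-57, -47) with a bound-state-dependent probability, otherwise coil
  torsions are drawn uniformly from the coil basin;
* every glycosidic pseudo-torsion of each non-anchor glycan is drawn from a
  user-specified mixture of angular modes (a wrapped-normal spread about each
  mode mean), with per-frame per-glycan mode labels recorded as ground truth.

Glycans are bead chains: one pseudo-atom per sugar ring plus one linker bead
per linkage, attached to a rigid sphere of attachment points standing in for
the ligand cage.  This is deliberately not real sugar chemistry - it is the
minimal geometry that exercises distance, binding, hydrogen-bond, dPCA and
correlation code with exact known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import place_atom, rotation_about_axis
from .io import Topology, Trajectory

__all__ = [
    "SyntheticSpec", "GroundTruth", "build_peptide_frame", "generate",
    "make_hbond_fixture", "make_peptide_trajectory", "make_helix_fixture",
    "make_extended_fixture", "make_hairpin_fixture", "SUGAR_NAMES",
]

# inner -> outer sugar residues of the glycan head group; PDB-safe 3-char codes
SUGAR_NAMES = ["Glc", "Gal", "GalNAc", "Gal'", "Neu"]
SUGAR_PDB_CODES = {"Ligand": "LIG", "Glc": "GLC", "Gal": "GAL",
                   "GalNAc": "GNA", "Gal'": "GAP", "Neu": "NEU"}
PDB_CODE_TO_SUGAR = {v: k for k, v in SUGAR_PDB_CODES.items()}

# ideal backbone geometry (Angstrom, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
HELIX_PHI_PSI = (-57.0, -47.0)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic trajectory."""

    n_residues: int = 40
    n_glycans: int = 24
    sugars_per_glycan: int = 5
    n_frames: int = 500
    frame_interval_ps: float = 200.0
    p_on: float = 0.05
    p_off: float = 0.05
    helix_segment: tuple[int, int] = (31, 37)      # 1-based inclusive
    p_helix_given_bound: float = 0.8
    p_helix_given_unbound: float = 0.2
    # (mean torsion deg, angular sd deg, weight); weights sum to 1
    dihedral_modes: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(60.0, 10.0, 0.5), (180.0, 10.0, 0.5)])
    # optional alternative mode weights used in bound frames (same means/sds)
    bound_mode_weights: list[float] | None = None
    contact_residues: tuple[int, int] = (26, 29)   # 1-based inclusive
    bound_distance: float = 30.0
    bound_distance_sd: float = 1.5
    unbound_distance: float = 50.0
    cluster_radius: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        for p in (self.p_on, self.p_off, self.p_helix_given_bound,
                  self.p_helix_given_unbound):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        w = sum(m[2] for m in self.dihedral_modes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"dihedral mode weights sum to {w}, not 1")
        for lo, hi in (self.helix_segment, self.contact_residues):
            if not (1 <= lo <= hi <= self.n_residues):
                raise ValueError(
                    f"residue range {lo}-{hi} outside 1..{self.n_residues}")
        if self.unbound_distance < 45.0:
            raise ValueError("unbound_distance must be >= 45 A")


@dataclass
class GroundTruth:
    """Frame-aligned truth for every downstream statistic."""

    bound: np.ndarray          # (n_frames,) 0/1
    helix: np.ndarray          # (n_frames, n_residues) 0/1
    mode_labels: np.ndarray    # (n_frames, n_glycans) int; -1 = anchor override
    phi_psi: np.ndarray        # (n_frames, n_residues, 2) torsions used


def build_peptide_frame(phi_psi: np.ndarray) -> np.ndarray:
    """Build N, CA, C, O backbone coordinates from per-residue (phi, psi) torsions.

    Ideal bond lengths/angles with omega fixed at 180 degrees; an all-(-57,-47)
    schedule yields a right-handed alpha-helix.  Returns an array of shape
    ``(4 * n_residues, 3)`` ordered N, CA, C, O per residue.
    """
    phi_psi = np.asarray(phi_psi, dtype=float)
    if phi_psi.ndim != 2 or phi_psi.shape[1] != 2:
        raise ValueError("phi_psi must have shape (n_residues, 2)")
    if not np.all(np.isfinite(phi_psi)):
        raise ValueError("non-finite torsions")
    n = phi_psi.shape[0]

    # seed the first residue in a canonical pose
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    t = np.radians(180.0 - _A_N_CA_C)
    C = CA + _B_CA_C * np.array([np.cos(t), np.sin(t), 0.0])
    out = []
    prev = (N, CA, C)
    for i in range(n):
        N_i, CA_i, C_i = prev
        if i + 1 < n:
            psi_i = phi_psi[i, 1]
            N_next = place_atom(N_i, CA_i, C_i, _B_C_N, _A_CA_C_N, psi_i)
            CA_next = place_atom(CA_i, C_i, N_next, _B_N_CA, _A_C_N_CA, 180.0)
            C_next = place_atom(C_i, N_next, CA_next, _B_CA_C, _A_N_CA_C,
                                phi_psi[i + 1, 0])
            O_i = place_atom(N_i, CA_i, C_i, _B_C_O, _A_CA_C_O, psi_i + 180.0)
            prev = (N_next, CA_next, C_next)
        else:
            O_i = place_atom(N_i, CA_i, C_i, _B_C_O, _A_CA_C_O,
                             phi_psi[i, 1] + 180.0)
        out.extend([N_i, CA_i, C_i, O_i])
    return np.array(out)


def _cluster_attachment_points(n_glycans: int, radius: float) -> np.ndarray:
    """Deterministic quasi-uniform points on a sphere (Fibonacci lattice)."""
    k = np.arange(n_glycans)
    golden = (1 + 5 ** 0.5) / 2
    z = 1 - 2 * (k + 0.5) / n_glycans
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    theta = 2 * np.pi * k / golden
    return radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _build_glycan_chain(anchor: np.ndarray, outward: np.ndarray,
                        torsions: np.ndarray) -> np.ndarray:
    """Bead chain grown outward from its attachment point.

    Bead 0 is the ligand attachment; subsequent beads alternate linker/ring at
    3.0 A bonds and 109.5-degree angles, with the supplied torsion at each
    extendable position.  ``len(torsions)`` beads are added beyond the first
    three seed beads.
    """
    outward = outward / np.linalg.norm(outward)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(outward @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    side = np.cross(outward, ref)
    side /= np.linalg.norm(side)
    b0 = anchor
    b1 = anchor + 3.0 * outward
    t = np.radians(180.0 - 109.5)
    b2 = b1 + 3.0 * (np.cos(t) * outward + np.sin(t) * side)
    beads = [b0, b1, b2]
    for tor in torsions:
        beads.append(place_atom(beads[-3], beads[-2], beads[-1],
                                3.0, 109.5, float(tor)))
    return np.array(beads)


def _sample_mode_torsions(rng: np.random.Generator, modes, weights,
                          n_torsions: int) -> tuple[int, np.ndarray]:
    label = int(rng.choice(len(modes), p=weights))
    mean, sd, _ = modes[label]
    tor = rng.normal(mean, sd, size=n_torsions)
    return label, (tor + 180.0) % 360.0 - 180.0


def _coil_phi_psi(rng: np.random.Generator, n: int) -> np.ndarray:
    phi = rng.uniform(-180.0, -30.0, size=n)
    psi = rng.uniform(60.0, 180.0, size=n)
    return np.column_stack([phi, psi])


def _glycan_topology_arrays(spec: SyntheticSpec):
    """Atom/residue bookkeeping for one glycan chain of bead atoms."""
    # residues: Ligand (1 bead) then sugars (2 beads each: linker + ring)
    res_names = ["Ligand"] + SUGAR_NAMES[:spec.sugars_per_glycan]
    if spec.sugars_per_glycan > len(SUGAR_NAMES):
        extra = [f"Sug{i}" for i in range(len(SUGAR_NAMES), spec.sugars_per_glycan)]
        res_names = ["Ligand"] + SUGAR_NAMES + extra
    atom_res = [0]          # ligand bead
    atom_names = ["L1"]
    for s in range(1, len(res_names)):
        atom_res.extend([s, s])
        atom_names.extend([f"K{s}", f"R{s}"])   # linker bead, ring bead
    return res_names, atom_res, atom_names


def generate(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a trajectory plus its :class:`GroundTruth`, reproducibly from the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_res, n_gly = spec.n_residues, spec.n_glycans
    seg_lo, seg_hi = spec.helix_segment
    con_lo, con_hi = spec.contact_residues

    modes = spec.dihedral_modes
    weights = np.array([m[2] for m in modes])
    bound_weights = (np.asarray(spec.bound_mode_weights, dtype=float)
                     if spec.bound_mode_weights is not None else weights)
    if abs(bound_weights.sum() - 1.0) > 1e-9:
        raise ValueError("bound_mode_weights must sum to 1")

    attach = _cluster_attachment_points(n_gly, spec.cluster_radius)
    gly_res_names, gly_atom_res, gly_atom_names = _glycan_topology_arrays(spec)
    beads_per_glycan = len(gly_atom_res)
    n_torsions = beads_per_glycan - 3

    # ---- topology -------------------------------------------------------
    atom_names: list[str] = []
    elements: list[str] = []
    atom_residue: list[int] = []
    res_names: list[str] = []
    res_numbers: list[int] = []
    res_chains: list[str] = []
    res_roles: list[str] = []

    for r in range(n_res):
        res_names.append("ALA")
        res_numbers.append(r + 1)
        res_chains.append("A")
        res_roles.append("peptide")
        for nm, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atom_names.append(nm)
            elements.append(el)
            atom_residue.append(r)

    chain_ids = [c for c in
                 "BCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"]
    glycan_units = []
    for g in range(n_gly):
        base = len(res_names)
        chain = chain_ids[g % len(chain_ids)]
        unit = []
        for k, rn in enumerate(gly_res_names):
            res_names.append(SUGAR_PDB_CODES.get(rn, rn[:3].upper()))
            res_numbers.append(k + 1)
            res_chains.append(chain)
            res_roles.append("glycan")
            unit.append(base + k)
        for nm, ar in zip(gly_atom_names, gly_atom_res):
            atom_names.append(nm)
            elements.append("C")
            atom_residue.append(base + ar)
        glycan_units.append(np.array(unit, dtype=int))

    topology = Topology(
        atom_names=atom_names, elements=elements, atom_residue=atom_residue,
        res_names=res_names, res_numbers=res_numbers, res_chains=res_chains,
        res_roles=res_roles, glycan_units=glycan_units,
    )

    # ---- frames ---------------------------------------------------------
    n_pep_atoms = 4 * n_res
    coords = np.empty((spec.n_frames, topology.n_atoms, 3))
    bound = np.zeros(spec.n_frames, dtype=int)
    helix = np.zeros((spec.n_frames, n_res), dtype=int)
    mode_labels = np.full((spec.n_frames, n_gly), -1, dtype=int)
    phi_psi_truth = np.empty((spec.n_frames, n_res, 2))

    state = 0  # start unbound
    contact_res = np.arange(con_lo - 1, con_hi)      # 0-based
    for f in range(spec.n_frames):
        if state == 0:
            state = 1 if rng.random() < spec.p_on else 0
        else:
            state = 0 if rng.random() < spec.p_off else 1
        bound[f] = state

        # helix state: all-or-none across the segment
        p_h = spec.p_helix_given_bound if state else spec.p_helix_given_unbound
        helical = rng.random() < p_h
        pp = _coil_phi_psi(rng, n_res)
        if helical:
            pp[seg_lo - 1:seg_hi] = HELIX_PHI_PSI
            helix[f, seg_lo - 1:seg_hi] = 1
        phi_psi_truth[f] = pp
        pep = build_peptide_frame(pp)

        # rigid placement of the peptide along +x from the cluster center
        if state:
            d = rng.normal(spec.bound_distance, spec.bound_distance_sd)
            d = max(d, spec.cluster_radius + 5.0)
        else:
            d = max(45.0, rng.normal(spec.unbound_distance, 2.0))
        rot = rotation_about_axis(rng.normal(size=3), rng.uniform(0, 360))
        pep = pep @ rot.T
        pep += np.array([d, 0.0, 0.0]) - pep.mean(axis=0)
        coords[f, :n_pep_atoms] = pep

        # glycans
        frame_weights = bound_weights if state else weights
        for g in range(n_gly):
            label, tors = _sample_mode_torsions(rng, modes, frame_weights,
                                                n_torsions)
            chain = _build_glycan_chain(attach[g], attach[g], tors)
            coords[f, n_pep_atoms + g * beads_per_glycan:
                   n_pep_atoms + (g + 1) * beads_per_glycan] = chain
            mode_labels[f, g] = label

        if state:
            # anchor glycan 0: snap its outermost ring beads onto the contact
            # residues (2.5 A outward of each CA) so binding truth is exact
            mode_labels[f, 0] = -1
            ca = pep[4 * contact_res + 1]
            outward = ca - pep.mean(axis=0)
            outward /= np.linalg.norm(outward, axis=1, keepdims=True)
            targets = ca + 2.5 * outward
            n_snap = len(contact_res)
            sl = slice(n_pep_atoms + beads_per_glycan - n_snap,
                       n_pep_atoms + beads_per_glycan)
            coords[f, sl] = targets

    truth = GroundTruth(bound=bound, helix=helix, mode_labels=mode_labels,
                        phi_psi=phi_psi_truth)
    return Trajectory(topology, coords,
                      frame_interval_ps=spec.frame_interval_ps), truth


def make_peptide_trajectory(chains: list[np.ndarray],
                            offsets: list[np.ndarray] | None = None,
                            frame_interval_ps: float = 1.0) -> Trajectory:
    """One-frame peptide-only trajectory from per-chain (phi, psi) schedules.

    Each entry of ``chains`` is an ``(n_res, 2)`` torsion array built into an
    N/CA/C/O backbone; ``offsets`` optionally translates each chain.  Chains
    are lettered A, B, ... and all residues get role ``peptide``.
    """
    atom_names, elements, atom_residue = [], [], []
    res_names, res_numbers, res_chains, res_roles = [], [], [], []
    xyz = []
    ri = 0
    for ci, pp in enumerate(chains):
        coords = build_peptide_frame(np.asarray(pp, dtype=float))
        if offsets is not None:
            coords = coords + np.asarray(offsets[ci], dtype=float)
        else:
            coords = coords + np.array([0.0, 0.0, 20.0 * ci])
        xyz.append(coords)
        for r in range(len(pp)):
            res_names.append("ALA")
            res_numbers.append(r + 1)
            res_chains.append(chr(ord("A") + ci))
            res_roles.append("peptide")
            for nm, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                atom_names.append(nm)
                elements.append(el)
                atom_residue.append(ri)
            ri += 1
    top = Topology(atom_names=atom_names, elements=elements,
                   atom_residue=atom_residue, res_names=res_names,
                   res_numbers=res_numbers, res_chains=res_chains,
                   res_roles=res_roles)
    return Trajectory(top, np.concatenate(xyz)[None],
                      frame_interval_ps=frame_interval_ps)


def make_helix_fixture(n_residues: int = 12) -> Trajectory:
    """Single ideal right-handed alpha-helix, one frame."""
    return make_peptide_trajectory(
        [np.tile(HELIX_PHI_PSI, (n_residues, 1))])


def make_extended_fixture(n_residues: int = 8) -> Trajectory:
    """Single fully isolated extended chain (no strand partner), one frame."""
    return make_peptide_trajectory([np.tile([-120.0, 120.0], (n_residues, 1))])


def _orient_strand(s: np.ndarray) -> np.ndarray:
    """Align a strand's CA axis with +x and its carbonyls with the xy-plane."""
    ca = s[1::4]
    ax = ca[-1] - ca[0]
    ax /= np.linalg.norm(ax)
    v = np.cross(ax, [1.0, 0.0, 0.0])
    c = float(ax @ [1.0, 0.0, 0.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    s = (s - ca[0]) @ (np.eye(3) + vx + vx @ vx / (1 + c)).T
    co = s[3 * 4 + 3] - s[3 * 4 + 2]
    roll = -np.degrees(np.arctan2(co[2], co[1]))
    return s @ rotation_about_axis(np.array([1.0, 0, 0]), roll).T


# rigid placement of the second strand of the antiparallel fixture, found by
# maximizing the number of inter-strand backbone hydrogen bonds over registry
_SHEET_TORSIONS = (-140.0, 135.0)
_SHEET_DX_PAST_EXTENT = 5.0    # A beyond the CA extent of strand A
_SHEET_DY = 5.5                # A inter-strand separation


def make_hairpin_fixture(n_residues: int = 8) -> Trajectory:
    """Two-strand antiparallel beta-sheet (hairpin without the loop), one frame.

    Strand B is strand A rotated 180 degrees about the sheet normal and
    shifted into hydrogen-bond registry; interiors of both strands assign as
    extended (E).
    """
    sA = _orient_strand(build_peptide_frame(
        np.tile(_SHEET_TORSIONS, (n_residues, 1))))
    R = rotation_about_axis(np.array([0.0, 0, 1]), 180.0)
    extent = sA[1::4][:, 0].max() - sA[1::4][:, 0].min()
    sB = sA @ R.T + np.array([extent + _SHEET_DX_PAST_EXTENT, _SHEET_DY, 0.0])
    traj = make_peptide_trajectory(
        [np.tile(_SHEET_TORSIONS, (n_residues, 1))] * 2)
    coords = np.concatenate([sA, sB])
    return Trajectory(traj.topology, coords[None])


def make_hbond_fixture(distance_AD: float, angle_AHD: float) -> Trajectory:
    """One-frame donor-H-acceptor triplet with exact requested geometry.

    The donor N sits at the origin with its hydrogen 1.0 A along +x; the
    acceptor O is placed so that the donor-acceptor distance is
    ``distance_AD`` and the A-H-D angle is ``angle_AHD`` (degrees).
    """
    if distance_AD <= 0:
        raise ValueError("distance_AD must be positive")
    if not 0.0 < angle_AHD <= 180.0:
        raise ValueError("angle_AHD must be in (0, 180]")
    D = np.array([0.0, 0.0, 0.0])
    H = np.array([1.0, 0.0, 0.0])
    # acceptor at distance r from H, angle theta between H->D and H->A
    theta = np.radians(angle_AHD)
    # law of cosines: |AD|^2 = |AH|^2 + |HD|^2 - 2|AH||HD|cos(theta)
    # solve for |AH| given |HD| = 1 and |AD| = distance_AD
    b = -2 * np.cos(theta)
    c = 1.0 - distance_AD ** 2
    ah = (-b + np.sqrt(b * b - 4 * c)) / 2
    A = H + ah * np.array([np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0])
    topology = Topology(
        atom_names=["N", "H", "O"], elements=["N", "H", "O"],
        atom_residue=[0, 0, 1],
        res_names=["DON", "ACC"], res_numbers=[1, 2],
        res_chains=["A", "B"], res_roles=["peptide", "glycan"],
    )
    return Trajectory(topology, np.array([[D, H, A]]), frame_interval_ps=1.0)
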