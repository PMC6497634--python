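"""Multi-model PDB trajectories, topology with residue roles, and atom selections.

The on-disk format is multi-model PDB (v3.3 fixed columns, one MODEL/ENDMDL
block per frame).  The in-memory containers are a :class:`Topology` (atoms,
residues, chain roles, optional per-atom charge and Lennard-Jones parameters)
and a :class:`Trajectory` (a ``(n_frames, n_atoms, 3)`` coordinate array in
Angstrom over one topology).

Coordinates are assumed unwrapped: no periodic imaging is applied anywhere in
the package, so inputs must be whole-molecule imaged beforehand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Topology", "Trajectory", "AtomSet",
    "read_pdb_models", "write_pdb_models", "select", "subsample",
    "PDBParseError", "SelectionError",
]

ROLES = ("peptide", "glycan", "other")


class PDBParseError(ValueError):
    """Raised when a PDB file violates the multi-model contract."""


class SelectionError(ValueError):
    """Raised for a malformed selection expression; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass
class Topology:
    """Static structure: atoms, their residues, and chain roles.

    Residue ``role`` is one of ``peptide``, ``glycan`` or ``other`` and drives
    every peptide-vs-glycan analysis downstream.  ``glycan_units`` groups
    glycan residue indices into whole-glycan chains (one entry per glycan copy).
    Optional per-atom fields hold partial charges (e) and 12-6 LJ parameters
    (well depth epsilon in kcal/mol, r_min/2 in Angstrom) for energy profiles.
    """

    atom_names: np.ndarray          # (n_atoms,) str
    elements: np.ndarray            # (n_atoms,) str, e.g. "C", "H"
    atom_residue: np.ndarray        # (n_atoms,) int index into residue arrays
    res_names: np.ndarray           # (n_res,) str
    res_numbers: np.ndarray         # (n_res,) int, 1-based within chain
    res_chains: np.ndarray          # (n_res,) str chain id
    res_roles: np.ndarray           # (n_res,) str in ROLES
    charges: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None
    lj_rmin_half: np.ndarray | None = None
    glycan_units: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.atom_residue = np.asarray(self.atom_residue, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.res_numbers = np.asarray(self.res_numbers, dtype=int)
        self.res_chains = np.asarray(self.res_chains, dtype=object)
        self.res_roles = np.asarray(self.res_roles, dtype=object)
        if self.atom_residue.size and (
            self.atom_residue.min() < 0 or self.atom_residue.max() >= self.n_residues
        ):
            raise ValueError("atom_residue indices out of range")
        bad = set(self.res_roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown residue roles: {sorted(bad)}")
        if not self.glycan_units:
            self.glycan_units = self._infer_glycan_units()

    def _infer_glycan_units(self) -> list[np.ndarray]:
        """Group glycan residues into units by chain id (one chain = one glycan)."""
        units: dict[str, list[int]] = {}
        for i, (chain, role) in enumerate(zip(self.res_chains, self.res_roles)):
            if role == "glycan":
                units.setdefault(chain, []).append(i)
        return [np.array(v, dtype=int) for _, v in sorted(units.items())]

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.res_names)

    def residue_atoms(self, res_index: int) -> np.ndarray:
        return np.nonzero(self.atom_residue == res_index)[0]

    def residues_with_role(self, role: str) -> np.ndarray:
        return np.nonzero(self.res_roles == role)[0]


@dataclass
class Trajectory:
    """Frame-indexed coordinates (Angstrom) over one :class:`Topology`."""

    topology: Topology
    coords: np.ndarray              # (n_frames, n_atoms, 3) float
    frame_interval_ps: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords has {self.coords.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class AtomSet:
    """Ordered, unique atom indices into a topology plus the descriptor that made them."""

    indices: np.ndarray
    descriptor: str = ""

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("duplicate atom indices in AtomSet")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# PDB reading / writing

_COORD_SLICES = {"x": slice(30, 38), "y": slice(38, 46), "z": slice(46, 54)}


def _parse_atom_line(line: str, lineno: int):
    name = line[12:16].strip()
    altloc = line[16]
    if altloc not in (" ", "A"):
        raise PDBParseError(f"line {lineno}: unsupported altloc {altloc!r}")
    resname = line[17:20].strip()
    chain = line[21]
    try:
        resseq = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad residue number {line[22:26]!r}") from exc
    xyz = []
    for axis, sl in _COORD_SLICES.items():
        try:
            xyz.append(float(line[sl]))
        except ValueError as exc:
            raise PDBParseError(
                f"line {lineno}: unparseable {axis} coordinate {line[sl]!r}"
            ) from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # PDB v3.3 element column is mandatory but be forgiving: first letter of name
        element = re.sub(r"[^A-Za-z]", "", name)[:1].upper()
    return name, resname, chain, resseq, xyz, element.capitalize()


def read_pdb_models(path, role_map: dict[str, str] | None = None,
                    frame_interval_ps: float = 1.0) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    One frame per MODEL/ENDMDL block; a file without MODEL records yields a
    single-frame trajectory.  The topology is taken from the first model; all
    models must list the same atoms in the same order.  ``role_map`` maps chain
    id to a role in ``("peptide", "glycan", "other")``; unmapped chains get
    ``other``.
    """
    role_map = role_map or {}
    for chain, role in role_map.items():
        if role not in ROLES:
            raise ValueError(f"role_map[{chain!r}] = {role!r} not in {ROLES}")

    models: list[list] = []
    current: list | None = None
    saw_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_record = True
                if current:
                    models.append(current)
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                    current = None
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    if saw_model_record and models:
                        raise PDBParseError(
                            f"line {lineno}: atom record outside MODEL block"
                        )
                    current = []
                current.append(_parse_atom_line(line, lineno))
    if current:
        models.append(current)
    if not models:
        raise PDBParseError("no atom records found")

    first = models[0]
    n_atoms = len(first)
    for m, model in enumerate(models[1:], start=2):
        if len(model) != n_atoms:
            raise PDBParseError(
                f"model {m} has {len(model)} atoms, model 1 has {n_atoms}"
            )

    # build topology from the first model
    atom_names, elements, atom_residue = [], [], []
    res_names, res_numbers, res_chains = [], [], []
    res_key_to_index: dict[tuple, int] = {}
    for name, resname, chain, resseq, _xyz, element in first:
        key = (chain, resseq, resname)
        if key not in res_key_to_index:
            res_key_to_index[key] = len(res_names)
            res_names.append(resname)
            res_numbers.append(resseq)
            res_chains.append(chain)
        atom_names.append(name)
        elements.append(element)
        atom_residue.append(res_key_to_index[key])
    roles = [role_map.get(chain, "other") for chain in res_chains]

    topology = Topology(
        atom_names=atom_names, elements=elements, atom_residue=atom_residue,
        res_names=res_names, res_numbers=res_numbers, res_chains=res_chains,
        res_roles=roles,
    )
    coords = np.array(
        [[atom[4] for atom in model] for model in models], dtype=float
    )
    return Trajectory(topology, coords, frame_interval_ps=frame_interval_ps)


def write_pdb_models(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (v3.3 columns, 3-decimal coordinates)."""
    top = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            serial = 1
            for a in range(top.n_atoms):
                r = top.atom_residue[a]
                name = top.atom_names[a]
                # PDB atom-name alignment: 1/2-char element names start in col 14
                field = f" {name:<3s}" if len(name) < 4 else name[:4]
                x, y, z = traj.coords[f, a]
                fh.write(
                    f"ATOM  {serial:5d} {field}{'':1s}{top.res_names[r][:3]:>3s} "
                    f"{top.res_chains[r]:1s}{top.res_numbers[r]:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{top.elements[a]:>2s}\n"
                )
                serial = serial % 99999 + 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selections

_TOKEN_RE = re.compile(r"\S+")


def _match_term(top: Topology, key: str, value: str | None, pos: int) -> np.ndarray:
    res_of_atom = top.atom_residue
    if key == "heavy":
        return top.elements != "H"
    if key == "role":
        if value not in ROLES:
            raise SelectionError(f"unknown role {value!r}", pos)
        return (top.res_roles == value)[res_of_atom]
    if key == "chain":
        return (top.res_chains == value)[res_of_atom]
    if key == "resname":
        return (top.res_names == value)[res_of_atom]
    if key == "name":
        return top.atom_names == value
    if key == "element":
        return top.elements == value.capitalize()
    if key == "resnum":
        m = re.fullmatch(r"(\d+)(?:-(\d+))?", value or "")
        if not m:
            raise SelectionError(f"bad residue number/range {value!r}", pos)
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        mask = (top.res_numbers >= lo) & (top.res_numbers <= hi)
        return mask[res_of_atom]
    raise SelectionError(f"unknown selection keyword {key!r}", pos)


def select(topology: Topology, expression: str) -> AtomSet:
    """Evaluate a selection expression, returning atom indices in topology order.

    Grammar: terms joined by ``and``.  Terms: ``role=peptide`` (or ``role
    peptide``), ``chain A``, ``resnum 13-15``, ``resname NEU``, ``name CA``,
    ``element C``, ``heavy`` / ``not hydrogen`` (exclude element H).
    Deterministic and order-preserving; conjunction is set intersection.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]
    i = 0
    expect_term = True
    while i < len(tokens):
        tok, pos = tokens[i]
        if tok == "and":
            if expect_term:
                raise SelectionError("unexpected 'and'", pos)
            expect_term = True
            i += 1
            continue
        if not expect_term:
            raise SelectionError(f"expected 'and' before {tok!r}", pos)
        if tok == "heavy":
            mask &= _match_term(topology, "heavy", None, pos)
            i += 1
        elif tok == "not":
            if i + 1 >= len(tokens) or tokens[i + 1][0] != "hydrogen":
                raise SelectionError("'not' must be followed by 'hydrogen'", pos)
            mask &= _match_term(topology, "heavy", None, pos)
            i += 2
        elif "=" in tok:
            key, _, value = tok.partition("=")
            mask &= _match_term(topology, key, value, pos)
            i += 1
        else:
            if i + 1 >= len(tokens):
                raise SelectionError(f"keyword {tok!r} missing its value", pos)
            value = tokens[i + 1][0]
            mask &= _match_term(topology, tok, value, pos)
            i += 2
        expect_term = False
    if expect_term and tokens:
        raise SelectionError("dangling 'and'", tokens[-1][1])
    return AtomSet(np.nonzero(mask)[0], descriptor=expression)


def subsample(traj: Trajectory, interval_ps: float) -> Trajectory:
    """Keep every (interval_ps / frame_interval_ps)-th frame, starting at frame 0.

    ``interval_ps`` must be an integer multiple of the trajectory's frame
    interval; the returned trajectory carries the new interval.
    """
    ratio = interval_ps / traj.frame_interval_ps
    stride = int(round(ratio))
    if stride < 1 or abs(ratio - stride) > 1e-9:
        raise ValueError(
            f"interval {interval_ps} ps is not an integer multiple of the "
            f"frame interval {traj.frame_interval_ps} ps"
        )
    return Trajectory(traj.topology, traj.coords[::stride].copy(),
                      frame_interval_ps=interval_ps)
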