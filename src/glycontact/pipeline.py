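"""Full-analysis orchestration: subsample -> contacts -> interactions ->
secondary structure -> helix content -> dPCA -> correlation/landscape.

Every stage writes TSV outputs into the output directory and the run ends
with a ``manifest.json`` recording package version, a hash of the resolved
configuration, and per-stage row counts, so identical configs and inputs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import contacts as ct
from . import dpca, helixcd, interactions, secstruct, statcorr
from .io import AtomSet, Trajectory, read_pdb_models, select, subsample

__all__ = ["PipelineConfig", "run_all", "load_config", "glycan_dihedral_spec"]

log = logging.getLogger("glycontact")


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run (defaults mirror the study conditions)."""

    trajectories: list[str] = field(default_factory=list)
    role_map: dict[str, str] = field(default_factory=dict)
    binding_cutoffs: tuple[float, float] = (3.5, 5.0)   # A
    correlation_cutoff: float = 5.0                      # A, for C_ij
    ca_cutoff: float = 8.0                               # A
    hbond_distance: float = 3.5                          # A
    hbond_angle: float = 135.0                           # deg
    equilibration_fraction: float = 0.5                  # discard leading fraction
    temperature: float = 300.0                           # K
    frame_interval_ps: float = 200.0                     # of the input files
    subsample_interval_ps: float = 200.0
    helix_class: str = "HGI"
    d_bin_width: float = 1.0                             # A
    c_bin_width: float = 2.0                             # %
    dpca_bins: int = 40
    seed: int = 0
    out_dir: str = "out"

    def validate(self) -> None:
        for v in (*self.binding_cutoffs, self.correlation_cutoff,
                  self.ca_cutoff, self.hbond_distance, self.temperature):
            if v <= 0:
                raise ValueError(f"cutoffs and temperature must be positive, got {v}")
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValueError("equilibration_fraction must be in [0, 1)")
        if not self.trajectories:
            raise ValueError("no input trajectories")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load a flat key: value YAML config; unknown keys raise."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    for key in ("binding_cutoffs",):
        val = getattr(cfg, key)
        if isinstance(val, list):
            setattr(cfg, key, tuple(val))
    return cfg


def glycan_dihedral_spec(topology) -> list[list[tuple[int, int, int, int]]]:
    """Consecutive-bead torsion quadruples for each glycan unit.

    Bead chains yield one torsion per extendable position: atoms (k, k+1,
    k+2, k+3) along the chain.  Returns one quadruple list per glycan copy
    (all copies share the torsion layout).
    """
    specs = []
    for unit in topology.glycan_units:
        atoms = np.nonzero(np.isin(topology.atom_residue, unit))[0]
        quads = [tuple(atoms[k:k + 4]) for k in range(len(atoms) - 3)]
        specs.append(quads)
    return specs


def _default_energy_params(top) -> None:
    """Assign constant per-atom charge/LJ parameters when the topology has none.

    N atoms get +0.1 e, O atoms -0.1 e, everything else 0; epsilon 0.1
    kcal/mol and r_min/2 1.9 A everywhere.  These are user-assignable
    constants, not force-field values.
    """
    if top.charges is None:
        q = np.zeros(top.n_atoms)
        q[top.elements == "N"] = 0.1
        q[top.elements == "O"] = -0.1
        top.charges = q
    if top.lj_epsilon is None:
        top.lj_epsilon = np.full(top.n_atoms, 0.1)
    if top.lj_rmin_half is None:
        top.lj_rmin_half = np.full(top.n_atoms, 1.9)


def _stage(manifest, name):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            entry = {"stage": name, "seconds": round(time.time() - self.t0, 3)}
            if exc_type is not None:
                entry["status"] = "failed"
                entry["error"] = str(exc)
                manifest["stages"].append(entry)
                return False
            entry["status"] = "complete"
            entry.update(self.info)
            manifest["stages"].append(entry)
            log.info("stage %-12s %6.2fs %s", name, entry["seconds"],
                     {k: v for k, v in self.info.items()})
            return False

        info: dict = {}

    return _Ctx()


def run_all(config: PipelineConfig) -> dict:
    """Execute the whole analysis; returns (and writes) the manifest dict.

    A stage failure aborts the run (the exception propagates) but the
    manifest is still written, with the failed stage recorded and
    ``complete: false``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": asdict(config),
                "config_hash": config.config_hash(), "stages": []}
    try:
        _run_stages(config, out, manifest)
    finally:
        manifest["complete"] = bool(manifest["stages"]) and all(
            s["status"] == "complete" for s in manifest["stages"])
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: dict) -> None:
    helix_class = set(config.helix_class)

    # ---- stage: subsample (load + trim + stride) ------------------------
    trajs: list[Trajectory] = []
    with _stage(manifest, "subsample") as st:
        for p in config.trajectories:
            t = read_pdb_models(p, role_map=config.role_map,
                                frame_interval_ps=config.frame_interval_ps)
            if t.frame_interval_ps < config.subsample_interval_ps:
                t = subsample(t, config.subsample_interval_ps)
            start = int(t.n_frames * config.equilibration_fraction)
            t = Trajectory(t.topology, t.coords[start:],
                           frame_interval_ps=t.frame_interval_ps)
            trajs.append(t)
        st.info = {"trajectories": len(trajs),
                   "frames": int(sum(t.n_frames for t in trajs))}

    top = trajs[0].topology
    # one jackknife block per trajectory; a single trajectory falls back to
    # five equal blocks
    boundaries = (np.cumsum([0] + [t.n_frames for t in trajs])[:-1]
                  if len(trajs) > 1 else None)
    pooled = Trajectory(top, np.concatenate([t.coords for t in trajs]),
                        frame_interval_ps=trajs[0].frame_interval_ps)
    pep_heavy = select(top, "role=peptide and heavy")
    clus_heavy = select(top, "role=glycan and heavy")
    pep_res = top.residues_with_role("peptide")
    glycan_sets = [
        AtomSet(np.nonzero(np.isin(top.atom_residue, unit)
                           & (top.elements != "H"))[0], f"glycan{u}")
        for u, unit in enumerate(top.glycan_units)
    ]

    # ---- stage: contacts ------------------------------------------------
    with _stage(manifest, "contacts") as st:
        com = ct.com_distance_series(pooled, pep_heavy, clus_heavy)
        pd.DataFrame({"frame": np.arange(pooled.n_frames),
                      "com_distance": com.values}).to_csv(
            out / "com_distance.tsv", sep="\t", index=False)
        counts = {f"cutoff_{c}": ct.bound_glycan_count(
            pooled, pep_heavy, glycan_sets, c) for c in config.binding_cutoffs}
        pd.DataFrame({"frame": np.arange(pooled.n_frames), **counts}).to_csv(
            out / "bound_count.tsv", sep="\t", index=False)
        summary = ct.residue_min_distance_summary(pooled, pep_res, clus_heavy)
        summary.to_csv(out / "residue_summary.tsv", sep="\t")
        sugar = ct.residue_sugar_matrix(pooled, pep_res)
        sugar.to_long_tsv(out / "residue_sugar_matrix.tsv")
        ca_dist, ca_freq = ct.ca_matrices(pooled, pep_res,
                                          cutoff=config.ca_cutoff)
        ca_dist.to_long_tsv(out / "ca_distance.tsv")
        ca_freq.to_long_tsv(out / "ca_contact.tsv")
        st.info = {"frames": pooled.n_frames}

    # ---- stage: interactions -------------------------------------------
    with _stage(manifest, "interactions") as st:
        _default_energy_params(top)
        criteria = interactions.HBondCriteria(
            max_AD_distance=config.hbond_distance,
            min_AHD_angle=config.hbond_angle)
        profile = interactions.interaction_energy_profile(
            pooled, pep_res, clus_heavy, criteria=criteria,
            n_blocks=max(2, len(trajs)))
        profile.to_frame().to_csv(out / "energy_profile.tsv", sep="\t")
        st.info = {"residues": len(pep_res)}

    # ---- stage: secstruct ----------------------------------------------
    with _stage(manifest, "secstruct") as st:
        assignment = secstruct.assign(pooled)
        lab = pd.DataFrame(assignment.labels,
                           columns=assignment.residue_numbers)
        lab.insert(0, "frame", np.arange(pooled.n_frames))
        lab.to_csv(out / "ss_labels.tsv", sep="\t", index=False)
        prop = secstruct.propensities(assignment, helix_class,
                                      boundaries=boundaries)
        prop.to_csv(out / "helix_propensity.tsv", sep="\t")
        st.info = {"frames": assignment.n_frames}

    # ---- stage: helixcd -------------------------------------------------
    with _stage(manifest, "helixcd") as st:
        c_series = helixcd.helix_content_series(assignment.labels,
                                                helix_class=helix_class)
        pd.DataFrame({"frame": np.arange(pooled.n_frames),
                      "helix_content_percent": c_series}).to_csv(
            out / "helix_content.tsv", sep="\t", index=False)
        st.info = {"frames": len(c_series)}

    # ---- stage: dpca ----------------------------------------------------
    with _stage(manifest, "dpca") as st:
        specs = glycan_dihedral_spec(top)
        if specs and specs[0]:
            per_glycan = [dpca.extract_dihedrals(pooled, quads)
                          for quads in specs]
            angles = np.concatenate(per_glycan, axis=0)  # frames x glycans pooled
            ds = dpca.transform(angles)
            model = dpca.fit(ds)
            proj = dpca.project(model, ds)
            pd.DataFrame({"eigenvalue": model.eigenvalues}).to_csv(
                out / "eigenvalues.tsv", sep="\t", index_label="component")
            pd.DataFrame(
                proj[:, :min(3, proj.shape[1])],
                columns=[f"PC{i + 1}" for i in range(min(3, proj.shape[1]))],
            ).to_csv(out / "projections.tsv", sep="\t", index_label="obs")
            cmap = dpca.density_map(proj, bins=config.dpca_bins)
            grid = [(ia, ib, int(cmap.counts[ia, ib]), int(cmap.bin_mode[ia, ib]))
                    for ia in range(cmap.counts.shape[0])
                    for ib in range(cmap.counts.shape[1]) if cmap.counts[ia, ib]]
            pd.DataFrame(grid, columns=["bin_a", "bin_b", "count",
                                        "mode_label"]).to_csv(
                out / "cluster_map.tsv", sep="\t", index=False)
            st.info = {"observations": int(proj.shape[0]),
                       "modes": cmap.n_modes}
        else:
            st.info = {"observations": 0, "modes": 0}

    # ---- stage: statcorr ------------------------------------------------
    with _stage(manifest, "statcorr") as st:
        X = statcorr.helix_indicator(assignment.labels, helix_class)
        Y = ct.residue_binding_indicators(pooled, pep_res, clus_heavy,
                                          cutoff=config.correlation_cutoff)
        cmat = statcorr.cross_correlation(
            X, Y, row_labels=list(assignment.residue_numbers),
            col_labels=list(assignment.residue_numbers))
        cdf = pd.DataFrame(cmat.values, index=cmat.row_labels,
                           columns=cmat.col_labels)
        cdf.to_csv(out / "C_ij.tsv", sep="\t", index_label="helix_residue")
        surf = statcorr.landscape(com.values, c_series,
                                  temperature=config.temperature,
                                  d_bin_width=config.d_bin_width,
                                  c_bin_width=config.c_bin_width)
        occ = np.argwhere(surf.occupied)
        pd.DataFrame(
            [(surf.d_edges[i], surf.c_edges[j], surf.f_values[i, j])
             for i, j in occ],
            columns=["d_bin_left", "c_bin_left", "F_kcal_mol"],
        ).to_csv(out / "free_energy.tsv", sep="\t", index=False)
        st.info = {"defined_cells": int((~cmat.mask).sum()),
                   "occupied_bins": int(surf.occupied.sum())}
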