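# glycontact

Trajectory analysis for peptide / glycan-cluster binding studies, built
around the question of how a 40-residue amyloid-β (Aβ40) peptide recognizes
a cluster of GM1-glycan head groups and what that binding does to the
peptide's secondary structure.

The package takes multi-model PDB trajectories (peptide plus glycan chains)
and computes, as a reusable library, a thin CLI, and a reproducible
pipeline:

- **Contacts and binding** — per-frame minimum heavy-atom distances,
  center-of-mass separation, bound-glycan counts at 3.5/5.0 Å cutoffs,
  per-residue binding indicators, residue-vs-sugar average-minimum-distance
  matrices, Cα distance/contact matrices (8.0 Å) and with/without-glycan
  difference matrices.
- **Hydrogen bonds and energies** — donor–acceptor bonds via the
  X<sub>AD</sub> < 3.5 Å, θ<sub>AHD</sub> > 135° criterion; per-residue
  Coulomb and 12-6 Lennard-Jones interaction-energy profiles.
- **Secondary structure** — an independent Kabsch–Sander (DSSP)
  implementation (H/G/I/E/B/T/S/C) with per-residue propensities and block
  jackknife errors.
- **Helix content from calculated CD ellipticity** — per-frame helix content
  `c = ([θ_calc] − [θ]_coil)/([θ]_hel − [θ]_coil) × 100` with
  `[θ_calc] = ([θ]_hel/N) Σ (n_i − k)` over DSSP helix fragments,
  `[θ]_hel = 42500(1 − 3/N)`, `[θ]_coil = 640` deg·cm²/dmol, `k = 3`.
- **Dihedral PCA** — PCA on sine/cosine-transformed glycosidic torsions
  (`q_{2n−1} = cos φ_n`, `q_{2n} = sin φ_n`), density maps over principal
  components, deterministic conformer-mode labeling, and conditional
  (bound vs. all) mode populations.
- **Binding–helix coupling** — the cross-correlation
  `C_ij = ⟨X_i Y_j⟩ / √(⟨X_i²⟩⟨Y_j²⟩)` between helix indicators X and
  binding indicators Y, and the free-energy landscape
  `F(d, c) = −k_B T log P(d, c) − F_min` over center-of-mass distance and
  helix content.
- **Synthetic trajectories with exact ground truth** — a generator that
  couples a two-state binding process to segment helix formation and samples
  glycan pseudo-torsions from known angular modes, so every statistic above
  can be validated against truth.

## Worked example

Generate a 200-frame synthetic trajectory in which binding of residues
26–29 to the glycan cluster raises the helix probability of residues 31–37
from 0.2 to 0.8, then run the full pipeline:

```bash
cat > spec.yaml <<EOF
n_frames: 200
n_glycans: 8
p_on: 0.15
p_off: 0.15
p_helix_given_bound: 0.8
p_helix_given_unbound: 0.2
EOF
glycontact synth --spec spec.yaml --out traj.pdb --truth truth.tsv --seed 1
cat > config.yaml <<EOF
trajectories: [traj.pdb]
role_map: {A: peptide, B: glycan, C: glycan, D: glycan, E: glycan,
           F: glycan, G: glycan, H: glycan, I: glycan}
equilibration_fraction: 0.25
out_dir: out
EOF
glycontact run --config config.yaml
```

The run writes TSV tables plus `manifest.json` into `out/`. For the seed
above:

- `helix_propensity.tsv` reports mean helix propensity 0.587 ± 0.031 at
  residues 31–37 — the coupled segment is helical in the bound-heavy frames,
  as designed;
- `C_ij.tsv` peaks at C = 0.808 for helix residue 31 × binding residue 27,
  i.e. the cross-correlation recovers exactly the (31–37) × (26–29)
  coupling block the generator imposed;
- `bound_count.tsv` averages 1.03 bound glycans at the 3.5 Å cutoff and
  1.16 at 5.0 Å (counts are monotone in the cutoff by construction);
- `helix_content.tsv` spans −1.7 % (all-coil frames; the small negative
  value is an honest artifact of the two reference ellipticities) up to
  11.1 %.

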