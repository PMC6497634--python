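# Methods

This note records the models, conventions and numerical choices behind each
analysis layer, what the synthetic-data generator does and does not emulate,
and the limitations a user should know before applying the package to real
simulation data.

## Input model and conventions

Trajectories are multi-model PDB files (v3.3 columns, one MODEL/ENDMDL block
per frame); the topology is taken from the first model and every model must
list the same atoms in the same order. Coordinates are assumed **unwrapped**:
no periodic imaging is applied anywhere, so inputs must be whole-molecule
imaged beforehand. Altloc fields other than blank or 'A' are rejected rather
than silently merged.

Residues carry a role (`peptide`, `glycan`, `other`) assigned per chain.
Peptide residues are numbered 1–40 by default, matching Aβ40 positions;
glycan residues use the head-group names Glc, Gal, GalNAc, Gal', Neu plus a
Ligand attachment residue. Every distance criterion in the package uses
**strict inequality** at its cutoff ("less than"): a pair at exactly 3.5,
5.0 or 8.0 Å is a non-contact. Centers of mass default to unit weights over
the supplied (heavy-atom) selection; true masses can be passed explicitly.

## Contacts and binding

The per-frame minimum distance between two groups is the exact minimum over
all atom pairs (no neighbor lists or cutoff approximations — system sizes
here do not need them, and exactness makes the brute-force oracle test
meaningful). A glycan counts as bound when its minimum heavy-atom distance
to the peptide is below the cutoff; per-residue binding indicators Y_j use
the same rule against the whole cluster. The residue-by-sugar matrix
averages, over frames, the per-frame minimum distance to a sugar type; with
multiple glycan copies the per-frame value is the **minimum over copies** by
default (an average over copies is available via `pool="mean"`) — with ~24
equivalent glycans in a cluster, the nearest copy is the chemically relevant
one. Cα matrices require exactly one CA per residue and report both the mean
distance and the contact frequency (fraction of frames below 8.0 Å);
difference matrices are plain elementwise subtractions and therefore
antisymmetric under argument exchange.

## Hydrogen bonds and interaction energies

A hydrogen bond requires X_AD < 3.5 Å and θ_AHD > 135°, both strict, with
donors/acceptors restricted to N and O (sulfur is excluded; the lone Met
thioether in Aβ40 is a poor donor/acceptor and including it would add noise,
not signal). Hydrogens are paired to their donor geometrically (nearest N/O
within 1.3 Å on the first frame), since PDB input carries no bond table.

Interaction energies are a direct-sum pairwise decomposition over all
inter-group pairs: Coulomb `k_e q_i q_j / r` with
k_e = 332.0636 kcal·Å/(mol·e²), and 12-6 Lennard-Jones
`ε_ij[(r_min,ij/r)^12 − 2(r_min,ij/r)^6]` with ε_ij = √(ε_i ε_j) and
r_min,ij = (r_min/2)_i + (r_min/2)_j. No cutoff, no Ewald, no polarization:
this is an analysis-time decomposition of direct interactions, not a
re-evaluation of a simulation Hamiltonian, and it is documented as such.
Energies are averaged over all post-equilibration frames by default (a
restriction to bound frames is a caller-side filter on the frame axis).

## DSSP secondary structure

The assignment is an independent implementation of the Kabsch–Sander
scheme. Backbone hydrogen bonds use the electrostatic model
`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol with a bond
declared at E < −0.5 kcal/mol; inter-atom distances are clamped below at
0.5 Å to avoid singularities, and exactly coincident atoms raise. Amide
hydrogens are reconstructed at 1.01 Å from N along the external bisector of
C(i−1)–N and CA–N in that plane, so stripped or generated backbones assign
identically to protonated ones. n-turns (n = 3, 4, 5) come from
CO(i)⋯HN(i+n) bonds; two consecutive n-turns label residues i..i+n−1 as
G/H/I; parallel and antiparallel bridge patterns give B, extended to E when
two same-type bridges sit on consecutive residues; isolated turns give T; a
bend S is flagged when the CA(i−2)–CA(i)–CA(i+2) kink exceeds 70°. Label
priority is H > E > B > G > I > T > S > C. Pairs closer than two residues in
sequence are never scored (no turn or bridge pattern uses them). Terminal
residues that lack the neighbors a pattern needs default to C; residues
missing backbone atoms are labeled C with a warning.

The test suite compares assignments against the DSSP implementation bundled
with mdtraj on ideal-helix, extended-chain and antiparallel-sheet fixtures;
agreement is required on ≥ 95 % of residues. "Helix" for all downstream
statistics pools {H, G, I} by default and is configurable (e.g. {H} only) —
analyses of helical propensity conventionally include 3₁₀ caps, but the
choice is exposed because it is a convention, not a fact.

## Helix content from calculated ellipticity

Per frame, maximal runs of helix-class labels give fragment lengths n_i; the
calculated mean residue ellipticity at 222 nm is
`[θ_calc] = ([θ]_hel/N) Σ max(n_i − k, 0)` with
`[θ]_hel = 42500(1 − 3/N)` deg·cm²/dmol and k = 3 the shortest fragment that
produces a CD signal. Fragments with n_i ≤ k contribute zero rather than a
negative signal — a one-residue "helix" cannot produce negative helical CD.
Helix content is `c = ([θ_calc] − 640)/([θ]_hel − 640) × 100` percent,
reported **unclamped**: an all-coil frame sits at ≈ −1.65 % for N = 40, an
honest artifact of the two reference ellipticities (a clamp flag exists for
plotting). Note c(full helix) ≈ 92.4 %, not 100 %, because each fragment
loses k residues of signal.

## Dihedral PCA

Each torsion enters as the pair (cos φ, sin φ), removing the 2π circularity.
The covariance uses 1/M (population) normalization — the averages are
ensemble averages, and at the observation counts involved (≥ 10³) the
difference from 1/(M−1) is below 0.1 %. Eigenvectors are orthonormalized by
`numpy.linalg.eigh` and sign-fixed (largest-magnitude component positive) so
projections are reproducible across platforms. Projections of the training
set have zero mean and per-component variance equal to the eigenvalue;
external datasets (e.g. conformers projected onto eigenvectors fitted on a
reference ensemble) are supported with a dimension check.

Observations pool frames × glycan copies. Density maps over two principal
components are 2-D histograms; conformer modes are labeled deterministically
by grid-density peaks: the histogram is smoothed with a Gaussian filter
(σ = max(1, bins/20) bins — scaling with resolution keeps mode counts stable
under bin refinement), peaks are 8-neighborhood maxima above a threshold
(default 0.1 of the smoothed maximum, with an optional absolute floor), and
every occupied bin joins the peak its steepest-ascent path reaches; bins
whose path ends below threshold are noise. Populations are fractions of raw
observations. The labeling is deterministic given bins and thresholds; it
does not claim to reproduce any particular hand-labeled cluster set.
Conditional maps (e.g. bound-only frames) reuse the full-data grid and
labels so populations are directly comparable. A known caveat of dPCA is
that eigenvalues are not invariant under rotating the source angles (the
sine/cosine embedding is not rotation-equivariant); tests document rather
than hide this.

## Cross-correlation, landscape, jackknife

For binary indicators, `C_ij = P(X_i=1, Y_j=1)/√(P(X_i=1) P(Y_j=1))`, which
lies in [0, 1]. Frames are pooled across trajectories before the estimate
(per-trajectory averaging is a caller-side option); residues with X ≡ 0 or
Y ≡ 0 have undefined C and are masked (NaN), never zero-filled. The
free-energy surface is `F = −k_B T ln P − F_min` with natural log,
k_B = 0.0019872041 kcal/(mol·K), P a normalized 2-D histogram (default bins:
1 Å in distance, 2 % in helix content), unoccupied bins undefined (NaN) and
F_min chosen so the occupied minimum is zero.

Errors on time averages use the delete-one-block jackknife: with block b
removed, m_b is the mean of the remainder, and
SE = √((B−1)/B · Σ_b (m_b − m̄)²). Blocks default to one per independent
trajectory (trajectories are the natural independent units); a fixed block
length or explicit boundaries are accepted, and a single trajectory falls
back to five equal blocks. The estimator is calibrated in the tests against
σ/√n for i.i.d. data and against the effective-sample-size prediction
n_eff = n(1−ρ)/(1+ρ) for an AR(1) process with ρ = 0.9, at block lengths
well beyond the correlation time. Analyses discard a leading equilibration
fraction of each trajectory (default one half) and subsample to a fixed
frame interval (default 200 ps) before anything else.

## The synthetic-data generator

The generator emulates the statistical structure of the study system, not
its chemistry:

- **Binding** is a two-state Markov chain (per-frame probabilities p_on,
  p_off; start unbound). Bound frames place the peptide center of mass at a
  configurable distance from the cluster center (default 30 Å, SD 1.5 Å)
  and snap the outermost beads of one anchor glycan to 2.5 Å outside the CA
  of each contact residue (default 26–29), so binding truth is exact by
  construction; unbound frames keep the peptide ≥ 45 Å away (default 50 Å).
- **Helix** is all-or-none across the helix segment (default 31–37):
  with probability p(helix | state) the segment adopts ideal α torsions
  (−57°, −47°); otherwise, and everywhere outside the segment, coil torsions
  are drawn uniformly from φ ∈ [−180°, −30°], ψ ∈ [60°, 180°]. The backbone
  is built from torsions with ideal bond geometry (N–CA 1.458 Å, CA–C
  1.525 Å, C–N 1.329 Å, C=O 1.231 Å, ω = 180°).
- **Glycans** are bead chains (one bead per sugar ring plus one linker bead
  per linkage, 3 Å bonds, 109.5° angles) grown from a rigid Fibonacci-lattice
  sphere of attachment points (default radius 15 Å) standing in for the
  ligand cage. Each frame, each glycan draws one angular mode from the
  declared mixture and samples all its pseudo-glycosidic torsions from a
  normal spread about that mode's mean; per-frame per-glycan mode labels are
  recorded as ground truth (the anchor glycan's label is −1 in bound frames,
  where its geometry is overridden). An optional separate weight vector for
  bound frames lets binding suppress chosen modes.

Default study conditions: 40 residues, 24 glycans of 5 sugars, 200 ps frame
interval, p_helix_given_bound = 0.8, p_helix_given_unbound = 0.2. What the
generator does **not** emulate: real sugar chemistry or sterics, solvent,
force-field energetics (charges and LJ parameters are user-assigned
constants), gradual binding pathways, or per-residue helix fraying. Passing
tests therefore demonstrate that the analysis layer recovers known
statistical structure exactly and robustly — not that the physics of any
real system is reproduced.

## Problem sizes in tests and validation

The validation suite and `scripts/acceptance.py` size their simulations for
desk-scale reproducibility: 200 random instances of ≤ 50 atoms for the
brute-force distance oracle; 5 000 observations for dPCA mode recovery;
10⁴ frames for cross-correlation recovery; 10⁵ samples for the Gaussian
landscape; 100 replicates of n = 1000 (i.i.d.) and 15 replicates of
n = 20 000 (AR(1), block length 1000) for jackknife calibration; and a
nine-trajectory coupled run of 100–120 frames × 8 glycans each, against an
uncoupled control. These sizes give 3-SE statistical resolution on every
recovered parameter while keeping the whole suite in the minutes range.

## Known limitations

- No periodic minimum-image distances; wrapped trajectories must be imaged
  upstream.
- The PDB parser accepts only the v3.3 fixed-column dialect; no DCD/XTC.
- The energy decomposition is not a force-field re-evaluation (no cutoff
  schemes, no PME, no 1-4 handling — only inter-group pairs are summed).
- DSSP here implements the classic eight-state scheme without PP-II helices
  or β-bulge ladder merging; highly irregular sheets may differ from other
  implementations at edge residues.
- dPCA mode labeling is a deterministic density-peak heuristic; k-means on
  the projections is available as an alternative viewpoint but neither is a
  substitute for inspecting the maps.
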