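# Methods

## Scope and model

`empiriscore` rescsores given protein–ligand poses with a calibrated
empirical scoring function and provides the surrounding binding-pharmacology
math.  It does not generate poses, run docking searches, or run molecular
dynamics: poses, receptors and trajectory snapshots are inputs.

### The scoring function

The score of a pose is

```
ΔG = Σ_t w_t · T_t(pose, receptor) / (1 + w_rot · N_rot / 5) + reward
```

where each `T_t` is a distance-dependent term accumulated over all
intermolecular heavy-atom pairs, `w_t` are dimensionless weights, `N_rot` is
the ligand's rotatable-bond count and `w_rot` the torsion-divisor weight
(default 1.923).  The nine default terms and weights are:

| term | parameters | weight |
|---|---|---|
| gauss | o=0, w=0.5 (normalized from 0), c=8 | −0.035579 |
| gauss | o=3, w=2, c=8 | −0.005156 |
| repulsion | o=0, c=8 | 0.840245 |
| hydrophobic | g=0.5, b=1.5, c=8 | −0.035069 |
| non_dir_h_bond | g=−0.7, b=0, c=8 | −0.587439 |
| vdw | i=4, j=8, cap=100, c=8 | 0.0003 |
| acceptor_acceptor_quadratic | o=0, c=8 | −1.5 |
| donor_donor_quadratic | o=0, c=8 | −2.0 |
| ad4_solvation | σ=3.6, k=0.01097 | 0.01148 |

Distances (Å): steric terms act on the *surface distance*
`d = r − R_i − R_j` (center distance minus both van der Waals radii,
negative at clash); the desolvation kernel acts on `r` itself.  Every term is
exactly zero at and beyond its center-distance cutoff `c`.

Term shapes: `gauss = exp(−((d−o)/w)²)`; `repulsion = (d−o)²` only for
`d < o`; the hydrophobic and hydrogen-bond terms are linear slides equal to 1
for `d ≤ g`, 0 for `d ≥ b`, applied respectively to hydrophobic–hydrophobic
and donor–acceptor pairs; `vdw` is the two-exponent potential
`(i(r0/r)^j − j(r0/r)^i)/(j−i)` with minimum −1 at `r0 = R_i + R_j`, clamped
above at `cap`; the like-polar quadratic terms are `(d−o)²` for
acceptor–acceptor (resp. donor–donor) pairs — with their negative default
weights these act as rewards and are evaluated exactly as configured, with no
sign policing; the desolvation term is
`(S_i V_j + S_j V_i)·exp(−r²/2σ²)` in the Wesson–Eisenberg/AutoDock4 style
with charge-augmented solvation parameters `S = S_type + k·|q|`
(k = 0.01097 e⁻¹·kcal/(mol·Å³), σ = 3.6 Å).

Numerical notes:

* A configured gaussian width of 0 is mathematically degenerate (a delta
  function scores every pose 0); it is normalized to 0.5 Å with a warning.
* The torsion penalty enters as the divisor `1 + w_rot·N_rot/5`.  The
  divisor form is isolated in one function (`scoring.torsion_divisor`) so an
  alternative normalization can be swapped in.
* Hydrogens are ignored in pairwise scoring (heavy-atom convention); donor
  capability is flagged on the heavy atom.
* The optional salt-bridge reward adds a fixed bonus (default −1.0 kcal/mol)
  once per pose when a cationic ligand nitrogen lies within a threshold
  (default 4.0 Å) of the named residue's carboxylate oxygens.  The magnitude
  is a package default, configurable and reported in the score result.

### Thermodynamics

`Ki = exp(ΔG/RT)` with `R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹` and `T = 298 K` by
default.  298 K (not 298.15) is chosen because it reproduces the bundled
calculated-affinity table to the last printed digit; the temperature is a
profile parameter.  Cheng–Prusoff (`Ki = IC50/(1 + c/Kd)`) corrects
competition IC50s for radioligand occupancy.  Replicate Ki values aggregate
as the geometric mean with a 95% t-interval on log10(Ki) — the CI scale of
published affinity tables is typically unstated; the log-scale t-interval is
this package's declared convention.  Censored entries ("> limit") are
excluded from aggregation and calibration by default.

### Weight calibration

With the torsion weight fixed, the score is linear in the weights, so
calibration is linear least squares on the ΔG (log Ki) scale: row i of the
design matrix is `term_vector_i / (1 + w_rot·N_rot,i/5)` and the response is
the experimental ΔG from `ki_to_dg`.  Fitting on linear Ki would be dominated
by the weakest binders, hence the ΔG scale.  Options: per-term sign
constraints (bounded least squares), a 1-D grid over the torsion weight
(it enters nonlinearly), and a one-sided hinge penalty
`max(0, ΔG_bound − ΔG_pred)²` for censored records.  Rank deficiency raises
an error naming the collinear columns.  R² is `1 − SS_res/SS_tot` on ΔG.

### Interaction fingerprints

Geometric detectors with conventional, configurable cutoffs: salt bridge
(cationic N to Asp/Glu carboxylate O, 4.0 Å; a longer 5.5 Å tier is reported
as `electrostatic` rather than a separate physics model), hydrogen bonds
(donor–acceptor heavy atoms ≤ 3.5 Å; the reported distance is H···acceptor
when an explicit hydrogen exists, else heavy–heavy with a flag; angle
criteria are applied only with explicit hydrogens), activated C–H hydrogen
bonds (aromatic or α-carbonyl carbons), π–π stacking (ring-centroid ≤ 5.5 Å,
parallel/T-shaped/tilted by interplanar angle with a 30° band), and
hydrophobic contacts (≤ 4.5 Å, deduplicated per residue).  Fingerprints
order events deterministically (residue number, then kind) and poses can be
filtered by a required salt bridge to a named residue — the same geometry
used by the scoring reward.

### MD contact analysis

Contact matrices are binary frames × residues with entry 1 iff any ligand
heavy atom is within the cutoff (default 3.5 Å; vendor analysis tools use
unpublished criteria, so this plain geometric definition is declared) of any
heavy atom of the residue.  Contact frequency is the column mean.  Across a
compound panel, each residue's frequencies are correlated with log10(Ki) by
Pearson r, so negative r means higher affinity ↔ more frequent contact;
zero-variance residues are flagged undefined, never reported as r = 0.
Pose stability is per-frame heavy-atom RMSD against a reference frame,
optionally after Kabsch superposition.  Frames are labeled 1-based in
reports and stored 0-based internally.

### Protonation microstates

Independent-site Henderson–Hasselbalch model: site i is protonated with
probability `1/(1 + 10^(pH − pKa_i))` and microstate fractions are the
per-site products, computed by exact enumeration of all 2^n states.
Coupled-microstate models of pKa predictors are not reproduced; optional
pairwise ΔpKa penalties (applied when both sites of a pair are protonated,
with Boltzmann renormalization) approximate site–site coupling, default 0.

## Structure handling

PDB and PDBQT are read with a fixed-column parser (first model,
highest-occupancy altloc, warnings logged); PDBQT partial charges always
win.  SDF/MOL2 ligands are read through RDKit with Gasteiger partial
charges.  Chargeless PDB receptors receive template charges on ionizable
groups (carboxylate O −0.5, Lys NZ +1.0, Arg guanidinium N +0.5) during
typing; backbone and neutral side-chain atoms stay at 0.  PDBQT ligands
recover integral formal charges from the charge column when |q| ≥ 0.5
(the format carries no formal charges).

Atom typing bundles an AutoDock4-style parameter table (radii, solvation
volumes and parameters, versioned in `ad4params.py`).  Carbon is hydrophobic
iff bonded only to C/H/halogen; nitrogen is a donor when protonated or
H-bearing and an acceptor unless cationic; oxygen is always an acceptor;
sulfur is typed non-donor/non-acceptor (the Vina convention rather than the
AD4 acceptor-sulfur convention — this affects only hydrogen-bond pairing).
Rotatable bonds follow the AutoDock torsion convention — non-ring single
bonds between heavy atoms that each carry a further heavy neighbor, amide
C–N excluded — which intentionally differs from RDKit's SMARTS-based
default.  Receptors are treated as rigid throughout.

## Synthetic data and what it shows

The fixture generators are pure functions of (seed, parameters):

* **Toy complexes** — typed random atom clouds with controllable class
  fractions, a guaranteed closest-approach distance, and optionally a
  cationic N planted at an exact distance from a Glu carboxylate.  They
  exercise every term and detector but have no realistic covalent geometry,
  so they validate the *math* of the scoring function, not its chemistry.
* **Calibration sets** — default 19 records × 9 terms, mirroring a
  training set of 19 compounds; term vectors are rescaled so noiseless
  responses span −6 to −12 kcal/mol, the realistic binding range; noise is
  Gaussian on ΔG (default experiments use σ = 0.3 kcal/mol).  Passing
  recovery tests show the fitting pipeline is correct and well-conditioned
  at the study scale; they do not certify any particular published weight
  set, which would require the original poses.
* **Contact panels** — default 19 compounds; one residue's contact
  probability is constructed with an exact target correlation against
  log10(Ki) and binarized per frame (default 250 frames), other residues
  independent.  Recovery of a planted ρ = −0.45 (the magnitude of reported
  contact–affinity correlations) validates the correlation pipeline; the
  original values would require the underlying 500 ns trajectories.
* **Binding curves** — 4PL responses over 11 half-log concentrations in
  triplicate, matching a standard competition-assay design (5–11
  concentrations, three replicates); with 2% response noise the median IC50
  error is about 3%.

## Problem sizes

Default test and acceptance runs use: 20 toy complexes (12 ligand × 60
receptor atoms) for oracle equivalence, 100 seeds × 19 records for
calibration recovery, 200 seeds × 19 compounds × 250 frames × 8 residues for
correlation recovery.  These sizes give stable statistics while keeping the
full suite in the seconds range.

## Known limitations

* The default weights are taken as published; refitting them exactly would
  require the original receptor models and docked poses, which are not
  deposited.  Calibration is therefore validated by parameter recovery on
  synthetic data only.
* Receptor protonation, hydrogen placement and bond-order perception beyond
  file content are out of scope; typing is template- and graph-based.
* The C–H hydrogen-bond and π–π criteria are distance/angle conventions;
  different diagram software will disagree on borderline contacts.
* The independent-site protomer model ignores site coupling unless explicit
  ΔpKa shifts are supplied.
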