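# empiriscore

Empirical protein–ligand rescoring and binding pharmacology, built for
medicinal-chemistry work on multi-target ligands (the motivating system is a
series of dual histamine H3 / sigma-1 receptor ligands, but nothing is
receptor-specific).

Given a receptor structure and docked ligand poses, `empiriscore` evaluates a
calibrated nine-term empirical scoring function

ΔG = Σ_t w_t·T_t / (1 + w_rot·N_rot/5) + reward,  Ki = exp(ΔG/RT)

whose terms are the familiar distance-dependent atom-pair shapes (two
gaussians, a clash repulsion, hydrophobic and hydrogen-bond slides, a
two-exponent van der Waals potential, two like-polar quadratic rewards, and a
Wesson–Eisenberg-style desolvation kernel with charge-augmented atomic
solvation parameters), divided by a rotatable-bond penalty and optionally
rewarded for forming a salt bridge with a named active-site residue.  Around
the scoring core the package provides:

* **ΔG ↔ Ki** interconversion, Cheng–Prusoff IC50→Ki correction,
  four-parameter logistic competition-curve fitting, σ2/σ1 selectivity
  ratios with censored-value handling, and replicate Ki aggregation
  (geometric mean, 95% CI);
* **weight calibration** of the scoring function against experimental
  affinities by (optionally sign-constrained) least squares on the ΔG scale,
  with R² reporting on training and test sets;
* **interaction fingerprints** — salt bridges, electrostatics, conventional
  and C–H hydrogen bonds, π–π stacking, hydrophobic contacts — and pose
  filtering by a required salt bridge;
* **MD contact analysis** — per-residue contact frequencies across
  trajectory frames, Pearson correlation of frequency with compound
  affinity, and pose-stability RMSD series;
* **protonation microstates** of multi-basic ligands at a given pH from
  site pKa values;
* **deterministic synthetic fixtures** for every pipeline, so the whole
  package is testable without external downloads.

See `docs/methods.md` for the model details and conventions.

## Worked example

```python
>>> from empiriscore import dg_to_ki, selectivity_ratio
>>> round(dg_to_ki(-11.6, 298.0) * 1e9, 4)   # kcal/mol -> nM
3.1106
>>> round(dg_to_ki(-10.0, 298.0) * 1e9, 4)
46.3707
>>> str(selectivity_ratio(22.4, 3.64))       # sigma2 Ki / sigma1 Ki
'6.2'
```

A ΔG of −11.6 kcal/mol at 298 K corresponds to a 3.11 nM inhibition
constant — a strong binder — and a compound with σ2 Ki 22.4 nM and σ1 Ki
3.64 nM is 6.2-fold selective for σ1.  Protonation states of a di-basic
ligand (site pKa 9.2 and 8.4) at physiological pH:

```python
>>> from empiriscore.protomers import microstate_fractions, dominant_states
>>> dist = microstate_fractions([9.2, 8.4], 7.4)
>>> [(s.occupancy, round(f, 4)) for s, f in dominant_states(dist)]
[((1, 1), 0.8949), ((1, 0), 0.0895)]
```

89.5% of the population is doubly protonated — the species that should be
docked.  Rescoring poses from the shell:

```bash
empiriscore rescore --receptor rec.pdbqt --ligand pose.pdbqt \
    --salt-bridge A:172 --out scores.csv
empiriscore fingerprint --receptor rec.pdbqt --ligand pose.pdbqt --out fp.json
empiriscore convert --dg -11.6 --temp 298
```

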