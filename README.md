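# idpbem

A desk-scale bias-exchange metadynamics (BEM) analysis pipeline for
intrinsically disordered peptides, built around the 27-residue C-terminal
region of the plant UV-B photoreceptor UVR8 (`GKSWVSPAERYAVVPDETGLTDGSSKG`,
residues 397–423) and its P411A mutant.

Intrinsically disordered peptides have no single native fold; their
behaviour is a free-energy landscape over an ensemble of interconverting
conformations.  This package implements the full analysis chain used to
characterize such a landscape:

1. **Collective variables (CVs).**  Seven scalar descriptors of a
   conformation: counts of 6-residue fragments matching ideal α-helix,
   parallel-sheet and antiparallel-sheet templates through the rational
   switch *n*(RMSD) = (1 − (RMSD/r₀)⁸)/(1 − (RMSD/r₀)¹²) with r₀ = 0.08 nm
   (CV1–CV3); hydrophobic and salt-bridge contact numbers
   C_N = Σᵢⱼ (1 − (rᵢⱼ/r₀)ⁿ)/(1 − (rᵢⱼ/r₀)ᵐ) (CV4–CV5); and side-chain
   χ₁/χ₂ similarity to folded-protein reference angles
   AB = Σᵢ ½[1 + cos(χᵢ − χ₀ʳᵉᶠ)] (CV6–CV7).
2. **Bias-exchange metadynamics.**  Parallel replicas each deposit
   one-dimensional Gaussian hills (height 0.2 kJ/mol every 4 ps) along
   their own CV and periodically attempt Metropolis swaps of the bias
   potentials (every 20 ps, 330 K).  The molecular-dynamics engine is
   replaced by pluggable desk-scale samplers: overdamped Langevin dynamics
   on packaged analytic potentials with quadrature-exact free-energy
   references, and torsion-space Monte Carlo for peptides.
3. **WHAM.**  The biased replica histograms on a CV grid are combined by
   weighted-histogram self-consistency into one free-energy surface, with
   the global minimum pinned to 0 kJ/mol.
4. **Windowed structural analysis.**  Frames are stratified into 5 kJ/mol
   free-energy windows and annotated per residue: simplified-DSSP
   secondary structure (H/E/C from backbone H-bond patterns), a
   polyproline-II overlay (coil residues with φ, ψ within ±29° of
   (−75°, 145°) in runs of ≥ 2), Shrake–Rupley solvent-accessible surface
   area, and the radius of gyration.

A synthetic-data module generates every input with known ground truth:
backbones built from dihedral specifications, ensembles with prescribed
per-residue secondary-structure probabilities, toy torsion energy models,
and analytic validation potentials.

## Worked example

```python
import numpy as np
from idpbem import PeptideSequence, UVR8_C27_WT, build_backbone_from_torsions
from idpbem.backbone import uniform_profile
from idpbem.colvars import compute_cvs, uvr8_cv_config
from idpbem.structure import label_conformation, radius_of_gyration
from idpbem.synthetic import SSSpec, BlockSpec, sample_ensemble

seq = PeptideSequence(UVR8_C27_WT, numbering_offset=397)
helix = build_backbone_from_torsions(seq, uniform_profile(27, -57.8, -47.0))
cvs = compute_cvs(helix, uvr8_cv_config())
print("ideal helix CVs:", np.round(cvs, 3))
print("helix Rg (nm):", round(radius_of_gyration(helix), 3))

spec = SSSpec(n_residues=27,
              blocks=[BlockSpec(14, 18, "H", 0.20),   # P411-T414
                      BlockSpec(13, 15, "P", 0.20)],  # VP motif
              noise_sd=8.0)
traj, truth = sample_ensemble(seq, spec, n_frames=500, seed=1)
labels = np.array([label_conformation(c) for c in traj.frames])
r = seq.index_of(412)
print("helix fraction at D412: generated %.3f, recovered %.3f"
      % ((truth[:, r] == "H").mean(), (labels[:, r] == "H").mean()))
```

prints

```
ideal helix CVs: [21.998  0.263  0.146  0.349  0.027  0.     0.   ]
helix Rg (nm): 1.226
helix fraction at D412: generated 0.202, recovered 0.198
```

The ideal 27-residue helix scores essentially all 22 of its 6-residue
fragment windows on the α-helix CV and almost nothing on the sheet CVs;
an ensemble generated with 20% helix probability on residues 411–414 is
recovered by the secondary-structure classifier to within sampling noise.

## Command line

The same stages are exposed as a pipeline of subcommands with file
handoffs (multi-model PDB ensembles, TSV series, JSON manifests):

```bash
idpbem generate --config cfg.yaml --seed 7 --out gen      # synthetic ensemble
idpbem cvs      --pdb gen/ensemble.pdb       --out cv     # 7-CV series
idpbem bem      --config cfg.yaml --seed 7   --out run    # metadynamics
idpbem fes      --cvs run/bem_cvs.tsv --hills run/hills.tsv --out fes
idpbem analyze  --pdb gen/ensemble.pdb --windows fes/windows.tsv --out rep
```

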