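# Methods

This note documents the models, numerical choices and limitations of the
pipeline.  It is written for a reader who wants to know exactly what is
computed, what the synthetic data do and do not emulate, and which design
decisions were genuinely open.

## Peptide representation

Conformations are reduced to five heavy atoms per residue (N, CA, C, O,
CB) plus the backbone amide hydrogen.  Internal units are nm and degrees;
PDB I/O converts to/from Å.  Chains are built from (φ, ψ) by sequential
internal-coordinate placement with ideal geometry (N–CA 0.1458 nm,
CA–C 0.1525 nm, C–N 0.1329 nm, ω = 180°); the carbonyl O is placed anti
to the next amide N, CB by the tetrahedral improper N–C–CA–CB = +122.6°
(L-chirality; the ideal-alanine reference in biotite gives +120°), and
the amide H on the direction opposed to the C(i−1)–N–CA bisector with
N–H = 0.101 nm.  Prolines and the N-terminal residue carry no amide H,
matching the 24 observable backbone NH groups of the 27-mer.  Glycine
receives a constructed pseudo-CB (written to PDB under the atom name `QB`
so it is never confused with a chemical CB).  Side-chain χ angles cannot
be represented in the reduced coordinates; they travel as per-residue
metadata and are therefore lost over a PDB round-trip — the χ-similarity
CVs read them from the in-memory objects.

## Collective variables

* **CV1–CV3 (fragment counts).**  For every admissible 6-residue fragment
  the 30 atom positions are superposed (Kabsch) on an ideal template and
  scored by n(RMSD) = (1 − x⁸)/(1 − x¹²), x = RMSD/0.08 nm; the value at
  the removable singularity x = 1 is the analytic limit n/m = 2/3, and the
  ratio is evaluated through `expm1`/`log` so it is accurate arbitrarily
  close to the singularity.  α fragments are the L−5 contiguous windows.
  A contiguous 6-mer cannot form a two-stranded sheet, so the sheet
  fragments are pairs of 3-residue segments (i..i+2, j..j+2), j − i ≥ 4,
  superposed on a two-strand template.  Because the switch decays only as
  x⁻⁴, summing over all ~230 segment pairs of a 27-mer would accumulate a
  spurious O(1) tail even for a pure helix; pairs therefore contribute
  only when their segment centroids are within 1.0 nm, the same cutoff
  device the standard implementations of these CVs use.  Templates are
  built internally from canonical dihedrals (α: −57.8°/−47.0°; parallel
  strand: −119°/+113°; antiparallel strand: −140°/+135°, two strands
  placed 0.48 nm apart) and shipped as PDB fixtures; the published
  structure-database average coordinates are not printed anywhere, so an
  ideal-geometry construction is the reproducible choice.
* **CV4 (hydrophobic contacts).**  All non-adjacent pairs (|i−j| ≥ 2)
  among the side-chain sites of V401, P403, A404, A408, V409, V410, P411
  with r₀ = 0.40 nm, n = 6, m = 12.  The defining text gives r₀ = 4 Å in
  one sentence and 4.5 Å in the next; 4.0 Å (from the sentence that
  defines the pair list) is the default and 4.5 Å ships as a preset.  The
  contact exponents are unstated; n = 6, m = 2n is the standard rational-
  switch convention and both are configurable.
* **CV5 (salt bridges).**  All (acidic, basic) = {D, E} × {R, K} site
  pairs, r₀ = 0.35 nm.  Interaction sites are side-chain heavy-atom
  centroids when a full-atom file supplies them, else CB.
* **CV6/CV7 (χ similarity).**  ½[1 + cos(χᵢ − χ₀ʳᵉᶠ)] summed over residues
  possessing χ₁ (CV6) or χ₂ (CV7).  The reference table is a frozen set of
  rotamer-library style means per residue type; proline is excluded (its
  χ is ring-constrained).

All seven CVs are validated against naive loop re-implementations to
1e-10 on random conformations, and the fragment CVs are invariant under
rigid-body transforms by construction.

## Bias-exchange metadynamics

Each replica deposits one-dimensional Gaussians of constant height
0.2 kJ/mol every 4 ps along its own CV (no well-tempered scaling), widths
(0.2, 0.2, 0.2, 2.0, 0.65, 0.5, 0.2) for CV1–CV7, at 330 K
(kT = 2.744 kJ/mol with k_B = 0.0083145 kJ/mol/K).  Every 20 ps a random
replica pair attempts a bias swap with Metropolis probability
min(1, e^Δ), Δ = [V_a(x_a) + V_b(x_b) − V_a(x_b) − V_b(x_a)]/kT.  The run
loop realizes an accepted swap by exchanging the walkers between replica
slots — dynamically identical to swapping the biases, and it keeps every
sample series attached to a single bias, which is what WHAM needs.
Randomness is organized as one generator per replica plus one for
exchanges, all spawned from the master seed, so the draw order cannot be
perturbed by scheduling.

**Samplers.**  Explicit-solvent MD is out of scope; the sampler interface
(`cv_values()`, `advance(duration, bias)`, `reseed()`) is a documented
contract a real MD backend could implement.

* *Overdamped Langevin* (Euler–Maruyama, dt = 0.004 time units, γ = 1) on
  packaged analytic potentials, with reflecting walls at the domain
  bounds ±2.5 (the quartic tails make an explicit integrator unstable
  outside, and reflection leaves the interior Boltzmann density
  unchanged).  The bias force is linearly interpolated from a 4001-point
  grid refreshed incrementally at each deposit; hill widths are ~100 grid
  spacings, so the interpolation error is negligible.
* *Torsion-space Metropolis Monte Carlo* for peptides: single-angle moves
  in (φ, ψ, χ), mixing local Gaussian steps (25°) with 20% uniform
  redraws — both symmetric proposals, so detailed balance with respect to
  exp(−(U + V_bias)/kT) holds.  One sweep is bookkept as 1 ps so the
  deposit/exchange schedule applies unchanged.  The toy energy is a sum
  of per-residue periodic Gaussian wells in (φ, ψ) plus an optional
  soft-sphere CA repulsion; the analytic gradient covers the torsion-well
  term (the excluded-volume term is a function of coordinates and has no
  torsion-space gradient here).

**Free-energy estimation from a single biased replica.**  The negated
bias estimates the free-energy profile.  Constant-height hills leave
O(hill-height) ripples in the instantaneous bias, so the default
estimator is the time-averaged bias over the final 65% of the deposition
history; the instantaneous final bias remains available as a config
choice.  On the packaged asymmetric double well (h = 6 kJ/mol,
tilt = 1.2 kJ/mol; barrier ≈ 7.2 kJ/mol ≈ 2.6 kT) a 20 000-time-unit run
(5×10⁶ steps, 5000 hills) recovers the quadrature basin ΔF to a few
tenths of a kJ/mol and the barrier within ~10% across seeds.  Hill width
0.2 was chosen of the order of the thermal basin width
√(kT/U″) ≈ 0.24 — narrower hills resolve the profile but leave larger
ripple, wider hills bias the barrier downward.

## WHAM

The CV space is divided into a regular grid (half-open bins, final bin
closed; a value exactly on an interior edge belongs to the upper bin).
Per-replica histograms, after discarding the first 6% of each series as
equilibration (mirroring 30 ns of a 500 ns protocol), are combined by the
standard self-consistency

    p(c) ∝ Σ_r n_r(c) / Σ_r N_r exp((f_r − b_r(c))/kT),
    f_r = −kT log Σ_c p(c) exp(−b_r(c)/kT),

iterated in log space until the max free-energy change is below 1e-6
kJ/mol.  b_r is the replica's static metadynamics bias (time-averaged by
default, see above) evaluated at the cell centre of its biased CV; a
replica biased on a CV that is not a grid dimension contributes with a
constant (zero) bias and a warning — an approximation appropriate for the
qualitative peptide landscape, not for quantitative profiles.  Unvisited
cells are +∞ and never interpolated; disconnected replica supports raise
an error.  The converged grid is pinned so min F = 0 (idempotent), frames
are stratified into [5k, 5k+5) kJ/mol windows for k = 0..4, and
marginals are Boltzmann-weighted: F_marg = −kT log Σ exp(−F/kT).

For the two-basin 2D validation surface (h(x²−1)² + tilt·x + ½k_y y² +
c·x·y with h = 6, tilt = 0.8, k_y = 4, c = 1.5), two replicas biasing x
and y for 20 000 time units each reproduce both quadrature 1D marginals
within ~0.4 kJ/mol RMS.  The analysis grid spans [−1.75, 1.75]² (35²
bins), covering marginal free energies up to ~25–30 kJ/mol — the same
range the windowed analysis resolves; outside it the true free energy
exceeds 40 kJ/mol and no analysis uses those cells.  Profiles are
compared after removing the arbitrary additive constant (mean offset),
the usual convention for free-energy profiles.

## Structural annotation

* **Secondary structure** is a simplified DSSP: backbone H-bonds scored
  by E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol (distances
  in Å, bond below −0.5 kcal/mol).  α-helix (H) requires two consecutive
  i→i+4 turns, covering residues i..i+3; strand (E) requires a parallel
  or antiparallel bridge partner by the ladder rules; everything else is
  coil.  3₁₀/π helices, bends and turns are not distinguished — they all
  fall into C, so "turn content" of spectroscopic decompositions has no
  separate label here.
* **PPII** overlays P on coil residues with φ ∈ [−104°, −46°] and
  ψ ∈ [116°, 174°] (the (−75°, 145°) ± 29° box) in runs of ≥ 2
  consecutive residues; H and E take precedence, and chain termini
  (undefined φ or ψ) are never P.  "Coil region" is read as non-H/non-E.
* **SASA** is Shrake–Rupley over heavy atoms (radii C 0.170, N 0.155,
  O 0.152 nm; probe 0.14 nm) with deterministic golden-spiral sphere
  points (default 960), bit-stable across runs.  Hydrogens are excluded
  so backbone-only inputs are handled uniformly.
* **Radius of gyration** is mass-weighted over heavy atoms.
* **Window report.**  Per residue and window: fractions of frames labeled
  H/E/P, computed against the total retained population (the landscape-
  figure convention, default) or within-window (the "probability of X%"
  convention) — both supported by a mode flag; per window: mean Rg, mean
  total SASA, and ΔSASA_r(w) = mean SASA_r(w) − mean SASA_r(window 0),
  differenced on per-residue means.  Empty windows are excluded with a
  notice.

## Synthetic ensembles and what they show

`sample_ensemble` draws, per frame, a state for each specified residue
block (Bernoulli with the block's probability) and realizes it in
dihedrals: helical blocks get canonical α angles on exactly the labeled
residues (the carbonyl O co-rotates with the following N, so a block of
m ≥ 4 yields exactly m DSSP-H labels); PPII blocks get the canonical PPII
angles; hairpin blocks get two antiparallel strands joined by a frozen
2-residue turn whose dihedrals were refined numerically from a type-I′
β-turn seed until the cross-strand H-bond ladder satisfies the DSSP
energy criterion without steric overlap.  Structured residues receive
Gaussian dihedral noise (default SD 8°).  Coil residues draw φ uniformly
from (−180°, −30°) and ψ from (−180°, 180°], excluding ±30° boxes around
all canonical states, so a coil residue can never fall into a structured
classification box.  Whole frames are redrawn (block states held fixed,
so realized state fractions stay unbiased) until sterically self-avoiding
(no heavy-atom pair of residues ≥ 3 apart closer than 0.20 nm): without
excluded volume, random-dihedral chains self-overlap and their clashing
backbones produce spurious H-bond bridges.  The residues flanking a
helical block are redrawn with extended ψ ≥ 120°, the dihedral signature
of natural helix capping; otherwise a stray coil draw completes one more
i→i+4 turn and the helix label bleeds one residue past the block.
Overlapping blocks drawn in the same frame are resolved by priority
H > E > P and the returned ground-truth matrix always reflects what was
actually built.

What passing the recovery tests shows: the classifier chain
(H-bond geometry → DSSP patterns → PPII overlay) inverts this generator
essentially without bias at 8° noise.  What it does not show: performance
on real ensembles, whose coil is not box-excluded, whose helices fray
continuously rather than block-wise, and whose β content involves
imperfect, shifting registers.  Hairpin strand labels in particular are
reliable only near the noise-free construction; at 8° noise strand
detection degrades well before helix detection does, which is why the
quantitative recovery conditions use helix and PPII blocks.

## Problem sizes

The validation computations are sized for a single CPU: 5×10⁶ Langevin
steps for the 1D metadynamics run, 2×(5×10⁶) for the 2D bias-exchange
run, 2000 frames for parameter recovery, 960 sphere points for SASA, and
a 7-replica, 240-sweep Monte-Carlo bias exchange for the qualitative
peptide landscape (its assertion — the low-free-energy basin is less
helical than the run average — is deliberately coarse at this scale).

## Known limitations

* The static-bias WHAM treatment of metadynamics histories is an
  approximation; error grows for replicas far from convergence.
* The 7-CV landscape is gridded only on a configurable CV subset (default
  CV1 × CV4); a dense 7-D grid is almost entirely empty at desk scale,
  and biases on non-grid CVs enter as constants.
* The torsion Monte-Carlo sampler has no solvent, no realistic force
  field and no explicit side chains; it exercises the machinery, not the
  peptide's true thermodynamics.
* χ angles are metadata, not coordinates: ensembles read back from PDB
  have CV6 = CV7 = 0.
* The simplified DSSP omits 3₁₀/π helices, bends and β-bulges.
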