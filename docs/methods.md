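# Methods

## Linear-response redox estimates

The package estimates one-electron oxidation quantities from two
vertical-gap ensembles.  Both gaps are defined in the ionization direction
(energy of the cation minus the neutral at the same geometry): the VIE on
geometries sampled from the neutral ensemble, the VAE on geometries from
the cationic one.  Under the linear-response (two equal parabolas)
approximation,

    ΔE_red = (⟨VIE⟩ + ⟨VAE⟩) / 2,    λ = (⟨VIE⟩ − ⟨VAE⟩) / 2,

so ΔE_red always lies between the two ensemble means and λ ≥ 0 whenever
⟨VIE⟩ ≥ ⟨VAE⟩.  Snapshots are weighted equally: the frames are assumed to
be random draws from an equilibrated trajectory, which also justifies the
plain standard error SD/√n without autocorrelation correction.  Standard
errors of the half-sum combine in quadrature,
SE(ΔE_red) = ½√(SE_VIE² + SE_VAE²).

Conversion to a potential subtracts an absolute electrode constant from
ΔE_red (one electron, eV → V numerically).  The constant is data, not
physics baked into code: the default 4.28 V (a common absolute-SHE
literature value) lives in one place and every consumer accepts an
override.

## Additive QM-region scheme

Five hole-delocalization scenarios are analysed: (I) one nucleobase,
(II) two nucleobases, (III) one full ligand, (IV) two full ligands,
(V) one ligand plus the nearest gold atoms.  Rather than one huge QM
region per scenario, each scenario is assembled from three families of
small calculations — single ligand, ligand + 4 Au, two ligands — by
adding signed differences to a reference calculation, assuming the added
effects do not cooperate.  The default compositions are:

| scenario | composition |
|---|---|
| I   | lig_nb |
| II  | lig_nb + (pair_nb2 − pair_nb1) |
| III | lig_full |
| IV  | lig_full + (pair_lig2 − pair_lig1) |
| V   | lig_full + (gold_on − gold_off) |

where `lig_nb`/`lig_full` are the single-ligand calculation with the hole
confined to the nucleobase or spread over the ligand, `pair_*` the
two-ligand calculation with one vs two nucleobases (or ligands) opened,
and `gold_*` the ligand+Au calculation with gold blocked vs allowed.
Schemes are plain data (JSON-serializable), so users can substitute their
own compositions without touching code.  `additive_combine` is exact
arithmetic; SEs of a combined scenario add in quadrature over its terms.

## Hole localization

The hole distribution is the per-atom charge difference Δq between the
constrained-cation and neutral states of the same geometry.  Fragment
fractions divide each fragment's Δq sum by the total Δq — not by the sum
of positive parts — so negative fragment sums (back-polarization) are
reported as-is and conservation holds exactly.  A pair whose total Δq is
below 0.5 e is rejected as not describing a single hole.  Gold is one
aggregate fragment by default (per-atom resolution behind a flag); any
fragment outside a scenario's QM region, solvent included, is pooled into
a `spillover` column.  The localization index of a scenario is the largest
mean fragment fraction.

## Geometric descriptors

* **Dihedral**: the standard signed torsion (atan2 formulation) about the
  guanine–linker bond, in (−180°, 180°].  The four atoms are named by
  role tags (`dihedral_a…d`) in the fragment map; the generator supplies
  them and users of real data must provide them, since no universal atom
  quadruple exists across linker chemistries.
* **Stacking angle**: the angle between least-squares plane normals of two
  nucleobase ring-atom sets, folded into [0°, 90°] — 0° means parallel,
  π-stacked rings.  The normal is the smallest-variance principal
  direction of the centroid-referenced coordinates (SVD), which is
  deterministic and orientation-agnostic.  Point sets whose second
  singular value vanishes (collinear) raise a degeneracy error.
* **Interligand distance**: nucleobase heavy-atom centroid separation to
  the nearest other ligand.  Centroid–centroid (rather than minimum
  interatomic) distance matches the base–base separation scale of ~5 Å.
  Exact ties — square ligand grids put two neighbours at the same
  distance — break to the lowest ligand id within 10⁻⁶ Å, so the partner
  is stable under rigid motions.

All three descriptors are invariant under global rotation + translation;
the dihedral's sign flips under reflection.

## Synthetic ensembles

The generator emulates the statistical structure of MD/constrained-DFT
output, not its physics.  Each frame holds an idealized Au(100) mesh
(pitch a/√2 with a = 4.08 Å) and a grid of coarse ligands: a sulfur
anchor, a bead linker (4/3/6 beads for alkane/alkene/arene) and a planar
9-atom ring proxy for guanine.  Per frame, the ligand-grid pitch is drawn
from N(5.0, 0.3) Å — nucleobase centroids are translated copies, so the
nearest-neighbour distance follows that normal exactly — and each
ligand's dihedral from a wrapped normal folded into (−180°, 180°].
Dihedral centres: 90° (alkane), 15° (alkene), 20° neutral / 45° cationic
(arene); the neutral arene value sits inside the 10–30° band its ensemble
populates.  Spread defaults to 12°.  Ring planes rotate with the
dihedral, so stacking angles emerge as differences of per-ligand
dihedrals rather than being sampled directly.

Vertical gaps are `centre(linker, kind) + scenario offset +
angle_coupling × stacking angle + N(0, σ)` with VIE centres 6.0/6.5/5.5 eV
for alkane/alkene/arene and σ = 0.3 eV.  VAE centres are not fixed by the
emulated study; the default `vae_centre = vie_centre − 1.0 eV` gives a
typical aqueous reorganization energy of λ = 0.5 eV.  Default scenario
offsets (I: 0, II: 0, III: −0.1, IV: −0.4, V: −1.5 eV) encode the
mechanism signature.  The Gaussian noise stream depends on
(seed, kind, frame) but never on the scenario label: the same snapshot
re-evaluated under a different constraint re-uses its noise (common
random numbers), which is both what the additivity assumption describes
physically and what makes the additive-scheme closure exact to float
precision.  `angle_coupling` (default 0.01 eV/deg) is a modelling knob —
the emulated study shows only scatter-plot associations, so no measured
covariance exists to match.

Charge differences draw fragment-level hole fractions from a Dirichlet
centred on a per-scenario profile (concentration 200, i.e. tight;
∞ degenerates to the profile), spread uniformly over each fragment's
atoms, with N(0, 0.005 e) noise outside the allowed region and exact
renormalization to +1 e.  Default profiles: I all on the reference
nucleobase; II 95 %/5 % across the two nucleobases (strong
single-nucleobase localization); III two-thirds/one-third
nucleobase:linker, 55/45 for the conjugated alkene; IV a milder 55/45
preference spread over two ligands; V 75 % gold with the remaining 25 %
split evenly over the reference ligand.

What the generator does **not** emulate: explicit solvent, counterions,
force-field energetics, frame-to-frame autocorrelation, anharmonic
dihedral wells, and any coupling between hole fractions and geometry.
Passing tests therefore demonstrate that the estimators recover known
statistical structure, not that the physical conclusions hold for real
trajectories.

## Statistics

Angular summaries use circular mean/SD; angle histograms use fixed 5°
bins over the natural domain so linkers and states are comparable;
distribution centres are reported both as (circular) mean and histogram
mode, since the two differ for skewed ensembles.  The stacking/energy
association uses Spearman rank correlation — the claim being tested is
monotone, not linear — with a seeded permutation p-value,
p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (B + 1), B = 999 by default.  Ranks are
computed once and permuted, so cost is one inner product per permutation.

## Reproducibility and problem sizes

Every stochastic quantity descends from one integer seed.  Stage streams
derive as `SeedSequence(seed, spawn_key=(linker_index, state_index))`,
first word masked to 31 bits, so stages are independent and a global seed
change moves everything.  The default study size — 3 linkers × 2 states ×
200 frames on a 2 × 2 ligand grid — was chosen so that scenario gaps of
0.1 eV resolve at > 2 SE with σ = 0.3 eV noise (SE ≈ 0.021 eV at
n = 200); statistical-recovery checks use 500-frame ensembles, and the
permutation-test calibration uses 200 replicates of 100 frames at
B = 199, where the test is exact at level ⌊0.05·(B+1)⌋/(B+1) = 0.05.

## Limitations

The additive scheme's accuracy on real systems rests on the
no-cooperativity assumption, which the package takes as given and cannot
test from synthetic data built to satisfy it.  The SHE reference constant
and the scheme compositions are defaults to be overridden when the
upstream protocol specifies its own.  Back-polarization of the metal and
per-atom gold resolution are representable but not modelled by the
generator.
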