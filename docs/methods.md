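# Methods

This note documents the models, conventions, defaults and numerical choices
behind `idrdyn`, and what the synthetic-data generators do and do not
emulate.

## Units and conventions

Coordinates are Å, frame intervals ps, correlation-function lags and time
constants ns; all spectral densities and relaxation rates are evaluated in
SI seconds. Angles are degrees in (−180°, 180°], with the IUPAC torsion sign
convention (cross-checked against mdtraj in the test suite). Residue
numbering is 1-based for the actual sequence; a leading ACE cap takes index
0 and a trailing NME cap index n+1, so cap presence never shifts sequence
positions. Caps carry no dihedral or NH entries, and φ/ψ are reported only
for residues flanked by real residues on both sides: a capped 64-residue
chain reports 62 interior residues, hence 248 dPCA features. Frames are
assumed equally spaced; irregular time grids are not supported because the
time-averaged correlation function requires a uniform origin grid.

## Ensemble core

`load_ensemble` delegates file parsing to MDAnalysis (PDB, multi-model PDB,
DCD, XTC, TRR) and converts to a plain in-memory container: a light
topology (residues, atoms, backbone/side-chain/cap roles) plus an
`(n_frames, n_atoms, 3)` float array. Atom roles are assigned by name
(backbone = N, CA, C, O, OXT and the amide/α hydrogens); elements are taken
from the file when present, otherwise inferred from the atom name. Missing
backbone atoms yield per-residue NaN dihedrals and a log message rather than
an error, so a single damaged residue does not abort an analysis. Radius of
gyration is mass-weighted. Periodic-image reconstruction is out of scope;
input ensembles are assumed whole-molecule imaged.

## NH correlation functions and multi-exponential fits

`nh_correlation` evaluates C_NH(τ) = ⟨P₂[n(t+τ)·n(t)]⟩ₜ over all valid
origins at every lag on the frame grid, using the expansion of (n·n′)² into
the six unique outer-product component autocorrelations, computed with FFTs
and normalized by the exact origin count T − τ. This is bit-identical (to
1e-12) to the brute-force double loop, which the tests assert.

Fitting uses `scipy.optimize.curve_fit` with bounds A ∈ [0, 1.2],
τ ∈ [1 ps, 1 µs], and five deterministic multi-starts with log-spaced τ
seeds spanning the lag range (the spread contracted between starts); the
best χ² wins. χ² is the unweighted sum of squared residuals (an optional
`sigma` enables weighting); parameter errors are the square root of the
covariance diagonal, and relative errors use |parameter|. The ladder starts
at order 1 so that genuinely single-exponential data selects order 1; the
acceptance rule between successive orders is identical from there on
(thresholds ¼, 1/6, ...). Fits are performed on a thinned lag grid — every
frame lag up to 2 ns, then logarithmic thinning to ≤ 400 points up to
25 ns — for conditioning and speed; the dense short-lag region is what
determines the fast amplitudes.

Field constants: γ_H = 2.6752218744e8, γ_N = −2.7126180e7 rad s⁻¹ T⁻¹ (the
negative sign is kept, so frequency combinations are signed and the NOE
comes out below 1 naturally), r_NH = 1.02 Å, Δ_CSA = −170 ppm, proton
frequency 800 MHz by default. With these defaults the dipolar constant
f_DD ≈ 5.2 × 10⁸ s⁻².

Two optional corrections: an ultrafast component with amplitude 1 − A_sum
and τ_f = 10 ps (restoring C(0) = 1), and timescale rescaling
τᵢ → τᵢ/(1 + τᵢ/τ_s) with τ_s of order 10 ns, which leaves sub-ns constants
nearly untouched while roughly halving a ~15 ns constant — a compensation
for force fields that exaggerate the slowest motion.

`compare_profiles` computes the RMSE of replicate-averaged predictions
against an experimental table, excluding the first and last residue of the
predicted span, and bootstrap 95% CIs by resampling replicates with
replacement (1000 draws, seeded). Correlation functions are computed and
fitted per replicate, then observables averaged, matching the
per-trajectory treatment of replicate simulations.

## Secondary structure and PPII

DSSP states come from mdtraj's Kabsch–Sander implementation (backbone
H-bond electrostatic energy, −0.5 kcal/mol cutoff), computed on an mdtraj
topology built from the in-memory ensemble; amide H positions are
reconstructed internally, so hydrogens are not required. PPII, invisible to
an H-bond-based assignment, is added by reclassifying maximal runs of ≥ 3
consecutive coil residues whose (φ, ψ) fall in the PPII region. Defaults:

- PPII region φ ∈ [−110°, −40°], ψ ∈ [110°, 180°] — a rectangle bracketing
  the canonical (−75°, 145°) PPII point; configurable, since published PPII
  boundaries vary between assignment schemes.
- "Coil" eligible for reclassification means DSSP C and S (bend); turns,
  helices and strands are never reclassified. Bend is coil-like in common
  trajectory-analysis reporting; the set is a parameter.
- In frequency tables, π-helix folds into H, isolated bridge B into E, and
  bend into C (the non-aggregated table is available).

The reclassification is idempotent and is verified against an exhaustive
per-frame run-scan oracle on random grids.

## Contacts and correlated segments

Two heavy atoms are in contact below 3.5 Å; same-residue pairs are
excluded. For each residue pair the representative frequency is computed
per atom pair first and then maximized over atom pairs (the alternative —
fraction of frames with *any* atom pair in contact — is exposed as
`representative="any_atom"`). The per-residue nonlocal contact number is
the mean representative frequency over all partners excluding the three
nearest neighbours on each side, with the denominator counting *all*
eligible partners including zero-frequency ones (fixed-denominator choice,
so sparse maps average down rather than being conditioned on contact).

Cation-π events require ring-COM-to-cationic-group-COM distance < 5 Å and
an angle < 60° between the connecting line and the ring normal (per-frame
plane fit by SVD). Salt bridges are Arg/Lys side-chain N within 3.5 Å of
Asp/Glu carboxylate O. Side-chain-to-backbone hydrogen bonds use a
3.5 Å / 135° D–H···A criterion — values chosen because common
trajectory-analysis defaults differ between tools and versions; both are
parameters. Without polar hydrogens the angle test is skipped with a
warning.

Correlated segments are a declared algorithmic surrogate for what is often
done by eye on a contact map: pairs with representative frequency ≥ 0.01
(the point where contact-map colour scales typically switch from linear to
logarithmic) and |i − j| ≥ 2 define edges; each edge spans its sequence
interval, overlapping intervals merge, and merged spans < 3 residues are
dropped. Raising the threshold can only shrink the total span.

## Dihedral PCA

Features are (sin, cos) pairs of φ and ψ per interior residue, ordered by
residue then angle. PCA is performed on the covariance (not correlation)
matrix of mean-centered features with the unbiased (ddof = 1) convention,
so projection variances equal eigenvalues exactly. Per-torsion mode
contributions are the summed squared sine and cosine eigenvector
components; they sum to 1 per mode by orthonormality. The free-energy
surface is F = −ln(p/p_max) in k_BT over a 100 × 100 histogram of the first
two projections, with empty bins masked. Clustering is hierarchical Ward on
the 2-D projections (scipy linkage). The similarity score uses all heavy
atoms by default (hydrogens add cost without discriminating conformers) and
excludes the self term from the cluster average — including it only adds a
constant and never changes the argmax for clusters of ≥ 2. Because the
score is quadratic in both atom and snapshot count, clusters larger than
200 members are subsampled uniformly (seeded) before scoring.

## Amide exchange

CLEANEX-PM buildup ratios follow the two-rate magnetization-transfer
solution V/V₀ = k_ex/(R1a + k_ex − R1w)·[e^(−R1w·t) − e^(−(R1a+k_ex)·t)].
The fit treats k_ex and the apparent rate R1a as free and the water rate
R1w as fixed (it is common to all residues); noiseless round trips recover
k_ex to four significant figures. Intrinsic rates k_intrinsic are an input
table (they come from sequence-based reference-rate servers, which are
external); protection factors are k_intrinsic/k_ex, with half-range means
over residues 5–32 and 33–60 and a Welch unequal-variance t-test between
halves.

## SAXS and size statistics

The Debye form factor I(q) = I₀·2(e^(−x) + x − 1)/x², x = (qR_g)², is fit
by least squares over q ≤ 0.15 Å⁻¹ (default, reported with the fit;
σ-weighted when uncertainties are provided), with a Guinier-based initial
R_g and a series expansion for numerically small x. The empirical IDP
scaling relation R_g = 2.54 N^0.522 Å gives 22.3 Å for a 64-residue chain.
The Kratky transform q²I(q) plateaus at 2I₀/R_g² for a Debye scatterer.
Half-vs-half comparisons default to residues 5–32 vs 33–60 (the common
reporting ranges that trim noisy termini); full halves are available.

## Synthetic data: what it emulates, and what it does not

Each generator is deterministic given (parameters, seed) and returns its
ground truth alongside the data:

- **Rotational diffusion**: sequential random rotations with Gaussian
  rotation vectors of per-component variance 2DΔt, sub-stepped so the
  per-step angle variance stays ≤ 0.01 rad², keeping the discretization
  bias of the exp(−6Dτ) oracle below 1%.
- **Multi-exponential curves**: direct synthesis on a 20 ps – 25 ns lag grid
  plus Gaussian noise; defaults mirror realistic disordered-chain fits
  (A ≈ 0.2–0.4, τ ≈ 0.3–12 ns).
- **Ramachandran series**: per-residue (or per-block, for joint switching)
  Markov states over Gaussian basins at PPII (−70°, 150°), α (−63°, −43°),
  extended (−120°, 130°), left-handed (60°, 45°), σ = 10° per angle;
  redraw-from-stationary switching makes the long-run occupancies equal the
  specification exactly. Note the chain is autocorrelated: occupancy
  estimates carry an effective sample size smaller than the frame count
  unless the switching probability is 1.
- **Planted contacts**: a straight coarse backbone with one side-chain atom
  per residue; contact frames place the two atoms 3.0 Å apart at a private
  meeting point, non-contact frames keep all inter-residue side-chain
  distances > 6 Å. No excluded volume — the fixture tests counting, not
  physics. A residue may join only one planted contact, since reuse would
  make the planted frequencies geometrically inconsistent.
- **CLEANEX buildups and Debye profiles**: the same closed forms the fitting
  routines assume, plus noise — round trips test the estimators, not model
  misspecification.
- **Ideal chains**: NeRF-built backbones (standard bond lengths/angles,
  ω = 180°) from prescribed φ/ψ, with planar amide hydrogens and optional
  ACE/NME caps; used for dihedral round trips and canonical DSSP
  geometries (helix, extended chain, a β-hairpin template).

Passing tests on these fixtures demonstrates that the analysis machinery is
correct and self-consistent. They do not demonstrate force-field accuracy,
convergence of real ensembles, solvent effects, or experimental noise
structure — conclusions about a real protein still require real ensembles
and measurements.

## Problem sizes and degenerate inputs

Test and acceptance workloads are sized for a desk machine: tens of
thousands of frames for stochastic recovery checks, hundreds for exact
oracles. Degenerate cases are defined rather than left to chance: a
singleton cluster's representative score is 1; zero k_ex flags the residue
instead of producing an infinite protection factor; a zero-amplitude fit
yields R1 = R2 = 0 and an undefined (NaN) NOE; rank-deficient dPCA input
yields zero trailing eigenvalues; a max-lag longer than the trajectory is
truncated with a warning; ties in representative selection go to the lowest
snapshot index.

## Interfaces

The library functions and `scripts/acceptance.py` are the interface; the
shell-command sketches that a pipeline wrapper might expose are fulfilled by
the module surface (tables are plain pandas/numpy objects that write to
delimited text directly).

## Known limitations

- DSSP is delegated to mdtraj; exotic states (π-helix ladders, chain
  breaks) follow its behaviour.
- The peptide-plane libration order parameter is not computed; the ultrafast
  amplitude is inferred only as 1 − A_sum.
- SAXS profiles are analyzed at the Debye level; no hydration-shell or
  explicit-atom profile computation.
- Contact maps are O(pairs × frames) dense computations, appropriate for a
  single chain of ~100 residues, not for large complexes.
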