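# idrdyn

Ensemble-analysis toolkit for intrinsically disordered proteins (IDPs):
from conformational ensembles of a single chain to backbone ¹⁵N relaxation
observables, polyproline-II (PPII) propensities, contact-based correlated
segments, dihedral-PCA landscapes, amide-exchange protection factors, and
SAXS-derived size metrics.

## Who it is for

Structural biophysicists who have (or simulate) conformational ensembles of a
disordered chain and want to connect them quantitatively to solution
measurements: ¹⁵N R₁/R₂/NOE profiles, CLEANEX-PM amide exchange rates, and
small-angle X-ray scattering. Because real multi-microsecond ensembles are
expensive, the package ships a first-class synthetic-data module whose
generators have exact ground truth, so every stage of the pipeline is
testable end to end.

## The model at the core

For each amide N–H unit vector **n**(t), the orientational correlation
function is the time-averaged second-order Legendre polynomial

    C_NH(τ) = ⟨ P₂[ **n**(t+τ) · **n**(t) ] ⟩_t ≈ Σᵢ Aᵢ e^(−τ/τᵢ)

fitted by a sum of exponentials whose order is selected by a χ² ladder:
order n+1 replaces order n only if χ²ₙ₊₁/χ²ₙ < ½(1 − n/(n+1)) (¼ for 1→2,
1/6 for 2→3) *and* every parameter of the larger fit has a relative error
below 10%. The amplitude sum is left unconstrained; its deficit 1 − A_sum is
attributed to an ultrafast librational decay (τ_f ≈ 10 ps) completed before
the first saved lag. The spectral density

    J(ω) = Σᵢ Aᵢ τᵢ / (1 + (ωτᵢ)²)

then yields R₁, R₂ and the heteronuclear NOE through the standard
dipolar/CSA expressions, and the area under C_NH(τ) equals J(0), whose
per-exponential decomposition separates slow "collective" from fast local
motion. Around this core sit: DSSP labelling extended with a PPII state
(runs of ≥ 3 in-region coil residues), heavy-atom contact maps at 3.5 Å with
salt-bridge/cation-π/H-bond typing and correlated-segment calling, dihedral
PCA with Ward clustering and similarity-score representatives, CLEANEX-PM
exchange-rate fits with protection factors k_intrinsic/k_ex, and Debye-model
SAXS fits with the empirical IDP scaling relation R_g = 2.54 N^0.522 Å.

## Worked example

Fit a noisy tri-exponential correlation function (known ground truth
A = 0.22/0.36/0.23, τ = 11.5/2.4/0.34 ns) and predict observables at
800 MHz:

```python
import numpy as np
import idrdyn.relaxation as rx
import idrdyn.synthetic as syn

corr, truth = syn.multiexp_corr_samples(
    amplitudes=[0.22, 0.36, 0.23], taus=[11.5, 2.4, 0.34], noise_sd=1e-3, seed=1)
fit = rx.multiexp_fit_ladder(corr)
print(f"selected order: {fit.order}")
print("amplitudes:", np.round(fit.amplitudes, 3))
print("time constants (ns):", np.round(fit.taus_ns, 2))
print(f"A_sum: {fit.a_sum:.3f}")
corrections = rx.Corrections(tau_f_ps=10.0)
rec = rx.relaxation_observables(fit, corrections, rx.FieldParams(proton_mhz=800))
print(f"R1 = {rec.r1:.2f} s^-1, R2 = {rec.r2:.2f} s^-1, NOE = {rec.noe:.2f}")
print(f"AUC = J(0) = {rec.auc_ns:.2f} ns")
```

prints

```
selected order: 3
amplitudes: [0.218 0.361 0.231]
time constants (ns): [11.57  2.41  0.34]
A_sum: 0.810
R1 = 1.39 s^-1, R2 = 6.67 s^-1, NOE = 0.35
AUC = J(0) = 3.48 ns
```

The ladder recovers the planted order and parameters; A_sum < 1 signals the
sub-20-ps librational amplitude the fit cannot see; the ~3.5 ns AUC is the
zero-frequency spectral density that drives R₂.

Loading real data instead of synthetic fixtures:

```python
from idrdyn import load_ensemble, nh_vectors
from idrdyn.relaxation import nh_correlation

ens = load_ensemble("topology.pdb", "trajectory.xtc", frame_interval=20.0)
corrs = nh_correlation(nh_vectors(ens), max_lag=25.0)
```

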