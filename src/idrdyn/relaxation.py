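"""Backbone 15N relaxation from NH bond-vector dynamics.

The pipeline follows the standard route from an ensemble to observables:

1. The P2 autocorrelation of each amide NH unit vector,
   ``C_NH(tau) = < P2[ n(t + tau) . n(t) ] >_t``, computed as a time average
   over all origins on the saved-frame grid (FFT accelerated).
2. A multi-exponential fit ``C(tau) = sum_i A_i exp(-tau / tau_i)`` with the
   amplitude sum left unconstrained; the model order is selected by a
   chi-square ladder: order n + 1 replaces order n only when
   ``chi2_{n+1} / chi2_n < (1/2) (1 - n/(n+1))`` and every fitted parameter of
   the larger model has a relative fitting error below 10%.
3. The spectral density ``J(w) = sum_i A_i tau_i / (1 + (w tau_i)^2)``,
   optionally augmented by an ultrafast librational term with amplitude
   ``1 - A_sum`` and time constant tau_f (default 10 ps, completed before the
   first saved lag), and optionally with every tau_i rescaled by
   ``1 / (1 + tau_i / tau_s)`` to compensate a force field that exaggerates
   the slowest timescale.
4. R1, R2 and the heteronuclear NOE from the standard dipolar/CSA expressions
   at a given proton Larmor frequency, plus the area under the correlation
   function (AUC = J(0)) with its per-exponential decomposition.

Time constants are handled in ns throughout; spectral densities and rates are
evaluated in SI seconds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from idrdyn.ensemble import VectorSeries

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationFunction",
    "MultiExpFit",
    "Corrections",
    "FieldParams",
    "RelaxationRecord",
    "nh_correlation",
    "ladder_threshold",
    "multiexp_fit_ladder",
    "thin_lag_grid",
    "spectral_density",
    "relaxation_observables",
    "auc_profile",
    "compare_profiles",
    "brute_force_p2_correlation",
]


@dataclass
class CorrelationFunction:
    """P2 autocorrelation of one NH vector on a lag grid (ns)."""

    residue_id: int
    lags_ns: np.ndarray
    values: np.ndarray
    n_frames: int = 0

    def __post_init__(self) -> None:
        self.lags_ns = np.asarray(self.lags_ns, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.lags_ns) <= 0):
            raise ValueError("lag grid must be strictly increasing")


def nh_correlation(vectors: VectorSeries, max_lag: float = 25.0) -> list[CorrelationFunction]:
    """Time-averaged P2 autocorrelation per residue, lags up to ``max_lag`` ns.

    Uses the identity ``P2(a . b) = (3 (a . b)^2 - 1) / 2`` and the expansion
    of ``(n(t) . n(t+tau))^2`` into autocorrelations of the six unique entries
    of the outer product ``n n^T``, evaluated with FFTs and normalized by the
    exact origin count ``T - tau`` at each lag.
    """
    dt_ns = vectors.frame_interval / 1000.0
    n_frames = vectors.n_frames
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    max_lag_frames = int(round(max_lag / dt_ns))
    if max_lag_frames >= n_frames:
        warnings.warn(
            f"max_lag {max_lag} ns exceeds the trajectory length; truncating",
            stacklevel=2,
        )
        max_lag_frames = n_frames - 1
    v = vectors.vectors  # (T, R, 3)
    # six unique outer-product components with multiplicities 1,1,1,2,2,2
    prods = np.stack(
        [
            v[..., 0] * v[..., 0],
            v[..., 1] * v[..., 1],
            v[..., 2] * v[..., 2],
            v[..., 0] * v[..., 1],
            v[..., 0] * v[..., 2],
            v[..., 1] * v[..., 2],
        ],
        axis=-1,
    )  # (T, R, 6)
    weights = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
    nfft = 1
    while nfft < 2 * n_frames:
        nfft *= 2
    spec = np.fft.rfft(prods, n=nfft, axis=0)
    raw = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=0)[: max_lag_frames + 1]
    counts = (n_frames - np.arange(max_lag_frames + 1)).astype(float)
    acf = np.einsum("trk,k->tr", raw, weights) / counts[:, None]
    c = 1.5 * acf - 0.5  # (lags+1, R)
    lags = np.arange(1, max_lag_frames + 1) * dt_ns
    return [
        CorrelationFunction(
            residue_id=rid, lags_ns=lags, values=c[1:, j], n_frames=n_frames
        )
        for j, rid in enumerate(vectors.residue_ids)
    ]


def brute_force_p2_correlation(vectors: np.ndarray, max_lag_frames: int) -> np.ndarray:
    """Direct double-loop P2 time average for one vector series (oracle-grade).

    ``vectors`` has shape (T, 3); returns C at lags 1..max_lag_frames.
    """
    T = vectors.shape[0]
    out = np.empty(max_lag_frames)
    for lag in range(1, max_lag_frames + 1):
        dots = np.einsum("ti,ti->t", vectors[: T - lag], vectors[lag:])
        out[lag - 1] = np.mean(1.5 * dots**2 - 0.5)
    return out


# ---------------------------------------------------------------------------
# multi-exponential fitting with the chi-square acceptance ladder


def ladder_threshold(n: int) -> float:
    """Acceptance threshold on chi2_{n+1}/chi2_n: (1/2)(1 - n/(n+1))."""
    return 0.5 * (1.0 - n / (n + 1.0))


@dataclass
class MultiExpFit:
    """Accepted multi-exponential fit, time constants sorted descending."""

    residue_id: int
    order: int
    amplitudes: np.ndarray
    amplitude_errors: np.ndarray
    taus_ns: np.ndarray
    tau_errors_ns: np.ndarray
    chi2: float
    chi2_by_order: dict = field(default_factory=dict)
    accepted: bool = True

    @property
    def a_sum(self) -> float:
        return float(np.sum(self.amplitudes))


def _multiexp(x: np.ndarray, *params: float) -> np.ndarray:
    n = len(params) // 2
    amps = np.asarray(params[:n])
    taus = np.asarray(params[n:])
    return np.sum(amps[:, None] * np.exp(-x[None, :] / taus[:, None]), axis=0)


def thin_lag_grid(
    corr: CorrelationFunction,
    dense_until_ns: float = 2.0,
    max_points: int = 400,
) -> CorrelationFunction:
    """Keep every lag up to 2 ns, then logarithmically thin to <= max_points."""
    lags, values = corr.lags_ns, corr.values
    dense = lags <= dense_until_ns
    if lags.size <= max_points or dense.all():
        return corr
    n_tail = max(2, max_points - int(dense.sum()))
    tail_idx = np.unique(
        np.geomspace(int(dense.sum()), lags.size - 1, n_tail).astype(int)
    )
    keep = np.concatenate([np.flatnonzero(dense), tail_idx])
    keep = np.unique(keep)
    return CorrelationFunction(
        residue_id=corr.residue_id,
        lags_ns=lags[keep],
        values=values[keep],
        n_frames=corr.n_frames,
    )


def _fit_single_order(
    x: np.ndarray, y: np.ndarray, order: int, sigma, n_starts: int
) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Best of several multi-start least-squares fits at a fixed order."""
    lo = np.concatenate([np.zeros(order), np.full(order, 1e-3)])
    hi = np.concatenate([np.full(order, 1.2), np.full(order, 1e3)])
    c0 = min(max(y[0], 0.1), 1.0)
    best = None
    span = (x[0], x[-1])
    for s in range(n_starts):
        # log-spaced tau seeds; shift the spread between starts
        lo_t = span[0] * (1.5 ** s)
        hi_t = span[1] / (1.5 ** s)
        if hi_t <= lo_t:
            hi_t = lo_t * 10.0
        taus0 = np.geomspace(lo_t, hi_t, order + 2)[1:-1] if order > 1 else [
            np.sqrt(lo_t * hi_t)
        ]
        p0 = np.concatenate([np.full(order, c0 / order), np.asarray(taus0)])
        p0 = np.clip(p0, lo + 1e-12, hi - 1e-12)
        try:
            popt, pcov = optimize.curve_fit(
                _multiexp, x, y, p0=p0, sigma=sigma, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - _multiexp(x, *popt)
        chi2 = float(np.sum((resid / sigma) ** 2)) if sigma is not None else float(
            np.sum(resid**2)
        )
        if best is None or chi2 < best[2]:
            best = (popt, pcov, chi2)
    if best is None:
        return None
    popt, pcov, chi2 = best
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    return popt, perr, chi2


def multiexp_fit_ladder(
    corr: CorrelationFunction,
    max_order: int = 5,
    error_frac: float = 0.10,
    start_order: int = 1,
    sigma: np.ndarray | None = None,
    n_starts: int = 5,
    thin: bool = True,
) -> MultiExpFit:
    """Fit C(tau) with the smallest adequate number of exponentials.

    Orders are tried from ``start_order`` upward.  Order n + 1 supersedes
    order n only when its chi-square ratio beats :func:`ladder_threshold` (1/4
    for 1 -> 2, 1/6 for 2 -> 3, ...) AND every parameter of the larger fit has
    a relative fitting error (sqrt of the covariance diagonal over |value|)
    at most ``error_frac``.  chi-square is the unweighted sum of squared
    residuals unless ``sigma`` is given.  The amplitude sum is not
    constrained to 1; its deficit is interpreted downstream as an ultrafast
    decay completed before the first lag.
    """
    if thin:
        corr = thin_lag_grid(corr)
    x, y = corr.lags_ns, corr.values
    if x.size < 3 * 2 * max_order:
        max_order = max(start_order, x.size // 6)

    fits: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    chi2_by_order: dict[int, float] = {}
    current = None
    order = start_order
    result = _fit_single_order(x, y, order, sigma, n_starts)
    if result is None:
        raise RuntimeError(
            f"residue {corr.residue_id}: no multi-exponential fit converged "
            f"at order {order} ({x.size} lags, C range "
            f"[{y.min():.3g}, {y.max():.3g}])"
        )
    fits[order] = result
    chi2_by_order[order] = result[2]
    current = order
    while order < max_order:
        nxt = _fit_single_order(x, y, order + 1, sigma, n_starts)
        if nxt is None:
            break
        chi2_by_order[order + 1] = nxt[2]
        popt, perr, chi2 = nxt
        ratio = chi2 / max(fits[current][2], 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(perr) / np.abs(popt)
        errors_ok = bool(np.all(np.isfinite(rel)) and np.all(rel <= error_frac))
        if ratio < ladder_threshold(order) and errors_ok:
            fits[order + 1] = nxt
            current = order + 1
            order += 1
        else:
            break

    popt, perr, chi2 = fits[current]
    n = current
    amps, amp_err = popt[:n], perr[:n]
    taus, tau_err = popt[n:], perr[n:]
    sort = np.argsort(taus)[::-1]  # tau_1 > tau_2 > ...
    return MultiExpFit(
        residue_id=corr.residue_id,
        order=n,
        amplitudes=amps[sort],
        amplitude_errors=amp_err[sort],
        taus_ns=taus[sort],
        tau_errors_ns=tau_err[sort],
        chi2=chi2,
        chi2_by_order=chi2_by_order,
        accepted=True,
    )


# ---------------------------------------------------------------------------
# spectral density and observables


@dataclass
class Corrections:
    """Optional modifications of the fitted correlation model.

    tau_f_ps:
        Ultrafast librational time constant (ps).  When set, a component with
        amplitude ``1 - A_sum`` and this time constant is added, restoring
        C(0) = 1; it must be shorter than the first saved lag.
    tau_s_ns:
        Timescale-rescaling constant (ns).  When set, each fitted tau_i is
        replaced by ``tau_i / (1 + tau_i / tau_s)``, which barely touches
        sub-ns constants but roughly halves a tau comparable to tau_s.
    """

    tau_f_ps: float | None = None
    tau_s_ns: float | None = None

    def __post_init__(self) -> None:
        if self.tau_f_ps is not None and self.tau_f_ps <= 0:
            raise ValueError("tau_f_ps must be positive")
        if self.tau_s_ns is not None and self.tau_s_ns <= 0:
            raise ValueError("tau_s_ns must be positive")

    def effective_taus_ns(self, taus_ns: np.ndarray) -> np.ndarray:
        taus = np.asarray(taus_ns, dtype=float)
        if self.tau_s_ns is not None:
            taus = taus / (1.0 + taus / self.tau_s_ns)
        return taus


@dataclass
class FieldParams:
    """Magnetic-field and interaction constants for 15N relaxation.

    Defaults correspond to an 800 MHz (proton) spectrometer, an NH bond
    length of 1.02 Å and a 15N CSA of -170 ppm.  Gyromagnetic ratios are
    CODATA values with the negative sign of gamma_N retained, so signed
    frequency combinations (e.g. omega_H - omega_N) come out naturally.
    """

    proton_mhz: float = 800.0
    r_nh_A: float = 1.02
    delta_csa_ppm: float = -170.0
    gamma_h: float = 2.6752218744e8  # rad s^-1 T^-1
    gamma_n: float = -2.7126180e7
    mu0: float = 1.25663706212e-6
    hbar: float = 1.054571817e-34

    @property
    def omega_h(self) -> float:
        return 2.0 * np.pi * self.proton_mhz * 1e6

    @property
    def b0(self) -> float:
        return self.omega_h / self.gamma_h

    @property
    def omega_n(self) -> float:
        return self.gamma_n * self.b0

    @property
    def f_dd(self) -> float:
        r = self.r_nh_A * 1e-10
        return 0.1 * (self.mu0 * self.hbar * self.gamma_n * self.gamma_h / (4.0 * np.pi * r**3)) ** 2

    @property
    def f_csa(self) -> float:
        return (2.0 / 15.0) * self.omega_n**2 * (self.delta_csa_ppm * 1e-6) ** 2


def spectral_density(
    fit: MultiExpFit,
    corrections: Corrections | None = None,
    omega: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """J(omega) in seconds from a fitted correlation model.

    ``J(w) = sum_i A_i tau_i / (1 + (w tau_i)^2)`` over the (optionally
    rescaled) fitted terms, plus the ultrafast term when enabled.
    """
    corrections = corrections or Corrections()
    taus_s = corrections.effective_taus_ns(fit.taus_ns) * 1e-9
    amps = fit.amplitudes
    w = np.atleast_1d(np.asarray(omega, dtype=float))
    j = np.sum(
        amps[:, None] * taus_s[:, None] / (1.0 + (taus_s[:, None] * w[None, :]) ** 2),
        axis=0,
    )
    if corrections.tau_f_ps is not None:
        tau_f_s = corrections.tau_f_ps * 1e-12
        j = j + (1.0 - fit.a_sum) * tau_f_s / (1.0 + (w * tau_f_s) ** 2)
    return float(j[0]) if np.ndim(omega) == 0 else j


@dataclass
class RelaxationRecord:
    """Predicted observables for one residue."""

    residue_id: int
    r1: float  # s^-1
    r2: float  # s^-1
    noe: float
    auc_ns: float
    auc_terms_ns: np.ndarray  # per-exponential contributions (+ ultrafast last if enabled)


def relaxation_observables(
    fit: MultiExpFit,
    corrections: Corrections | None = None,
    fieldp: FieldParams | None = None,
) -> RelaxationRecord:
    """R1, R2, NOE and AUC from a fitted correlation model.

    R1 = f_DD [J(wH - wN) + 3 J(wN) + 6 J(wH + wN)] + f_CSA J(wN)
    R2 = R1/2 + f_DD [2 J(0) + 3 J(wH)] + (2/3) f_CSA J(0)
    NOE = 1 + (f_DD gamma_H / (R1 gamma_N)) [6 J(wH + wN) - J(wH - wN)]
    """
    corrections = corrections or Corrections()
    fieldp = fieldp or FieldParams()
    wh, wn = fieldp.omega_h, fieldp.omega_n

    def J(w: float) -> float:
        return float(spectral_density(fit, corrections, w))

    r1 = fieldp.f_dd * (J(wh - wn) + 3.0 * J(wn) + 6.0 * J(wh + wn)) + fieldp.f_csa * J(wn)
    r2 = r1 / 2.0 + fieldp.f_dd * (2.0 * J(0.0) + 3.0 * J(wh)) + (2.0 / 3.0) * fieldp.f_csa * J(0.0)
    if r1 > 0:
        noe = 1.0 + (fieldp.f_dd * fieldp.gamma_h / (r1 * fieldp.gamma_n)) * (
            6.0 * J(wh + wn) - J(wh - wn)
        )
    else:
        noe = np.nan
        logger.warning("residue %s: R1 = 0, NOE undefined", fit.residue_id)

    terms = fit.amplitudes * corrections.effective_taus_ns(fit.taus_ns)
    if corrections.tau_f_ps is not None:
        terms = np.append(terms, (1.0 - fit.a_sum) * corrections.tau_f_ps * 1e-3)
    return RelaxationRecord(
        residue_id=fit.residue_id,
        r1=float(r1),
        r2=float(r2),
        noe=float(noe),
        auc_ns=float(np.sum(terms)),
        auc_terms_ns=terms,
    )


def auc_profile(
    fits: list[MultiExpFit], corrections: Corrections | None = None
) -> pd.DataFrame:
    """Area under C(tau) (= J(0), in ns) per residue with term decomposition."""
    corrections = corrections or Corrections()
    rows = []
    for fit in fits:
        terms = fit.amplitudes * corrections.effective_taus_ns(fit.taus_ns)
        row = {"residue": fit.residue_id, "auc_ns": float(np.sum(terms))}
        for i, term in enumerate(terms, start=1):
            row[f"term{i}_ns"] = float(term)
        if corrections.tau_f_ps is not None:
            uf = (1.0 - fit.a_sum) * corrections.tau_f_ps * 1e-3
            row["ultrafast_ns"] = float(uf)
            row["auc_ns"] += float(uf)
        rows.append(row)
    return pd.DataFrame(rows).set_index("residue")


# ---------------------------------------------------------------------------
# comparison with experiment


@dataclass
class ProfileComparison:
    """RMSE and bootstrap confidence intervals for one observable."""

    rmse: float
    table: pd.DataFrame  # residue-indexed: predicted, experimental, ci_low, ci_high
    mean_a: float
    mean_b: float
    n_replicates: int


def compare_profiles(
    predicted: pd.DataFrame,
    experimental: pd.Series,
    exclude_terminal: int = 1,
    n_boot: int = 1000,
    seed: int = 0,
    range_a: tuple[int, int] = (5, 32),
    range_b: tuple[int, int] = (33, 60),
) -> ProfileComparison:
    """RMSE of replicate-averaged predictions against experiment.

    ``predicted`` is residue-indexed with one column per replicate;
    ``experimental`` is a residue-indexed Series.  The first and last
    ``exclude_terminal`` residues of the predicted sequence span are excluded
    from the RMSE.  The 95% CI per residue comes from resampling replicates
    with replacement.
    """
    pred_mean = predicted.mean(axis=1)
    common = predicted.index.intersection(experimental.dropna().index)
    lo = predicted.index.min() + exclude_terminal
    hi = predicted.index.max() - exclude_terminal
    scored = [r for r in common if lo <= r <= hi]
    if not scored:
        raise ValueError("no residues left after terminal exclusion")
    diff = pred_mean.loc[scored] - experimental.loc[scored]
    rmse = float(np.sqrt(np.mean(diff.to_numpy() ** 2)))

    n_rep = predicted.shape[1]
    if n_rep >= 2:
        rng = np.random.default_rng(seed)
        draws = np.empty((n_boot, len(predicted.index)))
        values = predicted.to_numpy()
        for b in range(n_boot):
            cols = rng.integers(0, n_rep, size=n_rep)
            draws[b] = values[:, cols].mean(axis=1)
        ci_low = np.percentile(draws, 2.5, axis=0)
        ci_high = np.percentile(draws, 97.5, axis=0)
    else:
        warnings.warn("fewer than 2 replicates: point estimate only", stacklevel=2)
        ci_low = ci_high = predicted.to_numpy()[:, 0]

    table = pd.DataFrame(
        {
            "predicted": pred_mean,
            "experimental": experimental.reindex(predicted.index),
            "ci_low": ci_low,
            "ci_high": ci_high,
        },
        index=predicted.index,
    )
    in_a = (pred_mean.index >= range_a[0]) & (pred_mean.index <= range_a[1])
    in_b = (pred_mean.index >= range_b[0]) & (pred_mean.index <= range_b[1])
    return ProfileComparison(
        rmse=rmse,
        table=table,
        mean_a=float(pred_mean[in_a].mean()),
        mean_b=float(pred_mean[in_b].mean()),
        n_replicates=n_rep,
    )
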