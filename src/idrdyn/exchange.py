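"""Amide proton exchange: CLEANEX-PM rate fitting and protection factors.

In a CLEANEX-PM experiment the ratio of the cross-peak intensity after a
spin-lock (mixing) time ``t`` to a reference intensity follows the two-rate
magnetization-transfer solution

    V/V0 = k_ex / (R1a + k_ex - R1w) * [exp(-R1w t) - exp(-(R1a + k_ex) t)],

where ``k_ex`` is the water-to-amide exchange rate, ``R1w`` the water proton
longitudinal relaxation rate and ``R1a`` the apparent relaxation rate of the
amide proton during the spin lock (all s^-1).  Fitting this buildup per
residue yields ``k_ex``; dividing the sequence-predicted intrinsic rate
``k_intrinsic`` (an input table, e.g. from the SPHERE server) by ``k_ex``
gives the protection factor PF, with PF > 1 indicating shielding of the
backbone amide by transient structure or interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "cleanex_ratio",
    "fit_cleanex_kex",
    "protection_factor_profile",
    "CleanexFit",
    "ExchangeProfile",
]


def cleanex_ratio(t_s, k_ex: float, r1_apparent: float, r1_water: float) -> np.ndarray:
    """CLEANEX-PM buildup ratio at mixing times ``t_s`` (seconds)."""
    t = np.asarray(t_s, dtype=float)
    if k_ex == 0:
        return np.zeros_like(t)
    denom = r1_apparent + k_ex - r1_water
    if abs(denom) < 1e-12:
        # degenerate rates: limit of the two-exponential solution
        return k_ex * t * np.exp(-r1_water * t)
    return k_ex / denom * (np.exp(-r1_water * t) - np.exp(-(r1_apparent + k_ex) * t))


@dataclass
class CleanexFit:
    """Fitted exchange rate for one residue."""

    k_ex: float  # s^-1
    k_ex_err: float
    r1_apparent: float
    r1_apparent_err: float
    converged: bool


def fit_cleanex_kex(
    mixing_times_ms,
    ratios,
    r1_water: float = 0.6,
    k_ex_guess: float = 10.0,
    r1a_guess: float = 5.0,
) -> CleanexFit:
    """Least-squares fit of the CLEANEX buildup for one residue.

    ``k_ex`` and the apparent relaxation rate are fitted jointly; the water
    rate ``r1_water`` is held fixed (it is common to all residues).  Requires
    at least 4 mixing times.  Returns a flagged zero-rate result when the
    intensities carry no buildup or the fit fails to converge.
    """
    t_s = np.asarray(mixing_times_ms, dtype=float) / 1000.0
    y = np.asarray(ratios, dtype=float)
    if t_s.size < 4:
        raise ValueError("need at least 4 mixing times")
    if np.all(np.abs(y) < 1e-12):
        return CleanexFit(k_ex=0.0, k_ex_err=np.nan, r1_apparent=np.nan,
                          r1_apparent_err=np.nan, converged=False)
    try:
        popt, pcov = optimize.curve_fit(
            lambda t, kex, r1a: cleanex_ratio(t, kex, r1a, r1_water),
            t_s,
            y,
            p0=(k_ex_guess, r1a_guess),
            bounds=((0.0, 0.0), (np.inf, np.inf)),
            maxfev=20000,
        )
    except RuntimeError:
        logger.warning("CLEANEX fit did not converge; residue flagged missing")
        return CleanexFit(k_ex=np.nan, k_ex_err=np.nan, r1_apparent=np.nan,
                          r1_apparent_err=np.nan, converged=False)
    perr = np.sqrt(np.diag(pcov))
    return CleanexFit(
        k_ex=float(popt[0]),
        k_ex_err=float(perr[0]),
        r1_apparent=float(popt[1]),
        r1_apparent_err=float(perr[1]),
        converged=True,
    )


@dataclass
class ExchangeProfile:
    """Per-residue exchange rates and protection factors with half-means."""

    table: pd.DataFrame  # residue-indexed: k_ex, k_ex_err, k_intrinsic, pf
    mean_pf_a: float
    mean_pf_b: float
    welch: object  # WelchResult from size_stats
    range_a: tuple[int, int]
    range_b: tuple[int, int]


def protection_factor_profile(
    k_ex: pd.Series,
    k_intrinsic: pd.Series,
    k_ex_err: pd.Series | None = None,
    range_a: tuple[int, int] = (5, 32),
    range_b: tuple[int, int] = (33, 60),
) -> ExchangeProfile:
    """Protection factors PF = k_intrinsic / k_ex plus N-/C-half comparison.

    Both inputs are residue-indexed Series (s^-1); residues present in only
    one table, or with zero/NaN ``k_ex``, yield missing PF and are logged.
    """
    from idrdyn.size_stats import welch_half_comparison

    common = k_ex.index.intersection(k_intrinsic.index)
    dropped = k_ex.index.symmetric_difference(k_intrinsic.index)
    if len(dropped):
        logger.info("residues present in only one table skipped: %s", list(dropped))
    kx = k_ex.loc[common].astype(float)
    ki = k_intrinsic.loc[common].astype(float)
    pf = ki / kx.replace(0.0, np.nan)
    bad = pf.index[pf.isna()]
    if len(bad):
        logger.warning("protection factor undefined (zero/NaN k_ex) at residues %s", list(bad))
    table = pd.DataFrame({"k_ex": kx, "k_intrinsic": ki, "pf": pf})
    if k_ex_err is not None:
        table["k_ex_err"] = k_ex_err.reindex(common)
    welch = welch_half_comparison(pf, range_a=range_a, range_b=range_b)
    return ExchangeProfile(
        table=table,
        mean_pf_a=welch.mean_a,
        mean_pf_b=welch.mean_b,
        welch=welch,
        range_a=tuple(range_a),
        range_b=tuple(range_b),
    )
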