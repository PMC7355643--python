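"""SAXS- and sequence-derived size metrics plus half-vs-half statistics.

For a disordered chain the low-q part of a SAXS profile is well described by
the Debye form factor of a Gaussian chain,

    I(q) = I0 * 2 (e^{-x} + x - 1) / x^2,     x = (q Rg)^2,

which yields the radius of gyration by least squares.  The module also
provides the empirical IDP scaling relation Rg = 2.54 N^0.522 (Å), the Kratky
transform q^2 I(q), and the Welch t-test used to compare per-residue profiles
between the N- and C-terminal halves of a sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SAXSProfile",
    "DebyeFit",
    "debye_intensity",
    "debye_rg_fit",
    "kratky_transform",
    "rg_scaling_prediction",
    "welch_half_comparison",
    "read_saxs_profile",
]


@dataclass
class SAXSProfile:
    """1-D scattering profile: q (Å^-1), I(q) (a.u.), optional sigma."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be matching 1-D arrays")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be positive and strictly increasing")


@dataclass
class DebyeFit:
    """Debye-approximation fit result."""

    rg: float  # Å
    rg_err: float
    i0: float
    i0_err: float
    q_max: float
    n_points: int


def read_saxs_profile(path: str) -> SAXSProfile:
    """Read a 2- or 3-column delimited text profile (q, I[, sigma])."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected at least two columns (q, I)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SAXSProfile(q=data[:, 0], intensity=data[:, 1], sigma=sigma)


def debye_intensity(q, rg: float, i0: float = 1.0) -> np.ndarray:
    """Debye form factor of a Gaussian chain, stable for small (q Rg)^2."""
    x = (np.asarray(q, dtype=float) * rg) ** 2
    small = x < 1e-6
    safe = np.where(small, 1.0, x)
    out = 2.0 * (np.expm1(-safe) + safe) / safe**2
    return i0 * np.where(small, 1.0 - x / 3.0, out)


def debye_rg_fit(profile: SAXSProfile, q_max: float = 0.15) -> DebyeFit:
    """Fit I0 and Rg of the Debye form to the profile for q <= q_max.

    Weighted by the experimental sigma when available.  Initial Rg comes from
    a Guinier estimate on the lowest-q points.
    """
    mask = profile.q <= q_max
    if mask.sum() < 5:
        raise ValueError(f"need at least 5 points with q <= {q_max}")
    q = profile.q[mask]
    intensity = profile.intensity[mask]
    sigma = profile.sigma[mask] if profile.sigma is not None else None

    i0_guess = float(intensity[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = intensity[-1] / i0_guess
    rg_guess = 10.0
    if 0 < ratio < 1:
        rg_guess = float(np.sqrt(3.0 * -np.log(ratio)) / q[-1])

    try:
        popt, pcov = optimize.curve_fit(
            lambda qq, rg, i0: debye_intensity(qq, rg, i0),
            q,
            intensity,
            p0=(rg_guess, i0_guess),
            sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=((1e-3, 0.0), (np.inf, np.inf)),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Debye fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    return DebyeFit(
        rg=float(popt[0]),
        rg_err=float(perr[0]),
        i0=float(popt[1]),
        i0_err=float(perr[1]),
        q_max=q_max,
        n_points=int(mask.sum()),
    )


def kratky_transform(profile: SAXSProfile) -> pd.DataFrame:
    """Kratky representation (q, q^2 I(q)); rising/plateauing for IDPs."""
    return pd.DataFrame({"q": profile.q, "q2I": profile.q**2 * profile.intensity})


def rg_scaling_prediction(n_residues: int) -> float:
    """Empirical IDP scaling relation Rg = 2.54 N^0.522 (Å)."""
    if n_residues < 1:
        raise ValueError("N must be at least 1")
    return 2.54 * float(n_residues) ** 0.522


@dataclass
class WelchResult:
    """Welch two-sample comparison between two residue ranges."""

    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t: float
    p: float
    range_a: tuple[int, int]
    range_b: tuple[int, int]


def welch_half_comparison(
    values: pd.Series,
    range_a: tuple[int, int] = (5, 32),
    range_b: tuple[int, int] = (33, 60),
) -> WelchResult:
    """Welch's unequal-variance t-test between two residue ranges.

    ``values`` is indexed by residue number; missing residues (prolines,
    unassigned peaks) are simply absent.  Ranges are inclusive.
    """
    values = values.dropna()
    a = values[(values.index >= range_a[0]) & (values.index <= range_a[1])]
    b = values[(values.index >= range_b[0]) & (values.index <= range_b[1])]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each range needs at least 2 values")
    t, p = stats.ttest_ind(a.to_numpy(), b.to_numpy(), equal_var=False)
    return WelchResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=len(a),
        n_b=len(b),
        t=float(t),
        p=float(p),
        range_a=tuple(range_a),
        range_b=tuple(range_b),
    )
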