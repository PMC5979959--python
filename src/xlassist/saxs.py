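"""Small-angle X-ray scattering analysis for oligomer sizing.

The chain implemented here is the standard solution-SAXS workflow for a
folded particle of unknown size:

* Guinier fit of the low-angle region, ``I(q) = I(0) exp(-q^2 Rg^2 / 3)``
  (valid for q*Rg below ~1.3), giving the radius of gyration Rg and forward
  scattering I(0);
* dimensionless Kratky transform ``(q Rg)^2 I/I(0)`` vs ``q Rg``, whose peak
  near (sqrt(3), 1.1) diagnoses a compact fold;
* pair-distance distribution P(r) by regularized indirect transform, giving
  the maximum particle dimension Dmax and a real-space Rg;
* Porod invariant ``Q = integral q^2 [I(q) - background] dq`` with Guinier
  head and q^-4 tail extrapolation, giving the particle volume
  ``Vp = 2 pi^2 I(0) / Q``;
* the empirical volume-to-mass conversions MWp = Vp[nm^3]/1.6 kDa and
  MWa = Va[nm^3]/2 kDa, and subunit counts from a known monomer mass.

q units are declared on the curve (``nm^-1`` or ``A^-1``); lengths and
volumes come out in the matching unit.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.integrate
import scipy.interpolate
import scipy.optimize

__all__ = [
    "SAXSCurve",
    "GuinierResult",
    "KratkyResult",
    "PorodResult",
    "PrResult",
    "SizeEstimate",
    "read_dat",
    "write_dat",
    "guinier_fit",
    "kratky_dimensionless",
    "porod_volume",
    "pr_estimate",
    "mass_from_porod",
    "mass_from_excluded_volume",
    "subunit_count",
    "size_estimate",
]

_UNIT_FACTORS = {"nm^-1": 1.0, "A^-1": 10.0}  # to nm^-1


@dataclass
class SAXSCurve:
    """1-D scattering curve: q grid, intensity, optional uncertainty."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    q_unit: str = "nm^-1"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma shape mismatch")
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensities")
        if self.q_unit not in _UNIT_FACTORS:
            raise ValueError(f"q_unit must be one of {sorted(_UNIT_FACTORS)}")

    def in_unit(self, unit: str) -> "SAXSCurve":
        """Curve converted to another q unit (1 A^-1 = 10 nm^-1)."""
        f = _UNIT_FACTORS[self.q_unit] / _UNIT_FACTORS[unit]
        if f == 1.0:
            return self
        return SAXSCurve(self.q * f, self.intensity.copy(),
                         None if self.sigma is None else self.sigma.copy(), unit)


def read_dat(text: str) -> SAXSCurve:
    """Read a 3-column (q, I, sigma) or 2-column whitespace text curve.

    ``#`` lines are comments; a comment containing ``q_unit=nm^-1`` or
    ``q_unit=A^-1`` declares the q unit (default nm^-1).
    """
    unit = "nm^-1"
    for line in text.splitlines():
        if line.lstrip().startswith("#") and "q_unit=" in line:
            unit = line.split("q_unit=")[1].split()[0].strip()
    data = np.loadtxt(io.StringIO(text), comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError("need at least q and I columns")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SAXSCurve(data[:, 0], data[:, 1], sigma, unit)


def write_dat(curve: SAXSCurve) -> str:
    buf = io.StringIO()
    buf.write(f"# q I sigma  q_unit={curve.q_unit}\n")
    sig = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
    for q, i, s in zip(curve.q, curve.intensity, sig):
        buf.write(f"{q:.8e} {i:.8e} {s:.8e}\n")
    return buf.getvalue()


@dataclass
class GuinierResult:
    rg: float                    # in 1/q_unit lengths (nm for nm^-1)
    i0: float
    q_window: tuple[float, float]
    n_points: int
    qmax_rg: float
    aggregation_flag: bool
    rms_residual: float
    q_unit: str = "nm^-1"


def guinier_fit(curve: SAXSCurve, q_rg_limit: float = 1.3,
                min_points: int = 10) -> GuinierResult:
    """Guinier fit on the largest low-q window with q*Rg within the limit.

    The window is grown from the lowest usable q; leading points whose
    studentized residuals exceed 2.5 are dropped (a positive leading excess -
    a steep rise in a non-linear Guinier region - raises the aggregation
    flag) and the upper edge is iterated until qmax*Rg <= limit is
    self-consistent.  Deterministic.
    """
    pos = curve.intensity > 0
    q = curve.q[pos]
    lnI = np.log(curve.intensity[pos])
    if len(q) < min_points:
        raise ValueError(f"need at least {min_points} positive low-q points")
    q2 = q * q

    def fit(i0_idx: int, i1_idx: int) -> tuple[float, float, np.ndarray]:
        x, y = q2[i0_idx:i1_idx], lnI[i0_idx:i1_idx]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        return slope, intercept, resid

    start = 0
    aggregation = False
    for _ in range(200):
        end = len(q)
        slope, intercept, resid = fit(start, end)
        # iterate upper edge to self-consistency with the Rg estimate
        for _ in range(100):
            if slope >= 0:
                break
            rg = math.sqrt(-3.0 * slope)
            new_end = int(np.searchsorted(q, q_rg_limit / rg, side="right"))
            new_end = max(new_end, start + min_points)
            new_end = min(new_end, len(q))
            if new_end == end:
                break
            end = new_end
            slope, intercept, resid = fit(start, end)
        if slope >= 0:
            raise ValueError(
                "Guinier fit failed: non-negative slope (no decaying low-q region)"
            )
        sd = resid.std(ddof=2) if len(resid) > 2 else 0.0
        if sd > 0 and abs(resid[0]) > 2.5 * sd and end - start > min_points:
            if resid[0] > 0:
                aggregation = True  # steep low-q rise above the Guinier line
            start += 1
            continue
        break
    # curvature correction: the Guinier law is the q->0 limit, so a smooth
    # particle contributes a small negative q^4 term over the fit window that
    # biases the straight-line slope.  When that curvature is statistically
    # resolved (|c2| > 2 SE), remove its leverage on the slope; noise-level
    # curvature is left untouched.
    x, y = q2[start:end], lnI[start:end]
    if len(x) > 4:
        X = np.vander(x, 3)  # columns x^2, x, 1
        coef, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
        dof = len(x) - 3
        if dof > 0 and len(res_ss):
            sigma2 = float(res_ss[0]) / dof
            cov = sigma2 * np.linalg.inv(X.T @ X)
            c2 = coef[0]
            # the de-leveraged straight-line slope is exactly the quadratic
            # fit's linear coefficient; likewise the intercept at q^2 = 0
            if abs(c2) > 2.0 * math.sqrt(cov[0, 0]) and coef[1] < 0:
                slope = float(coef[1])
                intercept = float(coef[2])
    rg = math.sqrt(-3.0 * slope)
    return GuinierResult(
        rg=rg,
        i0=float(np.exp(intercept)),
        q_window=(float(q[start]), float(q[end - 1])),
        n_points=end - start,
        qmax_rg=float(q[end - 1] * rg),
        aggregation_flag=aggregation,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        q_unit=curve.q_unit,
    )


@dataclass
class KratkyResult:
    x: np.ndarray      # q * Rg
    y: np.ndarray      # (q Rg)^2 I / I0
    peak_x: float
    peak_y: float


def kratky_dimensionless(curve: SAXSCurve, g: GuinierResult,
                         x_max: float = 8.0) -> KratkyResult:
    """Dimensionless Kratky transform with spline-refined peak location.

    A compact globular particle peaks at (sqrt(3), 3/e ~ 1.104); flexible
    chains plateau without returning to the baseline.
    """
    if g.i0 <= 0:
        raise ValueError("non-positive I(0)")
    x = curve.q * g.rg
    y = x * x * curve.intensity / g.i0
    keep = x <= x_max
    xs, ys = x[keep], y[keep]
    if len(xs) < 4:
        raise ValueError("too few points below x_max")
    spline = scipy.interpolate.CubicSpline(xs, ys)
    dense = np.linspace(xs[0], xs[-1], 4096)
    i = int(np.argmax(spline(dense)))
    lo = dense[max(i - 2, 0)]
    hi = dense[min(i + 2, len(dense) - 1)]
    res = scipy.optimize.minimize_scalar(lambda t: -spline(t), bounds=(lo, hi),
                                         method="bounded",
                                         options={"xatol": 1e-12})
    return KratkyResult(x, y, float(res.x), float(spline(res.x)))


@dataclass
class PorodResult:
    invariant: float       # Q, in I-units * q_unit^3
    vp: float              # particle volume in (1/q_unit)^3
    background: float
    tail_constant: float   # Porod constant K with I ~ K q^-4
    q_unit: str = "nm^-1"


def porod_volume(curve: SAXSCurve, g: GuinierResult,
                 background: "float | str" = 0.0,
                 tail_fraction: float = 0.15) -> PorodResult:
    """Porod invariant and volume with head and tail extrapolation.

    The measured range is integrated directly; below the first data point
    the Guinier form is used, and beyond the last point an ideal q^-4 tail
    with a Porod constant averaged over the high-q window.  The default
    assumes buffer-subtracted data (zero flat background); pass
    ``background="auto"`` to estimate a residual constant from an
    ``I = B + K q^-4`` fit on the tail window, or a number to subtract it
    directly.
    """
    q, I = curve.q, curve.intensity
    if q[-1] * g.rg < 3:
        raise ValueError("curve does not extend far enough beyond the Guinier region")
    # tail window: well past the Guinier region but wide enough to average
    # over form-factor oscillations (at least the top 40% of the q range)
    q_tail_start = min(4.0 / g.rg, q[0] + 0.6 * (q[-1] - q[0]))
    i_tail = int(np.searchsorted(q, q_tail_start))
    i_tail = min(i_tail, len(q) - max(int(len(q) * tail_fraction), 8))
    qt, It = q[i_tail:], I[i_tail:]
    if background == "auto":
        A = np.vstack([np.ones_like(qt), qt**-4]).T
        b_est, _k = np.linalg.lstsq(A, It, rcond=None)[0]
        if b_est < 0 and -b_est > It.mean():
            raise ValueError("background estimate negative and larger than tail intensity")
        background = float(b_est)
    background = float(background)
    Isub = I - background
    # Porod constant from the cumulative invariant: for I ~ K q^-4 the
    # running integral of q^2 I behaves as C - K/q, so regressing it on -1/q
    # averages out form-factor oscillations that bias a plain q^4 I mean
    F = scipy.integrate.cumulative_trapezoid(qt * qt * (It - background), qt, initial=0.0)
    k_tail = float(np.polyfit(-1.0 / qt, F, 1)[0])
    if k_tail < 0:
        k_tail = 0.0
    q_mid = scipy.integrate.trapezoid(q * q * Isub, q)
    q_head_grid = np.linspace(0, q[0], 256)
    q_head = scipy.integrate.trapezoid(
        q_head_grid**2 * g.i0 * np.exp(-(q_head_grid * g.rg) ** 2 / 3.0), q_head_grid
    )
    q_tail = k_tail / q[-1]
    Q = q_mid + q_head + q_tail
    if Q <= 0:
        raise ValueError("non-positive Porod invariant")
    vp = 2.0 * math.pi**2 * g.i0 / Q
    return PorodResult(float(Q), float(vp), background, k_tail, curve.q_unit)


@dataclass
class PrResult:
    r: np.ndarray
    pr: np.ndarray
    dmax: float
    rg: float
    i0: float
    chi2: float
    alpha: float
    dmax_scores: "pd_frame_like" = None  # per-trial diagnostics (list of dicts)


def _pr_design(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    qr = np.outer(q, r)
    sinc = np.ones_like(qr)
    nz = qr != 0
    sinc[nz] = np.sin(qr[nz]) / qr[nz]
    return 4.0 * math.pi * sinc

def _solve_pr(q, I, w, dmax, n_r, alphas):
    """Non-negative regularized P(r) for one trial Dmax; returns best by L-curve."""
    r_full = np.linspace(0.0, dmax, n_r)
    r = r_full[1:-1]                      # P(0) = P(Dmax) = 0 built in
    dr = r_full[1] - r_full[0]
    A = _pr_design(q, r) * dr
    L = (np.diag(np.full(len(r), -2.0))
         + np.diag(np.ones(len(r) - 1), 1)
         + np.diag(np.ones(len(r) - 1), -1))
    Aw = A * w[:, None]
    yw = I * w
    scale = np.linalg.norm(Aw) / np.linalg.norm(L)
    sols = []
    for alpha in alphas:
        M = np.vstack([Aw, math.sqrt(alpha) * scale * L])
        rhs = np.concatenate([yw, np.zeros(len(r))])
        p, _ = scipy.optimize.nnls(M, rhs)
        chi2 = float(np.mean((Aw @ p - yw) ** 2))
        rough = float(np.sum((L @ p) ** 2))
        sols.append((alpha, p, chi2, rough))
    chi2_min = min(s[2] for s in sols)
    # largest regularization whose misfit stays within 10% of the best
    for alpha, p, chi2, rough in reversed(sols):
        if chi2 <= 1.10 * chi2_min + 1e-300:
            return r_full, np.concatenate([[0.0], p, [0.0]]), chi2, alpha
    alpha, p, chi2, rough = sols[0]
    return r_full, np.concatenate([[0.0], p, [0.0]]), chi2, alpha


def pr_estimate(curve: SAXSCurve, dmax_grid: Sequence[float],
                n_r: int = 101,
                alphas: Sequence[float] = tuple(np.logspace(-6, 2, 9)),
                chi2_slack: float = 2.0) -> PrResult:
    """P(r) by regularized, non-negative sine-kernel inversion with Dmax scan.

    Each trial Dmax is solved with non-negativity (so P(r) >= 0 always holds)
    and a smoothness penalty whose weight comes from a fixed L-curve-style
    grid.  Dmax is the smallest trial whose misfit is within ``chi2_slack``
    of the best over the scan and whose P(r) decays smoothly into the
    endpoint (the solution is not truncated).  Deterministic and seedless.
    """
    dmax_grid = sorted(dmax_grid)
    q, I = curve.q, curve.intensity
    if not np.any(I > 0):
        raise ValueError("all-zero or non-positive intensity")
    if np.max(np.diff(q)) > math.pi / max(dmax_grid):
        raise ValueError("q sampling too coarse for the requested Dmax range")
    sigma = curve.sigma if curve.sigma is not None else np.maximum(0.01 * np.abs(I), 1e-12)
    sigma = np.where(sigma > 0, sigma, np.max(sigma[sigma > 0]) if np.any(sigma > 0) else 1.0)
    w = 1.0 / sigma
    trials = []
    for d in dmax_grid:
        r, p, chi2, alpha = _solve_pr(q, I, w, d, n_r, alphas)
        pk = p.max()
        tail = float(np.mean(p[-max(n_r // 20, 2) - 1:-1])) / pk if pk > 0 else 0.0
        trials.append({"dmax": d, "chi2": chi2, "alpha": alpha, "tail": tail,
                       "r": r, "p": p})
    chi2_best = min(t["chi2"] for t in trials)
    chosen = None
    for t in trials:
        if t["chi2"] <= chi2_slack * chi2_best and t["tail"] <= 0.05:
            chosen = t
            break
    if chosen is None:  # fall back to pure misfit if no smooth-endpoint trial
        chosen = min(trials, key=lambda t: t["chi2"])
    r, p = chosen["r"], chosen["p"]
    norm = scipy.integrate.trapezoid(p, r)
    if norm <= 0:
        raise ValueError("degenerate P(r) solution")
    rg = math.sqrt(scipy.integrate.trapezoid(r * r * p, r) / (2.0 * norm))
    i0 = float(scipy.integrate.trapezoid(p, r) * 4.0 * math.pi)
    scores = [{k: t[k] for k in ("dmax", "chi2", "alpha", "tail")} for t in trials]
    return PrResult(r, p, float(chosen["dmax"]), rg, i0, chosen["chi2"],
                    chosen["alpha"], scores)


def mass_from_porod(vp_nm3: float) -> float:
    """Particle mass in kDa from the Porod volume in nm^3 (empirical /1.6)."""
    if vp_nm3 <= 0:
        raise ValueError("volume must be positive")
    return vp_nm3 / 1.6


def mass_from_excluded_volume(va_nm3: float) -> float:
    """Particle mass in kDa from an ab-initio model excluded volume in nm^3 (/2)."""
    if va_nm3 <= 0:
        raise ValueError("volume must be positive")
    return va_nm3 / 2.0


def subunit_count(mw_kda: float, monomer_kda: float = 26.9) -> int:
    """Nearest-integer subunit count, ties away from zero."""
    if mw_kda <= 0 or monomer_kda <= 0:
        raise ValueError("masses must be positive")
    return int(math.floor(mw_kda / monomer_kda + 0.5))


@dataclass
class SizeEstimate:
    """Volume -> mass -> subunit-count chain for one oligomer population."""

    vp_nm3: float
    mwp_kda: float
    subunits: int
    monomer_kda: float = 26.9
    va_nm3: Optional[float] = None
    mwa_kda: Optional[float] = None


def size_estimate(vp_nm3: float, monomer_kda: float = 26.9,
                  va_nm3: Optional[float] = None) -> SizeEstimate:
    """Full sizing chain from a Porod volume (and optional excluded volume).

    Masses are reported rounded to the nearest kDa, as conventional for this
    empirical calibration; the subunit count divides the rounded Porod mass
    by the monomer mass.
    """
    mwp = mass_from_porod(vp_nm3)
    mwp_rounded = float(math.floor(mwp + 0.5))
    mwa = None
    if va_nm3 is not None:
        mwa = float(math.floor(mass_from_excluded_volume(va_nm3) + 0.5))
    return SizeEstimate(
        vp_nm3=vp_nm3,
        mwp_kda=mwp_rounded,
        subunits=subunit_count(mwp_rounded, monomer_kda),
        monomer_kda=monomer_kda,
        va_nm3=va_nm3,
        mwa_kda=mwa,
    )
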