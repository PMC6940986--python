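"""Primary curve analysis: Guinier fit, indirect Fourier transform P(r),
Porod invariant/volume/exponent with molecular-mass estimates, dimensionless
Kratky representation, and oligomeric-state inference.

Conventions
-----------
P(r) = gamma(r) * r^2 with I(q) = 4 pi int_0^Dmax P(r) sin(qr)/(qr) dr, so
I(0) = 4 pi int P dr and Rg^2 = int r^2 P dr / (2 int P dr). q is 1/A,
lengths are A, Porod volumes are reported in nm^3 (1 nm^3 = 1000 A^3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, nnls

from .config import DEFAULT_CONFIG, Config
from .curves import ScatteringCurve, SequenceMassResult

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Guinier
# --------------------------------------------------------------------------

@dataclass
class GuinierResult:
    Rg: float
    Rg_err: float
    I0: float
    window: tuple[float, float]      # q interval used
    sRg_low: float                   # q_min * Rg
    sRg_high: float                  # q_max * Rg
    r_squared: float


def _wlinfit(x, y, w):
    """Weighted linear fit; returns slope, intercept, var(slope), R^2."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    sxy = np.sum(w * (x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    dof = max(len(x) - 2, 1)
    s2 = np.sum(w * resid ** 2) / dof
    var_slope = s2 / sxx
    ss_tot = np.sum(w * (y - ym) ** 2)
    r2 = 1.0 - np.sum(w * resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, var_slope, r2


def guinier_fit(curve: ScatteringCurve,
                window: tuple[float, float] | None = None,
                config: Config = DEFAULT_CONFIG) -> GuinierResult:
    """Weighted linear fit of ln I vs q^2 over the Guinier region.

    The window is auto-selected as the largest contiguous run of points with
    q*Rg in [srg_min, srg_max] (defaults 0.3-1.3), iterating the Rg estimate
    to self-consistency from a seed fit on the first 10 points. An explicit
    ``window`` (q interval) overrides the auto-selection.
    """
    g = config["guinier"]
    pos = curve.I > 0
    if pos.sum() < 3:
        raise ValueError("no Guinier region: too few positive intensities")
    q, I, s = curve.q[pos], curve.I[pos], curve.sigma[pos]
    lnI = np.log(I)
    w = (I / s) ** 2  # propagated weights for ln I

    def fit_mask(m):
        if m.sum() < 3:
            raise ValueError("no Guinier region: window has <3 points")
        slope, icpt, var_s, r2 = _wlinfit(q[m] ** 2, lnI[m], w[m])
        if slope >= 0:
            raise ValueError("no Guinier region: non-negative slope")
        Rg = float(np.sqrt(-3.0 * slope))
        Rg_err = float(3.0 * np.sqrt(var_s) / (2.0 * Rg))
        return Rg, Rg_err, float(np.exp(icpt)), r2, (float(q[m].min()), float(q[m].max()))

    if window is not None:
        m = (q >= window[0]) & (q <= window[1])
        Rg, Rg_err, I0, r2, win = fit_mask(m)
    else:
        seed = np.zeros(len(q), bool)
        seed[: min(10, len(q))] = True
        Rg, Rg_err, I0, r2, win = fit_mask(seed)
        for _ in range(int(g["max_iter"])):
            m = (q * Rg >= g["srg_min"]) & (q * Rg <= g["srg_max"])
            if m.sum() < 3:
                m = q * Rg <= g["srg_max"]
            new = fit_mask(m)
            converged = abs(new[0] - Rg) < 1e-4 * Rg
            Rg, Rg_err, I0, r2, win = new
            if converged:
                break
        # shrink the window top while significant curvature of ln I in q^2
        # remains: compact non-Gaussian shapes (e.g. spheres) bias the slope
        # near the q*Rg = 1.3 limit
        cap = g["srg_max"]
        while cap > 0.6:
            m = (q * Rg >= g["srg_min"]) & (q * Rg <= cap)
            if m.sum() < 5:
                break
            u = q[m] ** 2
            coef, cov = np.polyfit(u, lnI[m], 2, w=np.sqrt(w[m]), cov=True)
            c2, c1 = coef[0], coef[1]
            curved = (abs(c2) * u.max() > 0.01 * abs(c1)
                      and abs(c2) > 2.0 * np.sqrt(max(cov[0, 0], 0.0)))
            if not curved:
                break
            cap -= 0.1
            Rg, Rg_err, I0, r2, win = fit_mask(m)
        m = (q * Rg >= g["srg_min"]) & (q * Rg <= cap)
        if m.sum() >= 3:
            Rg, Rg_err, I0, r2, win = fit_mask(m)
    return GuinierResult(Rg=Rg, Rg_err=Rg_err, I0=I0, window=win,
                         sRg_low=win[0] * Rg, sRg_high=win[1] * Rg,
                         r_squared=float(r2))


# --------------------------------------------------------------------------
# P(r) by indirect Fourier transform
# --------------------------------------------------------------------------

@dataclass
class PairDistribution:
    r: np.ndarray
    P: np.ndarray
    Dmax: float
    Rg_pr: float
    I0_pr: float
    alpha: float
    quality: float           # reconstruction chi2 against the input curve
    roughness: float = 0.0   # normalized squared second differences
    neg_mass: float = 0.0    # negativity fraction of the unconstrained solve


def _ift_system(q, r, sigma):
    """Design matrix of I(q) = 4 pi int P(r) sinc(qr) dr (trapezoid weights),
    weighted rows (1/sigma), plus the interior second-difference operator."""
    dr = r[1] - r[0]
    wtrap = np.full(len(r), dr)
    wtrap[0] = wtrap[-1] = dr / 2.0
    qr = np.outer(q, r)
    A = 4.0 * np.pi * np.sinc(qr / np.pi) * wtrap[None, :]
    # endpoints P(0)=P(Dmax)=0: solve for interior values only
    A = A[:, 1:-1]
    Aw = A / sigma[:, None]
    n_in = len(r) - 2
    L = np.zeros((n_in, n_in))
    for j in range(n_in):
        L[j, j] = -2.0
        if j > 0:
            L[j, j - 1] = 1.0
        if j < n_in - 1:
            L[j, j + 1] = 1.0
    return Aw, L


def _solve_pr(Aw, L, bw, alpha):
    scale = np.linalg.norm(Aw) / max(np.linalg.norm(L), 1e-300)
    M = np.vstack([Aw, np.sqrt(alpha) * scale * L])
    rhs = np.concatenate([bw, np.zeros(L.shape[0])])
    p, _ = nnls(M, rhs, maxiter=10 * M.shape[1])
    resid = Aw @ p - bw
    chi2 = float(np.sum(resid ** 2) / max(len(bw) - 1, 1))
    rough = float(np.sum((L @ p) ** 2) / max(np.sum(p ** 2), 1e-300))
    return p, chi2, rough


def compute_pr(curve: ScatteringCurve, Dmax: float,
               alpha: float | None = None,
               config: Config = DEFAULT_CONFIG) -> PairDistribution:
    """Regularized non-negative least-squares inversion of the scattering
    curve into the pair-distance distribution on [0, Dmax].

    When ``alpha`` is absent a log-grid of smoothness weights is scanned and
    the corner of the (residual, roughness) L-curve is taken.
    """
    if Dmax <= 0:
        raise ValueError("Dmax must be positive")
    cw = curve.windowed()
    if Dmax < 2.0 * np.pi / cw.q.max():
        log.warning("Dmax %.1f below the resolution bound 2*pi/q_max = %.1f A",
                    Dmax, 2.0 * np.pi / cw.q.max())
    p_cfg = config["pr"]
    r = np.linspace(0.0, Dmax, int(p_cfg["n_r"]))
    Aw, L = _ift_system(cw.q, r, cw.sigma)
    bw = cw.I / cw.sigma

    if not np.any(cw.I):
        P = np.zeros(len(r))
        return PairDistribution(r, P, Dmax, 0.0, 0.0, alpha or 0.0, 0.0)

    if alpha is None:
        alphas = np.logspace(p_cfg["alpha_log_min"], p_cfg["alpha_log_max"],
                             int(p_cfg["alpha_n"]))
        sols = [_solve_pr(Aw, L, bw, a) for a in alphas]
        alpha = alphas[_lcurve_corner(
            np.log10([max(s[1], 1e-300) for s in sols]),
            np.log10([max(s[2], 1e-300) for s in sols]))]
    p, chi2, rough = _solve_pr(Aw, L, bw, alpha)

    # negativity of the unconstrained (sign-free) solve, for Dmax scoring
    scale = np.linalg.norm(Aw) / max(np.linalg.norm(L), 1e-300)
    M = np.vstack([Aw, np.sqrt(alpha) * scale * L])
    rhs = np.concatenate([bw, np.zeros(L.shape[0])])
    p_free, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    tot = np.sum(np.abs(p_free))
    neg = float(-np.sum(np.minimum(p_free, 0.0)) / tot) if tot > 0 else 0.0

    P = np.zeros(len(r))
    P[1:-1] = p
    dr = r[1] - r[0]
    integ = np.trapezoid(P, dx=dr)
    if integ <= 0:
        raise ValueError("singular system: P(r) integrates to zero")
    Rg_pr = float(np.sqrt(np.trapezoid(r ** 2 * P, dx=dr) / (2.0 * integ)))
    I0_pr = float(4.0 * np.pi * integ)
    return PairDistribution(r, P, Dmax, Rg_pr, I0_pr, float(alpha), chi2,
                            roughness=rough, neg_mass=neg)


def _lcurve_corner(lx: np.ndarray, ly: np.ndarray) -> int:
    """Index of maximum Menger curvature along the (lx, ly) polyline."""
    lx, ly = np.asarray(lx), np.asarray(ly)
    n = len(lx)
    if n < 3:
        return n // 2
    best, best_k = -np.inf, n // 2
    for k in range(1, n - 1):
        a = np.array([lx[k - 1], ly[k - 1]])
        b = np.array([lx[k], ly[k]])
        c = np.array([lx[k + 1], ly[k + 1]])
        ab, bc, ca = b - a, c - b, a - c
        area2 = abs(ab[0] * bc[1] - ab[1] * bc[0])
        denom = np.linalg.norm(ab) * np.linalg.norm(bc) * np.linalg.norm(ca)
        curv = 2.0 * area2 / denom if denom > 0 else 0.0
        # prefer corners that bend toward smoother solutions
        if curv > best:
            best, best_k = curv, k
    return best_k


def forward_transform(pr: PairDistribution, q_grid: np.ndarray) -> np.ndarray:
    """I(q) implied by a pair distribution (for round-trip checks)."""
    q = np.asarray(q_grid, dtype=float)
    dr = pr.r[1] - pr.r[0]
    qr = np.outer(q, pr.r)
    return 4.0 * np.pi * np.trapezoid(np.sinc(qr / np.pi) * pr.P[None, :],
                                      dx=dr, axis=1)


def find_dmax(curve: ScatteringCurve,
              config: Config = DEFAULT_CONFIG,
              scan: tuple[float, float] | None = None,
              alpha: float | None = None
              ) -> tuple[float, PairDistribution]:
    """Trial-and-error Dmax selection: scan candidate values and keep the one
    whose P(r) is the smoothest positive distribution that still fits.

    score = chi2 + w_neg * negativity + w_rough * normalized roughness.
    """
    d_cfg = config["dmax_scan"]
    if scan is None:
        g = guinier_fit(curve, config=config)
        scan = (d_cfg["lo_factor"] * g.Rg, d_cfg["hi_factor"] * g.Rg)
    cands = np.arange(scan[0], scan[1] + 1e-9, d_cfg["step"])
    # one smoothness weight for the whole scan so fit quality is comparable
    # across candidates; chosen at the scan's low end, where the fit is
    # hardest, to keep truncation misfit visible
    if alpha is None:
        alpha = compute_pr(curve, float(cands[0]), config=config).alpha
    scored = []
    for D in cands:
        pr = compute_pr(curve, float(D), alpha=alpha, config=config)
        score = pr.quality + d_cfg["w_neg"] * pr.neg_mass + d_cfg["w_rough"] * pr.roughness
        scored.append((score, float(D), pr))
    i_min = int(np.argmin([s for s, _, _ in scored]))
    return scored[i_min][1], scored[i_min][2]


# --------------------------------------------------------------------------
# Porod
# --------------------------------------------------------------------------

@dataclass
class PorodResult:
    invariant: float         # Q = int q^2 I dq, units I * A^-3
    porod_volume: float      # nm^3
    porod_exponent: float
    mw_porod: float          # kDa, 0.58 * V[nm^3] (primary rule)
    mw_half_porod: float     # kDa, V[A^3]/2 -> Da heuristic (secondary)


def porod_analysis(curve: ScatteringCurve, guinier: GuinierResult,
                   config: Config = DEFAULT_CONFIG) -> PorodResult:
    """Porod invariant with Guinier head extrapolation and q^-4 tail closure,
    the derived excluded volume 2 pi^2 I0 / Q, the high-q power-law exponent,
    and the two molecular-mass estimates."""
    q, I = curve.q, curve.I
    Rg, I0 = guinier.Rg, guinier.I0

    # flat background from the mean intensity over the high-q tail; it
    # absorbs the constant floor a discrete point-particle model (or an
    # imperfect buffer subtraction) leaves at large q
    tail_m = q >= 0.85 * q[-1]
    if tail_m.sum() < 10:
        tail_m = np.zeros(len(q), bool)
        tail_m[-min(10, len(q)):] = True
    # subtract only if the tail has actually leveled off: a still-decaying
    # curve (continuum Porod tail, coil) has no constant floor to remove
    qt, It = q[tail_m], I[tail_m]
    slope_t = np.polyfit(qt, It, 1)[0]
    rel_change = slope_t * (qt[-1] - qt[0]) / max(abs(float(np.mean(It))), 1e-300)
    if abs(rel_change) < 0.2:
        B = float(np.clip(np.mean(It), 0.0, 0.01 * I0))
    else:
        B = 0.0
    I_sub = I - B
    C = float(np.mean(np.maximum(I_sub[tail_m], 0.0) * q[tail_m] ** 4))

    # head: 0 .. q_min via the Guinier form; tail: I ~ C q^-4 beyond q_max
    qh = np.linspace(0.0, q[0], 64)
    head = np.trapezoid(qh ** 2 * I0 * np.exp(-(qh * Rg) ** 2 / 3.0), qh)
    body = np.trapezoid(q ** 2 * np.maximum(I_sub, 0.0), q)
    tail = C / q[-1]
    Q = float(head + body + tail)
    if Q <= 0:
        raise ValueError("non-positive Porod invariant")
    vol_A3 = 2.0 * np.pi ** 2 * I0 / Q
    vol_nm3 = vol_A3 / 1000.0

    p_cfg = config["porod"]
    lo, hi = p_cfg["exponent_srg_lo"] / Rg, p_cfg["exponent_srg_hi"] / Rg
    lo, hi = max(lo, q[0]), min(hi, q[-1])
    m = (q >= lo) & (q <= hi) & (I_sub > 0)
    if m.sum() >= 4:
        # flatness criterion: the exponent p for which q^p * I has zero
        # linear trend over the window; robust to the deep minima of
        # oscillatory form factors that break a log-log fit
        qq, II = q[m], I_sub[m]

        def _trend(p):
            y = qq ** p * II
            return np.polyfit(qq, y / y.mean(), 1)[0]

        try:
            exponent = float(brentq(_trend, 0.3, 8.0, xtol=1e-3))
        except ValueError:
            exponent = float("nan")
    else:
        exponent = float("nan")

    return PorodResult(
        invariant=Q,
        porod_volume=float(vol_nm3),
        porod_exponent=exponent,
        mw_porod=mw_from_porod_volume(vol_nm3),
        mw_half_porod=float(vol_A3 / 2.0 / 1000.0),
    )


def mw_from_porod_volume(volume_nm3: float) -> float:
    """Molecular mass in kDa from the Porod volume in nm^3 (factor 0.58)."""
    return 0.58 * volume_nm3


# --------------------------------------------------------------------------
# Dimensionless Kratky and oligomeric state
# --------------------------------------------------------------------------

@dataclass
class KratkyCurve:
    x: np.ndarray        # q * Rg
    y: np.ndarray        # (q Rg)^2 I / I0
    x_peak: float
    y_peak: float


def dimensionless_kratky(curve: ScatteringCurve,
                         guinier: GuinierResult) -> KratkyCurve:
    """(qRg)^2 I/I0 vs qRg; a globular particle peaks near (sqrt(3), 1.104),
    a flexible chain plateaus near 2. Peak refined by local parabola."""
    from scipy.signal import find_peaks

    x = curve.q * guinier.Rg
    y = x ** 2 * curve.I / guinier.I0
    # first prominent local maximum: for elongated particles the curve rises
    # again at large x, which is not the globularity hump being reported
    peaks, _ = find_peaks(y, prominence=0.05 * float(np.max(y)))
    k = int(peaks[0]) if len(peaks) else int(np.argmax(y))
    if 0 < k < len(x) - 1:
        # quadratic through the three points around the maximum
        x3, y3 = x[k - 1:k + 2], y[k - 1:k + 2]
        coef = np.polyfit(x3, y3, 2)
        xp = float(-coef[1] / (2 * coef[0])) if coef[0] < 0 else float(x[k])
        yp = float(np.polyval(coef, xp)) if coef[0] < 0 else float(y[k])
    else:
        xp, yp = float(x[k]), float(y[k])
    return KratkyCurve(x=x, y=y, x_peak=xp, y_peak=yp)


@dataclass
class OligomerResult:
    ratio: float
    state: int
    caution: bool


def oligomer_ratio(porod: PorodResult,
                   monomer: SequenceMassResult) -> OligomerResult:
    """Porod-mass / monomer-mass ratio with nearest-integer oligomeric state;
    flagged when the ratio sits >0.35 away from an integer."""
    if monomer.mass <= 0:
        raise ValueError("monomer mass must be positive")
    ratio = porod.mw_porod * 1000.0 / monomer.mass
    state = int(round(ratio))
    return OligomerResult(ratio=float(ratio), state=state,
                          caution=abs(ratio - round(ratio)) > 0.35)
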