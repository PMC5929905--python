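"""Deterministic correlation bounds under additive-signal-change classes.

An additive signal change (ASC) between states A and B writes the state-B
signal of a node as ``XB = XA + XN`` with the added component non-negatively
correlated with the signal it joins (``rho(XA, XN) >= 0`` when variance
increases; ``rho(XB, -XN) >= 0`` when it decreases, i.e. the removed signal
correlates non-negatively with what remains). Given the state-A correlation
and the variances of both states, each class of addition confines the
state-B correlation to a computable set:

* ``uncorrelated`` — each node's added signal is uncorrelated with the other
  node's signals. The state-B correlation is then the single point
  ``rho_A * (sd_ax * sd_ay) / (sd_bx * sd_by)``.
* ``common`` — both nodes receive (or lose) scaled copies of one shared
  latent process (perfectly correlated additions; opposite signs when the
  initial correlation is negative).
* ``additive`` — the general class: all five free second moments of the
  added pair (two scales, three cross-correlations), constrained only by the
  variance bookkeeping, the per-node direction rule and joint positive
  semi-definiteness.

Geometry
--------
All computations run in an explicit 4-dimensional inner-product space: the
four signals are unit-scaled vectors, covariances are inner products, and
joint positive semi-definiteness is automatic. Both the per-node variance
cap ``sigma_N^2 <= |var_B - var_A|`` and the direction rule collapse to the
single linear constraint ``cov(XA, XB) >= min(var_A, var_B)``, leaving a
smooth low-dimensional optimization (solved by dense grids plus simplex
refinement, multi-started from deterministic corners). The test suite
cross-checks the optimizer against an independent random-search oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "Direction",
    "AdditiveSignalSpec",
    "CorrInterval",
    "additive_direction_feasible",
    "forward_correlation",
    "uncorrelated_predicted_correlation",
    "common_signal_bounds",
    "additive_bounds",
    "extremal_specs",
]

#: Relative variance changes below this are treated as exactly zero so that
#: optimizer noise cannot produce spuriously non-collapsed intervals.
ZERO_DVAR_RTOL = 1e-10


class Direction(str, Enum):
    added_in_B = "added_in_B"
    added_in_A = "added_in_A"


@dataclass(frozen=True)
class AdditiveSignalSpec:
    """Second-moment parameterization of the added signals XN and YN.

    Scales are standard deviations of the added components; the five
    correlations tie them to the existing signals and to each other. The
    convention is always ``XB = XA + XN`` / ``YB = YA + YN``; ``direction``
    records the state in which the addition is interpreted to occur.
    """

    scale_xn: float
    scale_yn: float
    rho_xa_xn: float
    rho_ya_yn: float
    rho_xa_yn: float
    rho_ya_xn: float
    rho_xn_yn: float
    direction_x: Direction = Direction.added_in_B
    direction_y: Direction = Direction.added_in_B

    def __post_init__(self) -> None:
        if self.scale_xn < 0 or self.scale_yn < 0:
            raise ValueError("scales must be non-negative")
        for name in ("rho_xa_xn", "rho_ya_yn", "rho_xa_yn", "rho_ya_xn", "rho_xn_yn"):
            v = getattr(self, name)
            if not -1 - 1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name}={v} outside [-1, 1]")

    def correlation_matrix(self, rho_a: float) -> np.ndarray:
        """4x4 correlation matrix over (XA, YA, XN, YN).

        Zero-scale components are represented as nominal unit processes
        uncorrelated with everything, which keeps the matrix well defined.
        """
        m = np.eye(4)
        m[0, 1] = m[1, 0] = rho_a
        if self.scale_xn > 0:
            m[0, 2] = m[2, 0] = self.rho_xa_xn
            m[1, 2] = m[2, 1] = self.rho_ya_xn
        if self.scale_yn > 0:
            m[0, 3] = m[3, 0] = self.rho_xa_yn
            m[1, 3] = m[3, 1] = self.rho_ya_yn
        if self.scale_xn > 0 and self.scale_yn > 0:
            m[2, 3] = m[3, 2] = self.rho_xn_yn
        return m

    def is_psd(self, rho_a: float, tol: float = 1e-8) -> bool:
        w = np.linalg.eigvalsh(self.correlation_matrix(rho_a))
        return bool(w.min() >= -tol)


_ZERO_SPEC = dict(scale_xn=0.0, scale_yn=0.0, rho_xa_xn=0.0, rho_ya_yn=0.0,
                  rho_xa_yn=0.0, rho_ya_xn=0.0, rho_xn_yn=0.0)


@dataclass(frozen=True)
class CorrInterval:
    """Attainable interval of the state-B correlation for one ASC class."""

    class_id: str
    lo: float
    hi: float
    argmin_spec: AdditiveSignalSpec
    argmax_spec: AdditiveSignalSpec

    def __post_init__(self) -> None:
        if self.lo > self.hi + 1e-9:
            raise ValueError("interval lower end exceeds upper end")

    def contains(self, rho: float, tol: float = 1e-9) -> bool:
        return self.lo - tol <= rho <= self.hi + tol


def additive_direction_feasible(var_a: float, var_b: float, var_n: float) -> bool:
    """Whether an added variance ``var_n`` is admissible for the change.

    An additive change in one direction requires the added variance not to
    exceed the absolute variance change: ``var_n <= |var_b - var_a|``.
    """
    if var_a <= 0 or var_b <= 0 or var_n < 0:
        raise ValueError("variances must be positive and var_n non-negative")
    return bool(var_n <= abs(var_b - var_a) + 1e-12 * max(var_a, var_b))


def forward_correlation(rho_a: float, var_ax: float, var_ay: float,
                        spec: AdditiveSignalSpec) -> float:
    """State-B correlation produced by a fully specified additive change.

    Expands ``cov(XA + XN, YA + YN)`` and the implied state-B variances.
    Raises if the joint correlation structure is not positive semi-definite
    or an implied variance is non-positive.
    """
    if not spec.is_psd(rho_a):
        raise ValueError("spec implies a non-PSD joint correlation structure")
    a, b = np.sqrt(var_ax), np.sqrt(var_ay)
    sx, sy = spec.scale_xn, spec.scale_yn
    cov_b = (rho_a * a * b + spec.rho_xa_yn * a * sy + spec.rho_ya_xn * b * sx
             + spec.rho_xn_yn * sx * sy)
    var_bx = var_ax + sx ** 2 + 2 * spec.rho_xa_xn * a * sx
    var_by = var_ay + sy ** 2 + 2 * spec.rho_ya_yn * b * sy
    if var_bx <= 0 or var_by <= 0:
        raise ValueError("spec implies non-positive state-B variance")
    return float(np.clip(cov_b / np.sqrt(var_bx * var_by), -1.0, 1.0))


def uncorrelated_predicted_correlation(rho_a: float, sd_ratio_x: float,
                                       sd_ratio_y: float) -> float:
    """Point prediction under addition of uncorrelated signal.

    ``sd_ratio_x = sd(XB)/sd(XA)`` etc. A ratio below one means the
    uncorrelated signal was present in state A and removed; the prediction
    is unchanged because the cross-covariance is untouched either way.
    """
    if sd_ratio_x <= 0 or sd_ratio_y <= 0:
        raise ValueError("sd ratios must be positive")
    return float(np.clip(rho_a / (sd_ratio_x * sd_ratio_y), -1.0, 1.0))


# ---------------------------------------------------------------------------
# internal geometry helpers
#
# Basis: e1 = direction of XA; YA = b*(rho*e1 + q*e2); two fresh axes e3, e4.


def _canonical(rho_a, var_ax, var_ay, var_bx, var_by):
    """Zero-snap tiny variance changes and validate inputs."""
    for v in (var_ax, var_ay, var_bx, var_by):
        if v <= 0:
            raise ValueError("variances must be positive")
    if abs(var_bx - var_ax) < ZERO_DVAR_RTOL * var_ax:
        var_bx = var_ax
    if abs(var_by - var_ay) < ZERO_DVAR_RTOL * var_ay:
        var_by = var_ay
    rho_a = float(np.clip(rho_a, -1.0, 1.0))
    return rho_a, var_ax, var_ay, var_bx, var_by


def _spec_from_vectors(xa, ya, xb, yb, a, b, c, d) -> AdditiveSignalSpec:
    """Translate an explicit vector solution into an AdditiveSignalSpec."""
    xn = xb - xa
    yn = yb - ya
    sx = float(np.linalg.norm(xn))
    sy = float(np.linalg.norm(yn))
    rho_a = float(xa @ ya / (a * b))

    def corr(u, v, nu, nv):
        if nu < 1e-12 or nv < 1e-12:
            return 0.0
        return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))

    spec = AdditiveSignalSpec(
        scale_xn=0.0 if sx < 1e-12 else sx,
        scale_yn=0.0 if sy < 1e-12 else sy,
        rho_xa_xn=corr(xa, xn, a, sx),
        rho_ya_yn=corr(ya, yn, b, sy),
        rho_xa_yn=corr(xa, yn, a, sy),
        rho_ya_xn=corr(ya, xn, b, sx),
        rho_xn_yn=corr(xn, yn, sx, sy),
        direction_x=Direction.added_in_B if c >= a else Direction.added_in_A,
        direction_y=Direction.added_in_B if d >= b else Direction.added_in_A,
    )
    return spec


def _flip_spec_y(spec: AdditiveSignalSpec) -> AdditiveSignalSpec:
    """Map a spec of the sign-flipped problem back to the original Y channel."""
    return replace(spec, rho_xa_yn=-spec.rho_xa_yn, rho_ya_xn=-spec.rho_ya_xn,
                   rho_xn_yn=-spec.rho_xn_yn)


def _additive_vectors(gx, gy, theta, phi, a, b, c, d, rho):
    """Explicit R^4 vectors for a point of the additive parameterization."""
    q = np.sqrt(max(1.0 - rho * rho, 0.0))
    xa = np.array([a, 0.0, 0.0, 0.0])
    ya = np.array([b * rho, b * q, 0.0, 0.0])
    rx = np.sqrt(max(c * c - (gx / a) ** 2, 0.0))
    ry = np.sqrt(max(d * d - (gy / b) ** 2, 0.0))
    u = np.array([0.0, np.cos(theta), np.sin(theta), 0.0])      # unit, ⟂ xa
    w = np.array([q, -rho, 0.0, 0.0])                            # unit, ⟂ ya
    v = np.cos(phi) * w + np.sin(phi) * np.array([0.0, 0.0, 1.0, 0.0])
    xb = (gx / a ** 2) * xa + rx * u
    yb = (gy / b ** 2) * ya + ry * v
    return xa, ya, xb, yb


def _additive_objective(gx, gy, phi, a, b, c, d, rho, sign):
    """cov(XB, YB) maximized (sign=+1) or minimized (-1) over theta.

    For fixed (gx, gy, phi) the theta-dependence is ``c1*cos + c2*sin`` whose
    extremum is ``±hypot(c1, c2)``; the reduced objective is smooth in phi.
    """
    q = np.sqrt(max(1.0 - rho * rho, 0.0))
    rx = np.sqrt(np.maximum(c * c - (gx / a) ** 2, 0.0))
    ry = np.sqrt(np.maximum(d * d - (gy / b) ** 2, 0.0))
    A = gx * q * ry / a
    B = gy * q * rx / b
    R = rx * ry
    c1 = B - R * rho * np.cos(phi)
    c2 = R * np.sin(phi)
    fixed = gx * gy * rho / (a * b)
    return fixed + A * np.cos(phi) + sign * np.hypot(c1, c2)


def _solve_additive_side(a, b, c, d, rho, sign):
    """One side (max for sign=+1, min for -1) of the additive problem."""
    mx, Mx = min(a * a, c * c), a * c
    my, My = min(b * b, d * d), b * d

    # dense vectorized scan
    n_g, n_p = 21, 73
    gxs = np.linspace(mx, Mx, n_g) if Mx > mx else np.array([mx])
    gys = np.linspace(my, My, n_g) if My > my else np.array([my])
    phis = np.linspace(0.0, 2 * np.pi, n_p)
    GX, GY, PH = np.meshgrid(gxs, gys, phis, indexing="ij")
    vals = _additive_objective(GX, GY, PH, a, b, c, d, rho, sign)
    flat = np.argsort(sign * vals.ravel())[::-1]

    def neg(z):
        gx = float(np.clip(z[0], mx, Mx))
        gy = float(np.clip(z[1], my, My))
        return -sign * _additive_objective(gx, gy, z[2], a, b, c, d, rho, sign)

    starts = [np.array([GX.ravel()[i], GY.ravel()[i], PH.ravel()[i]]) for i in flat[:4]]
    for gx0 in (mx, Mx):
        for gy0 in (my, My):
            for p0 in (0.0, np.pi):
                starts.append(np.array([gx0, gy0, p0]))
    best_score, best_z = -np.inf, starts[0]
    candidates = []  # (score, z) with score = sign * cov, maximized
    for z0 in starts:
        res = minimize(neg, z0, method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-12, maxiter=600))
        score = -res.fun
        candidates.append((score, res.x))
        if score > best_score:
            best_score, best_z = score, res.x
    # tie-break: among near-optimal candidates prefer minimal added variance
    def added_var(z):
        gx = float(np.clip(z[0], mx, Mx))
        gy = float(np.clip(z[1], my, My))
        return (a * a + c * c - 2 * gx) + (b * b + d * d - 2 * gy)

    near = [z for s, z in candidates if abs(s - best_score) < 1e-9]
    best_z = min(near, key=added_var) if near else best_z

    gx = float(np.clip(best_z[0], mx, Mx))
    gy = float(np.clip(best_z[1], my, My))
    phi = float(best_z[2])
    # recover theta at the extremum
    q = np.sqrt(max(1.0 - rho * rho, 0.0))
    rx = np.sqrt(max(c * c - (gx / a) ** 2, 0.0))
    ry = np.sqrt(max(d * d - (gy / b) ** 2, 0.0))
    c1 = gy * q * rx / b - rx * ry * rho * np.cos(phi)
    c2 = rx * ry * np.sin(phi)
    theta = float(np.arctan2(sign * c2, sign * c1)) if (abs(c1) + abs(c2)) > 0 else 0.0
    cov = _additive_objective(gx, gy, phi, a, b, c, d, rho, sign)
    vecs = _additive_vectors(gx, gy, theta, phi, a, b, c, d, rho)
    return float(cov), vecs


def additive_bounds(rho_a: float, var_ax: float, var_ay: float,
                    var_bx: float, var_by: float) -> CorrInterval:
    """Attainable state-B correlation interval under the full additive class.

    All five free second moments of the added signals are optimized over,
    subject to the variance equations, the per-node direction rule and joint
    positive semi-definiteness. Contains the uncorrelated point and the
    common-signal interval for the same inputs.
    """
    rho_a, var_ax, var_ay, var_bx, var_by = _canonical(
        rho_a, var_ax, var_ay, var_bx, var_by)
    if rho_a < 0:
        flipped = additive_bounds(-rho_a, var_ax, var_ay, var_bx, var_by)
        return CorrInterval(
            class_id="additive", lo=-flipped.hi, hi=-flipped.lo,
            argmin_spec=_flip_spec_y(flipped.argmax_spec),
            argmax_spec=_flip_spec_y(flipped.argmin_spec))
    a, b, c, d = (np.sqrt(v) for v in (var_ax, var_ay, var_bx, var_by))
    if var_bx == var_ax and var_by == var_ay:
        spec = AdditiveSignalSpec(**_ZERO_SPEC)
        return CorrInterval("additive", rho_a, rho_a, spec, spec)
    cov_hi, vecs_hi = _solve_additive_side(a, b, c, d, rho_a, +1)
    cov_lo, vecs_lo = _solve_additive_side(a, b, c, d, rho_a, -1)
    denom = c * d
    lo = float(np.clip(cov_lo / denom, -1.0, 1.0))
    hi = float(np.clip(cov_hi / denom, -1.0, 1.0))
    return CorrInterval(
        class_id="additive", lo=min(lo, hi), hi=max(lo, hi),
        argmin_spec=_spec_from_vectors(*vecs_lo, a, b, c, d),
        argmax_spec=_spec_from_vectors(*vecs_hi, a, b, c, d))


# ---------------------------------------------------------------------------
# common-signal subclass
#
# A shared unit latent n is fully characterized (for second moments) by its
# correlations (cnx, cny) with the two state-A signals. Joint PSD of
# (XA, YA, n) confines (cnx, cny) to the ellipse
#   cnx^2 + cny^2 - 2*rho*cnx*cny <= 1 - rho^2.
# The per-node scale equations add one constraint line per node
# (cnx >= 0 for a variance increase, cnx >= -sqrt(-dvar_x)/a for a
# decrease), along which the objective has square-root cusps. Extrema
# therefore lie either at interior stationary points, on the ellipse edge,
# or exactly on a constraint line; each family is searched separately
# (dense grids with iterative shrinking, vectorized across instances).


def _common_cn(r, t, rho):
    """Whitened polar coordinates -> (cnx, cny) inside the PSD ellipse."""
    w1 = r * np.sqrt(1.0 + rho) * np.cos(t)
    w2 = r * np.sqrt(1.0 - rho) * np.sin(t)
    inv = 1.0 / np.sqrt(2.0)
    return (w1 + w2) * inv, (w1 - w2) * inv


def _common_scale_grid(proj, dvar):
    """Scale of a shared-signal addition given the latent's covariance with
    the node's state-A signal (``proj``) and the required variance change.

    NaN where infeasible. For a variance decrease only the smaller root of
    the quadratic respects the added-variance cap; the removed signal must
    anti-align with the state-A signal.
    """
    proj = np.asarray(proj, dtype=float)
    dvar = np.asarray(dvar, dtype=float)
    with np.errstate(invalid="ignore"):
        inc = -proj + np.sqrt(proj * proj + dvar)
        inc = np.where(proj < -1e-12, np.nan, inc)
        disc = proj * proj + dvar
        dec = np.where((proj > 1e-12) | (disc < -1e-15), np.nan,
                       -proj - np.sqrt(np.clip(disc, 0.0, None)))
    zero = np.where(proj >= -1e-12, 0.0, np.nan)
    return np.where(dvar > 0, inc, np.where(dvar < 0, dec, zero))


def _common_cov_cn(cnx, cny, a, b, c, d, rho):
    """cov(XB, YB) for a latent with correlations (cnx, cny); NaN infeasible."""
    q2 = 1.0 - rho * rho
    ell = cnx * cnx + cny * cny - 2.0 * rho * cnx * cny
    sx = _common_scale_grid(a * cnx, c * c - a * a)
    sy = _common_scale_grid(b * cny, d * d - b * b)
    cov = a * b * rho + sx * b * cny + sy * a * cnx + sx * sy
    bad = np.isnan(sx) | np.isnan(sy) | (ell > q2 + 1e-12)
    return np.where(bad, np.nan, cov)


def _common_cov_rt(r, t, a, b, c, d, rho):
    cnx, cny = _common_cn(r, t, rho)
    return _common_cov_cn(cnx, cny, a, b, c, d, rho)


def _line_segment(v, rho):
    """Feasible cny range on the vertical line cnx = v (ellipse section)."""
    q = np.sqrt(np.maximum(1.0 - rho * rho, 0.0))
    h = q * np.sqrt(np.maximum(1.0 - v * v, 0.0))
    return rho * v - h, rho * v + h


def _refine_1d(score_fn, lo, hi, n0=801, n=33, rounds=6):
    """Maximize score_fn along 1-D segments, vectorized over instances.

    ``score_fn(x)`` takes points of shape (m, k) and returns scores (NaN or
    -inf allowed). Returns (best_score, best_x), each (m,).
    """
    m = lo.shape[0]
    ctr = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    best_score = np.full(m, -np.inf)
    best_x = ctr.copy()
    npts = n0
    for _ in range(rounds + 1):
        grid = np.linspace(-1.0, 1.0, npts)
        x = np.clip(ctr[:, None] + half[:, None] * grid, lo[:, None], hi[:, None])
        sc = score_fn(x)
        sc = np.where(np.isnan(sc), -np.inf, sc)
        idx = np.argmax(sc, axis=1)
        cur = sc[np.arange(m), idx]
        cx = x[np.arange(m), idx]
        better = cur > best_score
        best_score = np.where(better, cur, best_score)
        best_x = np.where(better, cx, best_x)
        spacing = 2.0 * half / (npts - 1)
        ctr = best_x.copy()
        half = 2.0 * spacing
        npts = n
    return best_score, best_x


def _common_extremum(a, b, c, d, rho, sign):
    """Best (sign-maximal) common-signal covariance per instance.

    Arrays (m,) in, arrays out: (cov, cnx, cny). ``rho`` must be >= 0.
    NaN cov where no feasible configuration exists.
    """
    m = a.shape[0]
    dvx = c * c - a * a
    dvy = d * d - b * b
    sh = (m, 1)

    def score_cn(cnx, cny):
        cov = _common_cov_cn(cnx, cny, a.reshape(sh), b.reshape(sh),
                             c.reshape(sh), d.reshape(sh), rho.reshape(sh))
        return np.where(np.isnan(cov), -np.inf, sign * cov)

    best_score = np.full(m, -np.inf)
    best_cn = np.zeros((m, 2))

    def consider(score, cnx, cny):
        nonlocal best_score, best_cn
        better = score > best_score
        best_score = np.where(better, score, best_score)
        best_cn = np.where(better[:, None], np.stack([cnx, cny], axis=1), best_cn)

    # family 1: interior of the ellipse, 2-D shrink over (r, t)
    ctr = np.stack([np.full(m, 0.5), np.full(m, np.pi)], axis=1)
    half = np.stack([np.full(m, 0.5), np.full(m, np.pi)], axis=1)
    t1 = np.linspace(-1, 1, 25)
    t2 = np.linspace(-1, 1, 73, endpoint=False)
    fam_score = np.full(m, -np.inf)
    fam_arg = ctr.copy()
    shp = (m, 1, 1)
    for _ in range(7):
        rr = np.clip(ctr[:, 0, None] + half[:, 0, None] * t1, 0.0, 1.0)
        tt = ctr[:, 1, None] + half[:, 1, None] * t2
        vals = _common_cov_rt(rr[:, :, None], tt[:, None, :], a.reshape(shp),
                              b.reshape(shp), c.reshape(shp), d.reshape(shp),
                              rho.reshape(shp))
        sc = np.where(np.isnan(vals), -np.inf, sign * vals).reshape(m, -1)
        idx = np.argmax(sc, axis=1)
        i1, i2 = np.unravel_index(idx, vals.shape[1:])
        cur = sc[np.arange(m), idx]
        better = cur > fam_score
        fam_score = np.where(better, cur, fam_score)
        sel = np.stack([rr[np.arange(m), i1], tt[np.arange(m), i2]], axis=1)
        fam_arg = np.where(better[:, None], sel, fam_arg)
        ctr = fam_arg.copy()
        half = half * 0.4
    cnx_i, cny_i = _common_cn(fam_arg[:, 0], fam_arg[:, 1], rho)
    consider(fam_score, cnx_i, cny_i)

    # family 2: constraint line of node X (cnx fixed)
    with np.errstate(invalid="ignore"):
        x_line = np.where(dvx >= 0, 0.0, -np.sqrt(np.maximum(-dvx, 0.0)) / a)
    ok = np.abs(x_line) <= 1.0
    lo_y, hi_y = _line_segment(x_line, rho)
    sc, y_best = _refine_1d(lambda y: score_cn(np.broadcast_to(x_line[:, None], y.shape), y),
                            lo_y, hi_y)
    consider(np.where(ok, sc, -np.inf), x_line, y_best)

    # family 3: constraint line of node Y (cny fixed)
    with np.errstate(invalid="ignore"):
        y_line = np.where(dvy >= 0, 0.0, -np.sqrt(np.maximum(-dvy, 0.0)) / b)
    ok = np.abs(y_line) <= 1.0
    lo_x, hi_x = _line_segment(y_line, rho)
    sc, x_best = _refine_1d(lambda x: score_cn(x, np.broadcast_to(y_line[:, None], x.shape)),
                            lo_x, hi_x)
    consider(np.where(ok, sc, -np.inf), x_best, y_line)

    # family 4: ellipse edge (r = 1)
    def score_edge(t):
        cnx, cny = _common_cn(1.0, t, rho.reshape(sh))
        return score_cn(cnx, cny)

    sc, t_best = _refine_1d(score_edge, np.zeros(m), np.full(m, 2 * np.pi))
    cnx_e, cny_e = _common_cn(np.ones(m), t_best, rho)
    consider(sc, cnx_e, cny_e)

    cov = np.where(np.isfinite(best_score), sign * best_score, np.nan)
    return cov, best_cn[:, 0], best_cn[:, 1]


def _common_vectors(cnx, cny, a, b, c, d, rho):
    """Explicit R^4 vectors (xa, ya, xb, yb) for a latent at (cnx, cny)."""
    q = np.sqrt(max(1.0 - rho * rho, 0.0))
    beta = 0.0 if q == 0 else (cny - rho * cnx) / (q * q)
    n3sq = max(1.0 - cnx * cnx - (beta * q) ** 2, 0.0)
    n = np.array([cnx, beta * q, np.sqrt(n3sq), 0.0])
    xa = np.array([a, 0.0, 0.0, 0.0])
    ya = np.array([b * rho, b * q, 0.0, 0.0])
    sx = float(_common_scale_grid(a * cnx, c * c - a * a))
    sy = float(_common_scale_grid(b * cny, d * d - b * b))
    return xa, ya, xa + sx * n, ya + sy * n


def common_signal_bounds(rho_a: float, var_ax: float, var_ay: float,
                         var_bx: float, var_by: float) -> CorrInterval:
    """State-B correlation interval when one shared latent drives both changes.

    The latent process is a single unit-variance signal added (or removed)
    in both nodes with non-negative scales; for negative initial correlation
    the latent enters the two nodes with opposite signs. The interval is a
    subset of :func:`additive_bounds` for the same inputs.
    """
    rho_a, var_ax, var_ay, var_bx, var_by = _canonical(
        rho_a, var_ax, var_ay, var_bx, var_by)
    if rho_a < 0:
        flipped = common_signal_bounds(-rho_a, var_ax, var_ay, var_bx, var_by)
        return CorrInterval(
            class_id="common", lo=-flipped.hi, hi=-flipped.lo,
            argmin_spec=_flip_spec_y(flipped.argmax_spec),
            argmax_spec=_flip_spec_y(flipped.argmin_spec))
    a, b, c, d = (float(np.sqrt(v)) for v in (var_ax, var_ay, var_bx, var_by))
    if var_bx == var_ax and var_by == var_ay:
        spec = AdditiveSignalSpec(**_ZERO_SPEC)
        return CorrInterval("common", rho_a, rho_a, spec, spec)
    arrs = tuple(np.array([v]) for v in (a, b, c, d, rho_a))
    hi_cov, hx, hy = _common_extremum(*arrs, +1)
    lo_cov, lx, ly = _common_extremum(*arrs, -1)
    if np.isnan(hi_cov[0]) or np.isnan(lo_cov[0]):
        raise ValueError("no feasible common-signal configuration for these variances")
    denom = c * d
    lo = float(np.clip(lo_cov[0] / denom, -1.0, 1.0))
    hi = float(np.clip(hi_cov[0] / denom, -1.0, 1.0))
    return CorrInterval(
        class_id="common", lo=min(lo, hi), hi=max(lo, hi),
        argmin_spec=_spec_from_vectors(
            *_common_vectors(float(lx[0]), float(ly[0]), a, b, c, d, rho_a),
            a, b, c, d),
        argmax_spec=_spec_from_vectors(
            *_common_vectors(float(hx[0]), float(hy[0]), a, b, c, d, rho_a),
            a, b, c, d))


def extremal_specs(interval: CorrInterval) -> tuple[AdditiveSignalSpec, AdditiveSignalSpec]:
    """The (argmin, argmax) signal specifications stored on an interval."""
    return interval.argmin_spec, interval.argmax_spec


# ---------------------------------------------------------------------------
# vectorized batch solvers (values only)
#
# Monte-Carlo inference solves the class bounds once per posterior draw;
# these batch versions evaluate dense grids with broadcasting and refine by
# iterative grid shrinking. They return extremal correlations only (no
# argmin/argmax specs) and agree with the scalar solvers to ~1e-4, well
# below Monte-Carlo sampling noise.


def _additive_cov_grid(gx, gy, phi, a, b, c, d, rho, sign):
    q = np.sqrt(np.maximum(1.0 - rho * rho, 0.0))
    rx = np.sqrt(np.maximum(c * c - (gx / a) ** 2, 0.0))
    ry = np.sqrt(np.maximum(d * d - (gy / b) ** 2, 0.0))
    A = gx * q * ry / a
    B = gy * q * rx / b
    R = rx * ry
    c1 = B - R * rho * np.cos(phi)
    c2 = R * np.sin(phi)
    return gx * gy * rho / (a * b) + A * np.cos(phi) + sign * np.hypot(c1, c2)


def _additive_side_batch(a, b, c, d, rho, sign, n_grid=15, n_phi=33,
                         n_shrink=6, factor=0.4):
    m = a.shape[0]
    sh = (m, 1, 1, 1)
    a_, b_, c_, d_, rho_ = (v.reshape(sh) for v in (a, b, c, d, rho))
    mx = np.minimum(a * a, c * c)
    Mx = a * c
    my = np.minimum(b * b, d * d)
    My = b * d
    ctr = np.stack([(mx + Mx) / 2, (my + My) / 2, np.full(m, np.pi)], axis=1)
    half = np.stack([(Mx - mx) / 2, (My - my) / 2, np.full(m, np.pi)], axis=1)
    t1 = np.linspace(-1, 1, n_grid)
    tp = np.linspace(-1, 1, n_phi, endpoint=False)
    best_score = np.full(m, -np.inf)
    best = np.zeros(m)
    arg = ctr.copy()
    for it in range(n_shrink + 1):
        gx = ctr[:, 0, None] + half[:, 0, None] * t1
        gy = ctr[:, 1, None] + half[:, 1, None] * t1
        ph = ctr[:, 2, None] + half[:, 2, None] * tp
        gx = np.clip(gx, mx[:, None], Mx[:, None])
        gy = np.clip(gy, my[:, None], My[:, None])
        vals = _additive_cov_grid(
            gx[:, :, None, None], gy[:, None, :, None], ph[:, None, None, :],
            a_, b_, c_, d_, rho_, sign)
        flat = (sign * vals).reshape(m, -1)
        idx = np.argmax(flat, axis=1)
        i1, i2, i3 = np.unravel_index(idx, vals.shape[1:])
        cur = vals.reshape(m, -1)[np.arange(m), idx]
        better = sign * cur > best_score
        best_score = np.where(better, sign * cur, best_score)
        best = np.where(better, cur, best)
        sel = np.stack([gx[np.arange(m), i1], gy[np.arange(m), i2],
                        ph[np.arange(m), i3]], axis=1)
        arg = np.where(better[:, None], sel, arg)
        ctr = arg.copy()
        half = half * factor
    return best


def additive_bounds_batch(rho_a, var_ax, var_ay, var_bx, var_by):
    """Vectorized additive-class extremal correlations for many instances."""
    rho_a = np.atleast_1d(np.asarray(rho_a, float))
    var_ax, var_ay, var_bx, var_by = (np.broadcast_to(np.asarray(v, float), rho_a.shape).copy()
                                      for v in (var_ax, var_ay, var_bx, var_by))
    sgn = np.where(rho_a < 0, -1.0, 1.0)
    r = np.abs(rho_a)
    a, b, c, d = (np.sqrt(v) for v in (var_ax, var_ay, var_bx, var_by))
    hi_cov = _additive_side_batch(a, b, c, d, r, +1)
    lo_cov = _additive_side_batch(a, b, c, d, r, -1)
    lo = np.clip(lo_cov / (c * d), -1.0, 1.0)
    hi = np.clip(hi_cov / (c * d), -1.0, 1.0)
    lo_out = np.where(sgn < 0, -hi, lo)
    hi_out = np.where(sgn < 0, -lo, hi)
    collapse = (np.abs(var_bx - var_ax) < ZERO_DVAR_RTOL * var_ax) & \
               (np.abs(var_by - var_ay) < ZERO_DVAR_RTOL * var_ay)
    lo_out = np.where(collapse, rho_a, lo_out)
    hi_out = np.where(collapse, rho_a, hi_out)
    return lo_out, hi_out


def common_bounds_batch(rho_a, var_ax, var_ay, var_bx, var_by):
    """Vectorized common-class extremal correlations for many instances.

    Instances with no feasible common-signal configuration yield NaN.
    """
    rho_a = np.atleast_1d(np.asarray(rho_a, float))
    var_ax, var_ay, var_bx, var_by = (np.broadcast_to(np.asarray(v, float), rho_a.shape).copy()
                                      for v in (var_ax, var_ay, var_bx, var_by))
    sgn = np.where(rho_a < 0, -1.0, 1.0)
    r = np.abs(rho_a)
    a, b, c, d = (np.sqrt(v) for v in (var_ax, var_ay, var_bx, var_by))
    hi_cov, _, _ = _common_extremum(a, b, c, d, r, +1)
    lo_cov, _, _ = _common_extremum(a, b, c, d, r, -1)
    lo = np.clip(lo_cov / (c * d), -1.0, 1.0)
    hi = np.clip(hi_cov / (c * d), -1.0, 1.0)
    lo_out = np.where(sgn < 0, -hi, lo)
    hi_out = np.where(sgn < 0, -lo, hi)
    collapse = (np.abs(var_bx - var_ax) < ZERO_DVAR_RTOL * var_ax) & \
               (np.abs(var_by - var_ay) < ZERO_DVAR_RTOL * var_ay)
    lo_out = np.where(collapse, rho_a, lo_out)
    hi_out = np.where(collapse, rho_a, hi_out)
    return lo_out, hi_out
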