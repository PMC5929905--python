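"""Independent brute-force oracles for the class-bound optimizations.

These avoid the package's solvers and their vector-space reduction.
Candidates are parameterized by the added-signal scales (own-node
correlations follow from the variance equations) plus the free
cross-correlations. Feasibility of the joint 4x4 correlation matrix is
decided through its Schur complement on the (XA, YA) block, which also
yields the optimal rho(XN, YN) in closed form because the objective is
linear in it. What remains is searched by dense vectorized grids with
iterative shrinking.
"""

from __future__ import annotations

import numpy as np


def _own_corr(s, dvar, sd_a):
    """rho(existing, new) implied by the variance equation for scale s."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(s > 0, (dvar - s * s) / (2.0 * sd_a * s), 0.0)
    return r


def _schur(cx, cy, r1, r2, rho):
    """Schur-complement pieces of the 4x4 correlation matrix.

    ``r1 = rho(XA, YN)``, ``r2 = rho(YA, XN)``. Returns (h_xx, h_yy, h_xy)
    such that PSD of the joint matrix is equivalent to ``h_xx <= 1``,
    ``h_yy <= 1`` and ``(r3 - h_xy)^2 <= (1 - h_xx)(1 - h_yy)``.
    """
    q2 = 1.0 - rho * rho
    h_xx = (cx * cx - 2 * rho * cx * r2 + r2 * r2) / q2
    h_yy = (r1 * r1 - 2 * rho * r1 * cy + cy * cy) / q2
    h_xy = (cx * r1 - rho * (cx * cy + r1 * r2) + r2 * cy) / q2
    return h_xx, h_yy, h_xy


def _scale_grid(dvar, sd_a, n):
    """Feasible scales for one node, always including the exact cap and the
    scales at which the own-correlation hits +-1 (corner candidates)."""
    if abs(dvar) < 1e-15:
        return np.array([0.0])
    cap = np.sqrt(abs(dvar))
    s = np.linspace(cap / n, cap, n)
    corners = []
    for target in (1.0, -1.0):
        # own_corr(s) = target  <=>  s^2 + 2*target*sd_a*s - dvar = 0
        disc = sd_a * sd_a + dvar
        if disc >= 0:
            for root in (-target * sd_a + np.sqrt(disc),
                         -target * sd_a - np.sqrt(disc)):
                if 0 < root <= cap:
                    corners.append(root)
    s = np.concatenate([s, np.asarray(corners)])
    ok = np.abs(_own_corr(s, dvar, sd_a)) <= 1.0 + 1e-9
    s = np.sort(s[ok])
    return s if s.size else np.array([cap])


def _additive_value(sx, sy, r1, r2, rho, a, b, c, d, side):
    """Objective with the optimal rho(XN, YN) substituted in closed form.

    Broadcasts over arrays; NaN where infeasible.
    """
    dvx, dvy = c * c - a * a, d * d - b * b
    cx = _own_corr(sx, dvx, a)
    cy = _own_corr(sy, dvy, b)
    h_xx, h_yy, h_xy = _schur(cx, cy, r1, r2, rho)
    slack = (1.0 - h_xx) * (1.0 - h_yy)
    with np.errstate(invalid="ignore"):
        r3 = h_xy + side * np.sqrt(np.clip(slack, 0.0, None))
    bad = (h_xx > 1 + 1e-10) | (h_yy > 1 + 1e-10) | (np.abs(cx) > 1) | (np.abs(cy) > 1)
    cov = rho * a * b + a * sy * r1 + b * sx * r2 + sx * sy * r3
    return np.where(bad, np.nan, cov / (c * d))


def additive_oracle(rho, var_ax, var_ay, var_bx, var_by, n=33, seed=0):
    """(lo, hi) of the state-B correlation over the general additive class.

    4-D dense grid over (sx, sy, r1, r2) with the last correlation solved
    in closed form, followed by iterative local grid shrinking.
    """
    sgn = -1.0 if rho < 0 else 1.0
    r = abs(rho)
    a, b, c, d = map(np.sqrt, (var_ax, var_ay, var_bx, var_by))
    sxs = _scale_grid(c * c - a * a, a, n)
    sys_ = _scale_grid(d * d - b * b, b, n)
    r_grid = np.linspace(-1, 1, 2 * n + 1)

    out = {}
    lo_box = np.array([sxs[0], sys_[0], -1.0, -1.0])
    hi_box = np.array([sxs[-1], sys_[-1], 1.0, 1.0])
    t = np.linspace(-1, 1, 9)
    corners = [np.array([px, py, 0.0, 0.0]) for px in (sxs[0], sxs[-1])
               for py in (sys_[0], sys_[-1])]
    for side in (+1.0, -1.0):
        vals = _additive_value(sxs[:, None, None, None], sys_[None, :, None, None],
                               r_grid[None, None, :, None], r_grid[None, None, None, :],
                               r, a, b, c, d, side)
        score = np.where(np.isnan(vals), -np.inf, side * vals)
        order = np.argsort(score.ravel())[::-1][:6]
        starts = [np.array([sxs[i], sys_[j], r_grid[k], r_grid[l]])
                  for i, j, k, l in zip(*np.unravel_index(order, score.shape))]
        best = -np.inf
        for x in starts + corners:
            fx = _additive_value(*(np.array([v]) for v in x), r, a, b, c, d, side)[0]
            fx = -np.inf if np.isnan(fx) else side * fx
            half = (hi_box - lo_box) / n + 1e-12
            for _ in range(14):
                pts = np.clip(x[None, :] + half[None, :] * np.stack(
                    np.meshgrid(t, t, t, t, indexing="ij"), axis=-1).reshape(-1, 4),
                    lo_box, hi_box)
                v = _additive_value(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3],
                                    r, a, b, c, d, side)
                sc = np.where(np.isnan(v), -np.inf, side * v)
                j = int(np.argmax(sc))
                if sc[j] > fx:
                    fx = sc[j]
                    x = pts[j]
                half = half * 0.5
            best = max(best, fx)
        out[side] = side * best if np.isfinite(best) else np.nan
    lo, hi = out[-1.0], out[+1.0]
    return (-hi, -lo) if sgn < 0 else (lo, hi)


def common_oracle(rho, var_ax, var_ay, var_bx, var_by, n=801, seed=0):
    """(lo, hi) over the common-signal subclass; (nan, nan) if empty.

    The shared latent forces rho(XA, YN) = rho(XA, XN), rho(YA, XN) =
    rho(YA, YN) and rho(XN, YN) = 1, leaving a 2-D grid over the scales
    with a closed-form feasibility condition.
    """
    sgn = -1.0 if rho < 0 else 1.0
    r = abs(rho)
    a, b, c, d = map(np.sqrt, (var_ax, var_ay, var_bx, var_by))
    dvx, dvy = c * c - a * a, d * d - b * b

    def value(sx, sy):
        cx = _own_corr(sx, dvx, a)
        cy = _own_corr(sy, dvy, b)
        h_xx, h_yy, h_xy = _schur(cx, cy, cx, cy, r)
        feasible = ((np.abs(cx) <= 1) & (np.abs(cy) <= 1)
                    & (h_xx <= 1 + 1e-10) & (h_yy <= 1 + 1e-10)
                    & ((1.0 - h_xy) ** 2 <= (1 - h_xx) * (1 - h_yy) + 1e-10))
        cov = r * a * b + a * sy * cx + b * sx * cy + sx * sy
        return np.where(feasible, cov / (c * d), np.nan)

    sxs = _scale_grid(dvx, a, n)
    sys_ = _scale_grid(dvy, b, n)
    vals = value(sxs[:, None], sys_[None, :])
    if np.all(np.isnan(vals)):
        return np.nan, np.nan

    out = {}
    t = np.linspace(-1, 1, 17)
    lo_box = np.array([sxs[0], sys_[0]])
    hi_box = np.array([sxs[-1], sys_[-1]])
    corners = [np.array([px, py]) for px in (sxs[0], sxs[-1])
               for py in (sys_[0], sys_[-1])]
    for side in (+1.0, -1.0):
        score = np.where(np.isnan(vals), -np.inf, side * vals)
        order = np.argsort(score.ravel())[::-1][:5]
        starts = [np.array([sxs[i], sys_[j]])
                  for i, j in zip(*np.unravel_index(order, score.shape))]
        best = -np.inf
        for x in starts + corners:
            fx = value(np.array([x[0]]), np.array([x[1]]))[0]
            fx = -np.inf if np.isnan(fx) else side * fx
            half = (hi_box - lo_box) / n + 1e-12
            for _ in range(14):
                pts = np.clip(x[None, :] + half[None, :] * np.stack(
                    np.meshgrid(t, t, indexing="ij"), axis=-1).reshape(-1, 2),
                    lo_box, hi_box)
                v = value(pts[:, 0], pts[:, 1])
                sc = np.where(np.isnan(v), -np.inf, side * v)
                j = int(np.argmax(sc))
                if sc[j] > fx:
                    fx = sc[j]
                    x = pts[j]
                half = half * 0.5
            best = max(best, fx)
        out[side] = side * best if np.isfinite(best) else np.nan
    lo, hi = out[-1.0], out[+1.0]
    return (-hi, -lo) if sgn < 0 else (lo, hi)
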