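"""Compiled kernels for rigid-body geometry and the Metropolis sampler.

Everything in this module operates on plain float64 arrays so numba can
JIT-compile it; the public API in :mod:`gqstack.geometry` and
:mod:`gqstack.mc` wraps these functions in typed containers.

Conventions
-----------
A hard cylinder is (center c, unit axis a, radius R, height H); its two flat
bases sit at ``c + s*(H/2)*a`` with s = +1 or -1.  Chains store per-junction
base signs fixed at construction (the linker is chemically attached to one
specific base of each unit).
"""

from __future__ import annotations

import numpy as np
from numba import njit

GJK_MAX_ITER = 64
GJK_EPS = 1e-12


@njit(cache=True)
def _dot3(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


@njit(cache=True)
def _cross3(a, b, out):
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]


@njit(cache=True)
def _norm3(a):
    return np.sqrt(a[0] * a[0] + a[1] * a[1] + a[2] * a[2])


@njit(cache=True)
def _support_cylinder(c, a, R, H, d, out):
    """Farthest point of the solid cylinder in direction d (support map)."""
    da = _dot3(d, a)
    s = 1.0 if da >= 0.0 else -1.0
    wx = d[0] - da * a[0]
    wy = d[1] - da * a[1]
    wz = d[2] - da * a[2]
    nw = np.sqrt(wx * wx + wy * wy + wz * wz)
    hx = s * 0.5 * H
    if nw > 1e-14:
        f = R / nw
        out[0] = c[0] + hx * a[0] + f * wx
        out[1] = c[1] + hx * a[1] + f * wy
        out[2] = c[2] + hx * a[2] + f * wz
    else:
        out[0] = c[0] + hx * a[0]
        out[1] = c[1] + hx * a[1]
        out[2] = c[2] + hx * a[2]


@njit(cache=True)
def _mink_support(c1, a1, c2, a2, R, H, d, out):
    """Support of the Minkowski difference (cylinder1 - cylinder2)."""
    s1 = np.empty(3)
    s2 = np.empty(3)
    nd = np.empty(3)
    nd[0] = -d[0]
    nd[1] = -d[1]
    nd[2] = -d[2]
    _support_cylinder(c1, a1, R, H, d, s1)
    _support_cylinder(c2, a2, R, H, nd, s2)
    out[0] = s1[0] - s2[0]
    out[1] = s1[1] - s2[1]
    out[2] = s1[2] - s2[2]


@njit(cache=True)
def _triple_cross(a, b, out):
    """(a x b) x a -- direction perpendicular to a toward b."""
    t = np.empty(3)
    _cross3(a, b, t)
    _cross3(t, a, out)


@njit(cache=True)
def _do_simplex(simplex, nsimp, d):
    """GJK simplex update.  Returns (contains_origin, new_size).

    ``simplex`` rows 0..nsimp-1 hold the current simplex with the most
    recently added vertex last; ``d`` is overwritten with the next search
    direction.  Standard line/triangle/tetrahedron case analysis.
    """
    ab = np.empty(3)
    ac = np.empty(3)
    ad = np.empty(3)
    ao = np.empty(3)
    abc = np.empty(3)
    acd = np.empty(3)
    adb = np.empty(3)
    tmp = np.empty(3)

    while True:
        if nsimp == 2:
            # A = simplex[1] (new), B = simplex[0]
            for k in range(3):
                ab[k] = simplex[0, k] - simplex[1, k]
                ao[k] = -simplex[1, k]
            if _dot3(ab, ao) > 0.0:
                _triple_cross(ab, ao, d)
                if _norm3(d) < GJK_EPS:
                    # origin on segment
                    return True, nsimp
                return False, 2
            for k in range(3):
                simplex[0, k] = simplex[1, k]
                d[k] = ao[k]
            return False, 1

        if nsimp == 3:
            # A = simplex[2] (new), B = simplex[1], C = simplex[0]
            for k in range(3):
                ab[k] = simplex[1, k] - simplex[2, k]
                ac[k] = simplex[0, k] - simplex[2, k]
                ao[k] = -simplex[2, k]
            _cross3(ab, ac, abc)
            _cross3(abc, ac, tmp)
            if _dot3(tmp, ao) > 0.0:
                if _dot3(ac, ao) > 0.0:
                    # keep [C, A]
                    for k in range(3):
                        simplex[1, k] = simplex[2, k]
                    _triple_cross(ac, ao, d)
                    return False, 2
                # fall through to AB edge test
                if _dot3(ab, ao) > 0.0:
                    for k in range(3):
                        simplex[0, k] = simplex[1, k]
                        simplex[1, k] = simplex[2, k]
                    _triple_cross(ab, ao, d)
                    return False, 2
                for k in range(3):
                    simplex[0, k] = simplex[2, k]
                    d[k] = ao[k]
                return False, 1
            _cross3(ab, abc, tmp)
            if _dot3(tmp, ao) > 0.0:
                if _dot3(ab, ao) > 0.0:
                    for k in range(3):
                        simplex[0, k] = simplex[1, k]
                        simplex[1, k] = simplex[2, k]
                    _triple_cross(ab, ao, d)
                    return False, 2
                for k in range(3):
                    simplex[0, k] = simplex[2, k]
                    d[k] = ao[k]
                return False, 1
            side = _dot3(abc, ao)
            if side > 0.0:
                for k in range(3):
                    d[k] = abc[k]
                return False, 3
            if side < 0.0:
                # flip winding: swap B and C
                for k in range(3):
                    t = simplex[0, k]
                    simplex[0, k] = simplex[1, k]
                    simplex[1, k] = t
                    d[k] = -abc[k]
                return False, 3
            # origin in the triangle plane interior region
            return True, 3

        # nsimp == 4
        # A = simplex[3] (new), B = simplex[2], C = simplex[1], D = simplex[0]
        for k in range(3):
            ab[k] = simplex[2, k] - simplex[3, k]
            ac[k] = simplex[1, k] - simplex[3, k]
            ad[k] = simplex[0, k] - simplex[3, k]
            ao[k] = -simplex[3, k]
        _cross3(ab, ac, abc)
        _cross3(ac, ad, acd)
        _cross3(ad, ab, adb)
        if _dot3(abc, ao) > 0.0:
            # keep face [C, B, A] -> as triangle [C, B, A]
            for k in range(3):
                simplex[0, k] = simplex[1, k]
                simplex[1, k] = simplex[2, k]
                simplex[2, k] = simplex[3, k]
            nsimp = 3
            continue
        if _dot3(acd, ao) > 0.0:
            # keep face [D, C, A]
            for k in range(3):
                simplex[2, k] = simplex[3, k]
            nsimp = 3
            continue
        if _dot3(adb, ao) > 0.0:
            # keep face [B, D, A]
            for k in range(3):
                t = simplex[0, k]
                simplex[0, k] = simplex[2, k]
                simplex[1, k] = t
                simplex[2, k] = simplex[3, k]
            nsimp = 3
            continue
        return True, 4


@njit(cache=True)
def _gjk_overlap(c1, a1, c2, a2, R, H):
    """True iff the two (closed, solid) cylinders intersect.

    GJK boolean intersection on the Minkowski difference; support maps are
    exact for flat-capped cylinders, so the test is exact up to the iteration
    tolerance.  If the iteration cap is hit without a verdict the function
    conservatively reports an overlap (a measure-zero event in sampling).
    """
    d = np.empty(3)
    d[0] = c1[0] - c2[0]
    d[1] = c1[1] - c2[1]
    d[2] = c1[2] - c2[2]
    if _norm3(d) < 1e-9:
        d[0] = 1.0
        d[1] = 0.0
        d[2] = 0.0
    simplex = np.empty((4, 3))
    w = np.empty(3)
    _mink_support(c1, a1, c2, a2, R, H, d, w)
    for k in range(3):
        simplex[0, k] = w[k]
        d[k] = -w[k]
    nsimp = 1
    for _ in range(GJK_MAX_ITER):
        if _norm3(d) < GJK_EPS:
            return True
        _mink_support(c1, a1, c2, a2, R, H, d, w)
        if _dot3(w, d) < GJK_EPS:
            return False
        for k in range(3):
            simplex[nsimp, k] = w[k]
        nsimp += 1
        contains, nsimp = _do_simplex(simplex, nsimp, d)
        if contains:
            return True
    return True


@njit(cache=True)
def _point_circle_dist2(p, c, nrm, r):
    """Squared distance from a point to a circle (center c, normal nrm, radius r)."""
    vx = p[0] - c[0]
    vy = p[1] - c[1]
    vz = p[2] - c[2]
    vpar = vx * nrm[0] + vy * nrm[1] + vz * nrm[2]
    v2 = vx * vx + vy * vy + vz * vz
    vperp2 = v2 - vpar * vpar
    if vperp2 < 0.0:
        vperp2 = 0.0
    rho = np.sqrt(vperp2)
    dr = rho - r
    return vpar * vpar + dr * dr


@njit(cache=True)
def _circle_circle_dist(c1, n1, r1, c2, n2, r2):
    """Minimum distance between two circles in 3D.

    Parametrizes circle 1 and minimizes the exact point-to-circle distance to
    circle 2: a coarse 48-point angular scan brackets the global minimum,
    then golden-section refinement polishes it to ~1e-8 rad.
    """
    # orthonormal frame (u, v) in the plane of circle 1
    u = np.empty(3)
    v = np.empty(3)
    if abs(n1[0]) < 0.9:
        ex, ey, ez = 1.0, 0.0, 0.0
    else:
        ex, ey, ez = 0.0, 1.0, 0.0
    dn = ex * n1[0] + ey * n1[1] + ez * n1[2]
    u[0] = ex - dn * n1[0]
    u[1] = ey - dn * n1[1]
    u[2] = ez - dn * n1[2]
    nu = _norm3(u)
    u[0] /= nu
    u[1] /= nu
    u[2] /= nu
    _cross3(n1, u, v)

    p = np.empty(3)
    ncoarse = 48
    best = 1e300
    ibest = 0
    for i in range(ncoarse):
        th = 2.0 * np.pi * i / ncoarse
        ct = np.cos(th)
        st = np.sin(th)
        for k in range(3):
            p[k] = c1[k] + r1 * (ct * u[k] + st * v[k])
        d2 = _point_circle_dist2(p, c2, n2, r2)
        if d2 < best:
            best = d2
            ibest = i
    # golden-section refine on the bracketing interval
    lo = 2.0 * np.pi * (ibest - 1) / ncoarse
    hi = 2.0 * np.pi * (ibest + 1) / ncoarse
    gr = 0.6180339887498949
    x1 = hi - gr * (hi - lo)
    x2 = lo + gr * (hi - lo)

    for k in range(3):
        p[k] = c1[k] + r1 * (np.cos(x1) * u[k] + np.sin(x1) * v[k])
    f1 = _point_circle_dist2(p, c2, n2, r2)
    for k in range(3):
        p[k] = c1[k] + r1 * (np.cos(x2) * u[k] + np.sin(x2) * v[k])
    f2 = _point_circle_dist2(p, c2, n2, r2)
    for _ in range(48):
        if f1 < f2:
            hi = x2
            x2 = x1
            f2 = f1
            x1 = hi - gr * (hi - lo)
            for k in range(3):
                p[k] = c1[k] + r1 * (np.cos(x1) * u[k] + np.sin(x1) * v[k])
            f1 = _point_circle_dist2(p, c2, n2, r2)
        else:
            lo = x1
            x1 = x2
            f1 = f2
            x2 = lo + gr * (hi - lo)
            for k in range(3):
                p[k] = c1[k] + r1 * (np.cos(x2) * u[k] + np.sin(x2) * v[k])
            f2 = _point_circle_dist2(p, c2, n2, r2)
    fmin = f1 if f1 < f2 else f2
    if best < fmin:
        fmin = best
    return np.sqrt(fmin)


@njit(cache=True)
def _base_center(pos, ax, sgn, H, out):
    out[0] = pos[0] + sgn * 0.5 * H * ax[0]
    out[1] = pos[1] + sgn * 0.5 * H * ax[1]
    out[2] = pos[2] + sgn * 0.5 * H * ax[2]


@njit(cache=True)
def _junction_base_distance(p1, a1, s1, p2, a2, s2, H):
    """Distance between the two facing base centers of a tethered pair."""
    b1 = np.empty(3)
    b2 = np.empty(3)
    _base_center(p1, a1, s1, H, b1)
    _base_center(p2, a2, s2, H, b2)
    dx = b1[0] - b2[0]
    dy = b1[1] - b2[1]
    dz = b1[2] - b2[2]
    return np.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def _junction_rim_distance(p1, a1, s1, p2, a2, s2, R, H):
    """Minimum rim-to-rim distance between the facing bases of a pair."""
    b1 = np.empty(3)
    b2 = np.empty(3)
    _base_center(p1, a1, s1, H, b1)
    _base_center(p2, a2, s2, H, b2)
    return _circle_circle_dist(b1, a1, R, b2, a2, R)


@njit(cache=True)
def _rotate_about(a, k, phi, out):
    """Rodrigues rotation of vector a about unit axis k by angle phi."""
    c = np.cos(phi)
    s = np.sin(phi)
    kxa = np.empty(3)
    _cross3(k, a, kxa)
    ka = _dot3(k, a)
    for j in range(3):
        out[j] = a[j] * c + kxa[j] * s + k[j] * ka * (1.0 - c)
    # guard against slow drift of the norm
    nn = _norm3(out)
    out[0] /= nn
    out[1] /= nn
    out[2] /= nn


@njit(cache=True)
def _run_mc(pos, ax, sgn_a, sgn_b, R, H, delta, L_max, beta, sweeps,
            equilibration, stride, max_trans, max_rot, seed):
    """Metropolis Monte Carlo on a tethered hard-cylinder chain.

    Single-unit trial moves (translation within a cube of half-width
    ``max_trans`` plus axis rotation by a uniform angle within ``max_rot``
    about a random direction).  Hard rejections for cylinder overlap (any
    pair involving the moved unit) and for violated tether constraints
    (rim-to-rim distance of the facing bases > L_max on the junctions
    adjacent to the moved unit).  Square-well stacking of depth 1 (in units
    of u0) on the facing base centers: dE = -(new bonds) + (old bonds);
    acceptance min(1, exp(-beta*dE)) with beta = 1/T*.  beta = 0 means no
    attraction: every constraint-respecting move is accepted.

    Returns (positions, axes, junction base-center distances, accepted, tried).
    Snapshots recorded at the end of each sweep s >= equilibration with
    (s - equilibration) % stride == 0.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    nj = n - 1
    n_snap = (sweeps - equilibration - 1) // stride + 1
    snap_pos = np.empty((n_snap, n, 3))
    snap_ax = np.empty((n_snap, n, 3))
    snap_jd = np.empty((n_snap, nj))

    new_p = np.empty(3)
    new_a = np.empty(3)
    k = np.empty(3)
    accepted = 0
    tried = 0
    isnap = 0

    for sweep in range(sweeps):
        for _ in range(n):
            i = np.random.randint(0, n)
            tried += 1
            for j in range(3):
                new_p[j] = pos[i, j] + (2.0 * np.random.random() - 1.0) * max_trans
            # random rotation axis (uniform on the sphere)
            nk = 0.0
            while nk < 1e-12:
                k[0] = np.random.standard_normal()
                k[1] = np.random.standard_normal()
                k[2] = np.random.standard_normal()
                nk = _norm3(k)
            k[0] /= nk
            k[1] /= nk
            k[2] /= nk
            phi = (2.0 * np.random.random() - 1.0) * max_rot
            _rotate_about(ax[i], k, phi, new_a)

            # hard-core overlap with every other unit
            ok = True
            for j in range(n):
                if j == i:
                    continue
                if _gjk_overlap(new_p, new_a, pos[j], ax[j], R, H):
                    ok = False
                    break
            # tether constraints on adjacent junctions
            if ok and i > 0:
                rd = _junction_rim_distance(pos[i - 1], ax[i - 1], sgn_a[i - 1],
                                            new_p, new_a, sgn_b[i - 1], R, H)
                if rd > L_max:
                    ok = False
            if ok and i < nj:
                rd = _junction_rim_distance(new_p, new_a, sgn_a[i],
                                            pos[i + 1], ax[i + 1], sgn_b[i], R, H)
                if rd > L_max:
                    ok = False
            if not ok:
                continue

            if beta > 0.0:
                d_bonds = 0
                if i > 0:
                    od = _junction_base_distance(pos[i - 1], ax[i - 1], sgn_a[i - 1],
                                                 pos[i], ax[i], sgn_b[i - 1], H)
                    nd = _junction_base_distance(pos[i - 1], ax[i - 1], sgn_a[i - 1],
                                                 new_p, new_a, sgn_b[i - 1], H)
                    d_bonds += (1 if nd <= delta else 0) - (1 if od <= delta else 0)
                if i < nj:
                    od = _junction_base_distance(pos[i], ax[i], sgn_a[i],
                                                 pos[i + 1], ax[i + 1], sgn_b[i], H)
                    nd = _junction_base_distance(new_p, new_a, sgn_a[i],
                                                 pos[i + 1], ax[i + 1], sgn_b[i], H)
                    d_bonds += (1 if nd <= delta else 0) - (1 if od <= delta else 0)
                dE = -float(d_bonds)
                if dE > 0.0 and np.random.random() >= np.exp(-beta * dE):
                    continue

            for j in range(3):
                pos[i, j] = new_p[j]
                ax[i, j] = new_a[j]
            accepted += 1

        if sweep >= equilibration and (sweep - equilibration) % stride == 0:
            for u in range(n):
                for j in range(3):
                    snap_pos[isnap, u, j] = pos[u, j]
                    snap_ax[isnap, u, j] = ax[u, j]
            for jn in range(nj):
                snap_jd[isnap, jn] = _junction_base_distance(
                    pos[jn], ax[jn], sgn_a[jn], pos[jn + 1], ax[jn + 1], sgn_b[jn], H)
            isnap += 1

    return snap_pos, snap_ax, snap_jd, accepted, tried
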