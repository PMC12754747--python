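"""Numba kernels: interpolation, line integrals, likelihood gradients,
photon-pair transport and list-mode projectors.

Everything here works on plain arrays; the public modules wrap these in
typed containers.  Conventions shared by all kernels:

* grids are (nx, ny, nz) C-contiguous float64 with ``origin`` at the corner
  of voxel (0,0,0); interpolation is trilinear between voxel centres and the
  field is zero outside the support;
* the TOF coordinate of a point on the segment p1 -> p2 is its signed
  distance from the midpoint, positive toward p1 (endpoint swap mirrors it);
* quadrature along a segment uses midpoints ``s_i = (i + 0.5)/n_quad`` of a
  fixed subdivision of the *whole* segment, evaluating only samples inside
  the grid bounding box and (for TOF) a +/-3.75 sigma kernel window.  Fixing
  the subdivision count keeps the quadrature smooth in the endpoints, which
  the analytic gradients rely on.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ----------------------------------------------------------------- trilinear


@njit(cache=True, inline="always", fastmath=True)
def _trilinear(vals, origin, spacing, x, y, z):
    """Trilinear interpolation; exactly 0 outside the grid box."""
    nx, ny, nz = vals.shape
    if (
        x < origin[0] or x >= origin[0] + spacing[0] * nx
        or y < origin[1] or y >= origin[1] + spacing[1] * ny
        or z < origin[2] or z >= origin[2] + spacing[2] * nz
    ):
        return 0.0
    u = (x - origin[0]) / spacing[0] - 0.5
    v = (y - origin[1]) / spacing[1] - 0.5
    w = (z - origin[2]) / spacing[2] - 0.5
    i0 = int(np.floor(u))
    j0 = int(np.floor(v))
    k0 = int(np.floor(w))
    fu = u - i0
    fv = v - j0
    fw = w - k0
    acc = 0.0
    for di in range(2):
        i = i0 + di
        if i < 0 or i >= nx:
            continue
        wi = fu if di == 1 else 1.0 - fu
        for dj in range(2):
            j = j0 + dj
            if j < 0 or j >= ny:
                continue
            wj = fv if dj == 1 else 1.0 - fv
            for dk in range(2):
                k = k0 + dk
                if k < 0 or k >= nz:
                    continue
                wk = fw if dk == 1 else 1.0 - fw
                acc += wi * wj * wk * vals[i, j, k]
    return acc


@njit(cache=True, inline="always", fastmath=True)
def _trilinear_grad(vals, origin, spacing, x, y, z, out_g):
    """Value and spatial gradient of the trilinear field at (x, y, z)."""
    nx, ny, nz = vals.shape
    out_g[0] = 0.0
    out_g[1] = 0.0
    out_g[2] = 0.0
    if (
        x < origin[0] or x >= origin[0] + spacing[0] * nx
        or y < origin[1] or y >= origin[1] + spacing[1] * ny
        or z < origin[2] or z >= origin[2] + spacing[2] * nz
    ):
        return 0.0
    u = (x - origin[0]) / spacing[0] - 0.5
    v = (y - origin[1]) / spacing[1] - 0.5
    w = (z - origin[2]) / spacing[2] - 0.5
    i0 = int(np.floor(u))
    j0 = int(np.floor(v))
    k0 = int(np.floor(w))
    fu = u - i0
    fv = v - j0
    fw = w - k0
    acc = 0.0
    gx = 0.0
    gy = 0.0
    gz = 0.0
    for di in range(2):
        i = i0 + di
        if i < 0 or i >= nx:
            continue
        wi = fu if di == 1 else 1.0 - fu
        dwi = 1.0 if di == 1 else -1.0
        for dj in range(2):
            j = j0 + dj
            if j < 0 or j >= ny:
                continue
            wj = fv if dj == 1 else 1.0 - fv
            dwj = 1.0 if dj == 1 else -1.0
            for dk in range(2):
                k = k0 + dk
                if k < 0 or k >= nz:
                    continue
                wk = fw if dk == 1 else 1.0 - fw
                dwk = 1.0 if dk == 1 else -1.0
                val = vals[i, j, k]
                acc += wi * wj * wk * val
                gx += dwi * wj * wk * val
                gy += wi * dwj * wk * val
                gz += wi * wj * dwk * val
    out_g[0] = gx / spacing[0]
    out_g[1] = gy / spacing[1]
    out_g[2] = gz / spacing[2]
    return acc


@njit(cache=True)
def trilinear_many(vals, origin, spacing, pts):
    out = np.empty(pts.shape[0])
    for n in range(pts.shape[0]):
        out[n] = _trilinear(vals, origin, spacing, pts[n, 0], pts[n, 1], pts[n, 2])
    return out


# ------------------------------------------------------------ box clipping


@njit(cache=True, inline="always", fastmath=True)
def _clip_to_box(p0x, p0y, p0z, ux, uy, uz, lo, hi, pad):
    """Intersect segment p0 + s*u, s in [0,1], with the padded box.

    Returns (s_lo, s_hi); empty when s_lo >= s_hi.
    """
    s_lo = 0.0
    s_hi = 1.0
    for ax in range(3):
        if ax == 0:
            p = p0x
            u = ux
        elif ax == 1:
            p = p0y
            u = uy
        else:
            p = p0z
            u = uz
        a = lo[ax] - pad
        b = hi[ax] + pad
        if abs(u) < 1e-12:
            if p < a or p > b:
                return 1.0, 0.0
        else:
            t0 = (a - p) / u
            t1 = (b - p) / u
            if t0 > t1:
                t0, t1 = t1, t0
            if t0 > s_lo:
                s_lo = t0
            if t1 < s_hi:
                s_hi = t1
    return s_lo, s_hi


# --------------------------------------------------------- Joseph projector


@njit(cache=True, fastmath=True)
def joseph_line_integral(vals, origin, spacing, p0, p1):
    """Joseph's-method line integral of the trilinear field along p0 -> p1.

    Steps through the voxel-centre planes perpendicular to the principal
    (largest direction component) axis, interpolating bilinearly in the two
    transverse axes; partial first/last intervals are weighted by their true
    length so a constant field integrates exactly.
    """
    ux = p1[0] - p0[0]
    uy = p1[1] - p0[1]
    uz = p1[2] - p0[2]
    seg = np.sqrt(ux * ux + uy * uy + uz * uz)
    if seg <= 0.0:
        return 0.0
    lo = origin
    hi = np.empty(3)
    for ax in range(3):
        hi[ax] = origin[ax] + spacing[ax] * vals.shape[ax]
    s_lo, s_hi = _clip_to_box(p0[0], p0[1], p0[2], ux, uy, uz, lo, hi, 0.0)
    if s_hi <= s_lo:
        return 0.0
    # principal axis
    k = 0
    best = abs(ux)
    if abs(uy) > best:
        k = 1
        best = abs(uy)
    if abs(uz) > best:
        k = 2
        best = abs(uz)
    uk = ux if k == 0 else (uy if k == 1 else uz)
    p0k = p0[k]
    hk = spacing[k]
    # plane j has coordinate origin[k] + (j + 0.5) * hk, crossed at
    # s_j = s_first + j * step (step signed); each plane sample represents
    # the parameter interval of width |step| centred on the crossing.
    step = hk / uk
    ds = abs(step)
    s_first = ((origin[k] + 0.5 * hk) - p0k) / uk
    ja = (s_lo - s_first) / step
    jb = (s_hi - s_first) / step
    if ja > jb:
        ja, jb = jb, ja
    j_lo = int(np.floor(ja)) - 1
    j_hi = int(np.ceil(jb)) + 1
    acc = 0.0
    covered = 0.0
    refine = 4  # along-axis sub-midpoints per plane interval
    for j in range(j_lo, j_hi + 1):
        s_j = s_first + j * step
        a = s_j - 0.5 * ds
        b = s_j + 0.5 * ds
        if a < s_lo:
            a = s_lo
        if b > s_hi:
            b = s_hi
        if b <= a:
            continue
        dsub = (b - a) / refine
        for r in range(refine):
            sm = a + (r + 0.5) * dsub
            x = p0[0] + sm * ux
            y = p0[1] + sm * uy
            z = p0[2] + sm * uz
            acc += _trilinear(vals, origin, spacing, x, y, z) * dsub * seg
        covered += b - a
    if covered == 0.0 and s_hi > s_lo:
        # segment shorter than one plane interval: single midpoint sample
        sm = 0.5 * (s_lo + s_hi)
        x = p0[0] + sm * ux
        y = p0[1] + sm * uy
        z = p0[2] + sm * uz
        acc = _trilinear(vals, origin, spacing, x, y, z) * (s_hi - s_lo) * seg
    return acc


# ----------------------------------------------- TOF-weighted marcher (+grad)

_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


@njit(cache=True, fastmath=True)
def tof_weighted_line(
    vals, origin, spacing, p1, p2, bin_center, sigma, bin_width, no_tof, n_quad
):
    """TOF-kernel-weighted line integral (midpoint quadrature, no gradient)."""
    ux = p2[0] - p1[0]
    uy = p2[1] - p1[1]
    uz = p2[2] - p1[2]
    seg = np.sqrt(ux * ux + uy * uy + uz * uz)
    if seg <= 0.0:
        return 0.0
    lo = origin
    hi = np.empty(3)
    for ax in range(3):
        hi[ax] = origin[ax] + spacing[ax] * vals.shape[ax]
    s_lo, s_hi = _clip_to_box(p1[0], p1[1], p1[2], ux, uy, uz, lo, hi, 0.0)
    if not no_tof:
        w = 3.75 * sigma + 0.5 * bin_width
        # tau(s) = (0.5 - s) * seg must lie in [bin_center - w, bin_center + w]
        t_lo = 0.5 - (bin_center + w) / seg
        t_hi = 0.5 - (bin_center - w) / seg
        if t_lo > s_lo:
            s_lo = t_lo
        if t_hi < s_hi:
            s_hi = t_hi
    if s_hi <= s_lo:
        return 0.0
    i_lo = int(np.ceil(s_lo * n_quad - 0.5))
    i_hi = int(np.floor(s_hi * n_quad - 0.5))
    if i_lo < 0:
        i_lo = 0
    if i_hi > n_quad - 1:
        i_hi = n_quad - 1
    acc = 0.0
    for i in range(i_lo, i_hi + 1):
        s = (i + 0.5) / n_quad
        x = p1[0] + s * ux
        y = p1[1] + s * uy
        z = p1[2] + s * uz
        f = _trilinear(vals, origin, spacing, x, y, z)
        if f == 0.0:
            continue
        if no_tof:
            kk = 1.0
        else:
            tau = (0.5 - s) * seg
            zz = (tau - bin_center) / sigma
            kk = bin_width * _INV_SQRT_2PI / sigma * np.exp(-0.5 * zz * zz)
        acc += kk * f
    return acc * seg / n_quad


@njit(cache=True, fastmath=True)
def batch_expected_and_grad(
    d1,
    cr1,
    d2,
    cr2,
    tbin,
    origins,
    frames,
    dframes,
    lut_centers,
    lut_half,
    eff,
    jit1,
    jit2,
    f_vals,
    f_origin,
    f_spacing,
    r_vals,
    r_origin,
    r_spacing,
    has_att,
    a_vals,
    a_origin,
    a_spacing,
    tof_centers,
    tof_sigma,
    tof_binw,
    no_tof,
    n_quad,
    r_n_quad,
    want_grad,
    out_rate,
    out_grad,
):
    """Expected rates L(lambda1, lambda2, t) and gradients for a batch of bins.

    ``origins[d] = P_d + T_d`` and ``frames[d] = B_d @ Reuler(R_d)`` map
    crystal-local points to global space; ``dframes[d, k]`` is the derivative
    of ``frames[d]`` w.r.t. rotation angle k (degrees).  ``jit1/jit2`` hold
    per-(bin, sample) uniform[-1, 1] offsets used to draw points inside the
    two crystal voxels; the rate is the sample mean of
    ``exp(-int A) * int K_TOF * F`` times the two crystal efficiencies
    (global scale is profiled outside).

    ``out_grad[i]`` receives dL/d[T_d1 (3), R_d1 (3), T_d2 (3), R_d2 (3)].
    TOF-marginalized entries (``tbin < 0``) integrate the separate rate
    grid ``r_vals`` (typically a blurred/coarsened copy of the activity)
    with ``r_n_quad`` subdivisions.
    """
    nb = d1.shape[0]
    n_pairs = jit1.shape[1]
    f_hi = np.empty(3)
    for ax in range(3):
        f_hi[ax] = f_origin[ax] + f_spacing[ax] * f_vals.shape[ax]
    r_hi = np.empty(3)
    for ax in range(3):
        r_hi[ax] = r_origin[ax] + r_spacing[ax] * r_vals.shape[ax]
    a_hi = np.empty(3)
    if has_att:
        for ax in range(3):
            a_hi[ax] = a_origin[ax] + a_spacing[ax] * a_vals.shape[ax]
    gF = np.empty(3)
    l1 = np.empty(3)
    l2 = np.empty(3)
    p1 = np.empty(3)
    p2 = np.empty(3)
    dI1 = np.empty(3)
    dI2 = np.empty(3)
    dJ1 = np.empty(3)
    dJ2 = np.empty(3)
    for n in range(nb):
        a1 = d1[n]
        a2 = d2[n]
        c1 = cr1[n]
        c2 = cr2[n]
        # tbin < 0 requests the TOF-marginalized rate sum_t L (flat kernel)
        marginal = tbin[n] < 0 or no_tof
        bc = tof_centers[tbin[n]] if tbin[n] >= 0 else 0.0
        if tbin[n] < 0:
            gv, go, gsp, ghi, gnq = r_vals, r_origin, r_spacing, r_hi, r_n_quad
        else:
            gv, go, gsp, ghi, gnq = f_vals, f_origin, f_spacing, f_hi, n_quad
        e12 = eff[a1, c1] * eff[a2, c2]
        acc_rate = 0.0
        if want_grad:
            for q in range(12):
                out_grad[n, q] = 0.0
        if e12 == 0.0:
            out_rate[n] = 0.0
            continue
        for k in range(n_pairs):
            for ax in range(3):
                l1[ax] = lut_centers[c1, ax] + jit1[n, k, ax] * lut_half[c1, ax]
                l2[ax] = lut_centers[c2, ax] + jit2[n, k, ax] * lut_half[c2, ax]
            for ax in range(3):
                p1[ax] = (
                    origins[a1, ax]
                    + frames[a1, ax, 0] * l1[0]
                    + frames[a1, ax, 1] * l1[1]
                    + frames[a1, ax, 2] * l1[2]
                )
                p2[ax] = (
                    origins[a2, ax]
                    + frames[a2, ax, 0] * l2[0]
                    + frames[a2, ax, 1] * l2[1]
                    + frames[a2, ax, 2] * l2[2]
                )
            ux = p2[0] - p1[0]
            uy = p2[1] - p1[1]
            uz = p2[2] - p1[2]
            seg = np.sqrt(ux * ux + uy * uy + uz * uz)
            if seg <= 1e-9:
                continue
            hx = ux / seg
            hy = uy / seg
            hz = uz / seg
            # ---- TOF-weighted tracer integral with endpoint gradient
            s_lo, s_hi = _clip_to_box(p1[0], p1[1], p1[2], ux, uy, uz, go, ghi, 0.0)
            if not marginal:
                w = 3.75 * tof_sigma + 0.5 * tof_binw
                t_lo = 0.5 - (bc + w) / seg
                t_hi = 0.5 - (bc - w) / seg
                if t_lo > s_lo:
                    s_lo = t_lo
                if t_hi < s_hi:
                    s_hi = t_hi
            s0f = 0.0
            s1f = 0.0
            v1x = 0.0
            v1y = 0.0
            v1z = 0.0
            v2x = 0.0
            v2y = 0.0
            v2z = 0.0
            if s_hi > s_lo:
                i_lo = int(np.ceil(s_lo * gnq - 0.5))
                i_hi = int(np.floor(s_hi * gnq - 0.5))
                if i_lo < 0:
                    i_lo = 0
                if i_hi > gnq - 1:
                    i_hi = gnq - 1
                for i in range(i_lo, i_hi + 1):
                    s = (i + 0.5) / gnq
                    x = p1[0] + s * ux
                    y = p1[1] + s * uy
                    z = p1[2] + s * uz
                    if want_grad:
                        f = _trilinear_grad(gv, go, gsp, x, y, z, gF)
                    else:
                        f = _trilinear(gv, go, gsp, x, y, z)
                    if f == 0.0 and not want_grad:
                        continue
                    if marginal:
                        kk = 1.0
                        kprime = 0.0
                    else:
                        tau = (0.5 - s) * seg
                        zz = (tau - bc) / tof_sigma
                        kk = tof_binw * _INV_SQRT_2PI / tof_sigma * np.exp(-0.5 * zz * zz)
                        kprime = -kk * zz / tof_sigma
                    s0f += kk * f
                    if want_grad:
                        s1f += kprime * f * (0.5 - s)
                        v1x += kk * (1.0 - s) * gF[0]
                        v1y += kk * (1.0 - s) * gF[1]
                        v1z += kk * (1.0 - s) * gF[2]
                        v2x += kk * s * gF[0]
                        v2y += kk * s * gF[1]
                        v2z += kk * s * gF[2]
            tof_int = seg * s0f / gnq
            if want_grad:
                common = (s0f + seg * s1f) / gnq
                dI1[0] = -hx * common + seg * v1x / gnq
                dI1[1] = -hy * common + seg * v1y / gnq
                dI1[2] = -hz * common + seg * v1z / gnq
                dI2[0] = hx * common + seg * v2x / gnq
                dI2[1] = hy * common + seg * v2y / gnq
                dI2[2] = hz * common + seg * v2z / gnq
            # ---- attenuation along the full LOR
            att = 1.0
            if has_att:
                sa_lo, sa_hi = _clip_to_box(
                    p1[0], p1[1], p1[2], ux, uy, uz, a_origin, a_hi, 0.0
                )
                sa = 0.0
                wa1x = 0.0
                wa1y = 0.0
                wa1z = 0.0
                wa2x = 0.0
                wa2y = 0.0
                wa2z = 0.0
                if sa_hi > sa_lo:
                    i_lo = int(np.ceil(sa_lo * n_quad - 0.5))
                    i_hi = int(np.floor(sa_hi * n_quad - 0.5))
                    if i_lo < 0:
                        i_lo = 0
                    if i_hi > n_quad - 1:
                        i_hi = n_quad - 1
                    for i in range(i_lo, i_hi + 1):
                        s = (i + 0.5) / n_quad
                        x = p1[0] + s * ux
                        y = p1[1] + s * uy
                        z = p1[2] + s * uz
                        if want_grad:
                            f = _trilinear_grad(a_vals, a_origin, a_spacing, x, y, z, gF)
                            wa1x += (1.0 - s) * gF[0]
                            wa1y += (1.0 - s) * gF[1]
                            wa1z += (1.0 - s) * gF[2]
                            wa2x += s * gF[0]
                            wa2y += s * gF[1]
                            wa2z += s * gF[2]
                        else:
                            f = _trilinear(a_vals, a_origin, a_spacing, x, y, z)
                        sa += f
                mu_len = seg * sa / n_quad
                att = np.exp(-mu_len)
                if want_grad:
                    dJ1[0] = -hx * sa / n_quad + seg * wa1x / n_quad
                    dJ1[1] = -hy * sa / n_quad + seg * wa1y / n_quad
                    dJ1[2] = -hz * sa / n_quad + seg * wa1z / n_quad
                    dJ2[0] = hx * sa / n_quad + seg * wa2x / n_quad
                    dJ2[1] = hy * sa / n_quad + seg * wa2y / n_quad
                    dJ2[2] = hz * sa / n_quad + seg * wa2z / n_quad
            contrib = att * tof_int
            acc_rate += contrib
            if want_grad:
                for ax in range(3):
                    g1 = att * dI1[ax]
                    g2 = att * dI2[ax]
                    if has_att:
                        g1 -= contrib * dJ1[ax]
                        g2 -= contrib * dJ2[ax]
                    # translations
                    out_grad[n, ax] += g1
                    out_grad[n, 6 + ax] += g2
                    # rotations: d p / d theta_k = dframes[d, k] @ l
                    for kk3 in range(3):
                        out_grad[n, 3 + kk3] += g1 * (
                            dframes[a1, kk3, ax, 0] * l1[0]
                            + dframes[a1, kk3, ax, 1] * l1[1]
                            + dframes[a1, kk3, ax, 2] * l1[2]
                        )
                        out_grad[n, 9 + kk3] += g2 * (
                            dframes[a2, kk3, ax, 0] * l2[0]
                            + dframes[a2, kk3, ax, 1] * l2[1]
                            + dframes[a2, kk3, ax, 2] * l2[2]
                        )
        inv = e12 / n_pairs
        out_rate[n] = acc_rate * inv
        if want_grad:
            for q in range(12):
                out_grad[n, q] *= inv


# --------------------------------------------------------- photon transport


@njit(cache=True, fastmath=True)
def trace_events(
    points,
    dirs,
    positions,
    basis,
    half_dims,
    lut_shape,
    mu_crystal,
    u_depth,
    out_det,
    out_cr,
    out_entry,
):
    """Back-to-back ray transport to the interaction crystal voxel.

    For each emission point and direction, casts the two opposite rays and
    finds, per side, the nearest detector block hit (slab test in the
    block-local frame).  The interaction depth along the chord through the
    block is drawn from an exponential law with linear attenuation
    ``mu_crystal`` (1/mm) via the pre-drawn uniforms ``u_depth``; photons
    whose depth exceeds the chord escape (miss).  ``mu_crystal <= 0``
    degrades to assignment at the entry face.  Records the crystal voxel
    containing the interaction point and its global position; ``out_det``
    is -1 for a miss.
    """
    ne = points.shape[0]
    nd = positions.shape[0]
    nxc = lut_shape[0]
    nyc = lut_shape[1]
    nzc = lut_shape[2]
    px = 2.0 * half_dims[0] / nxc
    py = 2.0 * half_dims[1] / nyc
    pz = 2.0 * half_dims[2] / nzc
    for n in range(ne):
        for side in range(2):
            sgn = 1.0 if side == 0 else -1.0
            wx = sgn * dirs[n, 0]
            wy = sgn * dirs[n, 1]
            wz = sgn * dirs[n, 2]
            best_t = 1e30
            best_t1 = 0.0
            best_d = -1
            bex = 0.0
            bey = 0.0
            bez = 0.0
            bvx = 0.0
            bvy = 0.0
            bvz = 0.0
            for d in range(nd):
                rx = points[n, 0] - positions[d, 0]
                ry = points[n, 1] - positions[d, 1]
                rz = points[n, 2] - positions[d, 2]
                # local coordinates: columns of basis are the axes
                ox = basis[d, 0, 0] * rx + basis[d, 1, 0] * ry + basis[d, 2, 0] * rz
                oy = basis[d, 0, 1] * rx + basis[d, 1, 1] * ry + basis[d, 2, 1] * rz
                oz = basis[d, 0, 2] * rx + basis[d, 1, 2] * ry + basis[d, 2, 2] * rz
                vx = basis[d, 0, 0] * wx + basis[d, 1, 0] * wy + basis[d, 2, 0] * wz
                vy = basis[d, 0, 1] * wx + basis[d, 1, 1] * wy + basis[d, 2, 1] * wz
                vz = basis[d, 0, 2] * wx + basis[d, 1, 2] * wy + basis[d, 2, 2] * wz
                t0 = 0.0
                t1 = 1e30
                ok = True
                for ax in range(3):
                    if ax == 0:
                        o = ox
                        v = vx
                        h = half_dims[0]
                    elif ax == 1:
                        o = oy
                        v = vy
                        h = half_dims[1]
                    else:
                        o = oz
                        v = vz
                        h = half_dims[2]
                    if abs(v) < 1e-12:
                        if o < -h or o > h:
                            ok = False
                            break
                    else:
                        ta = (-h - o) / v
                        tb = (h - o) / v
                        if ta > tb:
                            ta, tb = tb, ta
                        if ta > t0:
                            t0 = ta
                        if tb < t1:
                            t1 = tb
                        if t0 > t1:
                            ok = False
                            break
                if ok and t0 > 1e-9 and t0 < best_t:
                    best_t = t0
                    best_t1 = t1
                    best_d = d
                    bex = ox + t0 * vx
                    bey = oy + t0 * vy
                    bez = oz + t0 * vz
                    bvx = vx
                    bvy = vy
                    bvz = vz
            if best_d >= 0 and mu_crystal > 0.0:
                depth = -np.log(u_depth[n, side]) / mu_crystal
                if depth >= best_t1 - best_t:
                    best_d = -1  # photon traverses the block without interacting
                else:
                    bex += depth * bvx
                    bey += depth * bvy
                    bez += depth * bvz
            out_det[n, side] = best_d
            if best_d >= 0:
                ix = int((bex + half_dims[0]) / px)
                iy = int((bey + half_dims[1]) / py)
                iz = int((bez + half_dims[2]) / pz)
                if ix < 0:
                    ix = 0
                if ix >= nxc:
                    ix = nxc - 1
                if iy < 0:
                    iy = 0
                if iy >= nyc:
                    iy = nyc - 1
                if iz < 0:
                    iz = 0
                if iz >= nzc:
                    iz = nzc - 1
                out_cr[n, side] = (ix * nyc + iy) * nzc + iz
                d = best_d
                out_entry[n, side, 0] = (
                    positions[d, 0]
                    + basis[d, 0, 0] * bex
                    + basis[d, 0, 1] * bey
                    + basis[d, 0, 2] * bez
                )
                out_entry[n, side, 1] = (
                    positions[d, 1]
                    + basis[d, 1, 0] * bex
                    + basis[d, 1, 1] * bey
                    + basis[d, 1, 2] * bez
                )
                out_entry[n, side, 2] = (
                    positions[d, 2]
                    + basis[d, 2, 0] * bex
                    + basis[d, 2, 1] * bey
                    + basis[d, 2, 2] * bez
                )
            else:
                out_cr[n, side] = -1


# ----------------------------------------------------- list-mode projectors


@njit(cache=True, fastmath=True)
def forward_events(
    vals, origin, spacing, p1s, p2s, bcenters, sigma, binw, no_tof, n_quad
):
    """TOF-weighted forward projection of the image along many event LORs."""
    ne = p1s.shape[0]
    out = np.empty(ne)
    for n in range(ne):
        out[n] = tof_weighted_line(
            vals, origin, spacing, p1s[n], p2s[n], bcenters[n], sigma, binw, no_tof, n_quad
        )
    return out


@njit(cache=True, fastmath=True)
def backproject_events(
    vals_out, origin, spacing, p1s, p2s, bcenters, weights, sigma, binw, no_tof, n_quad
):
    """Trilinear-splat backprojection of TOF-weighted event LORs."""
    nx, ny, nz = vals_out.shape
    hi = np.empty(3)
    for ax in range(3):
        hi[ax] = origin[ax] + spacing[ax] * vals_out.shape[ax]
    for n in range(p1s.shape[0]):
        wgt = weights[n]
        if wgt == 0.0:
            continue
        ux = p2s[n, 0] - p1s[n, 0]
        uy = p2s[n, 1] - p1s[n, 1]
        uz = p2s[n, 2] - p1s[n, 2]
        seg = np.sqrt(ux * ux + uy * uy + uz * uz)
        if seg <= 0.0:
            continue
        bc = bcenters[n]
        s_lo, s_hi = _clip_to_box(
            p1s[n, 0], p1s[n, 1], p1s[n, 2], ux, uy, uz, origin, hi, 0.0
        )
        if not no_tof:
            w = 4.5 * sigma + 0.5 * binw
            t_lo = 0.5 - (bc + w) / seg
            t_hi = 0.5 - (bc - w) / seg
            if t_lo > s_lo:
                s_lo = t_lo
            if t_hi < s_hi:
                s_hi = t_hi
        if s_hi <= s_lo:
            continue
        i_lo = int(np.ceil(s_lo * n_quad - 0.5))
        i_hi = int(np.floor(s_hi * n_quad - 0.5))
        if i_lo < 0:
            i_lo = 0
        if i_hi > n_quad - 1:
            i_hi = n_quad - 1
        for i in range(i_lo, i_hi + 1):
            s = (i + 0.5) / n_quad
            x = p1s[n, 0] + s * ux
            y = p1s[n, 1] + s * uy
            z = p1s[n, 2] + s * uz
            if no_tof:
                kk = 1.0
            else:
                tau = (0.5 - s) * seg
                zz = (tau - bc) / sigma
                kk = binw * _INV_SQRT_2PI / sigma * np.exp(-0.5 * zz * zz)
            amount = wgt * kk * seg / n_quad
            # trilinear splat
            u = (x - origin[0]) / spacing[0] - 0.5
            v = (y - origin[1]) / spacing[1] - 0.5
            w3 = (z - origin[2]) / spacing[2] - 0.5
            i0 = int(np.floor(u))
            j0 = int(np.floor(v))
            k0 = int(np.floor(w3))
            fu = u - i0
            fv = v - j0
            fw = w3 - k0
            for di in range(2):
                ii = i0 + di
                if ii < 0 or ii >= nx:
                    continue
                wi = fu if di == 1 else 1.0 - fu
                for dj in range(2):
                    jj = j0 + dj
                    if jj < 0 or jj >= ny:
                        continue
                    wj = fv if dj == 1 else 1.0 - fv
                    for dk in range(2):
                        kk2 = k0 + dk
                        if kk2 < 0 or kk2 >= nz:
                            continue
                        wk = fw if dk == 1 else 1.0 - fw
                        vals_out[ii, jj, kk2] += amount * wi * wj * wk


@njit(cache=True)
def sample_trilinear_density(vals, origin, spacing, n, cell_cdf, cell_index, seed):
    """Draw ``n`` points from the trilinear density defined by the grid.

    ``cell_cdf``/``cell_index`` describe the discrete distribution over
    interpolation cells (corner-mean weighted); within a cell, rejection
    sampling against the trilinear density is exact.
    """
    np.random.seed(seed)
    nx, ny, nz = vals.shape
    out = np.empty((n, 3))
    for m in range(n):
        r = np.random.random()
        # binary search in cdf
        lo = 0
        hi = cell_cdf.shape[0] - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if cell_cdf[mid] < r:
                lo = mid + 1
            else:
                hi = mid
        idx = cell_index[lo]
        # cell (i, j, k) spans voxel centres i..i+1 etc.
        k = idx % (nz - 1)
        j = (idx // (nz - 1)) % (ny - 1)
        i = idx // ((nz - 1) * (ny - 1))
        vmax = 0.0
        for di in range(2):
            for dj in range(2):
                for dk in range(2):
                    val = vals[i + di, j + dj, k + dk]
                    if val > vmax:
                        vmax = val
        while True:
            fu = np.random.random()
            fv = np.random.random()
            fw = np.random.random()
            val = 0.0
            for di in range(2):
                wi = fu if di == 1 else 1.0 - fu
                for dj in range(2):
                    wj = fv if dj == 1 else 1.0 - fv
                    for dk in range(2):
                        wk = fw if dk == 1 else 1.0 - fw
                        val += wi * wj * wk * vals[i + di, j + dj, k + dk]
            if vmax <= 0.0 or np.random.random() * vmax <= val:
                break
        out[m, 0] = origin[0] + (i + 0.5 + fu) * spacing[0]
        out[m, 1] = origin[1] + (j + 0.5 + fv) * spacing[1]
        out[m, 2] = origin[2] + (k + 0.5 + fw) * spacing[2]
    return out
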