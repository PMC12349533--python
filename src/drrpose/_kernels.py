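"""Optional numba-accelerated ray-casting kernel.

The kernel is numerically identical to the pure-numpy path in
:mod:`drrpose.drr` (same sample positions, same trilinear weighting, same
accumulation rule); it only removes interpreter overhead.  If numba is not
installed the package silently falls back to numpy.
"""

from __future__ import annotations

try:
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    numba = None
    HAVE_NUMBA = False


def _raycast_py(vol, origin, spacing, src, dirs, tmax, step, out):
    # Reference implementation of the fused kernel; jitted when numba is
    # available.  vol indexed [i, j, k] ~ (x, y, z).
    npix = dirs.shape[0]
    nx, ny, nz = vol.shape
    hx = origin[0] + spacing[0] * (nx - 1)
    hy = origin[1] + spacing[1] * (ny - 1)
    hz = origin[2] + spacing[2] * (nz - 1)
    for p in range(npix):
        dx, dy, dz = dirs[p, 0], dirs[p, 1], dirs[p, 2]
        tn = 0.0
        tf = tmax[p]
        ok = True
        for ax in range(3):
            d = dirs[p, ax]
            s = src[ax]
            lo = origin[ax]
            hi = hx if ax == 0 else (hy if ax == 1 else hz)
            if d == 0.0:
                if s < lo or s > hi:
                    ok = False
                    break
            else:
                t0 = (lo - s) / d
                t1 = (hi - s) / d
                if t0 > t1:
                    t0, t1 = t1, t0
                if t0 > tn:
                    tn = t0
                if t1 < tf:
                    tf = t1
        acc = 0.0
        if ok and tf > tn:
            n = int((tf - tn) / step)
            for k in range(n):
                t = tn + (k + 0.5) * step
                px = src[0] + t * dx
                py = src[1] + t * dy
                pz = src[2] + t * dz
                cx = (px - origin[0]) / spacing[0]
                cy = (py - origin[1]) / spacing[1]
                cz = (pz - origin[2]) / spacing[2]
                if (
                    cx < 0.0
                    or cy < 0.0
                    or cz < 0.0
                    or cx > nx - 1
                    or cy > ny - 1
                    or cz > nz - 1
                ):
                    continue
                i0 = int(cx)
                j0 = int(cy)
                k0 = int(cz)
                if i0 > nx - 2:
                    i0 = nx - 2
                if j0 > ny - 2:
                    j0 = ny - 2
                if k0 > nz - 2:
                    k0 = nz - 2
                fx = cx - i0
                fy = cy - j0
                fz = cz - k0
                c00 = vol[i0, j0, k0] * (1 - fx) + vol[i0 + 1, j0, k0] * fx
                c10 = vol[i0, j0 + 1, k0] * (1 - fx) + vol[i0 + 1, j0 + 1, k0] * fx
                c01 = vol[i0, j0, k0 + 1] * (1 - fx) + vol[i0 + 1, j0, k0 + 1] * fx
                c11 = vol[i0, j0 + 1, k0 + 1] * (1 - fx) + vol[i0 + 1, j0 + 1, k0 + 1] * fx
                c0 = c00 * (1 - fy) + c10 * fy
                c1 = c01 * (1 - fy) + c11 * fy
                acc += c0 * (1 - fz) + c1 * fz
        out[p] = acc * step
    return out


if HAVE_NUMBA:
    raycast = numba.njit(cache=True, fastmath=False)(_raycast_py)
else:  # pragma: no cover
    raycast = _raycast_py
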