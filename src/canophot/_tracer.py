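"""Numba kernels for forward Monte-Carlo ray transport over triangle soups.

Geometry lives in a uniform voxel grid over an axis-aligned box; rays are
walked cell-to-cell (Amanatides-Woo DDA).  On a hit the carried weight splits
into an absorbed part (1-kr-kt), a reflected child sampled from a Beckmann
(Cook-Torrance) lobe and, where kt > 0, a transmitted child sampled from a
Lambertian lobe on the far side.  Children below the termination fraction of
the primary ray weight are discarded (and accounted).  Lateral boundaries are
periodic in canopy mode and absorbing in chamber mode; the z = 0 plane is a
ground with configurable Lambertian reflectance.

A hand-rolled splitmix64/xorshift generator keyed by (seed, ray index) makes
traces bit-reproducible and independent of launch order.
"""

import math

import numpy as np
from numba import njit

_EPS = 1e-9
_T_MIN = 1e-7
_STACK = 512


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _rand(state):
    # xorshift64* step; state is a length-1 uint64 array
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    state[0] = x
    y = (x * np.uint64(0x2545F4914F6CDD1D)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return (np.float64(y >> np.uint64(11))) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _ortho_frame(n):
    # tangent frame around unit vector n
    if abs(n[0]) > 0.9:
        t0, t1, t2 = 0.0, 1.0, 0.0
    else:
        t0, t1, t2 = 1.0, 0.0, 0.0
    ux = t1 * n[2] - t2 * n[1]
    uy = t2 * n[0] - t0 * n[2]
    uz = t0 * n[1] - t1 * n[0]
    ul = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / ul, uy / ul, uz / ul
    vx = n[1] * uz - n[2] * uy
    vy = n[2] * ux - n[0] * uz
    vz = n[0] * uy - n[1] * ux
    return ux, uy, uz, vx, vy, vz


@njit(cache=True, inline="always")
def _cosine_dir(n, state):
    u1 = _rand(state)
    u2 = _rand(state)
    r = math.sqrt(u1)
    phi = 2.0 * math.pi * u2
    x = r * math.cos(phi)
    y = r * math.sin(phi)
    z = math.sqrt(max(0.0, 1.0 - u1))
    ux, uy, uz, vx, vy, vz = _ortho_frame(n)
    return (
        x * ux + y * vx + z * n[0],
        x * uy + y * vy + z * n[1],
        x * uz + y * vz + z * n[2],
    )


@njit(cache=True, inline="always")
def _ct_reflect_dir(n, d, roughness, state):
    """Cook-Torrance lobe: Beckmann half-vector sampling; below-horizon
    outcomes fall back to a cosine-weighted draw about the normal."""
    if roughness < 1e-6:
        dn = d[0] * n[0] + d[1] * n[1] + d[2] * n[2]
        return (d[0] - 2.0 * dn * n[0], d[1] - 2.0 * dn * n[1],
                d[2] - 2.0 * dn * n[2])
    for _ in range(4):
        u1 = _rand(state)
        u2 = _rand(state)
        tan2 = -roughness * roughness * math.log(max(1.0 - u1, 1e-12))
        c = 1.0 / math.sqrt(1.0 + tan2)
        s = math.sqrt(max(0.0, 1.0 - c * c))
        phi = 2.0 * math.pi * u2
        ux, uy, uz, vx, vy, vz = _ortho_frame(n)
        hx = s * math.cos(phi) * ux + s * math.sin(phi) * vx + c * n[0]
        hy = s * math.cos(phi) * uy + s * math.sin(phi) * vy + c * n[1]
        hz = s * math.cos(phi) * uz + s * math.sin(phi) * vz + c * n[2]
        dh = d[0] * hx + d[1] * hy + d[2] * hz
        ox = d[0] - 2.0 * dh * hx
        oy = d[1] - 2.0 * dh * hy
        oz = d[2] - 2.0 * dh * hz
        if ox * n[0] + oy * n[1] + oz * n[2] > 1e-6:
            return ox, oy, oz
    return _cosine_dir(n, state)


@njit(cache=True, inline="always")
def _hit_tri(v0, e1, e2, i, ox, oy, oz, dx, dy, dz):
    """Moller-Trumbore; returns t or -1."""
    px = dy * e2[i, 2] - dz * e2[i, 1]
    py = dz * e2[i, 0] - dx * e2[i, 2]
    pz = dx * e2[i, 1] - dy * e2[i, 0]
    det = e1[i, 0] * px + e1[i, 1] * py + e1[i, 2] * pz
    if abs(det) < 1e-14:
        return -1.0
    inv = 1.0 / det
    tx = ox - v0[i, 0]
    ty = oy - v0[i, 1]
    tz = oz - v0[i, 2]
    u = (tx * px + ty * py + tz * pz) * inv
    if u < -1e-9 or u > 1.0 + 1e-9:
        return -1.0
    qx = ty * e1[i, 2] - tz * e1[i, 1]
    qy = tz * e1[i, 0] - tx * e1[i, 2]
    qz = tx * e1[i, 1] - ty * e1[i, 0]
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < -1e-9 or u + v > 1.0 + 1e-9:
        return -1.0
    t = (e2[i, 0] * qx + e2[i, 1] * qy + e2[i, 2] * qz) * inv
    if t < _T_MIN:
        return -1.0
    return t


@njit(cache=True)
def build_grid(v0, e1, e2, box_lo, box_hi, nx, ny, nz):
    """CSR lists of triangle indices per voxel cell (by triangle AABB)."""
    ntri = v0.shape[0]
    ncell = nx * ny * nz
    csx = (box_hi[0] - box_lo[0]) / nx
    csy = (box_hi[1] - box_lo[1]) / ny
    csz = (box_hi[2] - box_lo[2]) / nz
    counts = np.zeros(ncell + 1, dtype=np.int64)
    lo_idx = np.empty((ntri, 3), dtype=np.int64)
    hi_idx = np.empty((ntri, 3), dtype=np.int64)
    for i in range(ntri):
        for a in range(3):
            p0 = v0[i, a]
            p1 = v0[i, a] + e1[i, a]
            p2 = v0[i, a] + e2[i, a]
            lo = min(p0, min(p1, p2))
            hi = max(p0, max(p1, p2))
            cs = csx if a == 0 else (csy if a == 1 else csz)
            n = nx if a == 0 else (ny if a == 1 else nz)
            li = int(math.floor((lo - box_lo[a]) / cs))
            hi_i = int(math.floor((hi - box_lo[a]) / cs))
            lo_idx[i, a] = min(max(li, 0), n - 1)
            hi_idx[i, a] = min(max(hi_i, 0), n - 1)
        for ix in range(lo_idx[i, 0], hi_idx[i, 0] + 1):
            for iy in range(lo_idx[i, 1], hi_idx[i, 1] + 1):
                for iz in range(lo_idx[i, 2], hi_idx[i, 2] + 1):
                    counts[(ix * ny + iy) * nz + iz + 1] += 1
    start = np.cumsum(counts)
    items = np.empty(start[-1], dtype=np.int64)
    fill = start[:-1].copy()
    for i in range(ntri):
        for ix in range(lo_idx[i, 0], hi_idx[i, 0] + 1):
            for iy in range(lo_idx[i, 1], hi_idx[i, 1] + 1):
                for iz in range(lo_idx[i, 2], hi_idx[i, 2] + 1):
                    c = (ix * ny + iy) * nz + iz
                    items[fill[c]] = i
                    fill[c] += 1
    return start[:-1], items


@njit(cache=True)
def _nearest_hit(v0, e1, e2, cell_start, cell_items, box_lo, box_hi,
                 nx, ny, nz, periodic, ox, oy, oz, dx, dy, dz):
    """Walk the grid; return (tri_index, t, wrapped ox, oy, oz).

    tri_index -2: left through the top or (non-periodic) a side wall.
    tri_index -3: reached the ground plane z = box_lo[2]; t is the distance.
    """
    lx = box_hi[0] - box_lo[0]
    ly = box_hi[1] - box_lo[1]
    ntri = v0.shape[0]
    # wrap origin laterally into the box
    if periodic:
        ox = box_lo[0] + ((ox - box_lo[0]) % lx)
        oy = box_lo[1] + ((oy - box_lo[1]) % ly)
    # clip to box in z from above
    if oz > box_hi[2]:
        if dz >= 0.0:
            return -2, 0.0, ox, oy, oz
        tz = (box_hi[2] - 1e-9 - oz) / dz
        ox += tz * dx
        oy += tz * dy
        oz = box_hi[2] - 1e-9
        if periodic:
            ox = box_lo[0] + ((ox - box_lo[0]) % lx)
            oy = box_lo[1] + ((oy - box_lo[1]) % ly)
        elif (ox < box_lo[0] or ox > box_hi[0] or
              oy < box_lo[1] or oy > box_hi[1]):
            return -2, 0.0, ox, oy, oz

    travel = 0.0
    for _wrap in range(10000):
        csx = lx / nx
        csy = ly / ny
        csz = (box_hi[2] - box_lo[2]) / nz
        ix = int(math.floor((ox - box_lo[0]) / csx))
        iy = int(math.floor((oy - box_lo[1]) / csy))
        iz = int(math.floor((oz - box_lo[2]) / csz))
        ix = min(max(ix, 0), nx - 1)
        iy = min(max(iy, 0), ny - 1)
        iz = min(max(iz, 0), nz - 1)
        stepx = 1 if dx > 0 else -1
        stepy = 1 if dy > 0 else -1
        stepz = 1 if dz > 0 else -1
        big = 1e30
        tdx = abs(csx / dx) if dx != 0.0 else big
        tdy = abs(csy / dy) if dy != 0.0 else big
        tdz = abs(csz / dz) if dz != 0.0 else big
        if dx > 0:
            tmx = ((ix + 1) * csx + box_lo[0] - ox) / dx
        elif dx < 0:
            tmx = (ix * csx + box_lo[0] - ox) / dx
        else:
            tmx = big
        if dy > 0:
            tmy = ((iy + 1) * csy + box_lo[1] - oy) / dy
        elif dy < 0:
            tmy = (iy * csy + box_lo[1] - oy) / dy
        else:
            tmy = big
        if dz > 0:
            tmz = ((iz + 1) * csz + box_lo[2] - oz) / dz
        elif dz < 0:
            tmz = (iz * csz + box_lo[2] - oz) / dz
        else:
            tmz = big

        while True:
            t_exit = min(tmx, min(tmy, tmz))
            # test triangles in this cell
            best_t = -1.0
            best_i = -1
            if ntri > 0:
                c = (ix * ny + iy) * nz + iz
                s = cell_start[c]
                e = cell_start[c + 1] if c + 1 < cell_start.shape[0] else cell_items.shape[0]
                for k in range(s, e):
                    i = cell_items[k]
                    t = _hit_tri(v0, e1, e2, i, ox, oy, oz, dx, dy, dz)
                    if t > 0.0 and (best_t < 0.0 or t < best_t):
                        best_t = t
                        best_i = i
            if best_i >= 0 and best_t <= t_exit + 1e-9:
                return best_i, best_t, ox, oy, oz
            # step to next cell
            if tmx <= tmy and tmx <= tmz:
                ix += stepx
                tmx += tdx
                if ix < 0 or ix >= nx:
                    if periodic:
                        # wrap: move origin along ray to the boundary, shift
                        tb = t_exit
                        ox2 = ox + tb * dx
                        oy2 = oy + tb * dy
                        oz2 = oz + tb * dz
                        if ix < 0:
                            ox2 += lx
                        else:
                            ox2 -= lx
                        ox, oy, oz = ox2, oy2, oz2
                        travel += tb
                        break  # restart DDA from wrapped origin
                    return -2, 0.0, ox, oy, oz
            elif tmy <= tmz:
                iy += stepy
                tmy += tdy
                if iy < 0 or iy >= ny:
                    if periodic:
                        tb = t_exit
                        ox2 = ox + tb * dx
                        oy2 = oy + tb * dy
                        oz2 = oz + tb * dz
                        if iy < 0:
                            oy2 += ly
                        else:
                            oy2 -= ly
                        ox, oy, oz = ox2, oy2, oz2
                        travel += tb
                        break
                    return -2, 0.0, ox, oy, oz
            else:
                iz += stepz
                tmz += tdz
                if iz < 0:
                    # ground plane
                    tg = (box_lo[2] - oz) / dz
                    return -3, tg, ox, oy, oz
                if iz >= nz:
                    return -2, 0.0, ox, oy, oz
    return -2, 0.0, ox, oy, oz


@njit(cache=True)
def trace_batch(v0, e1, e2, kr, kt, cell_start, cell_items,
                box_lo, box_hi, nx, ny, nz, periodic, ground_rho,
                origins, dirs, weight, threshold, roughness, seed,
                absorbed, incident):
    """Trace one batch of equal-weight rays.

    Returns (ground_absorbed, escaped, discarded) total power.  ``absorbed``
    and ``incident`` accumulate per-triangle power in place.
    """
    nray = origins.shape[0]
    ground_pow = 0.0
    escaped = 0.0
    discarded = 0.0
    sp = np.empty((_STACK, 7))
    state = np.empty(1, dtype=np.uint64)
    nvec = np.empty(3)
    dvec = np.empty(3)
    for r in range(nray):
        state[0] = _mix64(np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
                          ^ np.uint64(r) + np.uint64(0x632BE59BD9B4E019))
        if state[0] == np.uint64(0):
            state[0] = np.uint64(1)
        top = 0
        sp[0, 0] = origins[r, 0]
        sp[0, 1] = origins[r, 1]
        sp[0, 2] = origins[r, 2]
        sp[0, 3] = dirs[r, 0]
        sp[0, 4] = dirs[r, 1]
        sp[0, 5] = dirs[r, 2]
        sp[0, 6] = weight
        top = 1
        while top > 0:
            top -= 1
            ox, oy, oz = sp[top, 0], sp[top, 1], sp[top, 2]
            dx, dy, dz = sp[top, 3], sp[top, 4], sp[top, 5]
            w = sp[top, 6]
            idx, t, ox, oy, oz = _nearest_hit(
                v0, e1, e2, cell_start, cell_items, box_lo, box_hi,
                nx, ny, nz, periodic, ox, oy, oz, dx, dy, dz)
            if idx == -2:
                escaped += w
                continue
            if idx == -3:
                # ground plane
                ground_pow += w * (1.0 - ground_rho)
                wr = w * ground_rho
                if wr > threshold and top < _STACK - 1:
                    hx = ox + t * dx
                    hy = oy + t * dy
                    nvec[0] = 0.0
                    nvec[1] = 0.0
                    nvec[2] = 1.0
                    rx, ry, rz = _cosine_dir(nvec, state)
                    sp[top, 0] = hx
                    sp[top, 1] = hy
                    sp[top, 2] = box_lo[2] + 1e-7
                    sp[top, 3] = rx
                    sp[top, 4] = ry
                    sp[top, 5] = rz
                    sp[top, 6] = wr
                    top += 1
                elif wr > 0.0:
                    discarded += wr
                continue
            # triangle hit
            i = idx
            incident[i] += w
            absorbed[i] += w * (1.0 - kr[i] - kt[i])
            hx = ox + t * dx
            hy = oy + t * dy
            hz = oz + t * dz
            # geometric normal, oriented against the incoming ray
            nvx = e1[i, 1] * e2[i, 2] - e1[i, 2] * e2[i, 1]
            nvy = e1[i, 2] * e2[i, 0] - e1[i, 0] * e2[i, 2]
            nvz = e1[i, 0] * e2[i, 1] - e1[i, 1] * e2[i, 0]
            nl = math.sqrt(nvx * nvx + nvy * nvy + nvz * nvz)
            nvx, nvy, nvz = nvx / nl, nvy / nl, nvz / nl
            if nvx * dx + nvy * dy + nvz * dz > 0.0:
                nvx, nvy, nvz = -nvx, -nvy, -nvz
            # reflected child
            wr = w * kr[i]
            if wr > threshold and top < _STACK - 1:
                nvec[0] = nvx
                nvec[1] = nvy
                nvec[2] = nvz
                dvec[0] = dx
                dvec[1] = dy
                dvec[2] = dz
                rx, ry, rz = _ct_reflect_dir(nvec, dvec, roughness, state)
                sp[top, 0] = hx + 1e-7 * nvx
                sp[top, 1] = hy + 1e-7 * nvy
                sp[top, 2] = hz + 1e-7 * nvz
                sp[top, 3] = rx
                sp[top, 4] = ry
                sp[top, 5] = rz
                sp[top, 6] = wr
                top += 1
            elif wr > 0.0:
                discarded += wr
            # transmitted child (leaves only: kt > 0)
            wt = w * kt[i]
            if wt > threshold and top < _STACK - 1:
                nvec[0] = -nvx
                nvec[1] = -nvy
                nvec[2] = -nvz
                rx, ry, rz = _cosine_dir(nvec, state)
                sp[top, 0] = hx - 1e-7 * nvx
                sp[top, 1] = hy - 1e-7 * nvy
                sp[top, 2] = hz - 1e-7 * nvz
                sp[top, 3] = rx
                sp[top, 4] = ry
                sp[top, 5] = rz
                sp[top, 6] = wt
                top += 1
            elif wt > 0.0:
                discarded += wt
    return ground_pow, escaped, discarded
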