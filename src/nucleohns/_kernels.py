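"""Numba kernels: neighbor search, force evaluation, Langevin velocity-Verlet.

Everything here works on plain arrays so the hot loop stays inside one jitted
function.  Positions are integrated *unwrapped*; the minimum-image convention
(applied pairwise with round(d/L)) is exact for arbitrarily large excursions,
and wrapping/image counters are derived at the Python level when frames are
emitted.

Status codes returned by the integrator / force kernel:
  0 ok, 1 FENE bond overstretched, 2 non-finite coordinate, 3 neighbor-list
  capacity overflow (caller retries with a larger cap).
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_FENE = 1
STATUS_NONFINITE = 2
STATUS_NEIGH_OVERFLOW = 3


def _ziggurat_tables():
    """Layer tables for the 128-layer Marsaglia-Tsang normal ziggurat."""
    R = 3.442619855899
    V = 9.91256303526217e-3
    x = np.zeros(128)
    f = np.zeros(128)
    x[0] = R
    f[0] = np.exp(-0.5 * R * R)
    for i in range(1, 128):
        f[i] = V / x[i - 1] + f[i - 1]
        x[i] = np.sqrt(-2.0 * np.log(f[i])) if f[i] < 1.0 else 0.0
    f[127] = 1.0
    x[127] = 0.0
    return x, f, R, V / f[0]


ZIG_X, ZIG_F, ZIG_R, ZIG_W0 = _ziggurat_tables()


_U64 = np.uint64
_TWO_M53 = 1.1102230246251565e-16  # 2^-53


@njit(cache=True)
def rng_init(seed):
    """xoshiro256+ state from a 64-bit seed via splitmix64."""
    s = np.empty(4, dtype=np.uint64)
    z = _U64(seed)
    for i in range(4):
        z = z + _U64(0x9E3779B97F4A7C15)
        t = z
        t = (t ^ (t >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
        t = (t ^ (t >> _U64(27))) * _U64(0x94D049BB133111EB)
        s[i] = t ^ (t >> _U64(31))
    return s


@njit(cache=True, inline="always")
def _next_u64(s):
    r = s[0] + s[3]
    t = s[1] << _U64(17)
    s[2] ^= s[0]
    s[3] ^= s[1]
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    s[3] = (s[3] << _U64(45)) | (s[3] >> _U64(19))
    return r


@njit(cache=True, inline="always")
def _next_unit(s):
    """Uniform in (0, 1)."""
    return (float(_next_u64(s) >> _U64(11)) + 0.5) * _TWO_M53


@njit(cache=True, fastmath=True)
def _zig_normal(s):
    """One standard-normal draw (128-layer ziggurat over xoshiro256+).

    A single u64 supplies the layer index (7 bits), the sign (1 bit) and
    the 53-bit mantissa uniform, so the common path costs one RNG step."""
    while True:
        x = _next_u64(s)
        lay = int(x & _U64(127))
        sign = -1.0 if (x >> _U64(7)) & _U64(1) else 1.0
        u = float(x >> _U64(11)) * _TWO_M53
        if lay == 0:
            z = u * ZIG_W0
            if z < ZIG_X[0]:
                return sign * z
            while True:
                xx = -np.log(_next_unit(s)) / ZIG_R
                yy = -np.log(_next_unit(s))
                if yy + yy > xx * xx:
                    return sign * (ZIG_R + xx)
        else:
            z = u * ZIG_X[lay - 1]
            if z < ZIG_X[lay]:
                return sign * z
            y = ZIG_F[lay - 1] + _next_unit(s) * (ZIG_F[lay] - ZIG_F[lay - 1])
            if y < np.exp(-0.5 * z * z):
                return sign * z


@njit(cache=True, fastmath=True)
def _fill_normals(buf, nval, s):
    for k in range(nval):
        buf[k] = _zig_normal(s)


@njit(cache=True, fastmath=True)
def _pick_ncell(L, rlist, n):
    """Cell grid resolution: cells no smaller than rlist, and no more than
    ~8 cells per particle (sparse grids waste rebuild time)."""
    ncell = int(L / rlist)
    cmax = int(np.cbrt(8.0 * max(n, 1))) + 1
    if ncell > cmax:
        ncell = cmax
    return ncell


@njit(cache=True, fastmath=True)
def _build_neighbors(pos, L, rlist, neigh_idx, neigh_cnt):
    """Half (j > i) Verlet list within rlist, via cell binning.

    Falls back to an all-pairs scan when the box holds fewer than 3 cells
    per dimension.  Returns STATUS_NEIGH_OVERFLOW if any particle exceeds
    the list capacity.
    """
    n = pos.shape[0]
    cap = neigh_idx.shape[1]
    rlist2 = rlist * rlist
    neigh_cnt[:] = 0

    ncell = _pick_ncell(L, rlist, n)
    if ncell < 3 or n < 64:
        for i in range(n):
            xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
            for j in range(i + 1, n):
                dx = xi - pos[j, 0]
                dy = yi - pos[j, 1]
                dz = zi - pos[j, 2]
                dx -= L * np.rint(dx / L)
                dy -= L * np.rint(dy / L)
                dz -= L * np.rint(dz / L)
                if dx * dx + dy * dy + dz * dz <= rlist2:
                    c = neigh_cnt[i]
                    if c >= cap:
                        return STATUS_NEIGH_OVERFLOW
                    neigh_idx[i, c] = j
                    neigh_cnt[i] = c + 1
        return STATUS_OK

    cell_of = np.empty(n, dtype=np.int64)
    ncell3 = ncell * ncell * ncell
    count = np.zeros(ncell3 + 1, dtype=np.int64)
    inv = ncell / L
    for i in range(n):
        ix = int((pos[i, 0] - L * np.floor(pos[i, 0] / L)) * inv)
        iy = int((pos[i, 1] - L * np.floor(pos[i, 1] / L)) * inv)
        iz = int((pos[i, 2] - L * np.floor(pos[i, 2] / L)) * inv)
        if ix >= ncell:
            ix = ncell - 1
        if iy >= ncell:
            iy = ncell - 1
        if iz >= ncell:
            iz = ncell - 1
        c = ix + ncell * (iy + ncell * iz)
        cell_of[i] = c
        count[c + 1] += 1
    for c in range(ncell3):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int64)
    fill = count[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    for i in range(n):
        ci = cell_of[i]
        cx = ci % ncell
        cy = (ci // ncell) % ncell
        cz = ci // (ncell * ncell)
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        for ox in range(-1, 2):
            jx = (cx + ox) % ncell
            for oy in range(-1, 2):
                jy = (cy + oy) % ncell
                for oz in range(-1, 2):
                    jz = (cz + oz) % ncell
                    cj = jx + ncell * (jy + ncell * jz)
                    for k in range(count[cj], count[cj + 1]):
                        j = order[k]
                        if j <= i:
                            continue
                        dx = xi - pos[j, 0]
                        dy = yi - pos[j, 1]
                        dz = zi - pos[j, 2]
                        dx -= L * np.rint(dx / L)
                        dy -= L * np.rint(dy / L)
                        dz -= L * np.rint(dz / L)
                        if dx * dx + dy * dy + dz * dz <= rlist2:
                            c = neigh_cnt[i]
                            if c >= cap:
                                return STATUS_NEIGH_OVERFLOW
                            neigh_idx[i, c] = j
                            neigh_cnt[i] = c + 1
    return STATUS_OK


@njit(cache=True)
def insert_spheres(
    n_insert, L, existing_pos, min_d_existing, min_d_self, seed, max_trials
):
    """Random sequential insertion of ``n_insert`` points in a periodic cube.

    Each trial point must sit at least ``min_d_existing[k]`` away from
    existing point k (minimum image) and ``min_d_self`` away from previously
    inserted points (checked through a cell grid).  Returns (points,
    n_placed); n_placed < n_insert signals a packing failure.
    """
    np.random.seed(seed)
    out = np.zeros((n_insert, 3))
    n_exist = existing_pos.shape[0]

    ncell = max(1, int(L / max(min_d_self, 1e-9)))
    if ncell > 64:
        ncell = 64
    cell_cap = max(16, 8 * n_insert // max(ncell**3, 1) + 8)
    grid = -np.ones((ncell, ncell, ncell, cell_cap), dtype=np.int32)
    gcnt = np.zeros((ncell, ncell, ncell), dtype=np.int32)
    inv = ncell / L
    d2_self = min_d_self * min_d_self

    placed = 0
    trials = 0
    while placed < n_insert and trials < max_trials:
        trials += 1
        x = np.random.random() * L
        y = np.random.random() * L
        z = np.random.random() * L
        ok = True
        for k in range(n_exist):
            dx = x - existing_pos[k, 0]
            dy = y - existing_pos[k, 1]
            dz = z - existing_pos[k, 2]
            dx -= L * np.rint(dx / L)
            dy -= L * np.rint(dy / L)
            dz -= L * np.rint(dz / L)
            if dx * dx + dy * dy + dz * dz < min_d_existing[k] ** 2:
                ok = False
                break
        if not ok:
            continue
        ix = min(int(x * inv), ncell - 1)
        iy = min(int(y * inv), ncell - 1)
        iz = min(int(z * inv), ncell - 1)
        reach = 1 if ncell >= 3 else ncell  # small grids: scan everything
        for ox in range(-reach, reach + 1):
            jx = (ix + ox) % ncell
            for oy in range(-reach, reach + 1):
                jy = (iy + oy) % ncell
                for oz in range(-reach, reach + 1):
                    jz = (iz + oz) % ncell
                    for m in range(gcnt[jx, jy, jz]):
                        j = grid[jx, jy, jz, m]
                        dx = x - out[j, 0]
                        dy = y - out[j, 1]
                        dz = z - out[j, 2]
                        dx -= L * np.rint(dx / L)
                        dy -= L * np.rint(dy / L)
                        dz -= L * np.rint(dz / L)
                        if dx * dx + dy * dy + dz * dz < d2_self:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        out[placed, 0] = x
        out[placed, 1] = y
        out[placed, 2] = z
        c = gcnt[ix, iy, iz]
        if c < cell_cap:
            grid[ix, iy, iz, c] = placed
            gcnt[ix, iy, iz] = c + 1
        placed += 1
    return out, placed


@njit(cache=True, fastmath=True)
def _forces(
    pos, species, L,
    eps, sig2, rc2, shift, act,
    fene_bonds, fene_k0, fene_r0,
    harm_bonds, harm_k, harm_r0,
    angles, angle_k,
    neigh_idx, neigh_cnt,
    f,
):
    """Conservative forces and total potential energy.

    Nonbonded: truncated-shifted LJ over the Verlet list (half list, both
    sides accumulated).  Bonded: FENE ring bonds, harmonic radial bonds
    (H-NS core-patch and anchors), and harmonic patch-core-patch angles
    centred at 180 degrees.

    Returns (potential_energy, status, offending_bond_index).
    """
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    pe = 0.0

    for i in range(n):
        si = species[i]
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        fxi = 0.0
        fyi = 0.0
        fzi = 0.0
        for kk in range(neigh_cnt[i]):
            j = neigh_idx[i, kk]
            sj = species[j]
            if not act[si, sj]:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            dx -= L * np.rint(dx / L)
            dy -= L * np.rint(dy / L)
            dz -= L * np.rint(dz / L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2[si, sj]:
                continue
            s2 = sig2[si, sj] / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            pe += 4.0 * eps[si, sj] * (s12 - s6) - shift[si, sj]
            ff = 24.0 * eps[si, sj] * (2.0 * s12 - s6) / r2
            fxi += ff * dx
            fyi += ff * dy
            fzi += ff * dz
            f[j, 0] -= ff * dx
            f[j, 1] -= ff * dy
            f[j, 2] -= ff * dz
        f[i, 0] += fxi
        f[i, 1] += fyi
        f[i, 2] += fzi

    r0sq = fene_r0 * fene_r0
    for b in range(fene_bonds.shape[0]):
        i = fene_bonds[b, 0]
        j = fene_bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= L * np.rint(dx / L)
        dy -= L * np.rint(dy / L)
        dz -= L * np.rint(dz / L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r0sq:
            return pe, STATUS_FENE, b
        g = 1.0 - r2 / r0sq
        pe += -0.5 * fene_k0 * r0sq * np.log(g)
        ff = -fene_k0 / g
        f[i, 0] += ff * dx
        f[i, 1] += ff * dy
        f[i, 2] += ff * dz
        f[j, 0] -= ff * dx
        f[j, 1] -= ff * dy
        f[j, 2] -= ff * dz

    for b in range(harm_bonds.shape[0]):
        i = harm_bonds[b, 0]
        j = harm_bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= L * np.rint(dx / L)
        dy -= L * np.rint(dy / L)
        dz -= L * np.rint(dz / L)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - harm_r0[b]
        pe += harm_k[b] * dr * dr
        if r > 1e-12:
            ff = -2.0 * harm_k[b] * dr / r
            f[i, 0] += ff * dx
            f[i, 1] += ff * dy
            f[i, 2] += ff * dz
            f[j, 0] -= ff * dx
            f[j, 1] -= ff * dy
            f[j, 2] -= ff * dz

    for b in range(angles.shape[0]):
        p1 = angles[b, 0]
        c = angles[b, 1]
        p2 = angles[b, 2]
        ax = pos[p1, 0] - pos[c, 0]
        ay = pos[p1, 1] - pos[c, 1]
        az = pos[p1, 2] - pos[c, 2]
        bx = pos[p2, 0] - pos[c, 0]
        by = pos[p2, 1] - pos[c, 1]
        bz = pos[p2, 2] - pos[c, 2]
        ax -= L * np.rint(ax / L)
        ay -= L * np.rint(ay / L)
        az -= L * np.rint(az / L)
        bx -= L * np.rint(bx / L)
        by -= L * np.rint(by / L)
        bz -= L * np.rint(bz / L)
        ra = np.sqrt(ax * ax + ay * ay + az * az)
        rb = np.sqrt(bx * bx + by * by + bz * bz)
        ct = (ax * bx + ay * by + az * bz) / (ra * rb)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        dth = theta - np.pi
        pe += angle_k * dth * dth
        st = np.sqrt(1.0 - ct * ct)
        # coef = 2 k (theta - pi) / sin(theta); finite limit -2k at theta=pi
        if st < 1e-8:
            coef = -2.0 * angle_k
        else:
            coef = 2.0 * angle_k * dth / st
        inv_ab = 1.0 / (ra * rb)
        inv_a2 = 1.0 / (ra * ra)
        inv_b2 = 1.0 / (rb * rb)
        f1x = coef * (bx * inv_ab - ct * ax * inv_a2)
        f1y = coef * (by * inv_ab - ct * ay * inv_a2)
        f1z = coef * (bz * inv_ab - ct * az * inv_a2)
        f2x = coef * (ax * inv_ab - ct * bx * inv_b2)
        f2y = coef * (ay * inv_ab - ct * by * inv_b2)
        f2z = coef * (az * inv_ab - ct * bz * inv_b2)
        f[p1, 0] += f1x
        f[p1, 1] += f1y
        f[p1, 2] += f1z
        f[p2, 0] += f2x
        f[p2, 1] += f2y
        f[p2, 2] += f2z
        f[c, 0] -= f1x + f2x
        f[c, 1] -= f1y + f2y
        f[c, 2] -= f1z + f2z

    return pe, STATUS_OK, -1


@njit(cache=True, fastmath=True)
def _max_disp2(pos, ref):
    m = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > m:
            m = d2
    return m


@njit(cache=True, fastmath=True)
def integrate(
    pos, vel, species, mass, L,
    eps, sig2, rc2, shift, act,
    fene_bonds, fene_k0, fene_r0,
    harm_bonds, harm_k, harm_r0,
    angles, angle_k,
    dt, gamma, kT, thermostat, seed,
    n_steps, sample_every, dmax,
    rlist, out_pos, out_vel, out_pe, out_ke,
):
    """Langevin (or NVE) velocity-Verlet propagation.

    With ``thermostat``, a friction force -gamma*m*v and Gaussian noise of
    per-component variance 2*m*gamma*kT/dt enter the force at each
    evaluation (impulse-style Langevin, as in common MD engines).  With
    ``dmax > 0`` per-step displacements are capped (push-off warmup).

    Samples are taken every ``sample_every`` steps (step counts 1-based, so
    n_steps/sample_every frames result); unwrapped positions plus potential
    and kinetic energy are stored.  Returns (status, n_sampled, mean_T,
    bad_index) where mean_T averages the instantaneous kinetic temperature
    over all steps.
    """
    n = pos.shape[0]
    rs = rng_init(seed)
    f = np.zeros((n, 3))
    cap = 96
    neigh_idx = np.zeros((n, cap), dtype=np.int32)
    neigh_cnt = np.zeros(n, dtype=np.int32)
    ref = pos.copy()
    has_nonbonded = rc2.max() > 0.0
    skin2 = 0.25 * (rlist - np.sqrt(rc2.max())) ** 2 if has_nonbonded else 1e30

    if has_nonbonded:
        st = _build_neighbors(pos, L, rlist, neigh_idx, neigh_cnt)
        while st == STATUS_NEIGH_OVERFLOW:
            cap *= 2
            neigh_idx = np.zeros((n, cap), dtype=np.int32)
            st = _build_neighbors(pos, L, rlist, neigh_idx, neigh_cnt)

    pe, st, bad = _forces(
        pos, species, L, eps, sig2, rc2, shift, act,
        fene_bonds, fene_k0, fene_r0, harm_bonds, harm_k, harm_r0,
        angles, angle_k, neigh_idx, neigh_cnt, f,
    )
    if st != STATUS_OK:
        return st, 0, 0.0, bad
    noise_amp = np.sqrt(2.0 * gamma * kT / dt)
    noise = np.empty(3 * n)
    if thermostat:
        _fill_normals(noise, 3 * n, rs)
        for i in range(n):
            amp = noise_amp * np.sqrt(mass[i])
            for d in range(3):
                f[i, d] += -gamma * mass[i] * vel[i, d] + amp * noise[3 * i + d]

    t_acc = 0.0
    nsamp = 0
    for step in range(1, n_steps + 1):
        for i in range(n):
            h = 0.5 * dt / mass[i]
            vel[i, 0] += h * f[i, 0]
            vel[i, 1] += h * f[i, 1]
            vel[i, 2] += h * f[i, 2]
            dx = vel[i, 0] * dt
            dy = vel[i, 1] * dt
            dz = vel[i, 2] * dt
            if dmax > 0.0:
                dn = np.sqrt(dx * dx + dy * dy + dz * dz)
                if dn > dmax:
                    s = dmax / dn
                    dx *= s
                    dy *= s
                    dz *= s
            pos[i, 0] += dx
            pos[i, 1] += dy
            pos[i, 2] += dz

        if has_nonbonded and _max_disp2(pos, ref) > skin2:
            st = _build_neighbors(pos, L, rlist, neigh_idx, neigh_cnt)
            while st == STATUS_NEIGH_OVERFLOW:
                cap *= 2
                neigh_idx = np.zeros((n, cap), dtype=np.int32)
                st = _build_neighbors(pos, L, rlist, neigh_idx, neigh_cnt)
            ref[:, :] = pos

        pe, st, bad = _forces(
            pos, species, L, eps, sig2, rc2, shift, act,
            fene_bonds, fene_k0, fene_r0, harm_bonds, harm_k, harm_r0,
            angles, angle_k, neigh_idx, neigh_cnt, f,
        )
        if st != STATUS_OK:
            return st, nsamp, t_acc / max(step, 1), bad
        if thermostat:
            _fill_normals(noise, 3 * n, rs)
            for i in range(n):
                amp = noise_amp * np.sqrt(mass[i])
                for d in range(3):
                    f[i, d] += -gamma * mass[i] * vel[i, d] + amp * noise[3 * i + d]

        ke = 0.0
        for i in range(n):
            h = 0.5 * dt / mass[i]
            vel[i, 0] += h * f[i, 0]
            vel[i, 1] += h * f[i, 1]
            vel[i, 2] += h * f[i, 2]
            ke += 0.5 * mass[i] * (
                vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            )
        t_acc += 2.0 * ke / (3.0 * n)

        if not np.isfinite(pe) or not np.isfinite(ke):
            return STATUS_NONFINITE, nsamp, t_acc / step, -1

        if sample_every > 0 and step % sample_every == 0:
            out_pos[nsamp, :, :] = pos
            out_vel[nsamp, :, :] = vel
            out_pe[nsamp] = pe
            out_ke[nsamp] = ke
            nsamp += 1

    return STATUS_OK, nsamp, t_acc / max(n_steps, 1), -1
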