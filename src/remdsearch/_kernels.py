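"""Optional numba-compiled inner loops.

The numpy implementations in :mod:`remdsearch.forcefield` and
:mod:`remdsearch.dynamics` are the reference; when numba is importable the
fused kernels here evaluate the same mathematics in single passes over the
term lists (no temporaries), which is what makes million-step Langevin
runs and 24-replica ensembles practical on one core.  Equivalence of the
two paths is asserted by the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    AVAILABLE = True
except ImportError:  # pragma: no cover - exercised only without numba
    AVAILABLE = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def ff_eval(x, bond_idx, bond_k, bond_r0,
            angle_idx, angle_k, angle_t0,
            dih_idx, dih_k, dih_n, dih_g,
            pair_i, pair_j, eps4, sig2, qq,
            rs2, rc2, box, periodic, overlap2):
    """Bond + angle + dihedral + LJ/Coulomb energy and gradient.

    x: (B, N, 3).  Returns (energies (B, 5) ordered bond/angle/dihedral/
    LJ/Coulomb, grad (B, N, 3), status) where status >= 0 flags the pair
    index of an overlap and -2 a degenerate torsion.
    """
    b_sz, n, _ = x.shape
    energies = np.zeros((b_sz, 5))
    grad = np.zeros((b_sz, n, 3))
    rc = np.sqrt(rc2)
    inv_span = 1.0 / (rc2 - rs2)
    status = -1
    for b in range(b_sz):
        xb = x[b]
        gb = grad[b]
        # bonds
        e = 0.0
        for t in range(bond_idx.shape[0]):
            i = bond_idx[t, 0]
            j = bond_idx[t, 1]
            dx = xb[i, 0] - xb[j, 0]
            dy = xb[i, 1] - xb[j, 1]
            dz = xb[i, 2] - xb[j, 2]
            if periodic:
                dx -= box[0] * np.round(dx / box[0])
                dy -= box[1] * np.round(dy / box[1])
                dz -= box[2] * np.round(dz / box[2])
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            dr = r - bond_r0[t]
            e += bond_k[t] * dr * dr
            c = 2.0 * bond_k[t] * dr / r
            gb[i, 0] += c * dx
            gb[i, 1] += c * dy
            gb[i, 2] += c * dz
            gb[j, 0] -= c * dx
            gb[j, 1] -= c * dy
            gb[j, 2] -= c * dz
        energies[b, 0] = e
        # angles
        e = 0.0
        for t in range(angle_idx.shape[0]):
            i = angle_idx[t, 0]
            j = angle_idx[t, 1]
            k = angle_idx[t, 2]
            ux = xb[i, 0] - xb[j, 0]
            uy = xb[i, 1] - xb[j, 1]
            uz = xb[i, 2] - xb[j, 2]
            vx = xb[k, 0] - xb[j, 0]
            vy = xb[k, 1] - xb[j, 1]
            vz = xb[k, 2] - xb[j, 2]
            if periodic:
                ux -= box[0] * np.round(ux / box[0])
                uy -= box[1] * np.round(uy / box[1])
                uz -= box[2] * np.round(uz / box[2])
                vx -= box[0] * np.round(vx / box[0])
                vy -= box[1] * np.round(vy / box[1])
                vz -= box[2] * np.round(vz / box[2])
            nu = np.sqrt(ux * ux + uy * uy + uz * uz)
            nv = np.sqrt(vx * vx + vy * vy + vz * vz)
            ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            theta = np.arccos(ct)
            dt = theta - angle_t0[t]
            e += angle_k[t] * dt * dt
            st = np.sqrt(max(1.0 - ct * ct, 1e-14))
            coef = 2.0 * angle_k[t] * dt
            ci = coef / (nu * st)
            ck = coef / (nv * st)
            gix = ci * (ct * ux / nu - vx / nv)
            giy = ci * (ct * uy / nu - vy / nv)
            giz = ci * (ct * uz / nu - vz / nv)
            gkx = ck * (ct * vx / nv - ux / nu)
            gky = ck * (ct * vy / nv - uy / nu)
            gkz = ck * (ct * vz / nv - uz / nu)
            gb[i, 0] += gix
            gb[i, 1] += giy
            gb[i, 2] += giz
            gb[k, 0] += gkx
            gb[k, 1] += gky
            gb[k, 2] += gkz
            gb[j, 0] -= gix + gkx
            gb[j, 1] -= giy + gky
            gb[j, 2] -= giz + gkz
        energies[b, 1] = e
        # dihedrals
        e = 0.0
        for t in range(dih_idx.shape[0]):
            ia = dih_idx[t, 0]
            ib = dih_idx[t, 1]
            ic = dih_idx[t, 2]
            id_ = dih_idx[t, 3]
            b1x = xb[ib, 0] - xb[ia, 0]
            b1y = xb[ib, 1] - xb[ia, 1]
            b1z = xb[ib, 2] - xb[ia, 2]
            b2x = xb[ic, 0] - xb[ib, 0]
            b2y = xb[ic, 1] - xb[ib, 1]
            b2z = xb[ic, 2] - xb[ib, 2]
            b3x = xb[id_, 0] - xb[ic, 0]
            b3y = xb[id_, 1] - xb[ic, 1]
            b3z = xb[id_, 2] - xb[ic, 2]
            if periodic:
                b1x -= box[0] * np.round(b1x / box[0])
                b1y -= box[1] * np.round(b1y / box[1])
                b1z -= box[2] * np.round(b1z / box[2])
                b2x -= box[0] * np.round(b2x / box[0])
                b2y -= box[1] * np.round(b2y / box[1])
                b2z -= box[2] * np.round(b2z / box[2])
                b3x -= box[0] * np.round(b3x / box[0])
                b3y -= box[1] * np.round(b3y / box[1])
                b3z -= box[2] * np.round(b3z / box[2])
            n1x = b1y * b2z - b1z * b2y
            n1y = b1z * b2x - b1x * b2z
            n1z = b1x * b2y - b1y * b2x
            n2x = b2y * b3z - b2z * b3y
            n2y = b2z * b3x - b2x * b3z
            n2z = b2x * b3y - b2y * b3x
            nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            n1sq = n1x * n1x + n1y * n1y + n1z * n1z
            n2sq = n2x * n2x + n2y * n2y + n2z * n2z
            if n1sq < 1e-18 or n2sq < 1e-18:
                status = -2
                continue
            cxx = n1y * n2z - n1z * n2y
            cxy = n1z * n2x - n1x * n2z
            cxz = n1x * n2y - n1y * n2x
            y = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
            xdot = n1x * n2x + n1y * n2y + n1z * n2z
            phi = np.arctan2(y, xdot)
            arg = dih_n[t] * phi - dih_g[t]
            e += 0.5 * dih_k[t] * (1.0 + np.cos(arg))
            dedphi = -0.5 * dih_k[t] * dih_n[t] * np.sin(arg)
            fa = -nb2 / n1sq
            dax = fa * n1x
            day = fa * n1y
            daz = fa * n1z
            fd = nb2 / n2sq
            ddx = fd * n2x
            ddy = fd * n2y
            ddz = fd * n2z
            s = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
            tt = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
            dbx = -(1.0 + s) * dax + tt * ddx
            dby = -(1.0 + s) * day + tt * ddy
            dbz = -(1.0 + s) * daz + tt * ddz
            dcx = -(dax + dbx + ddx)
            dcy = -(day + dby + ddy)
            dcz = -(daz + dbz + ddz)
            gb[ia, 0] += dedphi * dax
            gb[ia, 1] += dedphi * day
            gb[ia, 2] += dedphi * daz
            gb[ib, 0] += dedphi * dbx
            gb[ib, 1] += dedphi * dby
            gb[ib, 2] += dedphi * dbz
            gb[ic, 0] += dedphi * dcx
            gb[ic, 1] += dedphi * dcy
            gb[ic, 2] += dedphi * dcz
            gb[id_, 0] += dedphi * ddx
            gb[id_, 1] += dedphi * ddy
            gb[id_, 2] += dedphi * ddz
        energies[b, 2] = e
        # nonbonded
        e_lj = 0.0
        e_q = 0.0
        for t in range(pair_i.shape[0]):
            i = pair_i[t]
            j = pair_j[t]
            dx = xb[i, 0] - xb[j, 0]
            dy = xb[i, 1] - xb[j, 1]
            dz = xb[i, 2] - xb[j, 2]
            if periodic:
                dx -= box[0] * np.round(dx / box[0])
                dy -= box[1] * np.round(dy / box[1])
                dz -= box[2] * np.round(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < overlap2:
                status = t
            if r2 >= rc2:
                continue
            inv_r2 = 1.0 / r2
            sr2 = sig2[t] * inv_r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            elj = eps4[t] * (sr12 - sr6)
            # smoothstep switch in r²
            yv = (rc2 - r2) * inv_span
            if yv > 1.0:
                sw = 1.0
                dsw = 0.0
            else:
                sw = yv * yv * (3.0 - 2.0 * yv)
                dsw = -6.0 * yv * (1.0 - yv) * inv_span
            e_lj += elj * sw
            dlj = eps4[t] * (3.0 * sr6 - 6.0 * sr12) * inv_r2 * sw + elj * dsw
            r = np.sqrt(r2)
            e_q += qq[t] * (1.0 / r - 2.0 / rc + r / rc2)
            dq = -0.5 * qq[t] * (inv_r2 - 1.0 / rc2) / r
            c = 2.0 * (dlj + dq)
            gb[i, 0] += c * dx
            gb[i, 1] += c * dy
            gb[i, 2] += c * dz
            gb[j, 0] -= c * dx
            gb[j, 1] -= c * dy
            gb[j, 2] -= c * dz
        energies[b, 3] = e_lj
        energies[b, 4] = e_q
    return energies, grad, status


@njit(cache=True)
def shake_iterate(x, rref, idx, d0, inv_m, mu, tol, max_iter):
    """Gauss–Seidel SHAKE on (B, N, 3) states; returns iterations or -1."""
    b_sz = x.shape[0]
    c = idx.shape[0]
    worst_it = 0
    for b in range(b_sz):
        xb = x[b]
        rb = rref[b]
        for it in range(max_iter):
            worst = 0.0
            for t in range(c):
                i = idx[t, 0]
                j = idx[t, 1]
                dx = xb[i, 0] - xb[j, 0]
                dy = xb[i, 1] - xb[j, 1]
                dz = xb[i, 2] - xb[j, 2]
                d2 = dx * dx + dy * dy + dz * dz
                diff = abs(np.sqrt(d2) - d0[t]) / d0[t]
                if diff > worst:
                    worst = diff
                if diff <= tol:
                    continue
                rx = rb[t, 0]
                ry = rb[t, 1]
                rz = rb[t, 2]
                dot = dx * rx + dy * ry + dz * rz
                g = (d2 - d0[t] * d0[t]) * mu[t] / (2.0 * dot)
                xb[i, 0] -= g * inv_m[i] * rx
                xb[i, 1] -= g * inv_m[i] * ry
                xb[i, 2] -= g * inv_m[i] * rz
                xb[j, 0] += g * inv_m[j] * rx
                xb[j, 1] += g * inv_m[j] * ry
                xb[j, 2] += g * inv_m[j] * rz
            if worst < tol:
                if it > worst_it:
                    worst_it = it
                break
        else:
            return -1
    return worst_it


@njit(cache=True)
def project_iterate(v, x, idx, inv_m, mu, tol, max_iter):
    """Remove relative velocities along constrained bonds (Gauss–Seidel)."""
    b_sz = v.shape[0]
    c = idx.shape[0]
    for b in range(b_sz):
        vb = v[b]
        xb = x[b]
        for _ in range(max_iter):
            worst = 0.0
            for t in range(c):
                i = idx[t, 0]
                j = idx[t, 1]
                ux = xb[i, 0] - xb[j, 0]
                uy = xb[i, 1] - xb[j, 1]
                uz = xb[i, 2] - xb[j, 2]
                rn = np.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= rn
                uy /= rn
                uz /= rn
                rel = ((vb[i, 0] - vb[j, 0]) * ux
                       + (vb[i, 1] - vb[j, 1]) * uy
                       + (vb[i, 2] - vb[j, 2]) * uz)
                if abs(rel) > worst:
                    worst = abs(rel)
                lam = rel * mu[t]
                vb[i, 0] -= lam * inv_m[i] * ux
                vb[i, 1] -= lam * inv_m[i] * uy
                vb[i, 2] -= lam * inv_m[i] * uz
                vb[j, 0] += lam * inv_m[j] * ux
                vb[j, 1] += lam * inv_m[j] * uy
                vb[j, 2] += lam * inv_m[j] * uz
            if worst < tol:
                break
    return 0
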