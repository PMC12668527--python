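"""Numba update kernels: leapfrog curl updates and CPML corrections.

Field layout (unit Yee cell, array index (i, j, k), pitch d):
Ex at (i+1/2, j, k), Ey at (i, j+1/2, k), Ez at (i, j, k+1/2),
Hx at (i, j+1/2, k+1/2), Hy at (i+1/2, j, k+1/2), Hz at (i+1/2, j+1/2, k).
Outermost tangential E stays zero (PEC wall behind the PML).

The three components of each field are updated in one fused pass per half
step — the update is memory-bandwidth bound, so touching every array once
matters more than arithmetic.  The CPML follows Roden & Gedney with
kappa = 1: each spatial derivative d f/d u near a boundary gains a
recursively updated memory term psi, added with the same coefficient the
raw difference carries in the main update.  psi arrays store raw
differences (not divided by the pitch), so the same cb / chd factors
apply.  The 1-D profile arrays (b, c) are identity outside the absorbing
slabs, letting the kernels skip interior planes cheaply.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True, fastmath=True)
def update_h(Ex, Ey, Ez, Hx, Hy, Hz, chd):
    """One half-step of all H components; chd = dt / (mu0 * pitch)."""
    nx, ny, nz = Ex.shape
    # branch-free bulk: all three components are valid on [0, n-1) per axis
    for i in range(nx - 1):
        for j in range(ny - 1):
            for k in range(nz - 1):
                Hx[i, j, k] += chd * (
                    (Ey[i, j, k + 1] - Ey[i, j, k]) - (Ez[i, j + 1, k] - Ez[i, j, k])
                )
                Hy[i, j, k] += chd * (
                    (Ez[i + 1, j, k] - Ez[i, j, k]) - (Ex[i, j, k + 1] - Ex[i, j, k])
                )
                Hz[i, j, k] += chd * (
                    (Ex[i, j + 1, k] - Ex[i, j, k]) - (Ey[i + 1, j, k] - Ey[i, j, k])
                )
    # remaining boundary faces per component
    for j in range(ny - 1):
        for k in range(nz - 1):
            Hx[nx - 1, j, k] += chd * (
                (Ey[nx - 1, j, k + 1] - Ey[nx - 1, j, k])
                - (Ez[nx - 1, j + 1, k] - Ez[nx - 1, j, k])
            )
    for i in range(nx - 1):
        for k in range(nz - 1):
            Hy[i, ny - 1, k] += chd * (
                (Ez[i + 1, ny - 1, k] - Ez[i, ny - 1, k])
                - (Ex[i, ny - 1, k + 1] - Ex[i, ny - 1, k])
            )
    for i in range(nx - 1):
        for j in range(ny - 1):
            Hz[i, j, nz - 1] += chd * (
                (Ex[i, j + 1, nz - 1] - Ex[i, j, nz - 1])
                - (Ey[i + 1, j, nz - 1] - Ey[i, j, nz - 1])
            )


@numba.njit(cache=True, fastmath=True)
def update_e(Ex, Ey, Ez, Hx, Hy, Hz, ca, cb):
    """One half-step of E with per-cell loss coefficients.

    ca = (1 - s)/(1 + s), cb = (dt/(eps eps0 d))/(1 + s),
    s = sigma dt / (2 eps eps0).
    """
    nx, ny, nz = Ex.shape
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            for k in range(1, nz - 1):
                cav = ca[i, j, k]
                cbv = cb[i, j, k]
                Ex[i, j, k] = cav * Ex[i, j, k] + cbv * (
                    (Hz[i, j, k] - Hz[i, j - 1, k]) - (Hy[i, j, k] - Hy[i, j, k - 1])
                )
                Ey[i, j, k] = cav * Ey[i, j, k] + cbv * (
                    (Hx[i, j, k] - Hx[i, j, k - 1]) - (Hz[i, j, k] - Hz[i - 1, j, k])
                )
                Ez[i, j, k] = cav * Ez[i, j, k] + cbv * (
                    (Hy[i, j, k] - Hy[i - 1, j, k]) - (Hx[i, j, k] - Hx[i, j - 1, k])
                )
    # the bulk loop starts at index 1; Ex[0], Ey[:,0], Ez[:,:,0] are valid
    # interior samples (half-cell off the wall) and are completed here
    for j in range(1, ny - 1):
        for k in range(1, nz - 1):
            Ex[0, j, k] = ca[0, j, k] * Ex[0, j, k] + cb[0, j, k] * (
                (Hz[0, j, k] - Hz[0, j - 1, k]) - (Hy[0, j, k] - Hy[0, j, k - 1])
            )
    for i in range(1, nx - 1):
        for k in range(1, nz - 1):
            Ey[i, 0, k] = ca[i, 0, k] * Ey[i, 0, k] + cb[i, 0, k] * (
                (Hx[i, 0, k] - Hx[i, 0, k - 1]) - (Hz[i, 0, k] - Hz[i - 1, 0, k])
            )
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            Ez[i, j, 0] = ca[i, j, 0] * Ez[i, j, 0] + cb[i, j, 0] * (
                (Hy[i, j, 0] - Hy[i - 1, j, 0]) - (Hx[i, j, 0] - Hx[i, j - 1, 0])
            )


@numba.njit(cache=True, fastmath=True)
def cpml_h(
    Ex, Ey, Ez, Hx, Hy, Hz,
    p_hyx, p_hzx, p_hxy, p_hzy, p_hxz, p_hyz,
    bxh, cxh, byh, cyh, bzh, czh,
    chd,
):
    """CPML memory updates and corrections for the H half-step.

    One loop nest per (component, derivative axis) term, ordered i, j, k
    so the innermost index is always memory-contiguous; interior planes
    where the profile is the identity are skipped.
    """
    nx, ny, nz = Ex.shape
    for i in range(nx - 1):
        if cxh[i] == 0.0 and bxh[i] == 1.0:
            continue
        b = bxh[i]
        c = cxh[i]
        for j in range(ny):  # Hy, d Ez / d x
            for k in range(nz - 1):
                d = Ez[i + 1, j, k] - Ez[i, j, k]
                p_hyx[i, j, k] = b * p_hyx[i, j, k] + c * d
                Hy[i, j, k] += chd * p_hyx[i, j, k]
        for j in range(ny - 1):  # Hz, d Ey / d x
            for k in range(nz):
                d = Ey[i + 1, j, k] - Ey[i, j, k]
                p_hzx[i, j, k] = b * p_hzx[i, j, k] + c * d
                Hz[i, j, k] -= chd * p_hzx[i, j, k]
    for i in range(nx):
        for j in range(ny - 1):
            if cyh[j] == 0.0 and byh[j] == 1.0:
                continue
            b = byh[j]
            c = cyh[j]
            for k in range(nz - 1):  # Hx, d Ez / d y
                d = Ez[i, j + 1, k] - Ez[i, j, k]
                p_hxy[i, j, k] = b * p_hxy[i, j, k] + c * d
                Hx[i, j, k] -= chd * p_hxy[i, j, k]
            if i < nx - 1:
                for k in range(nz):  # Hz, d Ex / d y
                    d = Ex[i, j + 1, k] - Ex[i, j, k]
                    p_hzy[i, j, k] = b * p_hzy[i, j, k] + c * d
                    Hz[i, j, k] += chd * p_hzy[i, j, k]
    for i in range(nx):
        for j in range(ny):
            for k in range(nz - 1):
                if czh[k] == 0.0 and bzh[k] == 1.0:
                    continue
                b = bzh[k]
                c = czh[k]
                if j < ny - 1:  # Hx, d Ey / d z
                    d = Ey[i, j, k + 1] - Ey[i, j, k]
                    p_hxz[i, j, k] = b * p_hxz[i, j, k] + c * d
                    Hx[i, j, k] += chd * p_hxz[i, j, k]
                if i < nx - 1:  # Hy, d Ex / d z
                    d = Ex[i, j, k + 1] - Ex[i, j, k]
                    p_hyz[i, j, k] = b * p_hyz[i, j, k] + c * d
                    Hy[i, j, k] -= chd * p_hyz[i, j, k]


@numba.njit(cache=True, fastmath=True)
def cpml_e(
    Ex, Ey, Ez, Hx, Hy, Hz,
    p_eyx, p_ezx, p_exy, p_ezy, p_exz, p_eyz,
    bxe, cxe, bye, cye, bze, cze,
    cb,
):
    """CPML memory updates and corrections for the E half-step."""
    nx, ny, nz = Ex.shape
    for i in range(1, nx - 1):
        if cxe[i] == 0.0 and bxe[i] == 1.0:
            continue
        b = bxe[i]
        c = cxe[i]
        for j in range(ny - 1):  # Ey, d Hz / d x
            for k in range(1, nz - 1):
                d = Hz[i, j, k] - Hz[i - 1, j, k]
                p_eyx[i, j, k] = b * p_eyx[i, j, k] + c * d
                Ey[i, j, k] -= cb[i, j, k] * p_eyx[i, j, k]
        for j in range(1, ny - 1):  # Ez, d Hy / d x
            for k in range(nz - 1):
                d = Hy[i, j, k] - Hy[i - 1, j, k]
                p_ezx[i, j, k] = b * p_ezx[i, j, k] + c * d
                Ez[i, j, k] += cb[i, j, k] * p_ezx[i, j, k]
    for i in range(nx - 1):
        for j in range(1, ny - 1):
            if cye[j] == 0.0 and bye[j] == 1.0:
                continue
            b = bye[j]
            c = cye[j]
            for k in range(1, nz - 1):  # Ex, d Hz / d y
                d = Hz[i, j, k] - Hz[i, j - 1, k]
                p_exy[i, j, k] = b * p_exy[i, j, k] + c * d
                Ex[i, j, k] += cb[i, j, k] * p_exy[i, j, k]
            if i >= 1:
                for k in range(nz - 1):  # Ez, d Hx / d y
                    d = Hx[i, j, k] - Hx[i, j - 1, k]
                    p_ezy[i, j, k] = b * p_ezy[i, j, k] + c * d
                    Ez[i, j, k] -= cb[i, j, k] * p_ezy[i, j, k]
    for i in range(nx - 1):
        for j in range(ny - 1):
            for k in range(1, nz - 1):
                if cze[k] == 0.0 and bze[k] == 1.0:
                    continue
                b = bze[k]
                c = cze[k]
                if j >= 1:  # Ex, d Hy / d z
                    d = Hy[i, j, k] - Hy[i, j, k - 1]
                    p_exz[i, j, k] = b * p_exz[i, j, k] + c * d
                    Ex[i, j, k] -= cb[i, j, k] * p_exz[i, j, k]
                if i >= 1:  # Ey, d Hx / d z
                    d = Hx[i, j, k] - Hx[i, j, k - 1]
                    p_eyz[i, j, k] = b * p_eyz[i, j, k] + c * d
                    Ey[i, j, k] += cb[i, j, k] * p_eyz[i, j, k]


@numba.njit(cache=True, fastmath=True)
def accumulate_dft(field, acc_re, acc_im, cw, sw):
    """acc += field * e^{-i w t}: one running-DFT deposit, cw/sw = cos/sin(w t)."""
    f = field.ravel()
    r = acc_re.ravel()
    m = acc_im.ravel()
    for q in range(f.size):
        v = f[q]
        r[q] += cw * v
        m[q] -= sw * v
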