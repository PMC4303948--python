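"""Numba core for the delay reaction-diffusion integrator.

The activation dynamic program here mirrors
:func:`gapcircuit.thermo.activation_dp` (which is cross-checked against
the enumeration oracle); it is re-evaluated for every gene, nucleus and
Euler step, so it runs inside one jitted kernel together with the
integrator.  All per-gene site data arrive as flat arrays with offsets.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_core", "activation_profile_core"]


@njit(cache=True)
def _e_dp(j0, j1, i, conc, s_tf, s_start, s_end, s_mid, s_qcoef,
          s_tval, s_role, s_beta, s_omega, s_drep, coop_range, q_btm,
          dp_off, dp_on):
    """Activation probability for one gene (sites [j0, j1)) in nucleus i."""
    n = j1 - j0
    if n == 0:
        return q_btm / (1.0 + q_btm)
    z_off = 1.0
    z_on = 1.0
    for jj in range(n):
        j = j0 + jj
        q = s_qcoef[j] * conc[s_tf[j], i]
        nflags = 2 if s_role[j] == -1 else 1
        for fj in range(2):
            dp_off[jj, fj] = 0.0
            dp_on[jj, fj] = 0.0
        for fj in range(nflags):
            if fj == 1:
                w_off = q * s_beta[j]
                w_on = w_off
            else:
                w_off = q
                w_on = q * s_tval[j] if s_role[j] == 1 else q
            acc_off = 1.0
            acc_on = 1.0
            for kk in range(jj):
                k = j0 + kk
                if s_start[j] < s_end[k]:   # overlap (starts are sorted)
                    continue
                coop = 1.0
                if (s_tf[k] == s_tf[j]
                        and s_start[j] - s_end[k] <= coop_range):
                    coop = s_omega[j]
                for fk in range(2):
                    if fk == 1:
                        if s_role[k] != -1:
                            continue
                        if s_mid[j] - s_mid[k] <= s_drep[k]:
                            continue
                    if fj == 1 and s_mid[j] - s_mid[k] <= s_drep[j]:
                        continue
                    acc_off += coop * dp_off[kk, fk]
                    acc_on += coop * dp_on[kk, fk]
            dp_off[jj, fj] = w_off * acc_off
            dp_on[jj, fj] = w_on * acc_on
            z_off += dp_off[jj, fj]
            z_on += dp_on[jj, fj]
    num = q_btm * z_on
    return num / (num + z_off)


@njit(cache=True)
def _fill_conc(conc, step, n_nuc, ext, v, tf_src_type, tf_src_idx):
    for t in range(tf_src_type.shape[0]):
        if tf_src_type[t] == 0:
            for i in range(n_nuc):
                conc[t, i] = ext[tf_src_idx[t], step, i]
        else:
            g = tf_src_idx[t]
            for i in range(n_nuc):
                c = v[g, i]
                conc[t, i] = c if c > 0.0 else 0.0


@njit(cache=True)
def activation_profile_core(n_nuc, site_off, s_tf, s_start, s_end, s_mid,
                            s_qcoef, s_tval, s_role, s_beta, s_omega,
                            s_drep, coop_range, q_btm, conc):
    """E over all nuclei for every gene at fixed TF concentrations."""
    n_genes = site_off.shape[0] - 1
    max_sites = 0
    for g in range(n_genes):
        ns = site_off[g + 1] - site_off[g]
        if ns > max_sites:
            max_sites = ns
    dp_off = np.zeros((max(max_sites, 1), 2))
    dp_on = np.zeros((max(max_sites, 1), 2))
    out = np.zeros((n_genes, n_nuc))
    for g in range(n_genes):
        for i in range(n_nuc):
            out[g, i] = _e_dp(site_off[g], site_off[g + 1], i, conc, s_tf,
                              s_start, s_end, s_mid, s_qcoef, s_tval,
                              s_role, s_beta, s_omega, s_drep,
                              coop_range[g], q_btm[g], dp_off, dp_on)
    return out


@njit(cache=True)
def simulate_core(
        n13, steps13, steps14, dt,
        site_off, s_tf, s_start, s_end, s_mid, s_qcoef, s_tval, s_role,
        s_beta, s_omega, s_drep, coop_range, q_btm,
        tf_src_type, tf_src_idx,
        r_u, r_v, du13, du14, dv13, dv14, dec_u, phi_u, dec_v, phi_v,
        lag_steps, ext13, ext14, u0, v0, out13, out14, blackout_steps):
    """Fixed-step integration of the two-phase delay RD equations.

    The update is exponential-Euler in the decay term:
    ``u <- u*exp(-lambda*dt) + (synthesis + diffusion)*phi`` with
    ``phi = (1 - exp(-lambda*dt))/lambda`` (``phi = dt`` for lambda = 0),
    which is exact for constant forcing and reduces to explicit Euler as
    ``lambda*dt -> 0``.  ``dec_*``/``phi_*`` are the per-gene precomputed
    factors.

    Phase 1 runs ``steps13`` steps on ``n13`` nuclei, each nucleus then
    divides into two daughters inheriting its concentrations, and phase 2
    runs ``steps14`` steps on ``2*n13`` nuclei.  Boundaries are no-flux;
    the delayed mRNA u(t - tau) is read from a per-step history buffer
    (clamped to the initial state before t0, mapped to the mother nucleus
    before the division).  Returns recorded (u, v) snapshots per phase
    and a status flag (0 ok, 1 non-finite state detected).
    """
    n_genes = site_off.shape[0] - 1
    n14 = 2 * n13
    max_sites = 1
    for g in range(n_genes):
        ns = site_off[g + 1] - site_off[g]
        if ns > max_sites:
            max_sites = ns
    dp_off = np.zeros((max_sites, 2))
    dp_on = np.zeros((max_sites, 2))
    conc13 = np.zeros((tf_src_type.shape[0], n13))
    conc14 = np.zeros((tf_src_type.shape[0], n14))
    e13 = np.zeros((n_genes, n13))
    e14 = np.zeros((n_genes, n14))

    u13h = np.zeros((steps13 + 1, n_genes, n13))
    u14h = np.zeros((steps14 + 1, n_genes, n14))
    u = u0.copy()
    v = v0.copy()
    u13h[0] = u
    un = np.zeros((n_genes, n14))
    vn = np.zeros((n_genes, n14))

    n_out13 = out13.shape[0]
    n_out14 = out14.shape[0]
    rec13_u = np.zeros((n_out13, n_genes, n13))
    rec13_v = np.zeros((n_out13, n_genes, n13))
    rec14_u = np.zeros((n_out14, n_genes, n14))
    rec14_v = np.zeros((n_out14, n_genes, n14))
    status = 0
    p = 0

    # ---- cleavage cycle 13 ----
    for s in range(steps13 + 1):
        while p < n_out13 and out13[p] == s:
            rec13_u[p] = u
            rec13_v[p] = v
            p += 1
        if s == steps13:
            break
        _fill_conc(conc13, s, n13, ext13, v, tf_src_type, tf_src_idx)
        for g in range(n_genes):
            for i in range(n13):
                e13[g, i] = _e_dp(site_off[g], site_off[g + 1], i, conc13,
                                  s_tf, s_start, s_end, s_mid, s_qcoef,
                                  s_tval, s_role, s_beta, s_omega, s_drep,
                                  coop_range[g], q_btm[g], dp_off, dp_on)
        for g in range(n_genes):
            # delayed mRNA: linear interpolation between history steps
            # keeps the solution smooth in tau
            df = s - lag_steps[g]
            if df < 0.0:
                df = 0.0
            i0 = int(np.floor(df))
            frac = df - i0
            if i0 >= s:
                i0 = s
                frac = 0.0
            for i in range(n13):
                u_del = u13h[i0, g, i]
                if frac > 0.0:
                    u_del += frac * (u13h[i0 + 1, g, i] - u_del)
                lap_u = 0.0
                lap_v = 0.0
                if i > 0:
                    lap_u += u[g, i - 1] - u[g, i]
                    lap_v += v[g, i - 1] - v[g, i]
                if i < n13 - 1:
                    lap_u += u[g, i + 1] - u[g, i]
                    lap_v += v[g, i + 1] - v[g, i]
                un[g, i] = (u[g, i] * dec_u[g]
                            + (r_u[g] * e13[g, i] + du13[g] * lap_u)
                            * phi_u[g])
                vn[g, i] = (v[g, i] * dec_v[g]
                            + (r_v[g] * u_del + dv13[g] * lap_v)
                            * phi_v[g])
        for g in range(n_genes):
            for i in range(n13):
                u[g, i] = un[g, i]
                v[g, i] = vn[g, i]
        u13h[s + 1] = u
        if s % 25 == 0:
            ok = True
            for g in range(n_genes):
                for i in range(n13):
                    if not (np.isfinite(u[g, i]) and np.isfinite(v[g, i])):
                        ok = False
            if not ok:
                status = 1
                return rec13_u, rec13_v, rec14_u, rec14_v, status

    # ---- division: each nucleus -> two daughters ----
    u2 = np.zeros((n_genes, n14))
    v2 = np.zeros((n_genes, n14))
    for g in range(n_genes):
        for i in range(n13):
            u2[g, 2 * i] = u[g, i]
            u2[g, 2 * i + 1] = u[g, i]
            v2[g, 2 * i] = v[g, i]
            v2[g, 2 * i + 1] = v[g, i]
    u = u2
    v = v2
    u14h[0] = u

    # ---- cleavage cycle 14A ----
    p = 0
    for s in range(steps14 + 1):
        while p < n_out14 and out14[p] == s:
            rec14_u[p] = u
            rec14_v[p] = v
            p += 1
        if s == steps14:
            break
        _fill_conc(conc14, s, n14, ext14, v, tf_src_type, tf_src_idx)
        for g in range(n_genes):
            for i in range(n14):
                e14[g, i] = _e_dp(site_off[g], site_off[g + 1], i, conc14,
                                  s_tf, s_start, s_end, s_mid, s_qcoef,
                                  s_tval, s_role, s_beta, s_omega, s_drep,
                                  coop_range[g], q_btm[g], dp_off, dp_on)
        for g in range(n_genes):
            sg = steps13 + s
            df = sg - lag_steps[g]
            if df < 0.0:
                df = 0.0
            i0 = int(np.floor(df))
            frac = df - i0
            if i0 >= sg:
                i0 = sg
                frac = 0.0
            syn_on = 0.0 if s < blackout_steps else 1.0
            for i in range(n14):
                if i0 >= steps13:
                    u_del = u14h[i0 - steps13, g, i]
                else:
                    u_del = u13h[i0, g, i // 2]
                if frac > 0.0:
                    i1 = i0 + 1
                    if i1 >= steps13:
                        u_next = u14h[i1 - steps13, g, i]
                    else:
                        u_next = u13h[i1, g, i // 2]
                    u_del += frac * (u_next - u_del)
                lap_u = 0.0
                lap_v = 0.0
                if i > 0:
                    lap_u += u[g, i - 1] - u[g, i]
                    lap_v += v[g, i - 1] - v[g, i]
                if i < n14 - 1:
                    lap_u += u[g, i + 1] - u[g, i]
                    lap_v += v[g, i + 1] - v[g, i]
                un[g, i] = (u[g, i] * dec_u[g]
                            + (syn_on * r_u[g] * e14[g, i]
                               + du14[g] * lap_u) * phi_u[g])
                vn[g, i] = (v[g, i] * dec_v[g]
                            + (r_v[g] * u_del + dv14[g] * lap_v)
                            * phi_v[g])
        for g in range(n_genes):
            for i in range(n14):
                u[g, i] = un[g, i]
                v[g, i] = vn[g, i]
        u14h[s + 1] = u
        if s % 25 == 0:
            ok = True
            for g in range(n_genes):
                for i in range(n14):
                    if not (np.isfinite(u[g, i]) and np.isfinite(v[g, i])):
                        ok = False
            if not ok:
                status = 1
                return rec13_u, rec13_v, rec14_u, rec14_v, status

    return rec13_u, rec13_v, rec14_u, rec14_v, status
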