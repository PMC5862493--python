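"""Compiled inner loop of the compartmental simulator.

One backward-Euler step of the branched cable per time step, solved by
tree-ordered (Hines) elimination in O(n); membrane mechanisms are advanced
by operator splitting:

1. photocycle occupancies advance with precomputed matrix-exponential
   propagators (exact for piecewise-constant light; kinetics here are
   voltage independent),
2. the voltage tree is solved implicitly with channel/synapse conductances
   frozen at their current values (linear opsin currents implicit,
   rectifier/constant forms explicit at the previous voltage),
3. Hodgkin-Huxley gates at the soma advance by exponential Euler at the
   new voltage.

Compartments must be ordered parents-before-children with the soma at
index 0.  Units: mV, ms, nA, uS, nF.
"""

import numpy as np
from numba import njit

#: voltage_fn form codes
F_LINEAR = 0
F_RECTIFIER = 1
F_CONSTANT = 2

STATUS_OK = 0


@njit(cache=True)
def _vtrap(x, y):
    # x/(exp(x/y)-1), stable near x = 0
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (np.exp(x / y) - 1.0)


@njit(cache=True)
def _hh_rates(v):
    a_m = 0.1 * _vtrap(-(v + 40.0), 10.0)
    b_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (np.exp(-(v + 35.0) / 10.0) + 1.0)
    a_n = 0.01 * _vtrap(-(v + 55.0), 10.0)
    b_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


@njit(cache=True)
def hh_steady_gates(v):
    a_m, b_m, a_h, b_h, a_n, b_n = _hh_rates(v)
    return np.array([a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n)])


@njit(cache=True)
def _f_volt(form, pa, pb, v):
    if form == F_LINEAR:
        return v - pa
    elif form == F_RECTIFIER:
        return pb * (1.0 - np.exp(-(v - pa) / pb))
    else:  # F_CONSTANT
        return pa


@njit(cache=True)
def run_kernel(n_steps, dt,
               parent, g_ax, cap, g_pas, e_pas, v,
               hh_on, gna, gk, gl, ena, ek, el, gates,
               n_ops, occ, prop_on, prop_off, wts, track, gpref,
               f_form, f_pa, f_pb, light_on, light_off,
               inj_comp, inj_amp, inj_on, inj_off,
               syn_comp, syn_decay, syn_e, syn_w, syn_g,
               ev_step, ev_syn,
               rec_idx, rec_v, rec_iph):
    """Advance the system n_steps; record into rec_v / rec_iph.

    Returns STATUS_OK or 1 + the step index at which a non-finite soma
    voltage was first detected.
    """
    n = parent.shape[0]
    n_syn = syn_comp.shape[0]
    n_inj = inj_comp.shape[0]
    n_rec = rec_idx.shape[0]
    K = occ.shape[1]
    S = occ.shape[2]

    diag = np.empty(n)
    rhs = np.empty(n)
    psi = np.zeros((occ.shape[0], K))
    occ_new = np.empty(S)

    # record initial state
    for r in range(n_rec):
        rec_v[0, r] = v[rec_idx[r]]
    for o in range(n_ops):
        rec_iph[0, o] = 0.0

    ev_ptr = 0
    n_ev = ev_step.shape[0]

    for it in range(n_steps):
        # --- synaptic events scheduled for this step -----------------------
        while ev_ptr < n_ev and ev_step[ev_ptr] == it:
            syn_g[ev_syn[ev_ptr]] += syn_w[ev_syn[ev_ptr]]
            ev_ptr += 1

        # --- photocycle occupancies (frozen V; exact propagator) ----------
        for o in range(n_ops):
            lit = light_on[o] <= it < light_off[o]
            for k in range(K):
                for s in range(S):
                    acc = 0.0
                    for s2 in range(S):
                        if lit:
                            acc += occ[o, k, s2] * prop_on[o, k, s2, s]
                        else:
                            acc += occ[o, k, s2] * prop_off[o, s2, s]
                    occ_new[s] = acc
                p = 0.0
                for s in range(S):
                    occ[o, k, s] = occ_new[s]
                    p += wts[o, s] * occ_new[s]
                psi[o, k] = p

        # --- assemble backward-Euler system -------------------------------
        for i in range(n):
            c = cap[i] / dt
            diag[i] = c + g_pas[i]
            rhs[i] = c * v[i] + g_pas[i] * e_pas

        if hh_on:
            m = gates[0]
            h = gates[1]
            ng = gates[2]
            gna_t = gna * m * m * m * h
            gk_t = gk * ng * ng * ng * ng
            diag[0] += gna_t + gk_t + gl
            rhs[0] += gna_t * ena + gk_t * ek + gl * el

        for j in range(n_syn):
            i = syn_comp[j]
            diag[i] += syn_g[j]
            rhs[i] += syn_g[j] * syn_e[j]

        for o in range(n_ops):
            for i in range(n):
                tk = track[o, i]
                if tk < 0:
                    continue
                g_eff = gpref[o, i] * psi[o, tk]
                if g_eff == 0.0:
                    continue
                if f_form[o] == F_LINEAR:
                    # conductance-like: implicit
                    diag[i] += g_eff
                    rhs[i] += g_eff * f_pa[o]  # pa = reversal
                else:
                    # explicit at previous voltage (outward positive)
                    rhs[i] -= g_eff * _f_volt(f_form[o], f_pa[o], f_pb[o], v[i])

        for j in range(n_inj):
            if inj_on[j] <= it < inj_off[j]:
                rhs[inj_comp[j]] += inj_amp[j]

        # --- axial coupling and Hines solve -------------------------------
        for i in range(1, n):
            diag[i] += g_ax[i]
            diag[parent[i]] += g_ax[i]
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = g_ax[i] / diag[i]
            diag[p] -= f * g_ax[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / diag[i]

        # --- HH gate update (exponential Euler at new soma voltage) --------
        if hh_on:
            a_m, b_m, a_h, b_h, a_n, b_n = _hh_rates(v[0])
            gates[0] += (1.0 - np.exp(-dt * (a_m + b_m))) * \
                (a_m / (a_m + b_m) - gates[0])
            gates[1] += (1.0 - np.exp(-dt * (a_h + b_h))) * \
                (a_h / (a_h + b_h) - gates[1])
            gates[2] += (1.0 - np.exp(-dt * (a_n + b_n))) * \
                (a_n / (a_n + b_n) - gates[2])

        # --- synaptic conductance decay ------------------------------------
        for j in range(n_syn):
            syn_g[j] *= syn_decay[j]

        # --- record ---------------------------------------------------------
        for r in range(n_rec):
            rec_v[it + 1, r] = v[rec_idx[r]]
        for o in range(n_ops):
            tot = 0.0
            for i in range(n):
                tk = track[o, i]
                if tk < 0:
                    continue
                g_eff = gpref[o, i] * psi[o, tk]
                if g_eff != 0.0:
                    tot += g_eff * _f_volt(f_form[o], f_pa[o], f_pb[o], v[i])
            rec_iph[it + 1, o] = tot

        if (it & 1023) == 0 and not np.isfinite(v[0]):
            return 1 + it
    if not np.isfinite(v[0]):
        return n_steps
    return STATUS_OK
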