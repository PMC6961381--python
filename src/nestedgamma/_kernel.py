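"""Compiled fixed-step integrator for conductance-based networks.

One kernel integrates an arbitrary collection of compartments coupled by
axial conductances, ligand-gated synapses and a single plastic spine.
Voltages are advanced with a backward-Euler step in which every channel
and synaptic conductance is frozen over the step (the resulting linear
system over all compartments is solved exactly each step); gating
variables and first-order calcium/detector/readout ODEs use exponential
(exact linear) updates, which keeps gating in [0, 1] unconditionally.

Channel kinetics (``gating_scheme`` identifiers in the model layer):
  Na/KDR  "rtm"      -- Traub & Miles (1991) hippocampal pyramidal-cell
                        rates as used in reduced PING models
                        (Ermentrout & Kopell 1998).
  KA      "bg_a"     -- Borg-Graham style A-type activation/inactivation
                        (sigmoid steady states, fixed time constants).
  CaL     "hva_l"    -- high-voltage-activated L-type, s^2 activation.
  KM      "yamada_m" -- Yamada/Koch/Adams muscarinic K+ kinetics.
  AHP     "ca_ahp"   -- Ca-gated AHP conductance, alpha proportional to
                        the compartmental calcium pool (Traub-like).
  H       "sigmoid_h"-- sigmoidal hyperpolarization-activated current.

Units: mV, ms, nF, uS, nA, uM throughout the kernel.
"""
import numpy as np
from numba import njit

E_NA = 55.0
E_K = -90.0
E_CA = 120.0
E_H = -30.0

# synapse kinds
K_BIEXP = 0
K_AMPA = 1
K_NMDA = 2

STATUS_OK = -1


@njit(cache=True)
def _vtrap(x, s):
    # x / (1 - exp(-x/s)), stable at x -> 0
    u = x / s
    if -1e-6 < u < 1e-6:
        return s * (1.0 + 0.5 * u)
    return x / (1.0 - np.exp(-u))


@njit(cache=True)
def _gate_step(x, xinf, tau, dt):
    return xinf + (x - xinf) * np.exp(-dt / tau)


@njit(cache=True)
def _update_gates(V, ca, m, h, n, a, b, s, u, q, r, dt):
    nc = V.shape[0]
    for i in range(nc):
        v = V[i]
        # Na (rtm)
        am = 0.32 * _vtrap(v + 54.0, 4.0)
        bm = 0.28 * _vtrap(-(v + 27.0), 5.0)
        ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
        bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
        # KDR (rtm)
        an = 0.032 * _vtrap(v + 52.0, 5.0)
        bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
        rm = am + bm
        rh = ah + bh
        rn = an + bn
        m[i] = am / rm + (m[i] - am / rm) * np.exp(-dt * rm)
        h[i] = ah / rh + (h[i] - ah / rh) * np.exp(-dt * rh)
        n[i] = an / rn + (n[i] - an / rn) * np.exp(-dt * rn)
        # KA (bg_a)
        ainf = 1.0 / (1.0 + np.exp(-(v + 25.0) / 15.0))
        binf = 1.0 / (1.0 + np.exp((v + 75.0) / 6.0))
        a[i] = _gate_step(a[i], ainf, 2.0, dt)
        b[i] = _gate_step(b[i], binf, 30.0, dt)
        # CaL (hva_l)
        sinf = 1.0 / (1.0 + np.exp(-(v + 15.0) / 6.0))
        s[i] = _gate_step(s[i], sinf, 1.5, dt)
        # KM (yamada_m)
        uinf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
        tauu = 1000.0 / (3.3 * (np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0)))
        u[i] = _gate_step(u[i], uinf, tauu, dt)
        # AHP (ca_ahp): alpha grows with the local Ca pool
        aq = 0.004 * ca[i] * ca[i]
        if aq > 0.05:
            aq = 0.05
        bq = 0.004
        rq = aq + bq
        q[i] = aq / rq + (q[i] - aq / rq) * np.exp(-dt * rq)
        # H (sigmoid_h)
        rinf = 1.0 / (1.0 + np.exp((v + 80.0) / 8.0))
        r[i] = _gate_step(r[i], rinf, 100.0, dt)


@njit(cache=True)
def _solve(M, rhs, V):
    # Gaussian elimination with partial pivoting; nc is tiny (<= ~8)
    nc = rhs.shape[0]
    for col in range(nc):
        piv = col
        best = abs(M[col, col])
        for row in range(col + 1, nc):
            if abs(M[row, col]) > best:
                best = abs(M[row, col])
                piv = row
        if piv != col:
            for k in range(nc):
                tmp = M[col, k]
                M[col, k] = M[piv, k]
                M[piv, k] = tmp
            tmp = rhs[col]
            rhs[col] = rhs[piv]
            rhs[piv] = tmp
        for row in range(col + 1, nc):
            f = M[row, col] / M[col, col]
            if f != 0.0:
                for k in range(col, nc):
                    M[row, k] -= f * M[col, k]
                rhs[row] -= f * rhs[col]
    for row in range(nc - 1, -1, -1):
        acc = rhs[row]
        for k in range(row + 1, nc):
            acc -= M[row, k] * V[k]
        V[row] = acc / M[row, row]


@njit(cache=True)
def run_network(
    dt,            # internal step (ms)
    substeps,      # internal steps per output sample
    nrec,          # number of output samples (after the initial one)
    # compartments
    cm, gl, el, gna, gkdr, gka, gcal, gkm, gahp, gh,  # (nc,)
    axial,         # (nc, nc) symmetric coupling conductances, uS
    ca_gain, ca_tau, ca_base,                          # (nc,) Ca pools
    # state (modified in place)
    V, m, h, n, a, b, s, u, q, r, ca,
    # cells
    soma_comp,     # (ncell,) soma compartment index per cell
    # synapses
    syn_kind, syn_pre, syn_post, syn_e, syn_g, syn_plastic,
    syn_dfac1, syn_dfac2, syn_norm, syn_delay, syn_mgk,
    s1, s2,        # synapse state (modified in place)
    # external (CA3 source) events: internal step index + target synapse
    ext_steps, ext_syn,
    # injected current per output step per compartment, nA (noise included)
    inj,
    # plasticity (spine_comp < 0 disables); pw = [P, W]
    spine_comp, nmda_frac, theta_p, k_p, tau_p, k_w, w_max, pw,
    # spike detection
    thresh, refrac_steps,
    spike_buf,     # (ncell, buflen) int64 ring buffer
    last_spike,    # (ncell,) int64, step of last spike (-10**9 initially)
    spike_times, spike_counts, max_spikes,
    # outputs
    out_v,         # (nrec, nc)
    out_ca,        # (nrec, nc)
    out_w,         # (nrec, 2) -> P, W
):
    nc = V.shape[0]
    ncell = soma_comp.shape[0]
    nsyn = syn_kind.shape[0]
    buflen = spike_buf.shape[1]
    next_ext = 0
    M = np.empty((nc, nc))
    rhs = np.empty(nc)
    Vold = np.empty(nc)
    P = pw[0]
    W = pw[1]
    tstep = 0
    for k in range(nrec):
        for _ in range(substeps):
            slot = tstep % buflen
            # decay synaptic states
            for j in range(nsyn):
                s1[j] *= syn_dfac1[j]
                if syn_kind[j] != K_AMPA:
                    s2[j] *= syn_dfac2[j]
            # increments from presynaptic spikes `delay` steps old
            # (delays are >= 1 step and < buflen, so the flag is still valid)
            for j in range(nsyn):
                if syn_pre[j] >= 0:
                    src = tstep - syn_delay[j]
                    if src >= 0 and spike_buf[syn_pre[j], src % buflen] == 1:
                        w = W if syn_plastic[j] == 1 else 1.0
                        s1[j] += w
                        if syn_kind[j] != K_AMPA:
                            s2[j] += w
            # external (CA3) events, pre-sorted by step
            while next_ext < ext_steps.shape[0] and ext_steps[next_ext] <= tstep:
                if ext_steps[next_ext] == tstep:
                    j = ext_syn[next_ext]
                    w = W if syn_plastic[j] == 1 else 1.0
                    s1[j] += w
                    if syn_kind[j] != K_AMPA:
                        s2[j] += w
                next_ext += 1

            # gating update (exponential Euler at current V, ca)
            _update_gates(V, ca, m, h, n, a, b, s, u, q, r, dt)

            # assemble the linear system for backward-Euler voltages
            for i in range(nc):
                for jj in range(nc):
                    M[i, jj] = -axial[i, jj]
                gna_i = gna[i] * m[i] * m[i] * m[i] * h[i]
                gk_i = gkdr[i] * n[i] * n[i] * n[i] * n[i]
                gka_i = gka[i] * a[i] * b[i]
                gcal_i = gcal[i] * s[i] * s[i]
                gkm_i = gkm[i] * u[i]
                gahp_i = gahp[i] * q[i]
                gh_i = gh[i] * r[i]
                gsum = gl[i] + gna_i + gk_i + gka_i + gcal_i + gkm_i + gahp_i + gh_i
                esum = (gl[i] * el[i] + gna_i * E_NA + (gk_i + gka_i + gkm_i + gahp_i) * E_K
                        + gcal_i * E_CA + gh_i * E_H)
                ax = 0.0
                for jj in range(nc):
                    ax += axial[i, jj]
                M[i, i] = cm[i] / dt + gsum + ax
                rhs[i] = cm[i] / dt * V[i] + esum + inj[k, i]
            # synaptic conductances
            for j in range(nsyn):
                if syn_kind[j] == K_AMPA:
                    g = syn_g[j] * s1[j]
                else:
                    g = syn_g[j] * syn_norm[j] * (s1[j] - s2[j])
                    if g < 0.0:
                        g = 0.0
                if syn_kind[j] == K_NMDA:
                    vpost = V[syn_post[j]]
                    g *= 1.0 / (1.0 + syn_mgk[j] * np.exp(-0.062 * vpost))
                p = syn_post[j]
                M[p, p] += g
                rhs[p] += g * syn_e[j]
            for i in range(nc):
                Vold[i] = V[i]
            _solve(M, rhs, V)

            # numerical sanity
            for i in range(nc):
                if not np.isfinite(V[i]) or abs(V[i]) > 200.0:
                    pw[0] = P
                    pw[1] = W
                    return tstep

            # calcium pools: CaL influx everywhere a pool exists, NMDA at spine
            for i in range(nc):
                if ca_gain[i] > 0.0:
                    ical = gcal[i] * s[i] * s[i] * (V[i] - E_CA)  # nA, negative inward
                    influx = 0.0
                    if ical < 0.0:
                        influx -= ical
                    if i == spine_comp:
                        for j in range(nsyn):
                            if syn_kind[j] == K_NMDA and syn_post[j] == i:
                                gnm = syn_g[j] * syn_norm[j] * (s1[j] - s2[j])
                                if gnm < 0.0:
                                    gnm = 0.0
                                gnm *= 1.0 / (1.0 + syn_mgk[j] * np.exp(-0.062 * V[i]))
                                # Ca component uses the Ca driving force
                                inm = gnm * (V[i] - E_CA)
                                if inm < 0.0:
                                    influx -= nmda_frac * inm
                    target = ca_base[i] + ca_gain[i] * influx * ca_tau[i]
                    ca[i] = target + (ca[i] - target) * np.exp(-dt / ca_tau[i])

            # plasticity detector / readout: P is exact for the indicator
            # held over the step; W uses the exact integral of P(t)
            if spine_comp >= 0:
                above = 1.0 if ca[spine_comp] > theta_p else 0.0
                rate = k_p * above + 1.0 / tau_p
                pinf = k_p * above / rate
                decay = np.exp(-dt * rate)
                p_int = pinf * dt + (P - pinf) * (1.0 - decay) / rate
                P = pinf + (P - pinf) * decay
                W = w_max + (W - w_max) * np.exp(-k_w * p_int)

            # spike detection at somas, write ring buffer
            for c in range(ncell):
                spike_buf[c, slot] = 0
                i = soma_comp[c]
                if (V[i] >= thresh and Vold[i] < thresh
                        and tstep - last_spike[c] >= refrac_steps):
                    last_spike[c] = tstep
                    spike_buf[c, slot] = 1
                    if spike_counts[c] < max_spikes:
                        spike_times[c, spike_counts[c]] = (tstep + 1) * dt
                        spike_counts[c] += 1
            tstep += 1
        for i in range(nc):
            out_v[k, i] = V[i]
            out_ca[k, i] = ca[i]
        out_w[k, 0] = P
        out_w[k, 1] = W
    pw[0] = P
    pw[1] = W
    return STATUS_OK
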