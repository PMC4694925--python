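"""Compiled inner loop for phase simulation.

The kernel advances the network for a whole phase.  It operates on a dense
weight matrix ``W`` plus an explicit adjacency list (``adj``/``deg``) of the
existing synapses so that STDP, synaptic normalization and structural
plasticity touch only the ~``p_ee * N^2`` live entries.  Within each step the
order of operations is: state update -> STDP -> structural change -> SN -> IP,
matching the lineage of the original SORN implementations.

All randomness (structural-plasticity draws, noise) is pre-generated by the
caller so that the kernel itself is purely deterministic.
"""

import numpy as np
from numba import njit

__all__ = ["phase_loop"]


@njit(cache=True)
def phase_loop(
    W,            # (N, N) float64, dense weights; nonzero iff synapse exists
    conn,         # (N, N) bool, synapse-existence mask
    adj,          # (N, N) int64 adjacency: adj[i, :deg[i]] = presyn partners of i
    deg,          # (N,) int64 in-degree
    w_ei,         # (N, Ni) inhibitory -> excitatory weights
    w_ie,         # (Ni, N) excitatory -> inhibitory weights
    t_e,          # (N,) excitatory thresholds (updated by IP)
    t_i,          # (Ni,) fixed inhibitory thresholds
    h_targets,    # (N,) per-neuron IP target rates
    x,            # (N,) float64 binary excitatory state (updated in place)
    y,            # (Ni,) float64 binary inhibitory state (updated in place)
    sym,          # (T,) int64 index into `drive` per step
    drive,        # (n_rows, N) float64 feed-forward input drive per symbol
    eta_stdp,
    eta_ip,
    stdp_on,      # bool flags
    sn_on,
    ip_on,
    struct_on,
    prune,
    struct_u,     # (T,) uniforms for structural-plasticity gating
    struct_i,     # (T,) candidate postsynaptic indices
    struct_j,     # (T,) candidate presynaptic indices
    struct_p,
    struct_w0,
    noise,        # (T, N) float64 Gaussian perturbations (empty if noise off)
    noise_on,
    spikes,       # (T, N) uint8 output raster
    inh_spikes,   # (T, Ni) uint8 output raster (may be empty)
    rec_inh,
    conn_frac,    # (n_samples,) float64 output, connection-fraction trace
    conn_every,   # sampling interval; 0 disables
):
    N = W.shape[0]
    Ni = w_ie.shape[0]
    T = sym.shape[0]

    act = np.zeros(N)
    inh_drive = np.zeros(N)
    xn = np.zeros(N)
    yn = np.zeros(Ni)
    rs = np.zeros(N)
    cs = np.zeros(N)
    old_idx = np.zeros(N, dtype=np.int64)
    new_idx = np.zeros(N, dtype=np.int64)

    n_edges = 0
    for i in range(N):
        n_edges += deg[i]
    flips = 0

    for t in range(T):
        s = sym[t]

        # -- indices of currently active units -------------------------------
        n_old = 0
        for j in range(N):
            if x[j] > 0.0:
                old_idx[n_old] = j
                n_old += 1

        # -- excitatory update: Theta(W_ee x - W_ei y + W_eu u - T_e) --------
        for i in range(N):
            inh_drive[i] = 0.0
        for m in range(Ni):
            if y[m] > 0.0:
                for i in range(N):
                    inh_drive[i] += w_ei[i, m]
        for i in range(N):
            a = drive[s, i] - inh_drive[i] - t_e[i]
            for k in range(deg[i]):
                j = adj[i, k]
                if x[j] > 0.0:
                    a += W[i, j]
            act[i] = a
        if noise_on:
            for i in range(N):
                spike_det = act[i] > 0.0
                spike = act[i] + noise[t, i] > 0.0
                xn[i] = 1.0 if spike else 0.0
                if spike != spike_det:
                    flips += 1
        else:
            for i in range(N):
                xn[i] = 1.0 if act[i] > 0.0 else 0.0

        n_new = 0
        for i in range(N):
            if xn[i] > 0.0:
                new_idx[n_new] = i
                n_new += 1

        # -- inhibitory update: Theta(W_ie x(t+1) - T_i) ---------------------
        for m in range(Ni):
            a = -t_i[m]
            for k in range(n_new):
                a += w_ie[m, new_idx[k]]
            yn[m] = 1.0 if a > 0.0 else 0.0

        # -- STDP on existing synapses ---------------------------------------
        if stdp_on:
            for ii in range(n_new):
                i = new_idx[ii]
                for jj in range(n_old):
                    j = old_idx[jj]
                    if i != j and conn[i, j]:
                        W[i, j] += eta_stdp
            for ii in range(n_old):
                i = old_idx[ii]
                for jj in range(n_new):
                    j = new_idx[jj]
                    if i != j and conn[i, j]:
                        W[i, j] -= eta_stdp
                        if W[i, j] <= 0.0:
                            W[i, j] = 0.0
                            if prune:
                                conn[i, j] = False
                                for k in range(deg[i]):
                                    if adj[i, k] == j:
                                        adj[i, k] = adj[i, deg[i] - 1]
                                        deg[i] -= 1
                                        n_edges -= 1
                                        break

        # -- structural plasticity: new random synapse ------------------------
        if struct_on and struct_u[t] < struct_p:
            i = struct_i[t]
            j = struct_j[t]
            if i != j and not conn[i, j]:
                conn[i, j] = True
                W[i, j] = struct_w0
                adj[i, deg[i]] = j
                deg[i] += 1
                n_edges += 1

        # -- synaptic normalization (pre- and postsynaptic) --------------------
        if sn_on:
            for i in range(N):
                rs[i] = 0.0
                cs[i] = 0.0
            for i in range(N):
                for k in range(deg[i]):
                    j = adj[i, k]
                    w = W[i, j]
                    rs[i] += w
                    cs[j] += w
            for i in range(N):
                for k in range(deg[i]):
                    j = adj[i, k]
                    d = 0.5 * rs[i] + 0.5 * cs[j]
                    if d > 0.0:
                        W[i, j] = 0.9 * W[i, j] + 0.1 * W[i, j] / d

        # -- intrinsic plasticity ----------------------------------------------
        if ip_on:
            for i in range(N):
                t_e[i] += eta_ip * (xn[i] - h_targets[i])

        # -- record and advance -------------------------------------------------
        for i in range(N):
            spikes[t, i] = np.uint8(xn[i])
            x[i] = xn[i]
        for m in range(Ni):
            if rec_inh:
                inh_spikes[t, m] = np.uint8(yn[m])
            y[m] = yn[m]
        if conn_every > 0 and t % conn_every == 0:
            conn_frac[t // conn_every] = n_edges / (N * (N - 1))

    return flips
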