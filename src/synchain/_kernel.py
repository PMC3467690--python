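"""Compiled inner loop of the network simulation.

One call integrates the whole network (N excitatory + 1 inhibitory LIF
neurons, alpha synapses, forward Euler) over the full stimulus while
applying STDP online.

Conventions baked in here (documented in the dynamics/plasticity modules):

* spikes are binary ones lasting one step; afferent spikes are delivered in
  the step they occur, recurrent and inhibitory spikes in the next step;
* per-neuron synaptic filters are aggregated per channel group
  (feed-forward, lateral, inhibitory), which is exact by linearity;
* within a step: deliver input -> integrate S_r, S_f -> integrate V ->
  threshold/reset;
* the afferent noise is an independent realization per excitatory neuron
  (the frozen pattern is the only shared component), drawn per step as a
  binomial spike count with distinct uniform afferent ids — exactly the
  per-bin Bernoulli process marginal;
* all-to-all STDP uses exponentially decaying pre/post traces; nearest-
  neighbor STDP pairs each postsynaptic spike with the single closest
  presynaptic spike (the last one at or before it, or the first one after
  it if closer and arriving no later than the next postsynaptic spike —
  the pairing is therefore resolved at that next pre or post event);
* weights are hard-clipped, and a neuron's incoming lateral vector is
  proportionally renormalized right after any potentiation touching it.

The kernel returns an error flag instead of raising: 0 ok, 1 non-finite
membrane potential, 2 spike buffer overflow.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ERR_OK = 0
ERR_NONFINITE = 1
ERR_OVERFLOW = 2

_NEVER = np.int64(-(1 << 60))


@njit(cache=True, fastmath=False)
def _draw_distinct(ids, k, lo, hi):
    """Draw k distinct uniform ints from [lo, hi) into ids[:k]."""
    for i in range(k):
        while True:
            cand = np.random.randint(lo, hi)
            dup = False
            for j in range(i):
                if ids[j] == cand:
                    dup = True
                    break
            if not dup:
                ids[i] = cand
                break
    return k


@njit(cache=True, fastmath=False, inline="always")
def _ff_on_pre(a, n, t, dt, plastic, all_to_all,
               w_ff, w_ff_max, a_p_ff, a_d_ff, tau_p, tau_d,
               tr_pre, tl_pre, res_ff, tr_post_d, tl_post):
    """Plasticity bookkeeping for one afferent spike on synapse (a, n)."""
    if not plastic:
        tl_pre[a, n] = t
        return
    if all_to_all:
        tlp = tl_post[n]
        if tlp > _NEVER:
            d = (t - tlp) * dt
            if d < 60.0 * tau_d:
                w = w_ff[a, n] + a_d_ff * tr_post_d[n] * np.exp(-d / tau_d)
                w_ff[a, n] = w if w > 0.0 else 0.0
        tl = tl_pre[a, n]
        if tl > _NEVER and (t - tl) * dt < 60.0 * tau_p:
            tr_pre[a, n] = tr_pre[a, n] * np.exp(-((t - tl) * dt) / tau_p) + 1.0
        else:
            tr_pre[a, n] = 1.0
    else:
        tp = tl_post[n]
        if tp > _NEVER and res_ff[a, n] < tp:
            gap_b = tp - tl_pre[a, n]   # huge if no pre ever
            gap_a = t - tp
            if gap_a < gap_b:
                d = gap_a * dt
                if d < 60.0 * tau_d:
                    w = w_ff[a, n] + a_d_ff * np.exp(-d / tau_d)
                    w_ff[a, n] = w if w > 0.0 else 0.0
            else:
                d = gap_b * dt
                if d < 60.0 * tau_p:
                    w = w_ff[a, n] + a_p_ff * np.exp(-d / tau_p)
                    w_ff[a, n] = w if w < w_ff_max else w_ff_max
            res_ff[a, n] = tp
    tl_pre[a, n] = t


@njit(cache=True, fastmath=False)
def simulate(
    seed,
    n_steps, dt,
    n_exc, n_aff, n_patt_aff,
    in_pres,                 # uint8[n_steps]: 1 while the pattern half shows a pattern
    pat_step, pat_aff,       # absolute-step frozen-pattern spike events, sorted by step
    p_full, p_bg,            # per-bin spike probabilities: carrier+background / background only
    shared_noise,
    tau_m, theta, v_reset, tau_r, tau_f,
    w_ff, w_lat,             # mutated in place
    w_ei, w_ie,
    w_ff_max, w_lat_max,
    plastic, lateral_on,
    a_p_ff, a_d_ff, a_p_lat, a_d_lat,
    tau_p, tau_d,
    all_to_all,
    tr_pre, tl_pre,          # float64[n_aff, n_exc], int64[n_aff, n_exc] (_NEVER = none yet)
    res_ff,                  # int64[n_aff, n_exc]: last post whose nn pairing is resolved
    tr_post_p, tr_post_d, tl_post,   # float64[n_exc] x2, int64[n_exc]
    res_lat,                 # int64[n_exc, n_exc]
    out_step, out_neuron,    # spike record buffers (neuron id n_exc = inhibitory)
    snap_interval,           # steps between lateral-weight snapshots (0 = none)
    snap_lat, snap_ffsum,
    ck_interval,             # steps between full-weight checkpoints (0 = none)
    ck_ff, ck_lat,
    v_stride,                # record membrane potentials every v_stride steps (0 = none)
    v_trace,                 # float32[n_rec, n_exc + 1]
):
    np.random.seed(seed)

    V = np.zeros(n_exc)
    sr_ff = np.zeros(n_exc)
    sf_ff = np.zeros(n_exc)
    sr_lat = np.zeros(n_exc)
    sf_lat = np.zeros(n_exc)
    v_i = 0.0
    sr_i = 0.0
    sf_i = 0.0

    I_ff = np.zeros(n_exc)
    norm_touch = np.zeros(n_exc, dtype=np.uint8)
    fired_prev = np.zeros(n_exc, dtype=np.uint8)
    inh_fired_prev = False

    ids = np.empty(512, dtype=np.int64)
    n_out = 0
    cap = out_step.shape[0]
    n_pat_ev = pat_step.shape[0]
    pp = 0
    ktot = 0

    n_noise_aff = n_aff - n_patt_aff
    cut_p = 60.0 * tau_p
    cut_d = 60.0 * tau_d

    c_r = dt / tau_r
    c_f = dt / tau_f
    c_m = dt / tau_m

    for t in range(n_steps):
        I_ei = 0.0
        for n in range(n_exc):
            I_ff[n] = 0.0

        # --- frozen-pattern spikes (shared across neurons)
        while pp < n_pat_ev and pat_step[pp] == t:
            a = pat_aff[pp]
            pp += 1
            for n in range(n_exc):
                I_ff[n] += w_ff[a, n]
                _ff_on_pre(a, n, t, dt, plastic, all_to_all,
                           w_ff, w_ff_max, a_p_ff, a_d_ff, tau_p, tau_d,
                           tr_pre, tl_pre, res_ff, tr_post_d, tl_post)

        # --- per-neuron independent noise spikes
        p_patt_half = p_bg if in_pres[t] == 1 else p_full
        if shared_noise:
            k1 = np.random.binomial(n_patt_aff, p_patt_half) if p_patt_half > 0.0 else 0
            _draw_distinct(ids, k1, 0, n_patt_aff)
            k2 = np.random.binomial(n_noise_aff, p_full) if (p_full > 0.0 and n_noise_aff > 0) else 0
            _draw_distinct(ids[k1:], k2, n_patt_aff, n_aff)
            ktot = k1 + k2
        for n in range(n_exc):
            if not shared_noise:
                k1 = np.random.binomial(n_patt_aff, p_patt_half) if p_patt_half > 0.0 else 0
                _draw_distinct(ids, k1, 0, n_patt_aff)
                k2 = np.random.binomial(n_noise_aff, p_full) if (p_full > 0.0 and n_noise_aff > 0) else 0
                _draw_distinct(ids[k1:], k2, n_patt_aff, n_aff)
                ktot = k1 + k2
            for i in range(ktot):
                a = ids[i]
                I_ff[n] += w_ff[a, n]
                _ff_on_pre(a, n, t, dt, plastic, all_to_all,
                           w_ff, w_ff_max, a_p_ff, a_d_ff, tau_p, tau_d,
                           tr_pre, tl_pre, res_ff, tr_post_d, tl_post)

        # --- lateral and inhibitory-loop input from the previous step
        any_fired = False
        for m in range(n_exc):
            if fired_prev[m] == 1:
                any_fired = True
                I_ei += w_ei
        if lateral_on and any_fired:
            for n in range(n_exc):
                acc = 0.0
                for m in range(n_exc):
                    if fired_prev[m] == 1 and m != n:
                        acc += w_lat[m, n]
                sr_lat[n] += c_r * (-sr_lat[n] + acc)
        else:
            for n in range(n_exc):
                sr_lat[n] += c_r * (-sr_lat[n])

        # --- integrate filters and membranes; an inhibitory spike from the
        # previous step hyperpolarizes every excitatory membrane directly
        # (instantaneous winner-takes-all kick, recovery over tau_m)
        for n in range(n_exc):
            sr_ff[n] += c_r * (-sr_ff[n] + I_ff[n])
            sf_ff[n] += c_f * (-sf_ff[n] + sr_ff[n])
            sf_lat[n] += c_f * (-sf_lat[n] + sr_lat[n])
            V[n] += c_m * (-V[n] + sf_ff[n] + sf_lat[n])
            if inh_fired_prev:
                V[n] -= w_ie
        sr_i += c_r * (-sr_i + I_ei)
        sf_i += c_f * (-sf_i + sr_i)
        v_i += c_m * (-v_i + sf_i)

        if not np.isfinite(V[0]):
            return n_out, ERR_NONFINITE

        if v_stride > 0 and t % v_stride == 0:
            r = t // v_stride
            if r < v_trace.shape[0]:
                for n in range(n_exc):
                    v_trace[r, n] = V[n]
                v_trace[r, n_exc] = v_i

        # --- threshold, reset, plasticity on postsynaptic spikes
        inh_fired_prev = False
        if v_i >= theta:
            v_i = v_reset
            inh_fired_prev = True
            if n_out >= cap:
                return n_out, ERR_OVERFLOW
            out_step[n_out] = t
            out_neuron[n_out] = n_exc
            n_out += 1

        for n in range(n_exc):
            if V[n] >= theta:
                V[n] = v_reset
                fired_prev[n] = 1
                if n_out >= cap:
                    return n_out, ERR_OVERFLOW
                out_step[n_out] = t
                out_neuron[n_out] = n
                n_out += 1
                if plastic:
                    t_prev = tl_post[n]
                    # ---- feed-forward potentiation
                    if all_to_all:
                        for a in range(n_aff):
                            tl = tl_pre[a, n]
                            if tl > _NEVER:
                                d = (t - tl) * dt
                                if d < cut_p:
                                    w = w_ff[a, n] + a_p_ff * tr_pre[a, n] * np.exp(-d / tau_p)
                                    w_ff[a, n] = w if w < w_ff_max else w_ff_max
                    else:
                        # resolve the previous post's still-pending pairings:
                        # no pre arrived since t_prev on those synapses, so the
                        # closest pre is the last one before t_prev -> potentiate
                        if t_prev > _NEVER:
                            for a in range(n_aff):
                                if res_ff[a, n] < t_prev:
                                    tl = tl_pre[a, n]
                                    if tl > _NEVER:
                                        d = (t_prev - tl) * dt
                                        if d < cut_p:
                                            w = w_ff[a, n] + a_p_ff * np.exp(-d / tau_p)
                                            w_ff[a, n] = w if w < w_ff_max else w_ff_max
                                    res_ff[a, n] = t_prev

                    # ---- lateral plasticity (n's spike is a post event for
                    # synapses m->n and a pre event for synapses n->m)
                    norm_touch[n] = 0
                    for m in range(n_exc):
                        norm_touch[m] = 0
                    for m in range(n_exc):
                        if m == n:
                            continue
                        tlm = tl_post[m]
                        if all_to_all:
                            if tlm > _NEVER:
                                d = (t - tlm) * dt
                                if d < cut_p:
                                    w = w_lat[m, n] + a_p_lat * tr_post_p[m] * np.exp(-d / tau_p)
                                    w_lat[m, n] = w if w < w_lat_max else w_lat_max
                                    norm_touch[n] = 1
                                if d < cut_d:
                                    w = w_lat[n, m] + a_d_lat * tr_post_d[m] * np.exp(-d / tau_d)
                                    w_lat[n, m] = w if w > 0.0 else 0.0
                        else:
                            # post event on m->n: resolve n's previous pending
                            if t_prev > _NEVER and res_lat[m, n] < t_prev:
                                if tlm > _NEVER and tlm < t_prev:
                                    d = (t_prev - tlm) * dt
                                    if d < cut_p:
                                        w = w_lat[m, n] + a_p_lat * np.exp(-d / tau_p)
                                        w_lat[m, n] = w if w < w_lat_max else w_lat_max
                                        norm_touch[n] = 1
                                res_lat[m, n] = t_prev
                            # pre event on n->m: resolve m's pending pairing
                            tpm = tl_post[m]
                            if tpm > _NEVER and res_lat[n, m] < tpm:
                                gap_b = tpm - t_prev if t_prev > _NEVER else np.int64(1 << 62)
                                gap_a = t - tpm
                                if gap_a < gap_b:
                                    d = gap_a * dt
                                    if d < cut_d:
                                        w = w_lat[n, m] + a_d_lat * np.exp(-d / tau_d)
                                        w_lat[n, m] = w if w > 0.0 else 0.0
                                else:
                                    d = gap_b * dt
                                    if d < cut_p:
                                        w = w_lat[n, m] + a_p_lat * np.exp(-d / tau_p)
                                        w_lat[n, m] = w if w < w_lat_max else w_lat_max
                                        norm_touch[m] = 1
                                res_lat[n, m] = tpm
                    if all_to_all:
                        norm_touch[n] = 1
                    # ---- renormalize every incoming vector that was potentiated
                    for q in range(n_exc):
                        if norm_touch[q] == 1:
                            s = 0.0
                            for m in range(n_exc):
                                s += w_lat[m, q]
                            if s > w_lat_max:
                                f = w_lat_max / s
                                for m in range(n_exc):
                                    w_lat[m, q] *= f
                    # ---- postsynaptic traces
                    if t_prev > _NEVER and (t - t_prev) * dt < cut_d:
                        d = (t - t_prev) * dt
                        tr_post_p[n] = tr_post_p[n] * np.exp(-d / tau_p) + 1.0
                        tr_post_d[n] = tr_post_d[n] * np.exp(-d / tau_d) + 1.0
                    else:
                        tr_post_p[n] = 1.0
                        tr_post_d[n] = 1.0
                    tl_post[n] = t
            else:
                fired_prev[n] = 0

        # --- snapshots
        if snap_interval > 0 and (t + 1) % snap_interval == 0:
            r = (t + 1) // snap_interval - 1
            if r < snap_lat.shape[0]:
                for m in range(n_exc):
                    for n in range(n_exc):
                        snap_lat[r, m, n] = w_lat[m, n]
                for n in range(n_exc):
                    s = 0.0
                    for a in range(n_aff):
                        s += w_ff[a, n]
                    snap_ffsum[r, n] = s
        if ck_interval > 0 and (t + 1) % ck_interval == 0:
            r = (t + 1) // ck_interval - 1
            if r < ck_ff.shape[0]:
                for a in range(n_aff):
                    for n in range(n_exc):
                        ck_ff[r, a, n] = w_ff[a, n]
                for m in range(n_exc):
                    for n in range(n_exc):
                        ck_lat[r, m, n] = w_lat[m, n]

    return n_out, ERR_OK
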