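"""Millisecond-resolution simulation loop (numba-compiled).

One kernel serves all protocols; flags select which drive terms are active.
Per 1-ms step, in order:

1. threshold detection (reset-before-update): units with v >= v_thresh are
   flagged as fired, reset, and their spikes scheduled to arrive ``D_i`` ms
   later (in scripted mode, fired units come from the forced schedule
   instead and the membrane dynamics are bypassed);
2. delivery of spikes due this step -> recurrent current ``w_ij / phi``;
3. background drive (theta inhibition, uniform noise), place-field drive,
   and the one-step cue pulse, summed into the total current;
4. STDP: pairing traces are refreshed, arrivals pair with the most recent
   post spike (depression, s <= 0 incl. coincident s = 0), post spikes pair
   with the most recent strictly-earlier arrival (potentiation + triplet
   boost), each increment scaled by the theta-modulation factor and phi,
   weights clipped to [0, w_max];
5. forward-Euler integration of v (two 0.5-ms half-steps) and u (one step).

The kernel mutates ``w`` in place and records spikes as (time, neuron) pairs.
All randomness comes from numba's internal RNG, seeded once per call.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate"]

_NO_EVENT = -1e9

MOD_NONE = 0
MOD_THETA = 1
MOD_INVERSE = 2

# Phase-window readings of the eight-segment schedule.
WIN_PARTITION = 0   # eight pi/4 windows tiling the cycle, centres pi/8..15pi/8
WIN_SPAN8 = 1       # eight 7pi/32 windows inside [pi/8, 15pi/8]
WIN_SPAN7 = 2       # seven pi/4 windows inside [pi/8, 15pi/8]

_PHASE_LO = np.pi / 8.0
_PHASE_HI = 15.0 * np.pi / 8.0


@njit(cache=True)
def simulate(
    duration,          # int: number of 1-ms steps
    conn,              # bool[n, n], pre -> post
    delays,            # int64[n]
    w,                 # float64[n, n], modified in place
    # neuron parameters and initial state
    a, b, c, d, v_thresh,
    v0, u0,            # float64[n]
    # background drive
    theta_on,          # bool: theta inhibition active
    inh_gain, sigma_inh, theta_freq,
    i_noise,
    # place-field drive
    ext_on,            # bool
    i_ext, sigma_ext,
    field_of,          # int64[n]
    field_start,       # float64[n_fields], cm
    diameter, speed, route_len,   # cm, cm/s, cm
    window_mode,       # WIN_PARTITION / WIN_SPAN8 / WIN_SPAN7
    # plasticity
    plast_on,          # bool
    a_plus, a_minus, tau_plus, tau_minus, tau_pp, eps, w_max,
    mod_scheme,        # MOD_NONE / MOD_THETA / MOD_INVERSE
    phi,
    # cue pulse
    cue_ids,           # int64[], may be empty
    i_cue, cue_t,
    # scripted mode
    forced,            # bool: spikes come only from the schedule below
    sched_t, sched_id, # int64[], sorted by time
    # rng and output sizing
    seed,
    max_spikes,
    snapshot_times,    # int64[], sorted; w copied after each listed step
):
    np.random.seed(seed)
    n = conn.shape[0]
    v = v0.copy()
    u = u0.copy()

    last_arr = np.full(n, _NO_EVENT)
    last_post = np.full(n, _NO_EVENT)
    dep_mag = np.zeros((n, n))
    dep_time = np.full((n, n), _NO_EVENT)

    d_max = 1
    for i in range(n):
        if delays[i] > d_max:
            d_max = delays[i]
    ring = np.zeros((d_max + 1, n), dtype=np.bool_)

    spike_t = np.empty(max_spikes, dtype=np.int64)
    spike_id = np.empty(max_spikes, dtype=np.int64)
    n_spikes = 0
    overflow = False

    n_snap = snapshot_times.shape[0]
    snapshots = np.zeros((n_snap, n, n))
    snap_i = 0

    fired = np.zeros(n, dtype=np.bool_)
    i_tot = np.zeros(n)
    sched_ptr = 0
    two_pi = 2.0 * np.pi
    period_ms = 1000.0 / theta_freq
    # phi = 0 is a frozen-plasticity control: recurrent gain stays at 1
    inv_phi = 1.0 / phi if phi > 0.0 else 1.0

    for t in range(duration):
        # -- 1. spike detection (or forced schedule) --------------------
        for j in range(n):
            fired[j] = False
        if forced:
            while sched_ptr < sched_t.shape[0] and sched_t[sched_ptr] == t:
                fired[sched_id[sched_ptr]] = True
                sched_ptr += 1
        else:
            for j in range(n):
                if v[j] >= v_thresh:
                    fired[j] = True
                    v[j] = c
                    u[j] = u[j] + d
        for j in range(n):
            if fired[j]:
                if n_spikes < max_spikes:
                    spike_t[n_spikes] = t
                    spike_id[n_spikes] = j
                    n_spikes += 1
                else:
                    overflow = True
                ring[(t + delays[j]) % (d_max + 1), j] = True

        # -- 2. spike delivery -> recurrent current ---------------------
        slot = t % (d_max + 1)
        arrived = ring[slot].copy()
        for i in range(n):
            ring[slot, i] = False
        for j in range(n):
            i_tot[j] = 0.0
        for i in range(n):
            if arrived[i]:
                for j in range(n):
                    if conn[i, j]:
                        i_tot[j] += w[i, j] * inv_phi

        # -- 3. external drive ------------------------------------------
        phase = (two_pi * t / period_ms) % two_pi
        theta = 0.5 * (1.0 + np.cos(phase))
        if theta_on:
            for j in range(n):
                i_tot[j] += np.random.normal(-inh_gain * theta, sigma_inh)
        if i_noise > 0.0:
            for j in range(n):
                i_tot[j] += np.random.uniform(0.0, i_noise)
        if ext_on:
            pos = (speed * t / 1000.0) % route_len
            for j in range(n):
                f = field_of[j]
                dist = (pos - field_start[f]) % route_len
                if dist < diameter:
                    seg = int(8.0 * dist / diameter)
                    if seg > 7:
                        seg = 7
                    if window_mode == WIN_PARTITION:
                        width = np.pi / 4.0
                        hi = two_pi - seg * width
                    elif window_mode == WIN_SPAN8:
                        width = (_PHASE_HI - _PHASE_LO) / 8.0
                        hi = _PHASE_HI - seg * width
                    else:  # WIN_SPAN7
                        width = np.pi / 4.0
                        widx = seg if seg < 7 else 6
                        hi = _PHASE_HI - widx * width
                    lo = hi - width
                    if lo <= phase < hi:
                        i_tot[j] += np.random.normal(i_ext, sigma_ext)
        if cue_ids.shape[0] > 0 and t == cue_t:
            for k in range(cue_ids.shape[0]):
                i_tot[cue_ids[k]] += i_cue

        # -- 4. plasticity ----------------------------------------------
        if plast_on and phi > 0.0:
            if theta_on and mod_scheme == MOD_THETA:
                m_plus = 1.0 - theta
                m_minus = theta
            elif theta_on and mod_scheme == MOD_INVERSE:
                m_plus = theta
                m_minus = 1.0 - theta
            else:
                m_plus = 1.0
                m_minus = 1.0
            # refresh own-side traces first so that coincident events see
            # each other (arrival+post in the same ms -> one s=0 depression)
            for j in range(n):
                if fired[j]:
                    last_post[j] = t
            for i in range(n):
                if arrived[i]:
                    last_arr[i] = t
            for i in range(n):
                if arrived[i]:
                    for j in range(n):
                        if conn[i, j] and last_post[j] > -1e8:
                            s = last_post[j] - t  # <= 0
                            dw = a_minus * np.exp(s / tau_minus) * m_minus * phi
                            nw = w[i, j] + dw
                            if nw < 0.0:
                                nw = 0.0
                            dec = w[i, j] - nw
                            if dec > 0.0:
                                dep_mag[i, j] = dec
                                dep_time[i, j] = t
                            w[i, j] = nw
            for j in range(n):
                if fired[j]:
                    for i in range(n):
                        if conn[i, j] and last_arr[i] > -1e8:
                            s = t - last_arr[i]
                            if s > 0:
                                dw = a_plus * np.exp(-s / tau_plus)
                                if eps > 0.0 and dep_time[i, j] > -1e8:
                                    dw += (
                                        eps
                                        * dep_mag[i, j]
                                        * np.exp(-(t - dep_time[i, j]) / tau_pp)
                                    )
                                dw *= m_plus * phi
                                nw = w[i, j] + dw
                                if nw > w_max:
                                    nw = w_max
                                w[i, j] = nw

        # -- 5. membrane integration ------------------------------------
        if not forced:
            for j in range(n):
                vj = v[j]
                uj = u[j]
                ij = i_tot[j]
                vj += 0.5 * (0.04 * vj * vj + 5.0 * vj + 140.0 - uj + ij)
                vj += 0.5 * (0.04 * vj * vj + 5.0 * vj + 140.0 - uj + ij)
                uj += a * (b * vj - uj)
                v[j] = vj
                u[j] = uj

        if snap_i < n_snap and snapshot_times[snap_i] == t:
            for i in range(n):
                for j in range(n):
                    snapshots[snap_i, i, j] = w[i, j]
            snap_i += 1

    return spike_t[:n_spikes], spike_id[:n_spikes], overflow, snapshots, v, u
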