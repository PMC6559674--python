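"""Numba kernels for the inhomogeneous l-TASEP Gillespie dynamics.

All kernels share the same elementary rules, applied to a configuration of
A-site positions held in *descending* order (index 0 = leading ribosome):

* initiation with rate ``alpha`` places a new A-site at codon 1, enabled
  only when no A-site occupies codons 1..ell+1 (a ribosome translating any
  of those positions sterically covers the start region);
* a ribosome at codon j hops to j+1 with rate ``omega[j-1]`` unless the
  ribosome ahead sits exactly ell codons away (A-sites may never be closer
  than ell);
* the leading ribosome terminates from the stop codon with rate ``beta``.

Waiting times are exponential in the total enabled rate and events are
selected proportionally to their rates (exact stochastic simulation).
Each kernel seeds numba's own RNG, so a fixed seed gives bit-identical
trajectories.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_ABSORBED = 1  # zero total rate (e.g. alpha = 0 and no ribosomes left)
STATUS_GUARD = 2  # event guard exhausted before the stopping condition


@njit(cache=True, inline="always")
def _fill_rates(pos, n, omega, alpha, beta, ell, nc, rates):
    """Enabled event rates: rates[0..n-1] ribosome moves, rates[n] initiation."""
    total = 0.0
    for i in range(n):
        p = pos[i]
        if i == 0:
            r = beta if p == nc else omega[p - 1]
        elif pos[i - 1] - p > ell:
            r = omega[p - 1]
        else:
            r = 0.0
        rates[i] = r
        total += r
    if n == 0 or pos[n - 1] > ell + 1:
        rates[n] = alpha
        total += alpha
    else:
        rates[n] = 0.0
    return total


@njit(cache=True, inline="always")
def _pick(rates, n_events, total):
    u = np.random.random() * total
    acc = 0.0
    for i in range(n_events):
        acc += rates[i]
        if u < acc:
            return i
    return n_events - 1


@njit(cache=True)
def steady_state_kernel(
    omega,
    alpha,
    beta,
    ell,
    snapshot_interval,
    target_reads,
    burnin_elong,
    burnin_proteins,
    max_events,
    max_snapshots,
    store_snapshots,
    seed,
):
    """Run to steady state, then record snapshots until the accumulated
    in-silico reads reach ``target_reads``.

    Snapshots are taken at fixed intervals of *simulated time* equal to
    ``snapshot_interval`` times the mean event waiting time observed during
    burn-in.  Sampling uniformly in time (rather than every k-th event) is
    what makes snapshot frequencies unbiased estimates of occupancy: the
    event rate grows with the number of ribosomes, so event-indexed
    sampling would oversample crowded configurations.

    Returns (counts, snap_offsets, snap_positions, n_snapshots, hop_counts,
    n_initiations, sampling_time, status).  ``counts`` are A-site positions
    summed over snapshots; ``hop_counts[j-1]`` tallies moves out of codon j
    (termination counted at the stop codon) after burn-in, for flux checks.
    """
    nc = omega.shape[0] + 1
    np.random.seed(seed)
    max_r = nc // ell + 2
    pos = np.zeros(max_r, dtype=np.int64)
    rates = np.zeros(max_r + 1)
    n = 0

    counts = np.zeros(nc, dtype=np.int64)
    hop_counts = np.zeros(nc, dtype=np.int64)
    cap = target_reads + max_r + 1
    off_cap = max_snapshots + 1
    if not store_snapshots:
        cap = 1
        off_cap = 1
    snap_positions = np.zeros(cap, dtype=np.int32)
    snap_offsets = np.zeros(off_cap, dtype=np.int64)

    t = 0.0
    t_start_sampling = 0.0
    events = 0
    elong = 0
    completed = 0
    n_init = 0
    burned = False
    reads = 0
    nsnap = 0
    nstored = 0
    dt_snap = 0.0
    next_snap = 0.0
    status = STATUS_GUARD
    done = False

    while events < max_events and not done:
        total = _fill_rates(pos, n, omega, alpha, beta, ell, nc, rates)
        if total <= 0.0:
            status = STATUS_ABSORBED
            break
        t_new = t + -np.log(np.random.random()) / total
        if burned:
            # the configuration is constant on (t, t_new]; record it at
            # every sampling time crossed by this waiting interval
            while next_snap <= t_new:
                if nsnap >= max_snapshots:
                    status = STATUS_GUARD
                    done = True
                    break
                if store_snapshots:
                    for i in range(n - 1, -1, -1):  # ascending within snapshot
                        snap_positions[nstored] = pos[i]
                        nstored += 1
                for i in range(n):
                    counts[pos[i] - 1] += 1
                reads += n
                nsnap += 1
                if store_snapshots:
                    snap_offsets[nsnap] = nstored
                next_snap += dt_snap
                if reads >= target_reads:
                    status = STATUS_OK
                    done = True
                    break
            if done:
                break
        t = t_new
        k = _pick(rates, n + 1, total)
        if k == n:
            pos[n] = 1  # descending order: the new trailing ribosome goes last
            n += 1
            if burned:
                n_init += 1
        else:
            p = pos[k]
            if k == 0 and p == nc:
                for i in range(1, n):
                    pos[i - 1] = pos[i]
                n -= 1
                completed += 1
                if burned:
                    hop_counts[nc - 1] += 1
            else:
                pos[k] = p + 1
                elong += 1
                if burned:
                    hop_counts[p - 1] += 1
        events += 1
        if not burned and elong >= burnin_elong and completed >= burnin_proteins:
            burned = True
            t_start_sampling = t
            dt_snap = snapshot_interval * t / events
            next_snap = t + dt_snap

    sampling_time = t - t_start_sampling
    n_off = nsnap + 1 if store_snapshots else 1
    return (
        counts,
        snap_offsets[:n_off].copy(),
        snap_positions[:nstored].copy(),
        nsnap,
        hop_counts,
        n_init,
        sampling_time,
        status,
    )


@njit(cache=True)
def traversal_kernel(omega, alpha, beta, ell, n_traversals, n_discard, max_events, seed):
    """First-passage (start codon -> termination) times under full exclusion
    dynamics.  The first ``n_discard`` completions are dropped as burn-in.

    Returns (times, status).
    """
    nc = omega.shape[0] + 1
    np.random.seed(seed)
    max_r = nc // ell + 2
    pos = np.zeros(max_r, dtype=np.int64)
    init_t = np.zeros(max_r)
    rates = np.zeros(max_r + 1)
    n = 0
    t = 0.0
    events = 0
    completed = 0
    times = np.zeros(n_traversals)
    recorded = 0
    status = STATUS_GUARD
    while events < max_events:
        total = _fill_rates(pos, n, omega, alpha, beta, ell, nc, rates)
        if total <= 0.0:
            status = STATUS_ABSORBED
            break
        t += -np.log(np.random.random()) / total
        k = _pick(rates, n + 1, total)
        if k == n:
            pos[n] = 1
            init_t[n] = t
            n += 1
        else:
            p = pos[k]
            if k == 0 and p == nc:
                completed += 1
                if completed > n_discard:
                    times[recorded] = t - init_t[0]
                    recorded += 1
                for i in range(1, n):
                    pos[i - 1] = pos[i]
                    init_t[i - 1] = init_t[i]
                n -= 1
                if recorded >= n_traversals:
                    status = STATUS_OK
                    break
            else:
                pos[k] = p + 1
        events += 1
    return times[:recorded], status


@njit(cache=True)
def dwell_kernel(
    omega, alpha, beta, ell, min_passages, burnin_elong, burnin_proteins, max_events, seed
):
    """Per-position dwell clocks: the time between a ribosome's arrival at a
    codon position and its departure from it, averaged over passages.

    Returns (dwell_sum, dwell_count, status); mean dwell = sum/count.
    """
    nc = omega.shape[0] + 1
    np.random.seed(seed)
    max_r = nc // ell + 2
    pos = np.zeros(max_r, dtype=np.int64)
    arr_t = np.zeros(max_r)
    rates = np.zeros(max_r + 1)
    n = 0
    t = 0.0
    events = 0
    elong = 0
    completed = 0
    burned = False
    post_completed = 0
    dwell_sum = np.zeros(nc)
    dwell_count = np.zeros(nc, dtype=np.int64)
    status = STATUS_GUARD
    while events < max_events:
        total = _fill_rates(pos, n, omega, alpha, beta, ell, nc, rates)
        if total <= 0.0:
            status = STATUS_ABSORBED
            break
        t += -np.log(np.random.random()) / total
        k = _pick(rates, n + 1, total)
        if k == n:
            pos[n] = 1
            arr_t[n] = t
            n += 1
        else:
            p = pos[k]
            if burned:
                dwell_sum[p - 1] += t - arr_t[k]
                dwell_count[p - 1] += 1
            if k == 0 and p == nc:
                for i in range(1, n):
                    pos[i - 1] = pos[i]
                    arr_t[i - 1] = arr_t[i]
                n -= 1
                completed += 1
                if burned:
                    post_completed += 1
                    if post_completed >= min_passages:
                        status = STATUS_OK
                        break
            else:
                pos[k] = p + 1
                arr_t[k] = t
                elong += 1
        events += 1
        if not burned and elong >= burnin_elong and completed >= burnin_proteins:
            burned = True
    return dwell_sum, dwell_count, status


@njit(cache=True)
def runoff_kernel(omega, beta, ell, start_offsets, start_positions, dts, max_events, seed):
    """Ribosome run-off: evolve each steady-state start configuration with
    initiation switched off and record A-site counts at every time in
    ``dts`` (must be increasing; a leading 0 records the start itself).

    Returns (counts[len(dts), nc], status).
    """
    nc = omega.shape[0] + 1
    np.random.seed(seed)
    max_r = nc // ell + 2
    pos = np.zeros(max_r, dtype=np.int64)
    rates = np.zeros(max_r + 1)
    ndt = dts.shape[0]
    counts = np.zeros((ndt, nc), dtype=np.int64)
    n_starts = start_offsets.shape[0] - 1
    status = STATUS_OK
    for s in range(n_starts):
        lo = start_offsets[s]
        hi = start_offsets[s + 1]
        n = hi - lo
        for i in range(n):
            # starts are stored ascending; kernel state is descending
            pos[i] = start_positions[hi - 1 - i]
        t = 0.0
        idx = 0
        while idx < ndt and dts[idx] <= 0.0:
            for i in range(n):
                counts[idx, pos[i] - 1] += 1
            idx += 1
        events = 0
        while idx < ndt and events < max_events:
            total = _fill_rates(pos, n, omega, 0.0, beta, ell, nc, rates)
            if total <= 0.0:
                break  # all ribosomes terminated; later dts stay empty
            t_next = t + -np.log(np.random.random()) / total
            while idx < ndt and dts[idx] <= t_next:
                for i in range(n):
                    counts[idx, pos[i] - 1] += 1
                idx += 1
            t = t_next
            k = _pick(rates, n + 1, total)
            if k < n:
                p = pos[k]
                if k == 0 and p == nc:
                    for i in range(1, n):
                        pos[i - 1] = pos[i]
                    n -= 1
                else:
                    pos[k] = p + 1
            events += 1
        if events >= max_events:
            status = STATUS_GUARD
    return counts, status
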