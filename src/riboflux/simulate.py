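"""Stochastic simulation of translation as an inhomogeneous l-TASEP.

The simulator provides four in-silico experiments:

* steady-state profiling: run the exact (Gillespie) dynamics to steady
  state and save decorrelated ribosome configurations until the summed
  A-site positions reach a target read depth — each saved snapshot plays
  the role of one mRNA copy, so the snapshot set both *is* the read
  profile and defines per-codon occupancy;
* ribosome run-off: from steady-state starts, switch initiation off and
  let elongation continue for each interval in a run-off time grid before
  freezing, emulating a harringtonine/cycloheximide time course;
* true synthesis times: first-passage times from initiation to
  termination, measured ribosome by ribosome under full exclusion;
* true codon dwell times: a clock per codon position recording
  arrival-to-departure intervals, queuing delays included.

The heavy loops live in :mod:`riboflux._kernels`; :func:`step_kinetics`
is a plain-Python single-event reference of the same rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .model import (
    FootprintProfile,
    RunoffSeries,
    SnapshotSet,
    TranscriptModel,
    validate_transcript_model,
)

__all__ = [
    "SimConfig",
    "SimulationError",
    "step_kinetics",
    "simulate_steady_state",
    "simulate_runoff",
    "measure_true_synthesis_time",
    "measure_true_codon_times",
]

DEFAULT_MAX_EVENTS = 4_000_000_000


class SimulationError(RuntimeError):
    """Raised when a simulation cannot reach its stopping condition."""


@dataclass
class SimConfig:
    """Knobs of the in-silico experiments.

    ``snapshot_interval`` sets the spacing of saved snapshots in units of
    the mean Gillespie event waiting time (default 100, which decorrelates
    successive configurations for typical transcript lengths); snapshots
    are taken uniformly in simulated time so that snapshot frequencies are
    unbiased occupancy estimates.  Burn-in discards events until at least
    ``burnin_elong_per_codon * n_codons`` elongation events *and*
    ``burnin_proteins`` completed proteins have occurred.  ``max_events``
    guards against non-convergence (e.g. vanishing initiation rate).
    """

    seed: int = 0
    snapshot_interval: int = 100
    target_reads: int = 10_000
    burnin_elong_per_codon: int = 300
    burnin_proteins: int = 100
    runoff_dts: Tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    max_events: int = DEFAULT_MAX_EVENTS
    max_snapshots: Optional[int] = None  # default: 200 * target_reads

    def __post_init__(self) -> None:
        if self.snapshot_interval < 1:
            raise ValueError("snapshot_interval must be >= 1")
        if self.target_reads < 1:
            raise ValueError("target_reads must be >= 1")


def _kernel_seed(seed: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(1, np.uint32)[0])


def step_kinetics(
    state: Sequence[int], model: TranscriptModel, rng: np.random.Generator
) -> Tuple[np.ndarray, float]:
    """Apply exactly one Gillespie event to a ribosome configuration.

    ``state`` is an ascending vector of A-site positions.  Returns the new
    configuration and the exponentially distributed elapsed time; an
    absorbing configuration (no enabled event) is returned unchanged with
    infinite elapsed time.
    """
    pos = np.sort(np.asarray(state, dtype=int))
    nc = model.n_codons
    ell = model.ell
    events: List[Tuple[str, int, float]] = []
    for i, p in enumerate(pos):
        ahead_blocked = i + 1 < len(pos) and pos[i + 1] - p <= ell
        if p == nc:
            events.append(("terminate", i, model.beta))
        elif not ahead_blocked:
            events.append(("hop", i, float(model.omega[p - 1])))
    if len(pos) == 0 or pos[0] > ell + 1:
        events.append(("initiate", -1, model.alpha))
    rates = np.array([e[2] for e in events])
    total = rates.sum()
    if total <= 0:
        return pos, math.inf
    dt = rng.exponential(1.0 / total)
    kind, i, _ = events[rng.choice(len(events), p=rates / total)]
    if kind == "initiate":
        pos = np.concatenate([[1], pos])
    elif kind == "terminate":
        pos = np.delete(pos, i)
    else:
        pos = pos.copy()
        pos[i] += 1
    return pos, float(dt)


def _check(status: int, what: str, model: TranscriptModel) -> None:
    if status == _kernels.STATUS_GUARD:
        raise SimulationError(
            f"{what} did not converge within the event guard for {model.gene_id} "
            "(alpha may be too small for the requested sampling depth)"
        )


def simulate_steady_state(
    model: TranscriptModel, config: SimConfig, store_snapshots: bool = True
) -> Tuple[SnapshotSet, FootprintProfile]:
    """Steady-state in-silico ribosome profiling of one transcript.

    Snapshots are recorded every ``config.snapshot_interval`` events after
    burn-in until the total number of in-silico reads reaches
    ``config.target_reads``; the read profile is the A-site positions
    summed over snapshots.  With ``alpha = 0`` the dynamics are absorbing
    and an empty profile is returned.
    """
    validate_transcript_model(model)
    max_snapshots = (
        config.max_snapshots
        if config.max_snapshots is not None
        else min(max(100_000, 200 * config.target_reads), 20_000_000)
    )
    counts, offsets, positions, nsnap, hops, n_init, t_samp, status = (
        _kernels.steady_state_kernel(
            model.omega,
            float(model.alpha),
            float(model.beta),
            model.ell,
            config.snapshot_interval,
            config.target_reads,
            config.burnin_elong_per_codon * model.n_codons,
            config.burnin_proteins,
            config.max_events,
            max_snapshots,
            store_snapshots,
            _kernel_seed(config.seed),
        )
    )
    if status == _kernels.STATUS_ABSORBED and model.alpha > 0:
        raise SimulationError(f"dynamics absorbed unexpectedly for {model.gene_id}")
    if model.alpha > 0:
        _check(status, "steady-state sampling", model)
    snapshots = SnapshotSet(model.gene_id, offsets, positions, model.n_codons, model.ell)
    profile = FootprintProfile(model.gene_id, counts)
    snapshots.flux_diagnostics = {  # type: ignore[attr-defined]
        "hop_counts": hops,
        "n_initiations": n_init,
        "sampling_time": t_samp,
    }
    return snapshots, profile


def simulate_runoff(
    models: Sequence[TranscriptModel],
    config: SimConfig,
    seed_offset: int = 0,
) -> RunoffSeries:
    """Ribosome run-off time course over a transcript set.

    For every transcript, steady-state snapshots (one per mRNA copy) serve
    as independent starts; each start contributes one profile snapshot per
    run-off time: initiation is switched off and the configuration is
    recorded after each elapsed ``delta_t``.  Replicates accumulate until
    the average read depth of the ``delta_t = 0`` sample reaches
    ``config.target_reads``.
    """
    dts = np.asarray(config.runoff_dts, dtype=float)
    if dts[0] != 0.0:
        raise ValueError("run-off grid must include delta_t = 0")
    profiles: Dict[float, Dict[str, FootprintProfile]] = {float(d): {} for d in dts}
    ss = np.random.SeedSequence(config.seed + seed_offset)
    child_seeds = ss.generate_state(2 * len(models), np.uint32)
    for m, model in enumerate(models):
        sub = SimConfig(
            seed=int(child_seeds[2 * m]),
            snapshot_interval=config.snapshot_interval,
            target_reads=config.target_reads,
            burnin_elong_per_codon=config.burnin_elong_per_codon,
            burnin_proteins=config.burnin_proteins,
            max_events=config.max_events,
            max_snapshots=config.max_snapshots,
        )
        snapshots, _ = simulate_steady_state(model, sub, store_snapshots=True)
        counts, status = _kernels.runoff_kernel(
            model.omega,
            float(model.beta),
            model.ell,
            snapshots.offsets,
            snapshots.positions,
            dts,
            config.max_events,
            int(child_seeds[2 * m + 1]),
        )
        _check(status, "run-off", model)
        for d_idx, d in enumerate(dts):
            profiles[float(d)][model.gene_id] = FootprintProfile(
                model.gene_id, counts[d_idx]
            )
    return RunoffSeries(tuple(float(d) for d in dts), profiles)


def measure_true_synthesis_time(
    model: TranscriptModel,
    n_ribosomes: int = 10_000,
    seed: int = 0,
    n_discard: int = 50,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> Tuple[float, float]:
    """Mean first-passage time from initiation to termination (seconds).

    Measured from ``n_ribosomes`` completed traversals under the full
    exclusion dynamics at the transcript's own initiation rate; the first
    ``n_discard`` completions are dropped so the measurement reflects the
    crowded steady state.  Returns (mean, standard error).
    """
    validate_transcript_model(model)
    if model.alpha <= 0:
        raise SimulationError("synthesis time undefined for alpha = 0")
    times, status = _kernels.traversal_kernel(
        model.omega,
        float(model.alpha),
        float(model.beta),
        model.ell,
        n_ribosomes,
        n_discard,
        max_events,
        _kernel_seed(seed),
    )
    _check(status, "synthesis-time measurement", model)
    return float(times.mean()), float(times.std(ddof=1) / math.sqrt(len(times)))


def measure_true_codon_times(
    model: TranscriptModel,
    min_passages: int = 10_000,
    seed: int = 0,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> np.ndarray:
    """Mean observed dwell time at every codon position (seconds).

    A clock at each position records the interval between a ribosome's
    arrival and departure; the mean over at least ``min_passages``
    completed traversals is returned for positions 1..n_codons.  These are
    *observed* times: exclusion delays are included, so the dwell at j is
    >= 1/omega(j) in expectation.
    """
    validate_transcript_model(model)
    if model.alpha <= 0:
        raise SimulationError("dwell times undefined for alpha = 0")
    dwell_sum, dwell_count, status = _kernels.dwell_kernel(
        model.omega,
        float(model.alpha),
        float(model.beta),
        model.ell,
        min_passages,
        20 * model.n_codons,
        20,
        max_events,
        _kernel_seed(seed),
    )
    _check(status, "dwell-time measurement", model)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = dwell_sum / dwell_count
    return mean
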