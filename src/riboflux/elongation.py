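"""Transcriptome-average elongation rate from ribosome run-off data.

After initiation is blocked at t = 0, ribosome density obeys a continuity
equation: the density within the first L codons can only decrease, at the
rate at which ribosomes flow out across position L.  Integrating gives a
linear depletion law,

    rho(t = dt, L) / rho(t = 0, L) = 1 - dt / tau(L),

so the x-intercept of the depletion ratio against run-off time is tau(L),
the time at which the last ribosomes have crossed position L.  Repeating
over a grid of L and fitting tau(L) against L yields the average
elongation rate <omega> = dL/dtau as the inverse slope; the intercept
absorbs fixed delays (e.g. the time harringtonine takes to engage
ribosomes in vivo, which makes it negative).

The metagene density averages transcripts with equal weight after each
(transcript, dt) profile is normalized by its own mean read depth over a
3' window that lies beyond the farthest run-off front, cancelling library
depth; transcripts shorter than a position simply drop out of the average
at that position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .model import ElongationFit, RunoffSeries

__all__ = [
    "MetageneDensity",
    "ElongationError",
    "metagene_normalize",
    "depletion_ratio",
    "select_L_grid",
    "fit_tau_L",
    "fit_global_rate",
    "estimate_elongation_rate",
]


class ElongationError(ValueError):
    pass


@dataclass
class MetageneDensity:
    """Normalized average read density per (run-off time, codon position)."""

    delta_ts: Tuple[float, ...]
    density: np.ndarray  # shape (n_delta_ts, j_max)
    n_transcripts: np.ndarray  # transcripts contributing at each position
    norm_window: Tuple[int, int]  # 1-based inclusive positions

    def at(self, delta_t: float) -> np.ndarray:
        return self.density[self.delta_ts.index(float(delta_t))]


def metagene_normalize(
    series: RunoffSeries,
    j_max: int,
    norm_window: Optional[Tuple[int, int]] = None,
) -> MetageneDensity:
    """Average per-transcript self-normalized profiles over the gene set.

    ``norm_window`` (1-based, inclusive) defaults to the final 20% of
    positions within ``j_max``; a transcript with zero reads in its window
    at some run-off time is dropped from that time's average.
    """
    if norm_window is None:
        norm_window = (int(np.ceil(0.8 * j_max)) + 1, j_max)
    lo, hi = norm_window
    if not (1 <= lo <= hi <= j_max):
        raise ElongationError("norm_window must lie within [1, j_max]")
    dts = series.delta_ts
    n_dt = len(dts)
    dens_sum = np.zeros((n_dt, j_max))
    n_contrib = np.zeros((n_dt, j_max), dtype=np.int64)
    for d_idx, dt in enumerate(dts):
        for gene_id, profile in series.profiles[dt].items():
            counts = profile.counts.astype(float)
            nc = counts.shape[0]
            if nc < hi:
                continue  # transcript too short to define the window
            norm = counts[lo - 1 : hi].mean()
            if norm <= 0:
                continue
            upto = min(nc, j_max)
            dens_sum[d_idx, :upto] += counts[:upto] / norm
            n_contrib[d_idx, :upto] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        density = dens_sum / n_contrib
    density[n_contrib == 0] = np.nan
    return MetageneDensity(
        delta_ts=tuple(dts),
        density=density,
        n_transcripts=n_contrib[0],
        norm_window=(lo, hi),
    )


def depletion_ratio(md: MetageneDensity, L: int) -> np.ndarray:
    """Per-run-off-time ratio of average density within the first L codons
    to its value at dt = 0 (1 at dt = 0 by construction)."""
    if not (1 <= L <= md.density.shape[1]):
        raise ElongationError("L outside the metagene range")
    window = md.density[:, :L]
    sums = np.nansum(window, axis=1)
    if sums[0] <= 0:
        raise ElongationError("zero density within [1, L] at delta_t = 0")
    return sums / sums[0]


def select_L_grid(
    md: MetageneDensity,
    L_range: Sequence[int],
    max_final_ratio: float = 0.5,
) -> List[int]:
    """Keep the window lengths L at which the longest run-off time still
    depletes the 5' density below ``max_final_ratio``.

    The x-intercept extrapolation of the depletion line is unstable when
    depletion is shallow, so windows that barely deplete within the time
    grid are excluded.
    """
    kept = []
    for L in L_range:
        ratios = depletion_ratio(md, int(L))
        if ratios[-1] < max_final_ratio:
            kept.append(int(L))
    return kept


def fit_tau_L(ratios: Sequence[float], delta_ts: Sequence[float]) -> Tuple[float, Dict]:
    """Depletion time tau(L): the x-intercept of the least-squares line
    through the (delta_t, ratio) points."""
    ratios = np.asarray(ratios, float)
    dts = np.asarray(delta_ts, float)
    if len(ratios) < 2:
        raise ElongationError("need >= 2 run-off times to fit tau(L)")
    fit = stats.linregress(dts, ratios)
    if fit.slope >= 0:
        raise ElongationError("no depletion at this L (non-negative slope)")
    tau = -fit.intercept / fit.slope
    return float(tau), {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
    }


def fit_global_rate(Ls: Sequence[int], taus: Sequence[float]) -> ElongationFit:
    """Average elongation rate as the inverse slope of tau(L) against L."""
    Ls = np.asarray(Ls, float)
    taus = np.asarray(taus, float)
    if len(Ls) < 3:
        raise ElongationError("need >= 3 L values")
    fit = stats.linregress(Ls, taus)
    if fit.slope <= 0:
        raise ElongationError("non-positive dtau/dL slope")
    return ElongationFit(
        L=Ls,
        tau_L=taus,
        omega=float(1.0 / fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def estimate_elongation_rate(
    series: RunoffSeries,
    L_grid: Sequence[int],
    j_max: Optional[int] = None,
    norm_window: Optional[Tuple[int, int]] = None,
) -> ElongationFit:
    """Full run-off analysis chain: metagene density, per-L depletion-line
    fits, and the tau(L)-vs-L slope inversion."""
    L_grid = sorted(int(L) for L in L_grid)
    if j_max is None:
        j_max = max(L_grid) if norm_window is None else norm_window[1]
    md = metagene_normalize(series, j_max=j_max, norm_window=norm_window)
    taus: List[float] = []
    Ls: List[int] = []
    per_L_r2: List[float] = []
    for L in L_grid:
        ratios = depletion_ratio(md, L)
        tau, diag = fit_tau_L(ratios, md.delta_ts)
        Ls.append(L)
        taus.append(tau)
        per_L_r2.append(diag["r_squared"])
    fit = fit_global_rate(Ls, taus)
    fit.per_L_r_squared = np.asarray(per_L_r2)
    return fit
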