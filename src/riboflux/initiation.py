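"""Absolute translation-initiation rates from ribosome occupancy.

At steady state the flux of ribosomes through every codon equals the
protein-release rate, and the initiation flux is the intrinsic initiation
rate alpha times the probability that the start region (the first ell+1
codon positions) carries no A-site.  Combining the two gives

    alpha = <rho> (Nc - 1) / ( <T> [1 - sum_{k=2..ell+1} rho(k)] )

where <rho> is the mean per-codon occupancy over positions 2..Nc and <T>
is the mean time to synthesize one full-length protein.  The relation is
first order in alpha: it drops correlations among the start-region
occupancies, which is accurate in the low-density regime most transcripts
inhabit.

Occupancies come either directly from simulation snapshots (each snapshot
is one mRNA copy) or from experimental data, where the per-mRNA ribosome
load R(i) — from polysome profiling, or from translation efficiency via
the fitted proportionality R = xi * TE — is apportioned along the CDS by
relative A-site read counts.  <T> comes from the CDS-length scaling
relation <T> = Nc * <tau_A> (transcriptome-average codon time, 200 ms by
default) or from a direct measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import FootprintProfile, OccupancyProfile, SnapshotSet

__all__ = [
    "InitiationEstimate",
    "CalibrationFit",
    "InitiationError",
    "synthesis_time_scaling",
    "calibrate_xi",
    "occupancy_from_snapshots",
    "occupancy_from_experiment",
    "estimate_initiation",
    "filter_initiation_genes",
]

DEFAULT_TAU_A = 0.200  # s, transcriptome-average codon translation time


class InitiationError(ValueError):
    """Raised when the initiation-rate relation is not applicable."""


@dataclass
class InitiationEstimate:
    gene_id: str
    alpha_hat: float  # 1/s
    mean_rho: float
    t_mean: float  # s
    blocked_occupancy: float  # sum of rho over positions 2..ell+1
    flagged: bool = False


@dataclass
class CalibrationFit:
    """Through-origin fit of per-mRNA ribosome load against translation
    efficiency, R = xi * TE."""

    xi: float
    n_genes: int
    r_squared: float

    def __post_init__(self) -> None:
        if not (self.xi > 0):
            raise InitiationError("calibration slope xi must be positive")


def synthesis_time_scaling(n_codons: int, tau_a: float = DEFAULT_TAU_A) -> float:
    """Mean protein synthesis time from the CDS-length scaling relation,
    <T> = Nc * <tau_A>."""
    if tau_a <= 0:
        raise InitiationError("tau_a must be positive")
    if n_codons < 1:
        raise InitiationError("n_codons must be >= 1")
    return n_codons * tau_a


def calibrate_xi(te: pd.Series, polysome_load: pd.Series) -> CalibrationFit:
    """Least-squares slope through the origin of ribosomes-per-mRNA on
    translation efficiency (closed form sum(xy)/sum(x^2))."""
    joined = pd.concat(
        {"te": te, "load": polysome_load}, axis=1, join="inner"
    ).dropna()
    if len(joined) == 0:
        raise InitiationError("no genes shared between TE and polysome tables")
    if len(joined) < 10:
        raise InitiationError("calibration requires at least 10 shared genes")
    x = joined["te"].to_numpy(float)
    y = joined["load"].to_numpy(float)
    xi = float(np.sum(x * y) / np.sum(x * x))
    resid = y - xi * x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationFit(xi=xi, n_genes=len(joined), r_squared=r2)


def occupancy_from_snapshots(snapshots: SnapshotSet) -> OccupancyProfile:
    """Per-codon occupancy as the A-site frequency across snapshots."""
    n = snapshots.n_snapshots
    if n == 0:
        rho = np.zeros(snapshots.n_codons)
    else:
        rho = snapshots.counts() / n
    return OccupancyProfile(snapshots.gene_id, rho, source="simulation_snapshots")


def occupancy_from_experiment(
    profile: FootprintProfile,
    ribosome_load: Optional[float] = None,
    te: Optional[float] = None,
    calibration: Optional[CalibrationFit] = None,
) -> OccupancyProfile:
    """Occupancy calibrated from experimental data.

    The per-mRNA ribosome load R(i) — given directly (polysome profiling)
    or as ``calibration.xi * te`` — is distributed along positions
    2..n_codons proportionally to the A-site read counts, so that
    rho(j) = R * c(j) / sum_{k>=2} c(k) and <rho> = R / (Nc - 1).
    Profiles whose implied occupancy exceeds 1 anywhere are flagged rather
    than rejected (the calibration is then inconsistent with the
    occupancy bound).
    """
    if ribosome_load is None:
        if te is None or calibration is None:
            raise InitiationError("need ribosome_load or (te, calibration)")
        ribosome_load = calibration.xi * te
    if ribosome_load < 0:
        raise InitiationError("negative ribosome load")
    counts = profile.counts.astype(float)
    denom = counts[1:].sum()
    rho = np.zeros_like(counts)
    if ribosome_load > 0:
        if denom <= 0:
            raise InitiationError(
                f"no reads beyond the start codon for {profile.gene_id}"
            )
        rho[1:] = ribosome_load * counts[1:] / denom
    flagged = bool(np.any(rho > 1))
    rho = np.clip(rho, 0.0, 1.0)
    return OccupancyProfile(
        profile.gene_id, rho, source="calibrated_experimental", flagged=flagged
    )


def estimate_initiation(
    occ: OccupancyProfile, t_mean: float, ell: int
) -> InitiationEstimate:
    """Initiation rate from occupancy and the mean synthesis time."""
    if t_mean <= 0:
        raise InitiationError("t_mean must be positive")
    nc = occ.n_codons
    blocked = float(occ.rho[1 : ell + 1].sum())  # positions 2..ell+1
    avail = 1.0 - blocked
    if avail <= 0:
        raise InitiationError(
            "initiation-blocked regime: first-order approximation invalid"
        )
    alpha = occ.mean_rho * (nc - 1) / (t_mean * avail)
    return InitiationEstimate(
        gene_id=occ.gene_id,
        alpha_hat=alpha,
        mean_rho=occ.mean_rho,
        t_mean=t_mean,
        blocked_occupancy=blocked,
        flagged=occ.flagged,
    )


def filter_initiation_genes(
    profiles: Iterable[FootprintProfile], min_nonzero_fraction: float = 0.95
) -> List[FootprintProfile]:
    """Keep genes whose profile has non-zero reads at >= 95% of codon
    positions (boundary inclusive) and no exclusion flags."""
    kept = []
    for p in profiles:
        if p.excluded:
            continue
        if p.nonzero_fraction() >= min_nonzero_fraction - 1e-12:
            kept.append(p)
    return kept
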