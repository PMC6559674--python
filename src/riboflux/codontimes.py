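"""Absolute per-position codon translation times from read apportionment.

At steady state the ribosome flux through every codon position equals the
protein-release rate, which makes the observed dwell time at a position
proportional to its steady-state ribosome occupancy and hence, under the
standard reads-proportional-to-ribosomes assumption, to its A-site read
count:

    tau(j, i) = c(j, i) / sum_{l=2..Nc} c(l, i) * <T(i)>.

The dwell times therefore sum exactly to the mean synthesis time of the
transcript.  They are *observed* times — queuing delays behind downstream
ribosomes are included — which is what shapes the wide per-codon-type
distributions the analytics below summarize.

Positions 1 and 2 carry signal from the initiation process and the stop
codon reflects termination, so the per-codon-type distribution summaries
cover sense codons at positions 3..Nc-1 only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import SENSE_CODONS, CodonTimeTable, FootprintProfile

__all__ = [
    "CodonTimeError",
    "filter_codon_rate_genes",
    "estimate_codon_times",
    "codon_type_summaries",
]


class CodonTimeError(ValueError):
    pass


def filter_codon_rate_genes(
    profiles: Iterable[FootprintProfile], min_reads: int = 3
) -> List[FootprintProfile]:
    """Keep genes with at least ``min_reads`` reads at every codon position
    j = 2..Nc and no exclusion flags (multi-mapping, introns, CDS
    overlap)."""
    kept = []
    for p in profiles:
        if p.excluded:
            continue
        if np.all(p.counts[1:] >= min_reads):
            kept.append(p)
    return kept


def estimate_codon_times(profile: FootprintProfile, t_mean: float) -> CodonTimeTable:
    """Apportion the mean synthesis time along the transcript by relative
    A-site reads (positions 2..Nc).

    Zero-count positions — which the read filter normally removes — yield
    a zero dwell time and are tallied on the returned table rather than
    raising, since a zero read count is a sampling artifact, not a
    zero-time codon.
    """
    if t_mean <= 0:
        raise CodonTimeError("t_mean must be positive")
    counts = profile.counts[1:].astype(float)  # positions 2..Nc
    total = counts.sum()
    if total <= 0:
        raise CodonTimeError(f"zero total counts for {profile.gene_id}")
    tau = counts / total * t_mean
    return CodonTimeTable(
        gene_id=profile.gene_id,
        tau=tau,
        synthesis_time_used=float(t_mean),
        zero_count_positions=int(np.count_nonzero(counts == 0)),
    )


def _bootstrap_se_median(values: np.ndarray, n_boot: int, rng: np.random.Generator) -> float:
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    return float(np.median(values[idx], axis=1).std(ddof=1))


def codon_type_summaries(
    tables: Sequence[CodonTimeTable],
    sequences: Dict[str, Sequence[str]],
    n_boot: int = 10_000,
    seed: int = 0,
) -> Tuple[pd.DataFrame, float]:
    """Distribution summaries of dwell times per sense-codon type.

    ``sequences`` maps gene_id to its codon tuple.  Occurrences at codon
    positions 1-2 (initiation signal) and the stop codon are excluded.
    Returns a table indexed by codon type with n, median, bootstrap SE of
    the median, and the 5th/95th percentiles, plus the transcriptome
    fold-variability: the ratio of the largest 95th percentile to the
    smallest 5th percentile across types (i.e. the dynamic range after
    trimming each type's extreme 5% tails).
    """
    rng = np.random.default_rng(seed)
    by_type: Dict[str, List[float]] = {c: [] for c in SENSE_CODONS}
    for table in tables:
        codons = sequences[table.gene_id]
        nc = len(codons)
        if nc != table.n_codons:
            raise CodonTimeError(f"sequence/profile length mismatch for {table.gene_id}")
        for j in range(3, nc):  # positions 3..Nc-1
            codon = str(codons[j - 1]).upper()
            if codon in by_type:
                by_type[codon].append(table.tau_at(j))
    rows = []
    for codon in SENSE_CODONS:
        values = np.asarray(by_type[codon], float)
        n = len(values)
        if n == 0:
            continue
        med = float(np.median(values))
        p5, p95 = (np.percentile(values, [5, 95]) if n > 1 else (values[0], values[0]))
        se = _bootstrap_se_median(values, n_boot, rng) if n >= 2 else np.nan
        rows.append(
            {
                "codon": codon,
                "n": n,
                "median_s": med,
                "se_median_s": se,
                "p5_s": float(p5),
                "p95_s": float(p95),
            }
        )
    summary = pd.DataFrame(rows).set_index("codon")
    eligible = summary[summary["n"] >= 2]
    fold = float(eligible["p95_s"].max() / eligible["p5_s"].min()) if len(eligible) else np.nan
    return summary, fold
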