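"""Synthetic transcriptomes and matched pseudo-experimental inputs.

The generator draws a yeast-like transcriptome whose kinetic parameters
have the statistical structure the estimators assume: coding-sequence
lengths log-normal with a mode near 400 codons; one intrinsic rate per
sense-codon type drawn log-uniformly over [2, 20] 1/s and rescaled so the
transcriptome-average elongation rate (total codons over total intrinsic
time) hits a target, 4.2 AA/s by default; initiation rates log-uniform
over [0.01, 0.5] 1/s; termination at 35 1/s.  Read depth defaults to a
mean of ~19 reads per codon, the coverage of a typical high-coverage
yeast ribosome-profiling library.

Codon usage is uniform over the 61 sense codons unless a frequency table
is supplied — codon identity matters for the sequence-feature analytics,
not for rate recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import SENSE_CODONS, STOP_CODONS, SnapshotSet, TranscriptModel

__all__ = [
    "SyntheticSpec",
    "draw_codon_rate_table",
    "generate_transcriptome",
    "draw_target_reads",
    "generate_ramp_variant",
    "generate_expression_tables",
    "transcriptome_average_rate",
]


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic transcriptome."""

    n_transcripts: int = 200
    length_mode: float = 400.0  # codons, mode of the log-normal CDS length law
    length_sigma: float = 0.35
    min_codons: int = 50
    rate_low: float = 2.0  # 1/s, per-codon-type intrinsic rate law
    rate_high: float = 20.0
    target_avg_rate: float = 4.2  # AA/s, transcriptome-average elongation rate
    alpha_low: float = 0.01  # 1/s, initiation-rate law
    alpha_high: float = 0.5
    beta: float = 35.0
    ell: int = 10
    a_site_offset: int = 5
    reads_per_codon: float = 19.0  # mean coverage of the read-depth law
    coverage_sigma: float = 1.0  # log-scale spread of per-transcript depth
    utr5_length: int = 60
    codon_usage: Optional[Dict[str, float]] = None  # overrides uniform usage
    seed: int = 0


def draw_codon_rate_table(spec: SyntheticSpec, rng: np.random.Generator) -> Dict[str, float]:
    """One intrinsic rate per sense-codon type, log-uniform on the spec range
    (unscaled; the transcriptome-level rescaling happens after sequences
    are drawn, because the average depends on codon usage)."""
    rates = np.exp(rng.uniform(np.log(spec.rate_low), np.log(spec.rate_high), len(SENSE_CODONS)))
    return dict(zip(SENSE_CODONS, rates))


def transcriptome_average_rate(models: Sequence[TranscriptModel]) -> float:
    """Average elongation speed in AA/s: total elongation steps divided by
    the total intrinsic time, i.e. the harmonic mean of the per-position
    intrinsic rates."""
    n_steps = sum(m.n_codons - 1 for m in models)
    t_total = sum(float(np.sum(1.0 / m.omega)) for m in models)
    return n_steps / t_total


def generate_transcriptome(spec: SyntheticSpec) -> List[TranscriptModel]:
    """Draw a synthetic transcriptome; reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    rate_table = draw_codon_rate_table(spec, rng)

    if spec.codon_usage is None:
        codon_choices = list(SENSE_CODONS)
        codon_p = None
    else:
        codon_choices = list(spec.codon_usage)
        weights = np.array([spec.codon_usage[c] for c in codon_choices], dtype=float)
        codon_p = weights / weights.sum()

    mu = np.log(spec.length_mode) + spec.length_sigma**2
    models: List[TranscriptModel] = []
    for i in range(spec.n_transcripts):
        nc = int(round(float(rng.lognormal(mu, spec.length_sigma))))
        nc = max(nc, spec.min_codons, spec.ell + 2)
        body = rng.choice(codon_choices, size=nc - 2, p=codon_p)
        codons = ("ATG",) + tuple(body) + (str(rng.choice(STOP_CODONS)),)
        omega = np.array([rate_table[c] for c in codons[:-1]])
        alpha = float(
            np.exp(rng.uniform(np.log(spec.alpha_low), np.log(spec.alpha_high)))
        )
        utr5 = "".join(rng.choice(list("ACGT"), size=spec.utr5_length))
        models.append(
            TranscriptModel(
                gene_id=f"SYN{i + 1:04d}",
                codons=codons,
                alpha=alpha,
                omega=omega,
                beta=spec.beta,
                utr5=utr5,
                ell=spec.ell,
                a_site_offset=spec.a_site_offset,
            )
        )

    # rescale all intrinsic rates so the transcriptome-average elongation
    # rate equals the target exactly
    scale = spec.target_avg_rate / transcriptome_average_rate(models)
    for m in models:
        m.omega = m.omega * scale
    return models


def draw_target_reads(spec: SyntheticSpec, models: Sequence[TranscriptModel]) -> Dict[str, int]:
    """Per-transcript target read counts: log-normal per-codon depth with
    mean ``spec.reads_per_codon``, times the CDS length."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    sigma = spec.coverage_sigma
    mu = np.log(spec.reads_per_codon) - sigma**2 / 2.0
    depth = rng.lognormal(mu, sigma, len(models))
    return {
        m.gene_id: max(1, int(round(d * m.n_codons))) for m, d in zip(models, depth)
    }


def generate_ramp_variant(
    models: Sequence[TranscriptModel], first_k: int = 100, slowdown: float = 0.5
) -> List[TranscriptModel]:
    """Slow the intrinsic rates of the first ``first_k`` codons by the given
    factor (a 5' translational ramp); positions beyond ``first_k`` are
    untouched."""
    if not (0 < slowdown <= 1):
        raise ValueError("slowdown must be in (0, 1]")
    out = []
    for m in models:
        omega = m.omega.copy()
        k = min(first_k, omega.shape[0])
        omega[:k] = omega[:k] * slowdown
        out.append(
            TranscriptModel(
                gene_id=m.gene_id,
                codons=m.codons,
                alpha=m.alpha,
                omega=omega,
                beta=m.beta,
                utr5=m.utr5,
                ell=m.ell,
                a_site_offset=m.a_site_offset,
            )
        )
    return out


def generate_expression_tables(
    models: Sequence[TranscriptModel],
    snapshot_sets: Dict[str, SnapshotSet],
    seed: int = 0,
    rna_depth_per_copy: float = 50.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pseudo RNA-Seq RPKM and polysome ribosome-load tables.

    The mRNA copy number of a gene is its snapshot count; RNA-Seq RPKM is
    proportional to copy number with Poisson counting noise, and the
    polysome load R(i) is the mean number of ribosomes per snapshot.
    """
    rng = np.random.default_rng(seed)
    rows_rpkm = []
    rows_poly = []
    for m in models:
        snaps = snapshot_sets[m.gene_id]
        copies = snaps.n_snapshots
        lam = copies * rna_depth_per_copy
        reads = rng.poisson(lam) if lam > 0 else 0
        rpkm = reads / rna_depth_per_copy  # arbitrary but consistent units
        load = (
            float(snaps.ribosomes_per_snapshot().mean()) if copies > 0 else 0.0
        )
        rows_rpkm.append({"gene_id": m.gene_id, "rpkm": rpkm})
        rows_poly.append({"gene_id": m.gene_id, "ribosomes_per_mrna": load})
    return pd.DataFrame(rows_rpkm), pd.DataFrame(rows_poly)
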