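"""Domain types shared across the package.

Conventions
-----------
Codon positions are 1-based: position 1 is the start codon (AUG) and
position ``n_codons`` is the stop codon.  A ribosome's location on a
transcript is the codon index of its A-site.  A ribosome footprint spans
``ell`` codons with the A-site at the ``a_site_offset``-th position from
the footprint's 5' end (0-based offset; the canonical 10-codon footprint
carries the A-site at the sixth codon, i.e. offset 5).  Two A-sites on the
same transcript therefore can never be closer than ``ell`` codons.

Rates are first-order rate constants in 1/s: ``alpha`` (initiation in the
absence of any blocking ribosome), ``omega[j-1]`` (intrinsic hop rate from
codon j to j+1, defined for j = 1..n_codons-1) and ``beta`` (termination
once the A-site reaches the stop codon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np

__all__ = [
    "ValidationError",
    "TranscriptModel",
    "FootprintProfile",
    "OccupancyProfile",
    "SnapshotSet",
    "RunoffSeries",
    "CodonTimeTable",
    "ElongationFit",
    "StructureAnnotation",
    "validate_transcript_model",
]

_VALID_BASES = frozenset("ACGT")
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in STOP_CODONS
)


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass
class TranscriptModel:
    """A gene's codon sequence plus the kinetic parameters of its translation.

    This is the ground truth of the simulator: everything the l-TASEP
    dynamics needs to run on one transcript.
    """

    gene_id: str
    codons: Tuple[str, ...]
    alpha: float
    omega: np.ndarray  # intrinsic elongation rates, positions 1..n_codons-1
    beta: float = 35.0
    utr5: str = ""
    ell: int = 10
    a_site_offset: int = 5

    def __post_init__(self) -> None:
        self.codons = tuple(str(c).upper() for c in self.codons)
        self.omega = np.asarray(self.omega, dtype=float)

    @property
    def n_codons(self) -> int:
        return len(self.codons)


def validate_transcript_model(model: TranscriptModel) -> TranscriptModel:
    """Check every invariant of a :class:`TranscriptModel`.

    Returns the model unchanged when valid; raises :class:`ValidationError`
    naming the offending field otherwise.
    """
    nc = model.n_codons
    if model.ell < 1:
        raise ValidationError("ell must be >= 1")
    if not (0 <= model.a_site_offset < model.ell):
        raise ValidationError("a_site_offset must lie within the footprint")
    if nc < model.ell + 2:
        raise ValidationError(
            f"transcript shorter than footprint+2 (n_codons={nc}, ell={model.ell})"
        )
    for j, codon in enumerate(model.codons, start=1):
        if len(codon) != 3 or not set(codon) <= _VALID_BASES:
            raise ValidationError(f"non-triplet codon at position {j}: {codon!r}")
    if model.omega.shape != (nc - 1,):
        raise ValidationError(
            f"omega must have length n_codons-1={nc - 1}, got {model.omega.shape}"
        )
    if not np.all(np.isfinite(model.omega)):
        raise ValidationError("non-finite elongation rate")
    bad = np.nonzero(model.omega <= 0)[0]
    if bad.size:
        raise ValidationError(f"non-positive rate at position {bad[0] + 1}")
    if not (model.alpha >= 0):
        raise ValidationError("non-positive rate: alpha")
    if not (model.beta > 0):
        raise ValidationError("non-positive rate: beta")
    if model.utr5 and not set(model.utr5.upper()) <= _VALID_BASES:
        raise ValidationError("utr5 contains non-nucleotide characters")
    return model


@dataclass
class FootprintProfile:
    """Per-codon A-site-assigned read counts for one transcript."""

    gene_id: str
    counts: np.ndarray
    multimap_excluded: bool = False
    has_intron: bool = False
    cds_overlap: bool = False

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValidationError("counts must be a 1-d vector")
        if np.any(counts < 0):
            raise ValidationError("negative read count")
        self.counts = counts.astype(np.int64)

    @property
    def n_codons(self) -> int:
        return int(self.counts.shape[0])

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def excluded(self) -> bool:
        return self.multimap_excluded or self.has_intron or self.cds_overlap

    def nonzero_fraction(self) -> float:
        return float(np.count_nonzero(self.counts)) / self.n_codons


@dataclass
class OccupancyProfile:
    """Per-codon ribosome occupancy probabilities rho(j) for one transcript.

    ``mean_rho`` is the average density per codon over positions 2..n_codons,
    the quantity the initiation-rate relation consumes.
    """

    gene_id: str
    rho: np.ndarray
    source: str = "simulation_snapshots"  # or "calibrated_experimental"
    flagged: bool = False

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        if np.any(rho < 0) or np.any(rho > 1 + 1e-12):
            raise ValidationError("occupancy out of [0, 1]")
        self.rho = rho

    @property
    def n_codons(self) -> int:
        return int(self.rho.shape[0])

    @property
    def mean_rho(self) -> float:
        return float(self.rho[1:].sum() / (self.n_codons - 1))


class SnapshotSet:
    """Decorrelated ribosome configurations saved along a simulation.

    Each snapshot is a vector of A-site codon positions; the number of
    snapshots plays the role of the mRNA copy number in the in-silico
    experiment, so per-codon occupancy is a simple snapshot frequency.

    Stored internally in a compact CSR-like layout (``offsets``/``positions``)
    because deep-coverage runs can hold millions of snapshots.
    """

    def __init__(
        self,
        gene_id: str,
        offsets: np.ndarray,
        positions: np.ndarray,
        n_codons: int,
        ell: int,
    ) -> None:
        self.gene_id = gene_id
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.positions = np.asarray(positions, dtype=np.int32)
        self.n_codons = int(n_codons)
        self.ell = int(ell)

    @classmethod
    def from_configurations(
        cls, gene_id: str, configurations: Sequence[Sequence[int]], n_codons: int, ell: int
    ) -> "SnapshotSet":
        offsets = np.zeros(len(configurations) + 1, dtype=np.int64)
        flat: List[int] = []
        for i, conf in enumerate(configurations):
            flat.extend(int(p) for p in conf)
            offsets[i + 1] = len(flat)
        return cls(gene_id, offsets, np.asarray(flat, dtype=np.int32), n_codons, ell)

    @property
    def n_snapshots(self) -> int:
        return int(self.offsets.shape[0] - 1)

    @property
    def configurations(self) -> List[np.ndarray]:
        return [
            self.positions[self.offsets[i] : self.offsets[i + 1]]
            for i in range(self.n_snapshots)
        ]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.configurations)

    def ribosomes_per_snapshot(self) -> np.ndarray:
        return np.diff(self.offsets)

    def counts(self) -> np.ndarray:
        """A-site counts summed over snapshots (the in-silico read profile)."""
        return np.bincount(self.positions - 1, minlength=self.n_codons).astype(np.int64)

    def validate(self) -> "SnapshotSet":
        if self.positions.size and (
            self.positions.min() < 1 or self.positions.max() > self.n_codons
        ):
            raise ValidationError("A-site position outside transcript")
        for conf in self:
            if conf.size > 1:
                gaps = np.diff(np.sort(conf))
                if np.any(gaps < self.ell):
                    raise ValidationError("excluded volume violated in snapshot")
        return self


@dataclass
class RunoffSeries:
    """Footprint profiles of a transcript set at a grid of run-off times.

    ``profiles[dt][gene_id]`` holds the profile observed when initiation is
    blocked at t = 0 and elongation frozen at t = dt.
    """

    delta_ts: Tuple[float, ...]
    profiles: Dict[float, Dict[str, FootprintProfile]]

    def __post_init__(self) -> None:
        dts = tuple(float(d) for d in self.delta_ts)
        if len(dts) < 1 or dts[0] != 0.0:
            raise ValidationError("delta_ts must start at 0")
        if np.any(np.diff(dts) <= 0):
            raise ValidationError("delta_ts must be strictly increasing")
        gene_sets = [frozenset(self.profiles[dt]) for dt in dts]
        if any(g != gene_sets[0] for g in gene_sets):
            raise ValidationError("same gene set required at every delta_t")
        self.delta_ts = dts

    @property
    def gene_ids(self) -> List[str]:
        return sorted(self.profiles[self.delta_ts[0]])


@dataclass
class CodonTimeTable:
    """Observed per-position dwell times tau(j) for one transcript.

    ``tau[k]`` is the dwell time of codon position ``j = k + 2`` (positions
    2..n_codons); the sum of the vector equals ``synthesis_time_used`` by
    construction.  Dwell times are *observed* times: they include queuing
    delays on top of the intrinsic codon rate.
    """

    gene_id: str
    tau: np.ndarray  # seconds, positions 2..n_codons
    synthesis_time_used: float
    zero_count_positions: int = 0

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        if np.any(tau < 0):
            raise ValidationError("negative dwell time")
        total = tau.sum()
        if total > 0 and abs(total - self.synthesis_time_used) > 1e-9 * abs(
            self.synthesis_time_used
        ):
            raise ValidationError("dwell times do not sum to the synthesis time")
        self.tau = tau

    @property
    def n_codons(self) -> int:
        return int(self.tau.shape[0] + 1)

    def tau_at(self, j: int) -> float:
        """Dwell time at 1-based codon position ``j`` (j >= 2)."""
        return float(self.tau[j - 2])


@dataclass
class ElongationFit:
    """Result of the run-off depletion analysis.

    ``omega`` is the transcriptome-average elongation rate in AA/s obtained
    as the inverse slope of the depletion time tau(L) against window length
    L; the intercept (in seconds) absorbs any fixed delay such as the time
    the initiation-blocking drug takes to engage ribosomes.
    """

    L: np.ndarray
    tau_L: np.ndarray
    omega: float
    intercept: float
    r_squared: float
    per_L_r_squared: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if len(self.L) < 3:
            raise ValidationError("fit requires at least 3 L values")
        if not (self.omega > 0):
            raise ValidationError("non-positive elongation rate")


@dataclass
class StructureAnnotation:
    """Per-codon secondary-structure call derived from DMS or PARS signals."""

    gene_id: str
    labels: Tuple[str, ...]  # each in {"structured", "unstructured", "excluded"}
    assay: str  # "DMS" or "PARS"

    def __post_init__(self) -> None:
        allowed = {"structured", "unstructured", "excluded"}
        if not set(self.labels) <= allowed:
            raise ValidationError("unknown structure label")
        if self.assay not in ("DMS", "PARS"):
            raise ValidationError("assay must be DMS or PARS")
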