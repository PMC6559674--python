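"""Readers and writers for the package's file formats.

All file formats carry 1-based codon indices; conversion to 0-based
arrays happens once, here.  Formats: FASTA for sequences (via Biopython),
long-form TSV for A-site count profiles (gene_id, codon_index, count),
TSV tables for expression/polysome/manifest data, JSON reports, and an
optionally gzipped TSV for simulation snapshots.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import FootprintProfile, SnapshotSet

__all__ = [
    "IOError_",
    "read_fasta",
    "write_fasta",
    "read_counts_tsv",
    "write_counts_tsv",
    "apply_fixed_asite_offset",
    "read_manifest",
    "read_table",
    "write_report",
    "write_snapshots",
    "read_snapshots",
]

logger = logging.getLogger("riboflux")

_PathLike = Union[str, Path]


class IOError_(ValueError):
    """Schema or content error in an input file."""


def read_fasta(path: _PathLike, rna_to_dna: bool = True) -> Dict[str, str]:
    """Sequences keyed by record id; uppercased, optionally U->T."""
    seqs: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise IOError_(f"duplicate FASTA id: {record.id}")
        seq = str(record.seq).upper()
        if rna_to_dna:
            seq = seq.replace("U", "T")
        if not set(seq) <= set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise IOError_(f"non-nucleotide characters {bad} in {record.id}")
        seqs[record.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: _PathLike) -> None:
    records = [SeqRecord(Seq(s), id=gid, description="") for gid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_counts_tsv(
    path: _PathLike, lengths: Optional[Mapping[str, int]] = None
) -> Dict[str, FootprintProfile]:
    """A-site count profiles from long-form TSV (gene_id, codon_index,
    count); indices are 1-based and missing indices densify to zero.
    Optional boolean columns multimap_excluded / has_intron / cds_overlap
    set the exclusion flags."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "codon_index", "count"}
    missing = required - set(df.columns)
    if missing:
        raise IOError_(f"counts TSV missing column(s): {sorted(missing)}")
    if len(df) == 0:
        logger.warning("empty counts file: %s", path)
        return {}
    if (df["count"] < 0).any():
        raise IOError_("negative count")
    if not np.array_equal(df["count"], df["count"].astype(int)):
        raise IOError_("non-integer count")
    if (df["codon_index"] < 1).any():
        raise IOError_("codon_index must be 1-based")
    flag_cols = [
        c for c in ("multimap_excluded", "has_intron", "cds_overlap") if c in df.columns
    ]
    profiles: Dict[str, FootprintProfile] = {}
    for gene_id, sub in df.groupby("gene_id", sort=True):
        n = int(lengths[gene_id]) if lengths and gene_id in lengths else int(
            sub["codon_index"].max()
        )
        counts = np.zeros(n, dtype=np.int64)
        idx = sub["codon_index"].to_numpy(int) - 1
        if idx.max() >= n:
            raise IOError_(f"codon_index beyond length {n} for {gene_id}")
        np.add.at(counts, idx, sub["count"].to_numpy(int))
        flags = {c: bool(sub[c].any()) for c in flag_cols}
        profiles[str(gene_id)] = FootprintProfile(str(gene_id), counts, **flags)
    return profiles


def write_counts_tsv(
    profiles: Iterable[FootprintProfile], path: _PathLike, dense: bool = True
) -> None:
    rows = []
    for p in profiles:
        for j, c in enumerate(p.counts, start=1):
            if dense or c > 0:
                rows.append((p.gene_id, j, int(c)))
    pd.DataFrame(rows, columns=["gene_id", "codon_index", "count"]).to_csv(
        path, sep="\t", index=False
    )


def apply_fixed_asite_offset(
    five_prime_nt: Sequence[int], read_lengths: Sequence[int], min_read_nt: int = 16
) -> Tuple[np.ndarray, int]:
    """Fixed-offset A-site assignment fallback.

    Maps each read's 5' end position (1-based nt within the CDS) to the
    A-site codon under the sixth-codon convention,
    ``codon = floor((p + 15) / 3) + 1``; reads shorter than ``min_read_nt``
    are skipped.  Returns (codon indices, number skipped).
    """
    p = np.asarray(five_prime_nt, dtype=int)
    ln = np.asarray(read_lengths, dtype=int)
    if p.shape != ln.shape:
        raise IOError_("positions and read lengths must align")
    keep = ln >= min_read_nt
    codons = (p[keep] + 15) // 3 + 1
    return codons, int((~keep).sum())


def read_manifest(path: _PathLike) -> pd.DataFrame:
    """Run-off sample manifest (sample_id, delta_t_s, counts_path), sorted
    by run-off time on load."""
    df = read_table(path, required=("sample_id", "delta_t_s", "counts_path"))
    return df.sort_values("delta_t_s").reset_index(drop=True)


def read_table(path: _PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise IOError_(f"{path}: missing column(s): {sorted(missing)}")
    return df


def _config_hash(config: Optional[Mapping]) -> Optional[str]:
    if config is None:
        return None
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_report(
    obj: Mapping,
    path: _PathLike,
    seed: Optional[int] = None,
    config: Optional[Mapping] = None,
) -> None:
    """JSON report with provenance metadata (seed, config hash)."""
    out = {
        "report": obj,
        "meta": {"seed": seed, "config_hash": _config_hash(config), "config": config},
    }
    Path(path).write_text(json.dumps(out, indent=2, default=_jsonify))
    logger.info("wrote report %s (seed=%s, config_hash=%s)", path, seed,
                out["meta"]["config_hash"])


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def write_snapshots(snapshots: SnapshotSet, path: _PathLike) -> None:
    """Snapshot dump as (gene_id, snapshot_index, a_site_position) TSV;
    gzip-compressed when the path ends in .gz."""
    n = snapshots.n_snapshots
    reps = np.diff(snapshots.offsets)
    df = pd.DataFrame(
        {
            "gene_id": snapshots.gene_id,
            "snapshot_index": np.repeat(np.arange(n), reps),
            "a_site_position": snapshots.positions,
        }
    )
    df.to_csv(path, sep="\t", index=False, compression="infer")
    # record snapshots with no ribosome so the copy number round-trips
    meta = Path(str(path) + ".meta.json")
    meta.write_text(
        json.dumps(
            {"gene_id": snapshots.gene_id, "n_snapshots": n,
             "n_codons": snapshots.n_codons, "ell": snapshots.ell}
        )
    )


def read_snapshots(path: _PathLike) -> SnapshotSet:
    df = pd.read_csv(path, sep="\t", compression="infer")
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    n = int(meta["n_snapshots"])
    offsets = np.zeros(n + 1, dtype=np.int64)
    counts_per_snap = df.groupby("snapshot_index").size()
    for idx, cnt in counts_per_snap.items():
        offsets[int(idx) + 1] = cnt
    offsets = np.cumsum(offsets)
    positions = df.sort_values("snapshot_index")["a_site_position"].to_numpy(np.int32)
    return SnapshotSet(
        meta["gene_id"], offsets, positions, int(meta["n_codons"]), int(meta["ell"])
    )
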