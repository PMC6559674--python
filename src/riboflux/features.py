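"""Sequence and structure covariates of translation rates, with the
statistics used to compare them.

Covers: Kozak-context similarity scoring around the start codon, upstream
AUG detection in 5' UTRs, per-codon secondary-structure calls from DMS or
PARS signals, two-group dwell-time comparisons (percent difference of
medians, Mann-Whitney U, bootstrap CI), position-resolved downstream-
structure scans with Benjamini-Hochberg correction, paired Watson-Crick
versus wobble decoding tests, and generic correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CodonTimeTable, StructureAnnotation

__all__ = [
    "KozakResult",
    "GroupComparison",
    "FeatureError",
    "kozak_score",
    "has_upstream_aug",
    "assign_codon_structure",
    "group_difference",
    "downstream_structure_scan",
    "wobble_comparison",
    "correlate",
]

# Degenerate S. cerevisiae Kozak consensus over the -6..+6 window:
# (A/T) A (A/C) A (A/C) A | ATG | T C (T/C)
_KOZAK_FLANKS: Tuple[Tuple[int, Tuple[str, ...]], ...] = (
    (0, ("A", "T")),
    (1, ("A",)),
    (2, ("A", "C")),
    (3, ("A",)),
    (4, ("A", "C")),
    (5, ("A",)),
    (9, ("T",)),
    (10, ("C",)),
    (11, ("T", "C")),
)


class FeatureError(ValueError):
    pass


@dataclass
class KozakResult:
    gene_id: str
    score: int  # 1..10 (0 only when the start codon itself is not ATG)
    kozak_class: str  # "kozak_like" (>7), "non_kozak" (<5), "intermediate"
    start_is_aug: bool


@dataclass
class GroupComparison:
    percent_difference: float  # 100 * (median_a - median_b) / median_b
    p_value: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_a: int
    n_b: int
    q_value: Optional[float] = None
    significant: Optional[bool] = None
    label: str = ""


def kozak_score(window12: str, gene_id: str = "") -> KozakResult:
    """Similarity of a 12-nt start-codon window (-6..+6) to the yeast Kozak
    consensus: one point for an ATG start plus one per matching flank
    position, for a 1..10 scale."""
    window = window12.upper().replace("U", "T")
    if len(window) != 12:
        raise FeatureError("window must be exactly 12 nt (-6..+6)")
    start_is_aug = window[6:9] == "ATG"
    score = 1 if start_is_aug else 0
    for idx, allowed in _KOZAK_FLANKS:
        if window[idx] in allowed:
            score += 1
    if score > 7:
        klass = "kozak_like"
    elif score < 5:
        klass = "non_kozak"
    else:
        klass = "intermediate"
    return KozakResult(gene_id=gene_id, score=score, kozak_class=klass,
                       start_is_aug=start_is_aug)


def has_upstream_aug(utr5: str) -> Tuple[bool, int]:
    """Scan a 5' UTR for AUG triplets at any offset (all three frames)."""
    seq = utr5.upper().replace("U", "T")
    count = sum(1 for i in range(len(seq) - 2) if seq[i : i + 3] == "ATG")
    return count > 0, count


def _nt_status_dms(base: str, signal: Optional[float]) -> str:
    if base not in ("A", "C") or signal is None or np.isnan(signal):
        return "no_info"  # G/U do not react with DMS
    if signal < 0.2:
        return "paired"
    if signal > 0.5:
        return "unpaired"
    return "ambiguous"


def _nt_status_pars(signal: Optional[float]) -> str:
    if signal is None or np.isnan(signal):
        return "ambiguous"  # missing PARS score excludes the codon
    return "paired" if signal > 0 else "unpaired"


def assign_codon_structure(
    per_nt: Sequence[Tuple[str, Optional[float]]], assay: str
) -> str:
    """Label one codon from its three per-nucleotide probing signals.

    DMS: A/C with signal < 0.2 are base-paired, > 0.5 unpaired, in
    [0.2, 0.5] ambiguous; G/U carry no information.  PARS: score > 0 means
    base-paired.  A codon is structured when at least two nucleotides are
    paired, or one is paired and the other two carry no information; any
    ambiguous nucleotide excludes the codon; otherwise unstructured.
    """
    if assay not in ("DMS", "PARS"):
        raise FeatureError("assay must be DMS or PARS")
    if len(per_nt) != 3:
        raise FeatureError("a codon has exactly 3 nucleotides")
    statuses = []
    for base, signal in per_nt:
        base = str(base).upper().replace("U", "T")
        if assay == "DMS":
            statuses.append(_nt_status_dms(base, signal))
        else:
            statuses.append(_nt_status_pars(signal))
    if "ambiguous" in statuses:
        return "excluded"
    paired = statuses.count("paired")
    no_info = statuses.count("no_info")
    if paired >= 2 or (paired == 1 and no_info == 2):
        return "structured"
    return "unstructured"


def group_difference(
    times_a: Sequence[float],
    times_b: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    label: str = "",
) -> GroupComparison:
    """Percent difference of medians (a relative to b), with a two-sided
    Mann-Whitney U p-value and a seeded bootstrap 95% CI."""
    a = np.asarray(times_a, float)
    b = np.asarray(times_b, float)
    if len(a) == 0 or len(b) == 0:
        raise FeatureError("both groups must be non-empty")
    med_b = np.median(b)
    if med_b == 0:
        raise FeatureError("zero reference median")
    pct = 100.0 * (np.median(a) - med_b) / med_b
    # exact test for small untied samples, normal approximation with tie
    # correction otherwise (p-values are reported at very large n)
    method = "exact" if max(len(a), len(b)) <= 20 else "asymptotic"
    try:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    except ValueError:  # ties under the exact method
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    ci_low = ci_high = None
    if len(a) >= 2 and len(b) >= 2:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            ra = a[rng.integers(0, len(a), len(a))]
            rb = b[rng.integers(0, len(b), len(b))]
            mb = np.median(rb)
            boots[i] = 100.0 * (np.median(ra) - mb) / mb if mb != 0 else np.nan
        ci_low, ci_high = (float(x) for x in np.nanpercentile(boots, [2.5, 97.5]))
    return GroupComparison(
        percent_difference=float(pct),
        p_value=p,
        ci_low=ci_low,
        ci_high=ci_high,
        n_a=len(a),
        n_b=len(b),
        label=label,
    )


def downstream_structure_scan(
    tables: Dict[str, CodonTimeTable],
    annotations: Dict[str, StructureAnnotation],
    offsets: Sequence[int] = tuple(range(1, 11)),
    alpha: float = 0.05,
    n_boot: int = 10_000,
    seed: int = 0,
) -> List[GroupComparison]:
    """Dwell-time change at the A-site as a function of the codon position
    of secondary structure downstream of it.

    For each offset k, A-site dwell times (positions 3..Nc-1) are split by
    the structure label of the codon exactly k positions 3' of the A-site
    (excluded codons drop the observation from that offset only), compared
    with :func:`group_difference`, and Benjamini-Hochberg corrected across
    offsets.  Offsets with no observations in either group are returned
    with NaN statistics and flagged non-significant.
    """
    if not all(1 <= k <= 10 for k in offsets):
        raise FeatureError("offsets must lie in [1, 10]")
    results: List[GroupComparison] = []
    for k_i, k in enumerate(offsets):
        structured: List[float] = []
        unstructured: List[float] = []
        for gene_id, table in tables.items():
            ann = annotations.get(gene_id)
            if ann is None:
                continue
            labels = ann.labels
            nc = table.n_codons
            for j in range(3, nc):  # A-site positions 3..Nc-1
                down = j + k
                if down > min(nc, len(labels)):
                    continue
                lab = labels[down - 1]
                if lab == "structured":
                    structured.append(table.tau_at(j))
                elif lab == "unstructured":
                    unstructured.append(table.tau_at(j))
        if not structured or not unstructured:
            results.append(
                GroupComparison(
                    percent_difference=float("nan"),
                    p_value=float("nan"),
                    ci_low=None,
                    ci_high=None,
                    n_a=len(structured),
                    n_b=len(unstructured),
                    significant=False,
                    label=f"offset_{k}",
                )
            )
            continue
        comp = group_difference(
            structured, unstructured, n_boot=n_boot, seed=seed + k_i, label=f"offset_{k}"
        )
        results.append(comp)
    ps = [r.p_value for r in results if np.isfinite(r.p_value)]
    if ps:
        reject, qs, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
        it = iter(zip(reject, qs))
        for r in results:
            if np.isfinite(r.p_value):
                rej, q = next(it)
                r.q_value = float(q)
                r.significant = bool(rej)
    return results


def wobble_comparison(
    per_type_medians: Dict[str, float],
    decoding_pairs: Sequence[Tuple[str, str]],
) -> Dict[str, object]:
    """Paired test of Watson-Crick versus wobble decoding.

    ``decoding_pairs`` lists (WC codon, wobble codon) for tRNAs that decode
    two codon types; pairs with a missing codon are skipped.  Returns the
    two-sided Wilcoxon signed-rank result plus the paired medians for an
    identity-line scatter.
    """
    wc: List[float] = []
    wob: List[float] = []
    used: List[Tuple[str, str]] = []
    skipped: List[Tuple[str, str]] = []
    for wc_codon, wob_codon in decoding_pairs:
        if wc_codon in per_type_medians and wob_codon in per_type_medians:
            wc.append(per_type_medians[wc_codon])
            wob.append(per_type_medians[wob_codon])
            used.append((wc_codon, wob_codon))
        else:
            skipped.append((wc_codon, wob_codon))
    if len(used) < 5:
        raise FeatureError("need >= 5 decodable pairs")
    wc_arr = np.asarray(wc)
    wob_arr = np.asarray(wob)
    if np.allclose(wc_arr, wob_arr):
        stat, p = 0.0, 1.0  # no difference in any pair
    else:
        res = stats.wilcoxon(wc_arr, wob_arr, alternative="two-sided", zero_method="zsplit")
        stat, p = float(res.statistic), float(res.pvalue)
    return {
        "statistic": stat,
        "p_value": p,
        "n_pairs": len(used),
        "pairs": used,
        "skipped": skipped,
        "wc_medians": wc_arr,
        "wobble_medians": wob_arr,
    }


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> Tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise FeatureError("x and y must be paired 1-d vectors")
    if len(x) < 3:
        raise FeatureError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise FeatureError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise FeatureError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise FeatureError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)
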