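import numpy as np
import pytest

from riboflux.features import (
    FeatureError,
    assign_codon_structure,
    correlate,
    downstream_structure_scan,
    group_difference,
    has_upstream_aug,
    kozak_score,
    wobble_comparison,
)
from riboflux.model import CodonTimeTable, StructureAnnotation


class TestKozak:
    def test_full_consensus_scores_ten(self):
        res = kozak_score("AAAAAAATGTCT")
        assert res.score == 10
        assert res.kozak_class == "kozak_like"

    def test_four_flank_matches_score_five(self):
        # keep flanks -6..-3 (AAAA), break the rest (G never matches)
        res = kozak_score("AAAAGGATGGGG")
        assert res.score == 5
        assert res.kozak_class == "intermediate"

    def test_no_flank_matches_score_one(self):
        res = kozak_score("CCGCGGATGGAG")
        assert res.score == 1
        assert res.kozak_class == "non_kozak"

    def test_non_aug_start_flagged(self):
        res = kozak_score("AAAAAACTGTCT")
        assert not res.start_is_aug
        assert res.score == 9  # flank matches only

    def test_score_monotone_in_matches(self):
        window = list("CCGCGGATGGAG")
        consensus = list("AAAAAAATGTCT")
        prev = kozak_score("".join(window)).score
        for i in [0, 1, 2, 3, 4, 5, 9, 10, 11]:
            window[i] = consensus[i]
            score = kozak_score("".join(window)).score
            assert score == prev + 1
            prev = score
        assert prev == 10


class TestUpstreamAug:
    @pytest.mark.parametrize(
        "utr,expected",
        [("CCCCCC", (False, 0)), ("CATGCC", (True, 1)), ("ATGATG", (True, 2)),
         ("AUGAUG", (True, 2)), ("", (False, 0))],
    )
    def test_scan_all_frames(self, utr, expected):
        assert has_upstream_aug(utr) == expected


class TestStructureAssignment:
    def test_dms_two_paired_is_structured(self):
        assert assign_codon_structure(
            [("A", 0.1), ("C", 0.15), ("G", None)], "DMS") == "structured"

    def test_dms_ambiguous_excludes_codon(self):
        assert assign_codon_structure(
            [("A", 0.3), ("C", 0.1), ("T", None)], "DMS") == "excluded"

    def test_dms_one_paired_two_noinfo_is_structured(self):
        assert assign_codon_structure(
            [("A", 0.05), ("G", None), ("T", None)], "DMS") == "structured"

    def test_dms_unpaired(self):
        assert assign_codon_structure(
            [("A", 0.9), ("C", 0.8), ("A", 0.6)], "DMS") == "unstructured"

    def test_pars_two_of_three_positive(self):
        assert assign_codon_structure(
            [("G", 1.2), ("C", -0.5), ("A", 0.3)], "PARS") == "structured"

    def test_pars_missing_signal_excludes(self):
        assert assign_codon_structure(
            [("G", 1.2), ("C", None), ("A", 0.3)], "PARS") == "excluded"


class TestGroupDifference:
    def test_identical_groups_null(self):
        x = np.linspace(0.1, 0.5, 60)
        comp = group_difference(x, x, n_boot=200, seed=0)
        assert comp.percent_difference == pytest.approx(0.0)
        assert comp.p_value > 0.99

    def test_scaled_group_shows_19_percent(self):
        rng = np.random.default_rng(0)
        b = rng.lognormal(-1.5, 0.4, 5000)
        a = 1.19 * b
        comp = group_difference(a, b, n_boot=500, seed=1)
        assert comp.percent_difference == pytest.approx(19.0, abs=1e-9)
        assert comp.p_value < 1e-6
        assert comp.ci_low <= 19.0 <= comp.ci_high

    def test_planted_shift_recovered_within_ci(self):
        rng = np.random.default_rng(5)
        b = rng.lognormal(-1.5, 0.5, 10_000)
        a = rng.lognormal(-1.5 + np.log(1.19), 0.5, 10_000)
        comp = group_difference(a, b, n_boot=2000, seed=2)
        assert comp.ci_low <= 19.0 <= comp.ci_high


class TestStructureScan:
    def _dataset(self, seed, effect_offset=None, effect=1.35, n_genes=12, nc=220):
        rng = np.random.default_rng(seed)
        tables, anns = {}, {}
        for g in range(n_genes):
            gid = f"g{g}"
            labels = rng.choice(
                ["structured", "unstructured"], size=nc, p=[0.35, 0.65]
            )
            tau = rng.lognormal(-1.6, 0.35, nc - 1)  # positions 2..nc
            if effect_offset is not None:
                for j in range(3, nc):
                    down = j + effect_offset
                    if down <= nc and labels[down - 1] == "structured":
                        tau[j - 2] *= effect
            tables[gid] = CodonTimeTable(
                gid, tau * 0 + tau, synthesis_time_used=float(tau.sum())
            )
            anns[gid] = StructureAnnotation(gid, tuple(labels), "DMS")
        return tables, anns

    def test_planted_offset_four_only_significant(self):
        tables, anns = self._dataset(seed=3, effect_offset=4)
        results = downstream_structure_scan(
            tables, anns, offsets=range(1, 11), n_boot=200, seed=0
        )
        sig = {int(r.label.split("_")[1]) for r in results if r.significant}
        assert 4 in sig
        assert sig <= {4}
        r4 = [r for r in results if r.label == "offset_4"][0]
        assert r4.percent_difference > 0
        assert r4.q_value >= r4.p_value

    def test_permuted_labels_rarely_significant(self):
        n_sig = 0
        n_runs = 30
        for s in range(n_runs):
            tables, anns = self._dataset(seed=100 + s, effect_offset=None, n_genes=4, nc=120)
            results = downstream_structure_scan(
                tables, anns, offsets=range(1, 11), n_boot=50, seed=s
            )
            if any(r.significant for r in results):
                n_sig += 1
        assert n_sig <= max(1, int(0.05 * n_runs) + 1)

    def test_all_unstructured_flagged_undefined(self):
        tables, anns = self._dataset(seed=9, n_genes=2, nc=60)
        for gid, ann in anns.items():
            anns[gid] = StructureAnnotation(gid, ("unstructured",) * 60, "DMS")
        results = downstream_structure_scan(tables, anns, offsets=[1, 2], n_boot=50)
        assert all(not r.significant for r in results)
        assert all(np.isnan(r.p_value) for r in results)


class TestWobble:
    PAIRS = [("GCT", "GCC"), ("CGT", "CGC"), ("GGT", "GGC"), ("CAT", "CAC"),
             ("AAT", "AAC"), ("TTT", "TTC")]

    def test_identical_pairs_p_one(self):
        med = {c: 0.2 for pair in self.PAIRS for c in pair}
        res = wobble_comparison(med, self.PAIRS)
        assert res["p_value"] == pytest.approx(1.0)

    def test_doubled_wobble_significant_at_six_pairs(self):
        med = {}
        for i, (wc, wob) in enumerate(self.PAIRS):
            med[wc] = 0.1 + 0.01 * i
            med[wob] = 2 * med[wc]
        res = wobble_comparison(med, self.PAIRS)
        assert res["p_value"] < 0.05

    def test_missing_codons_skipped(self):
        med = {c: 0.2 for pair in self.PAIRS for c in pair}
        res = wobble_comparison(med, self.PAIRS + [("XXX", "YYY")])
        assert ("XXX", "YYY") in res["skipped"]
        assert res["n_pairs"] == 6

    def test_too_few_pairs_error(self):
        med = {"GCT": 0.1, "GCC": 0.2}
        with pytest.raises(FeatureError):
            wobble_comparison(med, self.PAIRS[:1])


class TestCorrelate:
    def test_linear_relation_pearson_one(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x)[0] == pytest.approx(1.0)

    def test_monotone_spearman_minus_one(self):
        x = np.linspace(-2, 2, 20)
        r, _ = correlate(x, -(x**3), method="spearman")
        assert r == pytest.approx(-1.0)

    def test_independent_draws_near_zero(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            r, _ = correlate(rng.normal(size=1000), rng.normal(size=1000))
            hits += abs(r) < 0.1
        assert hits >= 19

    def test_constant_vector_rejected(self):
        with pytest.raises(FeatureError, match="constant"):
            correlate(np.ones(10), np.arange(10.0))
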