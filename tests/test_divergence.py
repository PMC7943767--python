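"""Ks / 4dTv estimation against hand and enumeration oracles; peaks; dating."""

import math

import numpy as np
import pytest

from paleodup.divergence import (
    CodonAlignment,
    PeakEstimate,
    SENSE_CODONS,
    backtranslate,
    date_peak,
    detect_peaks,
    divergence_table,
    estimate_pair,
    fourdtv,
    histogram_table,
    ng86,
)
from paleodup.genome_io import Gene, Genome, translate_cds
from paleodup.homology import HomologPair
from paleodup.synthetic_data import _evolve

from _oracles import fourdtv_site_oracle, pair_diff_oracle, syn_sites_oracle
from conftest import random_cds

PAIR = HomologPair("a", "b")


def aln(columns):
    return CodonAlignment(PAIR, list(columns))


class TestBacktranslate:
    def test_plain_column(self):
        out = backtranslate("G", "G", "GGT", "GGC", PAIR)
        assert out.columns == [("GGT", "GGC")] and out.n_dropped == 0

    def test_gap_column_dropped(self):
        out = backtranslate("G-", "GA", "GGT", "GGTGCA", PAIR)
        assert out.columns == [("GGT", "GGT")] and out.n_dropped == 1

    def test_ambiguous_codon_dropped(self):
        out = backtranslate("GG", "GG", "GGTGGN", "GGTGGT", PAIR)
        assert out.columns == [("GGT", "GGT")] and out.n_dropped == 1

    def test_length_mismatch_names_gene(self):
        with pytest.raises(ValueError, match="gene a"):
            backtranslate("GG", "GG", "GGT", "GGTGGT", PAIR)


class TestNg86:
    def test_identical_columns_give_zero(self):
        est = ng86(aln([("GGT", "GGT")] * 4))
        assert est.sd == 0 and est.ks == 0.0 and not est.saturated

    def test_hand_derived_toy_case(self):
        est = ng86(aln([("GGT", "GGC")] + [("GGT", "GGT")] * 3))
        assert est.S == pytest.approx(4.0)
        assert est.sd == pytest.approx(1.0)
        assert est.pS == pytest.approx(0.25)
        assert est.ks == pytest.approx(-0.75 * math.log(2 / 3), abs=1e-9)

    def test_saturation_flagged(self):
        est = ng86(aln([("GGT", "GGA")] * 5))
        assert est.pS == pytest.approx(1.0) and est.saturated

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError, match="empty alignment"):
            ng86(aln([]))

    def test_site_conservation_on_random_columns(self, rng):
        cols = [
            (rng.choice(SENSE_CODONS), rng.choice(SENSE_CODONS)) for _ in range(200)
        ]
        est = ng86(aln(cols))
        assert est.S + est.N == pytest.approx(3 * len(cols), abs=1e-9)
        assert 0 <= est.sd <= est.S

    def test_counts_match_enumeration_oracle(self, rng):
        """Per-codon S/sd/nd agree with an independent pathway enumerator."""
        for _ in range(400):
            c1, c2 = rng.choice(SENSE_CODONS), rng.choice(SENSE_CODONS)
            est = ng86(aln([(c1, c2)]))
            sd, nd = pair_diff_oracle(c1, c2)
            assert est.sd == pytest.approx(sd, abs=1e-12)
            assert est.nd == pytest.approx(nd, abs=1e-12)
            s_exp = (syn_sites_oracle(c1) + syn_sites_oracle(c2)) / 2
            assert est.S == pytest.approx(s_exp, abs=1e-12)


class TestFourdtv:
    def test_transition_counts_zero(self):
        est = fourdtv(aln([("GGT", "GGC")] + [("GGT", "GGT")] * 3))
        assert est.n_4d == 4 and est.tv_4d == 0 and est.fourdtv == 0.0

    def test_transversion_counted(self):
        est = fourdtv(aln([("GGT", "GGA")] + [("GGT", "GGT")] * 3))
        assert est.fourdtv == pytest.approx(0.25)

    def test_non_fourfold_codon_undefined(self):
        est = fourdtv(aln([("ATG", "ATG")]))
        assert est.n_4d == 0 and not est.fourdtv_defined

    def test_site_counting_matches_enumeration_oracle(self, rng):
        for _ in range(500):
            c1, c2 = rng.choice(SENSE_CODONS), rng.choice(SENSE_CODONS)
            est = fourdtv(aln([(c1, c2)]))
            counted, tv = fourdtv_site_oracle(c1, c2)
            assert est.n_4d == counted and est.tv_4d == tv

    def test_corrected_variant_monotone(self):
        lo = fourdtv(aln([("GGT", "GGA")] + [("GGT", "GGT")] * 9))
        hi = fourdtv(aln([("GGT", "GGA")] * 3 + [("GGT", "GGT")] * 7))
        assert lo.fourdtv_corrected < hi.fourdtv_corrected
        assert lo.fourdtv_corrected > lo.fourdtv  # correction inflates


class TestSelfDivergenceZero:
    def test_ks_and_fourdtv_zero_on_self(self, rng):
        for _ in range(20):
            cds = random_cds(rng, 60)
            pair = HomologPair("x", "y")
            est = estimate_pair(pair, translate_cds(cds), translate_cds(cds), cds, cds)
            assert est.ks == 0.0
            assert est.fourdtv in (0.0, float("nan")) or est.fourdtv == 0.0


class TestMonotonicityAndConsistency:
    def test_median_ks_and_fourdtv_increase_with_true_divergence(self):
        rng = np.random.default_rng(5)
        med_ks, med_tv = [], []
        for d in (0.1, 0.3, 0.6):
            ks_vals, tv_vals = [], []
            for _ in range(200):
                base = np.frombuffer(
                    bytes(random_cds(rng, 300), "ascii"), dtype=np.uint8
                )
                seq1 = np.array(["ACGT".index(chr(b)) for b in base], dtype=np.int8)
                seq2 = seq1.copy()
                _evolve(seq1, d / 2, 2.0, rng)
                _evolve(seq2, d / 2, 2.0, rng)
                cols = [
                    ("".join("ACGT"[x] for x in seq1[i : i + 3]),
                     "".join("ACGT"[x] for x in seq2[i : i + 3]))
                    for i in range(0, seq1.size, 3)
                ]
                cols = [
                    c for c in cols
                    if c[0] not in ("TAA", "TAG", "TGA") and c[1] not in ("TAA", "TAG", "TGA")
                ]
                est = ng86(aln(cols))
                est = fourdtv(aln(cols), est)
                if np.isfinite(est.ks):
                    ks_vals.append(est.ks)
                if est.fourdtv_defined:
                    tv_vals.append(est.fourdtv)
            med_ks.append(np.median(ks_vals))
            med_tv.append(np.median(tv_vals))
        assert med_ks[0] < med_ks[1] < med_ks[2]
        assert med_tv[0] < med_tv[1] < med_tv[2]
        # estimator consistency at true distance 0.3
        assert 0.24 <= med_ks[1] <= 0.36


class TestDetectPeaks:
    def test_single_component_recovered(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0.5, 0.05, 500)
        peaks = detect_peaks(values, "fourdtv", seed=1729)
        dominant = max(peaks, key=lambda p: p.weight)
        assert abs(dominant.mean - 0.5) < 0.03

    def test_two_components_recovered(self):
        rng = np.random.default_rng(2)
        values = np.concatenate(
            [rng.normal(0.2, 0.04, 500), rng.normal(0.8, 0.08, 500)]
        )
        peaks = detect_peaks(values, "fourdtv", seed=1729)
        big = sorted(sorted(peaks, key=lambda p: -p.weight)[:2], key=lambda p: p.mean)
        assert abs(big[0].mean - 0.2) < 0.05 and abs(big[1].mean - 0.8) < 0.08

    def test_weights_sum_to_one_and_labels_ascending(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(0.3, 0.03, 300), rng.normal(0.9, 0.05, 300)])
        peaks = detect_peaks(values, "fourdtv", seed=1729)
        assert sum(p.weight for p in peaks) == pytest.approx(1.0, abs=1e-6)
        labeled = [p for p in peaks if p.label]
        assert [p.label for p in labeled] == ["alpha", "beta", "gamma"][: len(labeled)]
        assert all(a.mean <= b.mean for a, b in zip(peaks, peaks[1:]))

    def test_constant_vector_degenerate(self):
        peaks = detect_peaks([0.4] * 100, "fourdtv")
        assert len(peaks) == 1 and peaks[0].sigma == 0.0

    def test_too_few_values_advises_kde(self):
        with pytest.raises(ValueError, match="kde"):
            detect_peaks([0.5] * 10 + [0.6] * 5, "fourdtv")

    def test_kde_fallback_on_sparse_data(self):
        rng = np.random.default_rng(4)
        peaks = detect_peaks(rng.normal(0.5, 0.02, 25), "fourdtv", method="kde")
        assert abs(max(peaks, key=lambda p: p.weight).mean - 0.5) < 0.05

    def test_ks_fitted_on_log_scale(self):
        rng = np.random.default_rng(6)
        values = np.exp(rng.normal(np.log(0.5), 0.1, 800))
        peaks = detect_peaks(values, "ks", seed=1729)
        dominant = max(peaks, key=lambda p: p.weight)
        assert abs(dominant.mean - 0.5) < 0.05


class TestDatePeak:
    def _peak(self, mean):
        return PeakEstimate("ks", mean, 1.0, 0.1)

    def test_direct_formula(self):
        assert date_peak(self._peak(0.9), 1.5e-8).time_mya == pytest.approx(30.0)

    def test_zero_mean(self):
        assert date_peak(self._peak(0.0), 1.5e-8).time_mya == 0.0

    def test_beta_peak_roundtrip(self):
        # Ks 0.771 under the dicot clock dates to 25.7 MY
        assert date_peak(self._peak(0.771), 1.5e-8).time_mya == pytest.approx(25.7, abs=0.05)

    def test_linearity(self):
        assert date_peak(self._peak(0.8)).time_mya == pytest.approx(
            2 * date_peak(self._peak(0.4)).time_mya
        )

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            date_peak(self._peak(0.5), 0.0)

    def test_non_ks_statistic_rejected(self):
        with pytest.raises(ValueError, match="Ks"):
            date_peak(PeakEstimate("fourdtv", 0.2, 1.0, 0.05))


class TestDivergenceTable:
    def _genome(self, rng, ids):
        genes = []
        for i, gid in enumerate(ids):
            cds = random_cds(rng, 50)
            genes.append(
                Gene(gene_id=gid, chromosome="chr1", start=1 + 500 * i, end=150 + 500 * i,
                     cds=cds, protein=translate_cds(cds))
            )
        return Genome.from_genes("sp", genes)

    def test_empty_input(self):
        assert divergence_table([], []).empty

    def test_row_equals_single_pair_estimate(self, rng):
        gm = self._genome(rng, ["a", "b"])
        pair = HomologPair("a", "b")
        table = divergence_table([pair], [gm])
        est = estimate_pair(pair, gm["a"].protein, gm["b"].protein, gm["a"].cds, gm["b"].cds)
        row = table.iloc[0]
        assert row["S"] == pytest.approx(est.S)
        assert row["n_4d"] == est.n_4d

    def test_unknown_gene_rejected(self, rng):
        gm = self._genome(rng, ["a", "b"])
        with pytest.raises(KeyError, match="ghost"):
            divergence_table([HomologPair("a", "ghost")], [gm])

    def test_histogram_counts(self):
        h = histogram_table([0.005, 0.006, 0.015], bin_width=0.01)
        assert h["count"].sum() == 3
        assert h.iloc[0]["count"] == 2
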