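import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ladomics.diffmeth import BetaMatrix
from ladomics.enrichment import (
    fisher_enrichment,
    fold_enrichment,
    peak_feature_distribution,
    probe_track_membership,
    stratified_delta_beta,
    yates_chi2,
)
from ladomics.intervals import AnnotationTrack, GenomicInterval


def hand_yates(table):
    t = np.asarray(table, dtype=float)
    rows, cols, n = t.sum(1), t.sum(0), t.sum()
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            d = abs(t[i, j] - e)
            chi2 += (d - min(0.5, d)) ** 2 / e
    return chi2


def fisher_enumeration(table):
    """Two-sided Fisher p by summing hypergeometric pmf <= observed pmf."""
    a, b, c, d = np.asarray(table).ravel()
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {x: stats.hypergeom.pmf(x, n, c1, r1) for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


class TestFoldEnrichment:
    def test_hand_expected_and_fold(self):
        sel = np.zeros(1000, dtype=bool); sel[:50] = True
        track = np.zeros(1000, dtype=bool)
        track[:25] = True          # 25 selected probes in track
        track[900:975] = True      # 75 unselected in track -> 100 total
        r = fold_enrichment(sel, track)
        assert r.expected == pytest.approx(5.0)
        assert r.signed_fold == pytest.approx(5.0)
        assert r.observed == 25

    def test_independence_gives_unit_fold_and_zero_chi2(self):
        # 2x2 exactly proportional: selected 50/500, in-track 10% everywhere
        sel = np.array([True] * 50 + [False] * 450)
        track = np.array([True] * 5 + [False] * 45 + [True] * 45 + [False] * 405)
        r = fold_enrichment(sel, track)
        assert r.signed_fold == 1.0
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_depletion_sign_convention(self):
        # observed 2 vs expected 5 -> -2.5
        sel = np.zeros(1000, dtype=bool); sel[:50] = True
        track = np.zeros(1000, dtype=bool)
        track[:2] = True
        track[500:598] = True
        r = fold_enrichment(sel, track)
        assert r.expected == pytest.approx(5.0)
        assert r.signed_fold == pytest.approx(-2.5)

    def test_doubling_counts_keeps_fold_increases_chi2(self, rng):
        sel = np.array([True] * 40 + [False] * 160)
        track = np.array([True] * 20 + [False] * 20 + [True] * 30 + [False] * 130)
        r1 = fold_enrichment(sel, track)
        r2 = fold_enrichment(np.tile(sel, 2), np.tile(track, 2))
        assert r2.signed_fold == pytest.approx(r1.signed_fold)
        assert r2.statistic > r1.statistic

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="selection"):
            fold_enrichment(np.zeros(10, bool), np.array([True] * 5 + [False] * 5))
        with pytest.raises(ValueError, match="margin"):
            fold_enrichment(np.array([True] * 5 + [False] * 5), np.ones(10, bool))

    def test_yates_matches_scipy(self, rng):
        for _ in range(200):
            t = rng.integers(1, 60, size=(2, 2))
            chi2, p = yates_chi2(t)
            ref_chi2, ref_p, _, _ = stats.chi2_contingency(t, correction=True)
            assert chi2 == pytest.approx(ref_chi2, abs=1e-10)
            assert p == pytest.approx(ref_p, abs=1e-10)


class TestFisher:
    def test_proportional_table(self):
        r = fisher_enrichment([[1, 9], [10, 90]])
        assert r["odds_ratio"] == pytest.approx(1.0)
        assert r["p_two_sided"] == pytest.approx(1.0)

    def test_hand_enumeration_example(self):
        r = fisher_enrichment([[3, 1], [1, 3]])
        assert r["odds_ratio"] == pytest.approx(9.0)
        assert r["p_two_sided"] == pytest.approx(34 / 70, abs=1e-12)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(150):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            r = fisher_enrichment(t)
            assert r["p_two_sided"] == pytest.approx(fisher_enumeration(t), abs=1e-12)

    def test_zero_cell_and_margins(self):
        r = fisher_enrichment([[0, 5], [5, 5]])
        assert r["odds_ratio"] == 0.0 and 0 < r["p_two_sided"] <= 1
        with pytest.raises(ValueError):
            fisher_enrichment([[0, 0], [5, 5]])

    def test_asymptotic_agreement_with_yates(self, rng):
        # the exact and corrected-chi2 p-values converge as counts grow;
        # the discrepancy is O(1/sqrt(N)), so the 0.02 band needs cells
        # in the hundreds
        for _ in range(50):
            t = rng.integers(400, 2000, size=(2, 2))
            pf = fisher_enrichment(t)["p_two_sided"]
            _, pc = yates_chi2(t)
            assert abs(pf - pc) < 0.02


class TestPeakDistribution:
    def tracks(self):
        genes = AnnotationTrack([GenomicInterval("chr1", 0, 1000)], name="genes")
        lad_a = AnnotationTrack([GenomicInterval("chr1", 500, 2000)], name="laminA")
        lad_b = AnnotationTrack([GenomicInterval("chr2", 0, 100)], name="laminB")
        return {"genes": genes, "laminA": lad_a, "laminB": lad_b}

    def test_hand_counts_and_non_exclusivity(self):
        peaks = AnnotationTrack(
            [
                GenomicInterval("chr1", 600, 700),   # gene + laminA
                GenomicInterval("chr1", 1500, 1600), # laminA only
                GenomicInterval("chr3", 0, 10),      # nothing
            ]
        )
        out = peak_feature_distribution(peaks, self.tracks(), ("laminA", "laminB"))
        assert out.loc["genes", "count"] == 1
        assert out.loc["laminA", "count"] == 2
        assert out.loc["non_LAD", "count"] == 1
        assert out.loc["laminA", "fraction"] == pytest.approx(2 / 3)

    def test_no_overlap_case(self):
        peaks = AnnotationTrack([GenomicInterval("chr9", 0, 10)])
        out = peak_feature_distribution(peaks, self.tracks(), ("laminA", "laminB"))
        assert out.loc["non_LAD", "fraction"] == 1.0
        assert (out.drop("non_LAD")["count"] == 0).all()

    def test_invariant_to_order_and_track_splitting(self):
        peaks = [GenomicInterval("chr1", s, s + 50) for s in (0, 600, 1900)]
        split = {
            "laminA": AnnotationTrack(
                [GenomicInterval("chr1", 500, 1200), GenomicInterval("chr1", 1200, 2000)]
            )
        }
        whole = {"laminA": AnnotationTrack([GenomicInterval("chr1", 500, 2000)])}
        a = peak_feature_distribution(AnnotationTrack(peaks), whole)
        b = peak_feature_distribution(AnnotationTrack(reversed(peaks)), split)
        pd.testing.assert_frame_equal(a, b)


class TestStratifiedDeltaBeta:
    def setup_data(self, rng, shift=0.0, n=400):
        n_case, n_ctrl = 5, 4
        base = rng.uniform(0.3, 0.7, size=n)
        vals = np.empty((n, n_case + n_ctrl))
        for j in range(n_case + n_ctrl):
            mean = base + (shift if j < n_case else 0.0)
            vals[:, j] = np.clip(mean + rng.normal(0, 0.03, size=n), 0, 1)
        beta = BetaMatrix(
            pd.DataFrame(
                vals,
                index=[f"p{i}" for i in range(n)],
                columns=[f"s{j}" for j in range(n_case + n_ctrl)],
            )
        )
        sheet = pd.DataFrame(
            {"group": ["case"] * n_case + ["control"] * n_ctrl},
            index=beta.sample_ids,
        )
        return beta, sheet

    def test_null_identity(self, rng):
        beta, sheet = self.setup_data(rng, shift=0.0)
        out = stratified_delta_beta(beta, sheet, {"all": np.ones(400, bool)})
        assert abs(out.loc["all", "median_delta_beta"]) < 0.01
        assert out.loc["all", "p"] > 0.01

    def test_planted_shift_recovered(self, rng):
        beta, sheet = self.setup_data(rng, shift=0.10, n=2000)
        mask = np.zeros(2000, bool); mask[:1500] = True
        out = stratified_delta_beta(beta, sheet, {"shifted": mask})
        assert out.loc["shifted", "median_delta_beta"] == pytest.approx(0.10, abs=0.01)
        assert out.loc["shifted", "p"] < 1e-10

    def test_empty_and_singleton_strata_error(self, rng):
        beta, sheet = self.setup_data(rng)
        with pytest.raises(ValueError, match="empty"):
            stratified_delta_beta(beta, sheet, {"x": np.zeros(400, bool)})
        single = np.zeros(400, bool); single[0] = True
        with pytest.raises(ValueError, match="single"):
            stratified_delta_beta(beta, sheet, {"x": single})


def test_probe_membership_uses_half_open_points():
    annot = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 101]},
                         index=["a", "b"])
    track = AnnotationTrack([GenomicInterval("chr1", 99, 100)])
    got = probe_track_membership(annot, {"t": track})
    # 1-based position 100 is the interval [99, 100): inside; 101 is not
    assert got.loc["a", "t"] and not got.loc["b", "t"]
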