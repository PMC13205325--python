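"""Metric oracles: AUROC/AP vs brute force, per-k-mer tables, regional
concordance, peak enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from anomod.evaluate import (
    RegionalReport,
    UndefinedMetricError,
    auroc,
    auroc_auprc,
    average_precision,
    peak_enrichment,
    per_kmer_auroc,
    regional_concordance,
    smooth_track,
)


def brute_force_auroc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_ap(scores, labels):
    """Step-wise AP over distinct thresholds, computed naively."""
    n_pos = labels.sum()
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_tp = 0.0, 0
    for t in thresholds:
        sel = scores >= t
        tp = int(labels[sel].sum())
        prec = tp / sel.sum()
        ap += (tp - prev_tp) / n_pos * prec
        prev_tp = tp
    return ap


class TestAurocAp:
    def test_perfect_separation(self):
        r = auroc_auprc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert r.auroc == 1.0 and r.auprc == 1.0

    def test_all_tied_scores(self):
        assert auroc([1, 1, 1, 1], [0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        # pairs: (0.35 vs 0.1) win, (0.35 vs 0.4) loss, (0.8 vs both) wins
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1, 2], [1, 1])
        with pytest.raises(UndefinedMetricError):
            average_precision([1, 2], [0, 0])

    @given(
        n=st.integers(min_value=2, max_value=200),
        seed=st.integers(min_value=0, max_value=10_000),
        ties=st.booleans(),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force(self, n, seed, ties):
        """Rank-based AUROC and stepwise AP equal the brute-force
        estimators on arbitrary score/label sets (to 1e-12)."""
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, n).astype(float) if ties else rng.random(n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12
        )
        assert average_precision(scores, labels) == pytest.approx(
            brute_force_ap(scores, labels), abs=1e-12
        )

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_ap_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        transformed = np.exp(3 * scores) + 7
        assert average_precision(scores, labels) == pytest.approx(
            average_precision(transformed, labels), abs=1e-12
        )
        assert auroc(scores, labels) == pytest.approx(
            auroc(transformed, labels), abs=1e-12
        )

    def test_agrees_with_sklearn(self, rng):
        """Independent cross-check against scikit-learn's implementations."""
        from sklearn.metrics import average_precision_score, roc_auc_score

        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )
        assert average_precision(scores, labels) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12
        )


class TestPerKmer:
    def frame(self, kmers, scores):
        return pd.DataFrame({"kmer": kmers, "score": scores})

    def test_single_class_kmers_omitted(self, rng):
        df = self.frame(["ACG"] * 10 + ["TTT"] * 10, rng.random(20))
        labels = [1, 0] * 5 + [0] * 10  # TTT has no positives
        out = per_kmer_auroc(df, labels, min_instances=2)
        assert set(out["kmer"]) == {"ACG"}

    def test_pooled_auroc_within_per_kmer_range(self, rng):
        """With uniform class balance across k-mers and per-k-mer score
        scales, pooled AUROC lies within [min, max] of per-k-mer AUROCs."""
        kmers, scores, labels = [], [], []
        for i, u in enumerate(["AAA", "CCC", "GGG"]):
            n = 40
            lab = np.array([0, 1] * (n // 2))
            sc = lab * (0.5 + 0.3 * i) + rng.random(n) * 0.8
            kmers += [u] * n
            scores += sc.tolist()
            labels += lab.tolist()
        df = self.frame(kmers, scores)
        table = per_kmer_auroc(df, labels, min_instances=5)
        pooled = auroc(np.array(scores), np.array(labels))
        assert table["auroc"].min() - 1e-9 <= pooled <= table["auroc"].max() + 1e-9

    def test_min_instances_above_counts_empty(self, rng):
        df = self.frame(["ACG"] * 6, rng.random(6))
        out = per_kmer_auroc(df, [0, 1] * 3, min_instances=100)
        assert out.empty


def make_tracks(rng, n=120, block=(40, 80)):
    pos = np.arange(n) * 2
    occ = np.where((np.arange(n) >= block[0]) & (np.arange(n) < block[1]), 85.0, 5.0)
    occ = np.clip(occ + rng.normal(0, 3, n), 0, 100)
    score = occ / 100 + rng.normal(0, 0.08, n)
    sites = pd.DataFrame(
        {"contig": "c", "pos": pos, "strand": "+", "score": score, "coverage": 10}
    )
    truth = pd.DataFrame(
        {"contig": "c", "pos": pos, "strand": "+", "occupancy_percent": occ}
    )
    return sites, truth


class TestRegionalConcordance:
    def test_truth_equals_score_is_perfect(self, rng):
        sites, truth = make_tracks(rng)
        sites["score"] = truth["occupancy_percent"]
        rep = regional_concordance(
            sites, truth, ("c", 0, 1000), cutoffs=(20.0, 50.0), smoothing_window=1
        )
        assert rep.spearman == pytest.approx(1.0)
        assert all(a == 1.0 for a in rep.auroc_per_cutoff)

    def test_block_enrichment_beats_prevalence(self, rng):
        sites, truth = make_tracks(rng)
        rep = regional_concordance(sites, truth, ("c", 0, 1000))
        for ap, prev in zip(rep.ap_per_cutoff, rep.prevalence_per_cutoff):
            assert ap > prev
        assert all(a > 0.5 for a in rep.auroc_per_cutoff)
        assert rep.spearman > 0

    def test_permuted_truth_near_chance(self, rng):
        """Scores independent of truth: AUROC ~ 0.5 and AP ~ prevalence
        within Monte-Carlo error over permutations."""
        sites, truth = make_tracks(rng)
        aurocs, ap_excess = [], []
        for _ in range(30):
            perm = truth.copy()
            perm["occupancy_percent"] = rng.permutation(
                perm["occupancy_percent"].to_numpy()
            )
            rep = regional_concordance(
                sites, perm, ("c", 0, 1000), cutoffs=(50.0,), smoothing_window=1
            )
            aurocs.append(rep.auroc_per_cutoff[0])
            ap_excess.append(rep.ap_per_cutoff[0] - rep.prevalence_per_cutoff[0])
        assert np.mean(aurocs) == pytest.approx(0.5, abs=0.05)
        assert abs(np.mean(ap_excess)) < 0.05

    def test_small_region_refused(self, rng):
        sites, truth = make_tracks(rng, n=5)
        with pytest.raises(UndefinedMetricError):
            regional_concordance(sites, truth, ("c", 0, 1000))

    def test_low_coverage_sites_excluded(self, rng):
        sites, truth = make_tracks(rng)
        sites.loc[:50, "coverage"] = 1
        rep = regional_concordance(sites, truth, ("c", 0, 1000), min_coverage=4)
        assert rep.n_sites == len(sites) - 51


class TestPeakEnrichment:
    def frame(self, n, scores):
        return pd.DataFrame(
            {"contig": "c", "pos": np.arange(n), "strand": "+", "score": scores}
        )

    def test_all_sites_in_peaks_ratio_one(self, rng):
        df = self.frame(50, rng.random(50))
        ratio, tail = peak_enrichment(df, [("c", 0, 50)], top_fraction=0.2)
        assert ratio == 1.0 and tail == pytest.approx(1.0)

    def test_uniform_top_expected_ratio_one(self, rng):
        ratios = []
        for _ in range(100):
            df = self.frame(100, rng.random(100))
            ratio, _ = peak_enrichment(df, [("c", 0, 20)], top_fraction=0.1)
            ratios.append(ratio)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.25)

    def test_constructed_hypergeometric_case(self):
        """100 sites, 20 in peaks, top 10 all inside peaks: enrichment 5
        and tail C(20,10)/C(100,10)."""
        scores = np.zeros(100)
        scores[:10] = 1.0  # top 10 are sites 0..9, all inside the peak
        df = self.frame(100, scores)
        ratio, tail = peak_enrichment(df, [("c", 0, 20)], top_fraction=0.1)
        assert ratio == pytest.approx((10 / 10) / (20 / 100))
        assert tail == pytest.approx(comb(20, 10) / comb(100, 10))

    def test_empty_peaks_rejected(self, rng):
        with pytest.raises(ValueError):
            peak_enrichment(self.frame(10, rng.random(10)), [])


def test_smooth_track_is_centered_mean():
    x = np.array([0.0, 3.0, 6.0, 9.0, 12.0])
    np.testing.assert_allclose(smooth_track(x, 3), [1.5, 3, 6, 9, 10.5])
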