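"""Discrimination metrics, per-k-mer breakdowns and regional concordance.

AUROC uses the rank-sum (Mann–Whitney) estimator with midrank tie handling;
AUPRC is average precision with step-wise interpolation over distinct score
thresholds.  Both definitions are exact, so tests can compare against
brute-force pairwise/stepwise oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr, rankdata, spearmanr


class UndefinedMetricError(ValueError):
    """Raised when labels contain a single class."""


@dataclass
class EvalResult:
    level: str
    auroc: float
    auprc: float
    n_pos: int
    n_neg: int

    @property
    def prevalence(self) -> float:
        return self.n_pos / (self.n_pos + self.n_neg)


def auroc(scores, labels) -> float:
    """Mann–Whitney AUROC with midrank ties; equals the all-pairs estimator
    P(s_pos > s_neg) + 0.5 P(s_pos = s_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("need at least one positive and one negative")
    ranks = rankdata(scores)  # midranks
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def average_precision(scores, labels) -> float:
    """AP with step-wise interpolation: sum over distinct thresholds of
    (recall step) x (precision at threshold); ties grouped."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise UndefinedMetricError("need at least one positive and one negative")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    pred = np.arange(1, len(y) + 1)
    # last index of each tie group
    last = np.nonzero(np.append(np.diff(s) != 0, True))[0]
    tp_t = tp[last].astype(float)
    prec_t = tp_t / pred[last]
    recall_step = np.diff(np.concatenate(([0.0], tp_t))) / n_pos
    return float((recall_step * prec_t).sum())


def auroc_auprc(scores, labels, level: str = "instance") -> EvalResult:
    labels = np.asarray(labels, dtype=int)
    return EvalResult(
        level=level,
        auroc=float(auroc(scores, labels)),
        auprc=float(average_precision(scores, labels)),
        n_pos=int(labels.sum()),
        n_neg=int(len(labels) - labels.sum()),
    )


def per_kmer_auroc(instance_scores, labels, min_instances: int = 5) -> pd.DataFrame:
    """AUROC per sequence context (k-mer), for contexts with at least
    ``min_instances`` of each class; other contexts are omitted.

    ``instance_scores`` is a DataFrame with columns kmer/score (e.g. from
    :func:`anomod.scoring.scores_to_frame`); ``labels`` aligns with its rows.
    """
    df = instance_scores.copy()
    df["label"] = np.asarray(labels, dtype=int)
    rows = []
    for kmer, grp in df.groupby("kmer", sort=True):
        n_pos = int(grp["label"].sum())
        n_neg = len(grp) - n_pos
        if n_pos < min_instances or n_neg < min_instances:
            continue
        rows.append(
            (kmer, auroc(grp["score"].to_numpy(), grp["label"].to_numpy()), n_pos, n_neg)
        )
    return pd.DataFrame(rows, columns=["kmer", "auroc", "n_pos", "n_neg"])


@dataclass
class RegionalReport:
    region: tuple
    cutoffs: list
    auroc_per_cutoff: list = field(default_factory=list)
    ap_per_cutoff: list = field(default_factory=list)
    prevalence_per_cutoff: list = field(default_factory=list)
    pearson: float = np.nan
    spearman: float = np.nan
    n_sites: int = 0


def smooth_track(values: np.ndarray, window: int = 11) -> np.ndarray:
    """Centered rolling mean over neighbouring sites (site-count window)."""
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def regional_concordance(
    site_track: pd.DataFrame,
    truth_track: pd.DataFrame,
    region: tuple[str, int, int],
    cutoffs=(10.0, 25.0, 50.0, 75.0, 90.0),
    min_coverage: int = 4,
    smoothing_window: int = 11,
) -> RegionalReport:
    """Concordance between a site-score track and a continuous truth track.

    ``site_track`` needs columns contig/pos/strand/score/coverage;
    ``truth_track`` needs contig/pos/strand/occupancy_percent in [0, 100].
    For each cutoff c, positives are region sites with truth >= c (after
    dropping coverage < min_coverage); AP, AUROC and the prevalence baseline
    are reported per cutoff.  Pearson/Spearman correlate the smoothed score
    with the continuous truth.
    """
    contig, start, end = region
    merged = site_track.merge(truth_track, on=["contig", "pos", "strand"])
    merged = merged[
        (merged["contig"] == contig)
        & (merged["pos"] >= start)
        & (merged["pos"] < end)
        & (merged["coverage_x" if "coverage_x" in merged else "coverage"] >= min_coverage)
    ].sort_values("pos")
    if len(merged) < 10:
        raise UndefinedMetricError(
            f"region has {len(merged)} usable sites (< 10); refusing"
        )
    truth = merged["occupancy_percent"].to_numpy(dtype=float)
    score = merged["score"].to_numpy(dtype=float)
    smoothed = smooth_track(score, smoothing_window)

    report = RegionalReport(region=region, cutoffs=list(cutoffs), n_sites=len(merged))
    for c in cutoffs:
        y = (truth >= c).astype(int)
        report.prevalence_per_cutoff.append(float(y.mean()))
        if 0 < y.sum() < len(y):
            report.auroc_per_cutoff.append(float(auroc(score, y)))
            report.ap_per_cutoff.append(float(average_precision(score, y)))
        else:
            report.auroc_per_cutoff.append(np.nan)
            report.ap_per_cutoff.append(np.nan)
    if np.ptp(truth) > 0 and np.ptp(smoothed) > 0:
        report.pearson = float(pearsonr(smoothed, truth)[0])
        report.spearman = float(spearmanr(smoothed, truth)[0])
    return report


def peak_enrichment(
    site_track: pd.DataFrame, peak_intervals, top_fraction: float = 0.1
):
    """Enrichment of top-scoring sites inside annotated peak intervals.

    ``peak_intervals`` is a list of (contig, start, end), half-open, sorted.
    Returns ``(enrichment_ratio, hypergeometric_tail)`` where the ratio is
    (fraction of top sites in peaks) / (fraction of all sites in peaks) and
    the tail is the exact hypergeometric P(X >= observed overlap).
    """
    if not peak_intervals:
        raise ValueError("empty peak list")
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    df = site_track.reset_index(drop=True)
    in_peak = np.zeros(len(df), dtype=bool)
    for contig, start, end in peak_intervals:
        in_peak |= (
            (df["contig"] == contig) & (df["pos"] >= start) & (df["pos"] < end)
        ).to_numpy()
    M = len(df)
    K = int(in_peak.sum())
    n_top = max(1, int(round(top_fraction * M)))
    top_idx = np.argsort(-df["score"].to_numpy(), kind="mergesort")[:n_top]
    x = int(in_peak[top_idx].sum())
    overall = K / M
    if overall == 0:
        return 0.0, 1.0
    enrichment = (x / n_top) / overall
    tail = float(hypergeom.sf(x - 1, M, K, n_top))
    return enrichment, tail


# -- truth track I/O --------------------------------------------------------

def read_truth_track(path) -> pd.DataFrame:
    """Read a bedMethyl-like TSV with contig/pos/strand/occupancy_percent."""
    return pd.read_csv(path, sep="\t")


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return sorted(out)
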