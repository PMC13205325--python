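"""Instance-level anomaly scores and site-level aggregation.

The anomaly score of a (read, site) instance is the reconstruction error
s = MSE(x, x_hat) over valid window positions, with x_hat decoded from the
posterior mean (deterministic).  Site-level evidence S is the mean (or
median) of instance scores across the reads covering the site, reported
with coverage and dispersion summaries (sd, unscaled MAD, sem = sd/sqrt(n)).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vae import CnnTransformerVae, elbo_terms, feature_schema_hash, windows_to_arrays

log = logging.getLogger(__name__)


class SchemaMismatchError(ValueError):
    pass


@dataclass
class InstanceScore:
    read_id: str
    contig: str
    site_j: int
    strand: str
    score: float
    kmer_u: str


@dataclass
class SiteScore:
    contig: str
    site_j: int
    strand: str
    S: float
    n: int
    sd: float
    mad: float
    sem: float


def score_windows(model: CnnTransformerVae, x, mask=None) -> np.ndarray:
    """Masked per-window reconstruction MSE for a batch array (B, L, C)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    B, L, C = x.shape
    if mask is None:
        mask = np.ones((B, L), dtype=bool)
    post = model.encode(x)
    xhat = model.decode(post.mu)
    sq = (x - xhat) ** 2 * mask[:, :, None]
    return sq.sum(axis=(1, 2)) / (mask.sum(axis=1) * C)


def score_instances(model: CnnTransformerVae, instance_stream, batch_size: int = 512):
    """Yield an InstanceScore per window; deterministic given the checkpoint.

    Windows must have been built under the same feature schema (L, C and
    channel layout) as the model was trained on; a mismatch is refused.
    """
    buf = []

    def flush():
        x, mask = windows_to_arrays(buf)
        if x.shape[1:] != (model.config.L, model.config.C):
            raise SchemaMismatchError(
                f"window shape {x.shape[1:]} does not match model schema "
                f"{model.schema_hash} (L={model.config.L}, C={model.config.C})"
            )
        scores = score_windows(model, x, mask)
        for w, s in zip(buf, scores):
            yield InstanceScore(
                read_id=w.read_id,
                contig=w.contig,
                site_j=w.site_j,
                strand=w.strand,
                score=float(s),
                kmer_u=w.kmer_u,
            )
        buf.clear()

    for w in instance_stream:
        buf.append(w)
        if len(buf) >= batch_size:
            yield from flush()
    if buf:
        yield from flush()


def scores_to_frame(scores) -> pd.DataFrame:
    rows = [
        (s.read_id, s.contig, s.site_j, s.strand, s.kmer_u, s.score) for s in scores
    ]
    return pd.DataFrame(
        rows, columns=["read_id", "contig", "pos", "strand", "kmer", "score"]
    )


def aggregate_sites(
    scores, aggregator: str = "mean", min_coverage: int = 4
) -> list[SiteScore]:
    """Aggregate instance scores into per-site evidence.

    Sites with coverage below ``min_coverage`` are dropped (the drop count is
    logged).  sd uses ddof=1 with the n=1 convention sd = sem = 0; MAD is the
    unscaled median absolute deviation.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    df = scores if isinstance(scores, pd.DataFrame) else scores_to_frame(scores)
    if df.empty:
        return []
    out = []
    dropped = 0
    for (contig, pos, strand), grp in df.groupby(
        ["contig", "pos", "strand"], sort=True
    ):
        v = grp["score"].to_numpy(dtype=float)
        n = len(v)
        if n < min_coverage:
            dropped += 1
            continue
        S = float(np.mean(v)) if aggregator == "mean" else float(np.median(v))
        sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
        mad = float(np.median(np.abs(v - np.median(v))))
        out.append(
            SiteScore(
                contig=contig,
                site_j=int(pos),
                strand=strand,
                S=S,
                n=n,
                sd=sd,
                mad=mad,
                sem=sd / np.sqrt(n) if n > 1 else 0.0,
            )
        )
    if dropped:
        log.info("aggregate_sites: dropped %d sites below coverage %d", dropped, min_coverage)
    return out


def sites_to_frame(sites: list[SiteScore]) -> pd.DataFrame:
    rows = [(s.contig, s.site_j, s.strand, s.S, s.n, s.sd, s.mad, s.sem) for s in sites]
    return pd.DataFrame(
        rows, columns=["contig", "pos", "strand", "score", "coverage", "sd", "mad", "sem"]
    )


def differential_track(site_scores_test, site_scores_control) -> pd.DataFrame:
    """Per-site score difference test - control over the shared site set.

    Mirrors a native-vs-unmodified-proxy comparison: both tracks are keyed by
    (contig, pos, strand); only sites present in both are emitted, with the
    combined coverage attached.
    """
    a = site_scores_test if isinstance(site_scores_test, pd.DataFrame) else sites_to_frame(site_scores_test)
    b = site_scores_control if isinstance(site_scores_control, pd.DataFrame) else sites_to_frame(site_scores_control)
    merged = a.merge(b, on=["contig", "pos", "strand"], suffixes=("_test", "_control"))
    if merged.empty:
        log.warning("differential_track: zero overlapping sites")
        return pd.DataFrame(
            columns=["contig", "pos", "strand", "diff", "coverage_test", "coverage_control"]
        )
    merged["diff"] = merged["score_test"] - merged["score_control"]
    return merged[
        ["contig", "pos", "strand", "diff", "coverage_test", "coverage_control"]
    ].rename(columns={})


def rolling_median_smooth(values: np.ndarray, window: int = 11) -> np.ndarray:
    """Centered rolling-median smoother for plotting/denoising site tracks."""
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


# -- serialization ----------------------------------------------------------

def write_instance_scores(scores, path) -> None:
    df = scores if isinstance(scores, pd.DataFrame) else scores_to_frame(scores)
    df.to_csv(path, sep="\t", index=False)


def read_instance_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_site_scores(sites, path) -> None:
    """bedMethyl-like TSV: contig, pos (0-based), strand, score, coverage,
    dispersion summaries."""
    df = sites if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
    df.to_csv(path, sep="\t", index=False)


def read_site_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph(sites, path, track_name: str = "anomod_site_score") -> None:
    df = sites if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for _, r in df.sort_values(["contig", "pos"]).iterrows():
            fh.write(f"{r['contig']}\t{int(r['pos'])}\t{int(r['pos']) + 1}\t{r['score']:.6g}\n")
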