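"""Per-nucleotide instance windows: the L x C feature tensor.

Each scored instance is one (read, reference site) pair.  The window covers
L consecutive read bases centered on the base aligned to the site; every
position contributes C = 11 channels:

====  =======================================================
0-3   one-hot base identity (A, C, G, T), read-oriented
4     winsorized mean of the base's raw samples (5th/95th pct)
5-7   first, second, third quartiles (linear interpolation)
8     central sample value (left-middle on even segment length)
9     RMS energy, sqrt(mean(sample^2))
10    basecaller quality, Phred/40 clipped to [0, 1]
====  =======================================================

Signal channels are computed on per-read z-normalized samples.  Window
positions that fall off the read are zero-filled (one-hot all zero) and
masked out; downstream losses and scores use the validity mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_io import SignalRead, _as_ref_dict, read_signal_bam
from .util import revcomp

log = logging.getLogger(__name__)

N_CHANNELS = 11
#: Bump when the channel layout above changes; checkpoints refuse to score
#: features produced under a different schema.
FEATURE_SCHEMA = "onehot4+wmean+quartiles3+central+rms+qual/v1"


class ConstantSignalError(ValueError):
    """Raised for degenerate reads whose signal cannot be z-normalized."""


def znormalize_read(raw_samples: np.ndarray) -> np.ndarray:
    """Per-read z-normalization (population sd), applied once per read."""
    x = np.asarray(raw_samples, dtype=np.float64)
    if x.size < 2:
        raise ConstantSignalError("need at least 2 samples")
    sd = x.std()
    if sd == 0:
        raise ConstantSignalError("constant signal; cannot z-normalize")
    return (x - x.mean()) / sd


_ONEHOT = {b: i for i, b in enumerate("ACGT")}


def _segment_features(seg: np.ndarray) -> np.ndarray:
    lo, q1, q2, q3, hi = np.percentile(seg, [5, 25, 50, 75, 95])  # linear interp
    wmean = np.clip(seg, lo, hi).mean()
    central = seg[(len(seg) - 1) // 2]
    rms = np.sqrt(np.mean(seg**2))
    return np.array([wmean, q1, q2, q3, central, rms])


def read_feature_matrix(read: SignalRead, normalized: np.ndarray) -> np.ndarray:
    """Per-base feature rows (n_bases, C) for a whole read, computed once;
    windows are then slices of this matrix.

    Bases are grouped by dwell length so the order statistics run on
    stacked arrays instead of one tiny call per base.
    """
    m = read.n_bases
    feats = np.zeros((m, N_CHANNELS), dtype=np.float32)
    starts = read.sample_starts()
    dwells = read.dwells

    seq = read.sequence.upper()
    for i, base in enumerate(seq):
        oh = _ONEHOT.get(base)
        if oh is not None:
            feats[i, oh] = 1.0
    feats[:, 10] = np.minimum(read.base_qualities, 40) / 40.0

    for d in np.unique(dwells):
        idx = np.nonzero(dwells == d)[0]
        segs = normalized[starts[idx, None] + np.arange(d)[None, :]]
        lo, q1, q2, q3, hi = np.percentile(segs, [5, 25, 50, 75, 95], axis=1)
        feats[idx, 4] = np.clip(segs, lo[:, None], hi[:, None]).mean(axis=1)
        feats[idx, 5] = q1
        feats[idx, 6] = q2
        feats[idx, 7] = q3
        feats[idx, 8] = segs[:, (d - 1) // 2]
        feats[idx, 9] = np.sqrt(np.mean(segs**2, axis=1))
    return feats


@dataclass
class InstanceWindow:
    """Feature matrix for one (read, site) instance plus its context."""

    x: np.ndarray  # (L, C) float32
    mask: np.ndarray  # (L,) bool validity
    read_id: str
    contig: str
    site_j: int
    strand: str
    kmer_u: str
    center_index: int

    @property
    def L(self) -> int:
        return self.x.shape[0]


def build_window(
    read: SignalRead,
    site_j: int,
    reference=None,
    L: int = 7,
    k: int = 7,
    normalized: np.ndarray | None = None,
    feats: np.ndarray | None = None,
) -> InstanceWindow | None:
    """Build the L x C window centered on the base aligned to ``site_j``.

    Returns ``None`` when the site is deleted or outside the read.  Pass the
    read's z-normalized samples via ``normalized`` (or a precomputed
    :func:`read_feature_matrix` via ``feats``) to avoid recomputation per
    site; otherwise they are computed here.
    """
    if L % 2 == 0 or k % 2 == 0:
        raise ValueError("L and k must be odd")
    center = read.ref_to_read_index(site_j)
    if center is None:
        return None
    if feats is None:
        if normalized is None:
            normalized = znormalize_read(read.raw_samples)
        feats = read_feature_matrix(read, normalized)

    x = np.zeros((L, N_CHANNELS), dtype=np.float32)
    mask = np.zeros(L, dtype=bool)
    half = L // 2
    lo_i = max(0, center - half)
    hi_i = min(read.n_bases, center + half + 1)
    x[lo_i - (center - half) : hi_i - (center - half)] = feats[lo_i:hi_i]
    mask[lo_i - (center - half) : hi_i - (center - half)] = True

    half_k = k // 2
    if reference is not None:
        ref = _as_ref_dict(reference)
        seq = ref[read.contig]
        lo, hi = site_j - half_k, site_j + half_k + 1
        core = seq[max(lo, 0) : min(hi, len(seq))].upper()
        kmer = "N" * (0 - min(lo, 0)) + core + "N" * max(hi - len(seq), 0)
        if read.strand == "-":
            kmer = revcomp(kmer)
    else:
        lo, hi = center - half_k, center + half_k + 1
        core = read.sequence[max(lo, 0) : min(hi, read.n_bases)].upper()
        kmer = "N" * (0 - min(lo, 0)) + core + "N" * max(hi - read.n_bases, 0)

    return InstanceWindow(
        x=x,
        mask=mask,
        read_id=read.read_id,
        contig=read.contig,
        site_j=site_j,
        strand=read.strand,
        kmer_u=kmer,
        center_index=half,
    )


def iter_read_instances(
    read: SignalRead,
    reference=None,
    L: int = 7,
    k: int = 7,
    region: tuple[str, int, int] | None = None,
    min_baseq: int = 0,
):
    """Yield an InstanceWindow for every aligned site of one read."""
    try:
        normalized = znormalize_read(read.raw_samples)
    except ConstantSignalError as exc:
        log.warning("read %s rejected: %s", read.read_id, exc)
        return
    feats = read_feature_matrix(read, normalized)
    pairs = read.aligned_pairs()
    for i in sorted(pairs):
        site_j = pairs[i]
        if region is not None:
            contig, start, end = region
            if read.contig != contig or not (start <= site_j < end):
                continue
        if read.base_qualities[i] < min_baseq:
            continue
        win = build_window(read, site_j, reference, L=L, k=k, feats=feats)
        if win is not None:
            yield win


def iter_instances(
    bam_path,
    reference,
    L: int = 7,
    k: int = 7,
    region: tuple[str, int, int] | None = None,
    min_mapq: int = 0,
    min_baseq: int = 0,
):
    """Stream every QC-passing (read, aligned site) instance from a signal
    BAM, in deterministic (coordinate, read, site) order."""
    ref = _as_ref_dict(reference) if reference is not None else None
    for read in read_signal_bam(bam_path, region=region):
        if read.mapq < min_mapq:
            continue
        yield from iter_read_instances(
            read, ref, L=L, k=k, region=region, min_baseq=min_baseq
        )


def iter_instances_from_reads(
    reads,
    reference=None,
    L: int = 7,
    k: int = 7,
    min_mapq: int = 0,
    min_baseq: int = 0,
):
    """In-memory variant of :func:`iter_instances` over SignalRead objects."""
    ref = _as_ref_dict(reference) if reference is not None else None
    for read in reads:
        if read.mapq < min_mapq:
            continue
        yield from iter_read_instances(read, ref, L=L, k=k, min_baseq=min_baseq)
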