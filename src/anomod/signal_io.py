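"""Aligned reads with embedded raw signal ("signal BAM") and re-squiggling.

The on-disk dialect stores, per alignment record, three local-use BAM tags:

===  =====================  ==========================================
tag  SAM type               content
===  =====================  ==========================================
sg   B,f (float array)      raw current samples, in read (time) order
dw   B,I (uint32 array)     per-base sample counts, read-oriented
so   i  (int)               index of the first sample assigned to base 0
===  =====================  ==========================================

Base i of the read-oriented sequence owns the contiguous raw-sample interval
``[so + sum(dw[:i]), so + sum(dw[:i+1]))``.  For minus-strand alignments the
SEQ/QUAL fields follow SAM convention (reverse complement), while the three
tags always remain in read/time order; readers convert back.  No claim of
compatibility with any other tool's signal-embedding scheme is made.
"""

from __future__ import annotations

import logging
import re
from array import array
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .util import revcomp

log = logging.getLogger(__name__)

TAG_SAMPLES = "sg"
TAG_DWELLS = "dw"
TAG_OFFSET = "so"

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class SignalBamError(ValueError):
    pass


@dataclass
class SignalRead:
    """One aligned read carrying its raw-signal samples and move information.

    ``sequence``, ``dwells``, ``base_qualities`` and ``raw_samples`` are all
    read-oriented (time order).  ``cigar`` follows SAM convention (reference
    orientation over the SAM-stored query); ``None`` means a full-length
    match.  Reference coordinates are 0-based half-open.
    """

    read_id: str
    contig: str
    ref_start: int
    strand: str  # '+' or '-'
    sequence: str
    raw_samples: np.ndarray
    dwells: np.ndarray
    base_qualities: np.ndarray
    cigar: str | None = None
    sample_offset: int = 0
    mapq: int = 60
    _pairs: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.raw_samples = np.asarray(self.raw_samples, dtype=np.float32)
        self.dwells = np.asarray(self.dwells, dtype=np.int64)
        self.base_qualities = np.asarray(self.base_qualities, dtype=np.int64)
        if self.strand not in "+-":
            raise SignalBamError(f"bad strand {self.strand!r}")
        n = len(self.sequence)
        if not (len(self.dwells) == len(self.base_qualities) == n):
            raise SignalBamError("sequence/dwells/qualities length mismatch")
        if self.raw_samples.size == 0:
            raise SignalBamError("zero-length raw_samples")
        if np.any(self.dwells < 1):
            raise SignalBamError("every base needs at least one sample")
        if self.sample_offset + int(self.dwells.sum()) > self.raw_samples.size:
            raise SignalBamError("move table exceeds raw sample count")

    # -- derived geometry ---------------------------------------------------

    @property
    def n_bases(self) -> int:
        return len(self.sequence)

    def sample_starts(self) -> np.ndarray:
        """Start index in raw_samples of each base's interval (read order)."""
        return self.sample_offset + np.concatenate(
            ([0], np.cumsum(self.dwells[:-1]))
        )

    def base_samples(self, i: int) -> np.ndarray:
        """Raw-sample slice owned by read-oriented base ``i``."""
        starts = self.sample_starts()
        return self.raw_samples[starts[i] : starts[i] + self.dwells[i]]

    def effective_cigar(self) -> str:
        return self.cigar if self.cigar is not None else f"{self.n_bases}M"

    def aligned_pairs(self) -> dict[int, int]:
        """Mapping read-oriented base index -> 0-based reference position,
        for match/mismatch columns only (insertions and clips absent)."""
        if self._pairs is None:
            pairs = {}
            q, r = 0, self.ref_start
            for n, op in _CIGAR_RE.findall(self.effective_cigar()):
                n = int(n)
                if op in "M=X":
                    for t in range(n):
                        pairs[q + t] = r + t
                    q += n
                    r += n
                elif op in "IS":
                    q += n
                elif op in "DN":
                    r += n
                # H, P consume nothing we track
            if self.strand == "-":
                m = self.n_bases
                pairs = {m - 1 - qi: rp for qi, rp in pairs.items()}
            self._pairs = pairs
        return self._pairs

    def ref_to_read_index(self, ref_pos: int) -> int | None:
        if not hasattr(self, "_rev_pairs") or self._rev_pairs is None:
            self._rev_pairs = {rp: qi for qi, rp in self.aligned_pairs().items()}
        return self._rev_pairs.get(ref_pos)

    @property
    def ref_end(self) -> int:
        return max(self.aligned_pairs().values()) + 1


def _as_ref_dict(reference) -> dict[str, str]:
    if isinstance(reference, dict):
        return reference
    path = str(reference)
    with pysam.FastaFile(path) as fa:
        return {name: fa.fetch(name) for name in fa.references}


def write_reference_fasta(reference: dict[str, str], path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    pysam.faidx(str(path))


def write_signal_bam(reads: list[SignalRead], reference, path) -> None:
    """Write a coordinate-sorted, indexed signal BAM.

    ``reference`` is a dict name->sequence or a FASTA path; contig names in
    the reads must be known to it.
    """
    ref = _as_ref_dict(reference)
    names = list(ref)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": len(ref[n])} for n in names],
        }
    )
    tid = {n: i for i, n in enumerate(names)}
    for read in reads:
        if read.contig not in tid:
            raise SignalBamError(f"unknown contig {read.contig!r}")

    path = str(path)
    ordered = sorted(reads, key=lambda r: (tid[r.contig], r.ref_start, r.read_id))
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for read in ordered:
            a = pysam.AlignedSegment(header)
            a.query_name = read.read_id
            a.reference_id = tid[read.contig]
            a.reference_start = read.ref_start
            a.mapping_quality = read.mapq
            a.cigarstring = read.effective_cigar()
            if read.strand == "-":
                a.flag = 16
                a.query_sequence = revcomp(read.sequence)
                a.query_qualities = array(
                    "B", read.base_qualities[::-1].astype(np.uint8)
                )
            else:
                a.flag = 0
                a.query_sequence = read.sequence
                a.query_qualities = array("B", read.base_qualities.astype(np.uint8))
            a.set_tag(TAG_SAMPLES, array("f", read.raw_samples.astype(np.float32)))
            a.set_tag(TAG_DWELLS, array("I", read.dwells.astype(np.uint32)))
            a.set_tag(TAG_OFFSET, int(read.sample_offset))
            bam.write(a)
    pysam.index(path)


def read_signal_bam(path, region: tuple[str, int, int] | None = None):
    """Yield SignalRead for every primary alignment, optionally restricted to
    reads overlapping ``region = (contig, start, end)`` (0-based half-open).

    Records missing the signal tags or with an inconsistent move table are
    skipped with a logged warning; a summary count is logged at the end.
    """
    skipped = 0
    with pysam.AlignmentFile(str(path), "rb") as bam:
        it = bam.fetch(*region) if region is not None else bam.fetch()
        for a in it:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            if not (a.has_tag(TAG_SAMPLES) and a.has_tag(TAG_DWELLS)):
                log.warning("read %s lacks signal tags; skipped", a.query_name)
                skipped += 1
                continue
            samples = np.asarray(a.get_tag(TAG_SAMPLES), dtype=np.float32)
            dwells = np.asarray(a.get_tag(TAG_DWELLS), dtype=np.int64)
            offset = int(a.get_tag(TAG_OFFSET)) if a.has_tag(TAG_OFFSET) else 0
            strand = "-" if a.is_reverse else "+"
            seq = a.query_sequence
            quals = np.asarray(a.query_qualities, dtype=np.int64)
            if strand == "-":
                seq = revcomp(seq)
                quals = quals[::-1].copy()
            try:
                yield SignalRead(
                    read_id=a.query_name,
                    contig=a.reference_name,
                    ref_start=a.reference_start,
                    strand=strand,
                    sequence=seq,
                    raw_samples=samples,
                    dwells=dwells,
                    base_qualities=quals,
                    cigar=a.cigarstring,
                    sample_offset=offset,
                    mapq=a.mapping_quality,
                )
            except SignalBamError as exc:
                log.warning("read %s invalid (%s); skipped", a.query_name, exc)
                skipped += 1
    if skipped:
        log.warning("read_signal_bam: skipped %d invalid records", skipped)


def resquiggle(read: SignalRead, site_j: int, reference=None, k: int = 7):
    """Per-base signal segment and strand-oriented reference k-mer at a site.

    Returns ``(segment, kmer)`` for the base of ``read`` aligned to reference
    position ``site_j``, or ``None`` when the site falls in a deletion or
    outside the read (the "not covered" signal — callers filter).  The k-mer
    is taken from ``reference`` (dict or FASTA path) centered on ``site_j``
    and reverse-complemented for minus-strand reads; positions off the contig
    are padded with ``N``.  Without a reference the k-mer is read from the
    read's own sequence.
    """
    qi = read.ref_to_read_index(site_j)
    if qi is None:
        return None
    segment = read.base_samples(qi)
    half = k // 2
    if reference is not None:
        ref = _as_ref_dict(reference)
        seq = ref[read.contig]
        lo, hi = site_j - half, site_j + half + 1
        core = seq[max(lo, 0) : min(hi, len(seq))].upper()
        kmer = "N" * (0 - min(lo, 0)) + core + "N" * max(hi - len(seq), 0)
        if read.strand == "-":
            kmer = revcomp(kmer)
    else:
        lo, hi = qi - half, qi + half + 1
        core = read.sequence[max(lo, 0) : min(hi, read.n_bases)].upper()
        kmer = "N" * (0 - min(lo, 0)) + core + "N" * max(hi - read.n_bases, 0)
    return segment, kmer
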