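"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtn", "TGCANYRSWMKVHDBtgcan")

# IUPAC degenerate codes -> set of concrete bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_matches(motif: str, seq: str) -> bool:
    """True if `seq` (concrete bases) matches the IUPAC `motif` of equal length."""
    if len(motif) != len(seq):
        return False
    for m, s in zip(motif.upper(), seq.upper()):
        allowed = IUPAC.get(m)
        if allowed is None or s not in allowed:
            return False
    return True


def scan_motif(seq: str, motif: str, offset: int):
    """Yield 0-based positions of the marked base for every motif hit on the
    forward orientation of `seq`."""
    w = len(motif)
    s = seq.upper()
    for i in range(len(s) - w + 1):
        if iupac_matches(motif, s[i : i + w]):
            yield i + offset


def kmer_index(kmer: str) -> int:
    """Base-4 integer code of an ACGT k-mer; raises on other characters."""
    idx = 0
    for b in kmer:
        idx = idx * 4 + BASES.index(b)
    return idx


def index_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def all_kmers(k: int):
    for i in range(4**k):
        yield index_kmer(i, k)


def is_acgt(seq: str) -> bool:
    return all(b in BASES for b in seq)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
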