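"""Streaming mini-batch construction with soft k-mer balancing.

Sequence-context frequencies in genomic data are heavily skewed; training on
a raw stream over-represents common contexts.  The balancer accepts a
candidate instance with k-mer context u with probability

    p_accept(u) = min(1, C_max / (N_seen(u) + 1)),

where N_seen(u) counts instances of context u accepted so far (tracked
online) and C_max is a global soft cap: acceptance decays hyperbolically for
frequent contexts while rare contexts are always kept.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .util import is_acgt


@dataclass
class BalancerState:
    """Online acceptance counters for soft k-mer balancing.

    ``cmax = math.inf`` disables balancing (everything accepted).  Counters
    persist across epochs unless :meth:`reset` is called.
    """

    cmax: float = math.inf
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.cmax <= 0:
            raise ValueError("cmax must be positive")

    def n_seen(self, u: str) -> int:
        return self.counts.get(u, 0)

    def record_accept(self, u: str) -> None:
        self.counts[u] = self.counts.get(u, 0) + 1

    def reset(self) -> None:
        self.counts.clear()

    def save(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["kmer", "count"])
            for u in sorted(self.counts):
                w.writerow([u, self.counts[u]])

    @classmethod
    def load(cls, path, cmax: float = math.inf) -> "BalancerState":
        state = cls(cmax=cmax)
        with open(path) as fh:
            r = csv.DictReader(fh, delimiter="\t")
            for row in r:
                state.counts[row["kmer"]] = int(row["count"])
        return state


def accept_probability(state: BalancerState, u: str) -> float:
    """min(1, C_max / (N_seen(u) + 1)); a pure function of the state."""
    return min(1.0, state.cmax / (state.n_seen(u) + 1))


def stream_accept(instance_stream, state: BalancerState, seed: int = 0):
    """Filter an instance stream through the soft balancer.

    Candidates whose k-mer contains non-ACGT characters bypass balancing and
    are rejected (undefined context).  Accepted instances increment
    N_seen(kmer).  Single-pass: rejected candidates are not revisited.
    """
    rng = np.random.default_rng(seed)
    for inst in instance_stream:
        u = inst.kmer_u
        if not is_acgt(u):
            continue
        if rng.random() < accept_probability(state, u):
            state.record_accept(u)
            yield inst


def stream_batches(instance_stream, state: BalancerState, batch_size: int, seed: int = 0):
    """Group balancer-accepted instances into batches of ``batch_size``.

    A final short batch (stream exhausted mid-batch) is still emitted; its
    length flags it.  Reproducible given the seed.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    batch = []
    for inst in stream_accept(instance_stream, state, seed=seed):
        batch.append(inst)
        if len(batch) == batch_size:
            yield batch
            batch = []
    if batch:
        yield batch


def split_train_validation(read_ids, fraction: float, seed: int = 0):
    """Deterministic read-level train/validation split (no instance leakage).

    Returns ``(train_ids, validation_ids)`` as disjoint sets whose union is
    the input; validation gets ``max(1, round(n * fraction))`` reads.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    ids = sorted(set(read_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 reads to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_val = min(max(1, round(len(ids) * fraction)), len(ids) - 1)
    val = {ids[i] for i in perm[:n_val]}
    train = {ids[i] for i in perm[n_val:]}
    return train, val
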