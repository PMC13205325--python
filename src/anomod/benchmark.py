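"""Self-contained benchmark of the whole pipeline on simulated data.

Encodes the package's reference study conditions for the controlled-oligo
analog: a short synthetic reference sequenced deeply, a reference model
trained on the unmodified corpus, and CpG-motif modified vs unmodified test
sets scored and compared at instance and site level.  Both the acceptance
tests and scripts/acceptance.py run these functions; problem sizes are
documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import auroc, auroc_auprc
from .features import iter_instances_from_reads
from .sampler import BalancerState, split_train_validation, stream_accept
from .scoring import score_windows
from .simulate import ModificationSpec, make_pore_model, make_reference, simulate_reads
from .vae import CnnTransformerVae, VaeConfig, train, windows_to_arrays


@dataclass
class StudyConditions:
    """Scaled-down controlled-oligo regime (defaults; see docs/methods.md)."""

    k: int = 7
    L: int = 7
    reference_length: int = 300
    n_train_reads: int = 70
    n_test_reads: int = 20  # ~10 same-strand reads per site
    read_length: int = 300
    level_shift: float = 2.0
    dwell_factor: float = 1.0
    per_site_occupancy: float = 1.0
    site_selection_rate: float = 1.0
    motif: str = "CG"
    noise_sd: float = 2.0
    offset_scale_jitter: float = 0.15
    cmax: float = float("inf")
    max_train_windows: int = 18000
    validation_fraction: float = 0.15
    min_site_coverage: int = 4
    vae: dict = field(default_factory=dict)


@dataclass
class BenchmarkResult:
    instance_auroc: float
    instance_auprc: float
    site_auroc: float
    site_auprc: float
    n_instances: tuple
    n_sites: tuple
    model: CnnTransformerVae
    history: list
    instance_frame: pd.DataFrame  # per-instance scores with labels
    site_frame: pd.DataFrame  # per-site mean scores with labels


def simulate_study(conditions: StudyConditions, seed: int):
    """Simulate the unmodified training corpus plus modified/unmodified
    test sets over one shared reference and pore model."""
    c = conditions
    pore = make_pore_model(c.k, seed=seed)
    reference = make_reference(c.reference_length, seed=seed + 1)
    spec = ModificationSpec(
        motif=c.motif,
        offset=0,
        level_shift=c.level_shift,
        dwell_factor=c.dwell_factor,
        per_site_occupancy=c.per_site_occupancy,
        site_selection_rate=c.site_selection_rate,
    )
    common = dict(
        noise_sd=c.noise_sd, offset_scale_jitter=c.offset_scale_jitter,
        read_length=c.read_length,
    )
    train_ds = simulate_reads(
        reference, pore, None, n_reads=c.n_train_reads, seed=seed + 2, **common
    )
    mod_ds = simulate_reads(
        reference, pore, spec, n_reads=c.n_test_reads, seed=seed + 3, **common
    )
    ctrl_ds = simulate_reads(
        reference, pore, None, n_reads=c.n_test_reads, seed=seed + 4, **common
    )
    return reference, pore, train_ds, mod_ds, ctrl_ds


def train_reference_model(conditions: StudyConditions, reference, train_ds, seed: int):
    """Balanced streaming extraction + VAE training on unmodified reads."""
    c = conditions
    windows = list(
        iter_instances_from_reads(train_ds.reads, reference, L=c.L, k=c.k)
    )
    train_ids, val_ids = split_train_validation(
        [r.read_id for r in train_ds.reads], c.validation_fraction, seed=seed
    )
    balancer = BalancerState(cmax=c.cmax)
    train_wins = list(
        stream_accept(
            (w for w in windows if w.read_id in train_ids), balancer, seed=seed
        )
    )[: c.max_train_windows]
    # a 2k-window validation subset is ample for checkpoint selection
    val_wins = [w for w in windows if w.read_id in val_ids][:2000]
    cfg = VaeConfig(L=c.L, seed=seed, **conditions.vae)
    state = train(train_wins, val_wins, cfg)
    return state


def score_motif_sites(model, reference, mod_ds, ctrl_ds, conditions: StudyConditions):
    """Score CpG-site instances of the modified and control sets.

    Mirrors the controlled-oligo evaluation: positives are motif-site
    instances from the modified sample, negatives the same sites in the
    unmodified sample (within-molecule negatives are avoided because the
    level shift bleeds into neighbouring windows).
    """
    c = conditions
    sites = set(mod_ds.truth_site)
    rows = []
    for ds, label in ((mod_ds, 1), (ctrl_ds, 0)):
        wins = [
            w
            for w in iter_instances_from_reads(ds.reads, reference, L=c.L, k=c.k)
            if (w.contig, w.site_j, w.strand) in sites
        ]
        x, mask = windows_to_arrays(wins)
        scores = score_windows(model, x, mask)
        for w, s in zip(wins, scores):
            rows.append((w.contig, w.site_j, w.strand, label, float(s)))
    return pd.DataFrame(rows, columns=["contig", "pos", "strand", "label", "score"])


def evaluate_benchmark(inst: pd.DataFrame, min_site_coverage: int = 4):
    """Instance- and site-level AUROC/AUPRC from the scored instances."""
    inst_res = auroc_auprc(inst["score"], inst["label"], level="instance")
    grouped = (
        inst.groupby(["contig", "pos", "strand", "label"])["score"]
        .agg(["mean", "count"])
        .reset_index()
    )
    grouped = grouped[grouped["count"] >= min_site_coverage]
    site_res = auroc_auprc(grouped["mean"], grouped["label"], level="site")
    return inst_res, site_res, grouped


def run_benchmark(conditions: StudyConditions, seed: int) -> BenchmarkResult:
    """Simulate, train, score, evaluate: one full pipeline run."""
    reference, pore, train_ds, mod_ds, ctrl_ds = simulate_study(conditions, seed)
    state = train_reference_model(conditions, reference, train_ds, seed)
    inst = score_motif_sites(state.model, reference, mod_ds, ctrl_ds, conditions)
    inst_res, site_res, site_frame = evaluate_benchmark(
        inst, conditions.min_site_coverage
    )
    return BenchmarkResult(
        instance_auroc=inst_res.auroc,
        instance_auprc=inst_res.auprc,
        site_auroc=site_res.auroc,
        site_auprc=site_res.auprc,
        n_instances=(inst_res.n_pos, inst_res.n_neg),
        n_sites=(
            int((site_frame["label"] == 1).sum()),
            int((site_frame["label"] == 0).sum()),
        ),
        model=state.model,
        history=state.history,
        instance_frame=inst,
        site_frame=site_frame,
    )
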