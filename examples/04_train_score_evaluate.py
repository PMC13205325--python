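"""Full pipeline: train a reference VAE on unmodified reads, score a
modified and an unmodified test set, aggregate to sites, and evaluate.

Uses a deliberately small problem (150 bp reference, ~9k training windows,
50 epochs, two to three minutes on one CPU).  Discrimination emerges only
once the model converges — see docs/methods.md — so the benchmark sizes in
anomod.benchmark train longer on a larger reference.
"""

import numpy as np

import anomod as am
from anomod.vae import VaeConfig

pore = am.make_pore_model(k=7, seed=1)
reference = am.make_reference(length=150, seed=2)
spec = am.ModificationSpec(motif="CG", offset=0, level_shift=2.0,
                           per_site_occupancy=1.0, site_selection_rate=1.0)

train_ds = am.simulate_reads(reference, pore, None, n_reads=60, read_length=150, seed=3)
mod_ds = am.simulate_reads(reference, pore, spec, n_reads=20, read_length=150, seed=4)
ctrl_ds = am.simulate_reads(reference, pore, None, n_reads=20, read_length=150, seed=5)

windows = list(am.iter_instances_from_reads(train_ds.reads, reference))
train_ids, val_ids = am.split_train_validation(
    [r.read_id for r in train_ds.reads], 0.15, seed=6
)
cfg = VaeConfig(max_epochs=50, patience=50, seed=7)
state = am.train(
    [w for w in windows if w.read_id in train_ids],
    [w for w in windows if w.read_id in val_ids],
    cfg,
)
last = state.history[-1]
print(f"trained {len(state.history)} epochs; validation reconstruction MSE "
      f"{last['val_recon']:.4f}, KL {last['val_kl']:.1f} nats")

# score CpG instances of both test sets; truth sites from the modified set
sites = set(mod_ds.truth_site)
scores, labels = [], []
for ds, label in ((mod_ds, 1), (ctrl_ds, 0)):
    wins = [w for w in am.iter_instances_from_reads(ds.reads, reference)
            if (w.contig, w.site_j, w.strand) in sites]
    for s in am.score_instances(state.model, wins):
        scores.append(s)
        labels.append(label)

inst = am.auroc_auprc([s.score for s in scores], labels, level="instance")
print(f"instance AUROC {inst.auroc:.3f}, AUPRC {inst.auprc:.3f} "
      f"({inst.n_pos} modified vs {inst.n_neg} unmodified CpG instances)")

# site-level: aggregate each sample separately, compare across samples
df = am.scores_to_frame(scores).assign(label=labels)
site_scores, site_labels = [], []
for label in (1, 0):
    part = df[df["label"] == label]
    for s in am.aggregate_sites(part, "mean", min_coverage=4):
        site_scores.append(s.S)
        site_labels.append(label)
site = am.auroc_auprc(site_scores, site_labels, level="site")
print(f"site AUROC {site.auroc:.3f}, AUPRC {site.auprc:.3f} "
      f"({site.n_pos}+{site.n_neg} sites at coverage >= 4)")
print("site-level aggregation averages per-read noise, so site AUROC "
      "should sit above instance AUROC")
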