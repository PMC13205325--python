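"""Soft k-mer balancing during streaming window extraction.

Genomic k-mer frequencies are skewed; the balancer accepts an instance of
context u with probability min(1, C_max/(N_seen(u)+1)), flattening the
accepted distribution without hard stratification.
"""

import numpy as np

import anomod as am

pore = am.make_pore_model(k=5, seed=1)
reference = am.make_reference(length=500, seed=2)
dataset = am.simulate_reads(reference, pore, None, n_reads=60, read_length=250, seed=3)

state = am.BalancerState(cmax=16)
candidates = list(
    am.iter_instances_from_reads(dataset.reads, reference, L=7, k=5)
)
accepted = list(am.stream_accept(iter(candidates), state, seed=4))

from collections import Counter

cand_counts = np.array(list(Counter(w.kmer_u for w in candidates).values()), float)
acc_counts = np.array(list(state.counts.values()), float)
cv = lambda v: v.std() / v.mean()
print(f"candidates {len(candidates)}, accepted {len(accepted)} "
      f"(rate {len(accepted)/len(candidates):.2f})")
print(f"per-k-mer count CV: candidates {cv(cand_counts):.2f} -> accepted {cv(acc_counts):.2f}")
print("the drop in CV is the balancing effect: frequent contexts are")
print("down-sampled once they exceed the soft cap, rare ones always kept")

# acceptance decays hyperbolically with what was already accepted
for n_seen in (0, 15, 31, 63):
    state_view = am.BalancerState(cmax=16)
    state_view.counts["AAAAA"] = n_seen
    p = am.accept_probability(state_view, "AAAAA")
    print(f"  N_seen={n_seen:3d} -> p_accept={p:.3f}")
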