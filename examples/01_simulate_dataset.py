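"""Simulate a synthetic nanopore dataset with CpG modifications.

Builds a k-mer pore model, draws a short oligo-like reference, simulates
aligned reads with embedded raw signal, and writes the standard outputs
(FASTA, signal BAM, truth TSVs) to ./example_output/.
"""

from pathlib import Path

import anomod as am

out = Path("example_output/simulated")
out.mkdir(parents=True, exist_ok=True)

pore = am.make_pore_model(k=7, seed=1)
reference = am.make_reference(length=400, seed=2, n_contigs=4)
spec = am.ModificationSpec(
    motif="CG", offset=0, level_shift=2.0,
    per_site_occupancy=0.8, site_selection_rate=1.0,
)
dataset = am.simulate_reads(
    reference, pore, spec, n_reads=60, read_length=100, seed=3
)

am.write_reference_fasta(reference, out / "reference.fasta")
am.write_signal_bam(dataset.reads, reference, out / "reads.bam")
inst_path, site_path = am.write_truth(dataset, out)

n_sites = len(dataset.truth_site)
n_mod = sum(dataset.truth_instance.values())
print(f"reference: {len(reference)} contigs x {len(next(iter(reference.values())))} bp")
print(f"reads: {len(dataset.reads)}, raw samples per read ~"
      f"{int(sum(r.raw_samples.size for r in dataset.reads) / len(dataset.reads))}")
print(f"CG sites (both strands): {n_sites}; modified read-instances: {n_mod}")
print(f"wrote {out}/reference.fasta, reads.bam, {inst_path.name}, {site_path.name}")
# Each read instance over a CG cytosine on the read's strand carries a
# level shift of 2 x the local k-mer spread with probability 0.8 (the
# per-site occupancy); the truth TSVs record exactly which ones.
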