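"""Synthetic nanopore squiggle simulator.

Generates references, aligned reads with raw-signal samples and per-base
dwell (move) counts, and modification ground truth with the statistical
structure the anomaly-scoring pipeline assumes:

* a k-mer pore model: each sequence context has its own expected current
  level and spread, i.i.d. across contexts;
* per-read amplitude offset and scale jitter (what per-read z-normalization
  removes);
* integer per-base dwell counts with overdispersion;
* Gaussian per-sample noise;
* modification-induced level shifts at motif-targeted sites, bleeding into
  every k-mer window that contains the modified base, plus an optional dwell
  change.

Training of the reference model is fully label-free; the truth maps produced
here exist only so that evaluation has ground-truth labels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_io import SignalRead
from .util import all_kmers, kmer_index, random_sequence, revcomp, scan_motif

# Loose picoampere-like scales for the synthetic pore response.
LEVEL_CENTER = 90.0
LEVEL_SPREAD = 12.0  # sd of level means across k-mers
LEVEL_SD_RANGE = (1.5, 3.0)  # within-k-mer level spread
DWELL_RANGE = (6.0, 12.0)  # expected samples per base


class SimulationParameterError(ValueError):
    pass


class PoreModel:
    """Per-k-mer expected current level/spread and dwell parameters.

    Backed by dense arrays indexed by the base-4 code of the k-mer; the
    mapping-style accessors take k-mer strings.
    """

    def __init__(self, k, level_mean, level_sd, dwell_mean, dwell_dispersion):
        self.k = int(k)
        n = 4**self.k
        self._level_mean = np.asarray(level_mean, dtype=np.float64)
        self._level_sd = np.asarray(level_sd, dtype=np.float64)
        self._dwell_mean = np.asarray(dwell_mean, dtype=np.float64)
        self.dwell_dispersion = float(dwell_dispersion)
        if not (
            self._level_mean.shape
            == self._level_sd.shape
            == self._dwell_mean.shape
            == (n,)
        ):
            raise SimulationParameterError("pore model tables must have 4^k entries")
        if np.any(self._level_sd <= 0) or np.any(self._dwell_mean < 1):
            raise SimulationParameterError("level_sd must be > 0, dwell_mean >= 1")
        if self.dwell_dispersion <= 0:
            raise SimulationParameterError("dwell_dispersion must be > 0")

    def __len__(self):
        return self._level_mean.size

    @property
    def level_mean(self) -> dict[str, float]:
        return {u: self._level_mean[i] for i, u in enumerate(all_kmers(self.k))}

    @property
    def level_sd(self) -> dict[str, float]:
        return {u: self._level_sd[i] for i, u in enumerate(all_kmers(self.k))}

    @property
    def dwell_mean(self) -> dict[str, float]:
        return {u: self._dwell_mean[i] for i, u in enumerate(all_kmers(self.k))}

    def level_for(self, kmer: str) -> tuple[float, float]:
        i = kmer_index(kmer)
        return float(self._level_mean[i]), float(self._level_sd[i])

    def dwell_for(self, kmer: str) -> float:
        return float(self._dwell_mean[kmer_index(kmer)])

    @property
    def level_scale(self) -> float:
        """Cross-k-mer sd of level means; the natural amplitude unit."""
        return float(self._level_mean.std())


def make_pore_model(k: int, seed: int) -> PoreModel:
    """Draw a complete synthetic 4^k pore table from a fixed seed.

    Levels are i.i.d. across k-mers (nearby k-mers uncorrelated), so the
    table carries no exploitable sequence-similarity structure.
    """
    if k % 2 == 0 or not (3 <= k <= 9):
        raise SimulationParameterError(f"k must be odd and in [3, 9], got {k}")
    rng = np.random.default_rng(seed)
    n = 4**k
    level_mean = rng.normal(LEVEL_CENTER, LEVEL_SPREAD, size=n)
    level_sd = rng.uniform(*LEVEL_SD_RANGE, size=n)
    dwell_mean = rng.uniform(*DWELL_RANGE, size=n)
    return PoreModel(k, level_mean, level_sd, dwell_mean, dwell_dispersion=1.0)


@dataclass
class ModificationSpec:
    """Where and how strongly a base modification perturbs the signal.

    ``motif`` is an IUPAC string with ``offset`` marking the modified base
    (e.g. motif="CG", offset=0 for CpG cytosines).  ``level_shift`` is in
    units of the local k-mer's level_sd; ``dwell_factor`` multiplies the
    expected dwell of the modified base.  ``site_selection_rate`` picks which
    motif sites are modifiable at all; ``per_site_occupancy`` is the fraction
    of molecules modified at a selected site.  ``region`` (contig, start,
    end), when given, confines site selection to that interval — emulating
    the clustered, island-like layout of real modification domains; motif
    sites outside it stay unmodified but are still tracked in the truth.
    """

    motif: str = "CG"
    offset: int = 0
    level_shift: float = 2.0
    dwell_factor: float = 1.0
    per_site_occupancy: float = 1.0
    site_selection_rate: float = 1.0
    region: tuple | None = None

    def __post_init__(self):
        if not (0 <= self.offset < len(self.motif)):
            raise SimulationParameterError("marked offset must lie inside the motif")
        for name in ("per_site_occupancy", "site_selection_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationParameterError(f"{name} must be in [0, 1]")
        if self.dwell_factor <= 0:
            raise SimulationParameterError("dwell_factor must be > 0")


@dataclass
class SimulatedDataset:
    """Reads plus evaluation-only ground truth.

    ``truth_instance`` maps (read_id, contig, pos, strand) -> {0,1} for every
    aligned (read, motif-site) pair on the site's strand; pairs not listed
    are unmodified by construction.  ``truth_site`` maps (contig, pos,
    strand) -> dict(selected, occupancy, coverage) with occupancy equal to
    the mean of that site's instance labels.
    """

    reference: dict[str, str]
    reads: list[SignalRead]
    truth_instance: dict[tuple, int] = field(default_factory=dict)
    truth_site: dict[tuple, dict] = field(default_factory=dict)
    pore_model: PoreModel | None = None

    def instance_label(self, read_id, contig, pos, strand) -> int:
        return self.truth_instance.get((read_id, contig, pos, strand), 0)

    def site_label(self, contig, pos, strand) -> int:
        rec = self.truth_site.get((contig, pos, strand))
        return int(bool(rec and rec["occupancy"] > 0))


def _motif_sites(reference: dict[str, str], spec: ModificationSpec):
    """All (contig, pos, strand) of the marked motif base, both strands."""
    sites = []
    for contig, seq in reference.items():
        for pos in scan_motif(seq, spec.motif, spec.offset):
            sites.append((contig, pos, "+"))
        rc = revcomp(seq)
        n = len(seq)
        for pos in scan_motif(rc, spec.motif, spec.offset):
            sites.append((contig, n - 1 - pos, "-"))
    return sorted(sites)


def _read_kmers(reference, contig, ref_start, read_len, strand, k):
    """Read-oriented k-mer context for every base of a read cut from the
    reference, extended with flanking reference context (N off-contig)."""
    seq = reference[contig]
    half = k // 2
    lo, hi = ref_start - half, ref_start + read_len + half
    ext = (
        "N" * max(0, -lo)
        + seq[max(lo, 0) : min(hi, len(seq))]
        + "N" * max(0, hi - len(seq))
    )
    if strand == "-":
        ext = revcomp(ext)
    return [ext[i : i + k] for i in range(read_len)]


def simulate_reads(
    reference,
    pore_model: PoreModel,
    mod_spec: ModificationSpec | None,
    n_reads: int,
    read_length: int,
    noise_sd: float = 2.0,
    offset_scale_jitter: float = 0.15,
    seed: int = 0,
    q_mean: float = 20.0,
    q_sd: float = 5.0,
) -> SimulatedDataset:
    """Simulate aligned reads with embedded signal from a reference.

    ``reference`` is a dict name->sequence or a single sequence string.
    Per read: offset ~ N(0, jitter * level_scale), scale ~ LogNormal(0,
    jitter); base i emits ``dwell_i`` samples of ``offset + scale * (level +
    N(0, noise_sd))``.  A modified molecule position shifts the level of
    every base whose k-mer window contains it by ``level_shift * level_sd``
    of that base's k-mer, and multiplies the modified base's expected dwell
    by ``dwell_factor``.  Deterministic given the seed.
    """
    if isinstance(reference, str):
        reference = {"ref": reference}
    if not reference or any(len(s) == 0 for s in reference.values()):
        raise SimulationParameterError("empty reference")
    if n_reads < 1:
        raise SimulationParameterError("n_reads must be >= 1")
    k = pore_model.k
    if read_length < k or any(len(s) < read_length for s in reference.values()):
        raise SimulationParameterError("need reference length >= read_length >= k")

    rng = np.random.default_rng(seed)
    half = k // 2
    contigs = sorted(reference)
    lengths = np.array([len(reference[c]) for c in contigs], dtype=float)

    # Site selection on the reference (fixed for the whole dataset).
    selected_sites: list[tuple] = []
    all_sites: list[tuple] = []
    if mod_spec is not None:
        all_sites = _motif_sites(reference, mod_spec)
        keep = rng.random(len(all_sites)) < mod_spec.site_selection_rate
        if mod_spec.region is not None:
            rc, rs, re_ = mod_spec.region
            keep &= np.array(
                [c == rc and rs <= p < re_ for c, p, _ in all_sites]
            )
        selected_sites = [s for s, kp in zip(all_sites, keep) if kp]
    selected_set = set(selected_sites)

    reads: list[SignalRead] = []
    truth_instance: dict[tuple, int] = {}
    site_counts = {s: [0, 0] for s in all_sites}  # site -> [n_modified, n_covered]

    for ridx in range(n_reads):
        ci = rng.choice(len(contigs), p=lengths / lengths.sum())
        contig = contigs[ci]
        seq = reference[contig]
        start = int(rng.integers(0, len(seq) - read_length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = seq[start : start + read_length]
        read_seq = frag if strand == "+" else revcomp(frag)
        read_id = f"read_{ridx:06d}"

        kmers = _read_kmers(reference, contig, start, read_length, strand, k)
        levels = np.empty(read_length)
        sds = np.empty(read_length)
        dwell_mu = np.empty(read_length)
        for i, u in enumerate(kmers):
            if "N" in u:
                levels[i], sds[i] = LEVEL_CENTER, float(np.mean(LEVEL_SD_RANGE))
                dwell_mu[i] = float(np.mean(DWELL_RANGE))
            else:
                levels[i], sds[i] = pore_model.level_for(u)
                dwell_mu[i] = pore_model.dwell_for(u)

        # Which selected sites does this molecule carry as modified?
        if mod_spec is not None:
            for contig_s, pos, strand_s in sorted(
                s for s in selected_set
                if s[0] == contig and s[2] == strand and start <= s[1] < start + read_length
            ):
                modified = int(rng.random() < mod_spec.per_site_occupancy)
                truth_instance[(read_id, contig, pos, strand)] = modified
                site_counts[(contig, pos, strand)][0] += modified
                site_counts[(contig, pos, strand)][1] += 1
                if modified:
                    b = pos - start if strand == "+" else (read_length - 1 - (pos - start))
                    lo, hi = max(0, b - half), min(read_length, b + half + 1)
                    levels[lo:hi] += mod_spec.level_shift * sds[lo:hi]
                    dwell_mu[b] = 1.0 + (dwell_mu[b] - 1.0) * mod_spec.dwell_factor
            # Unselected motif sites covered by this read count toward
            # coverage with label 0 (occupancy stays 0 exactly).
            for contig_s, pos, strand_s in (
                s for s in all_sites
                if s not in selected_set
                and s[0] == contig and s[2] == strand and start <= s[1] < start + read_length
            ):
                truth_instance[(read_id, contig_s, pos, strand_s)] = 0
                site_counts[(contig_s, pos, strand_s)][1] += 1

        # Dwells: 1 + NegBinomial with mean dwell_mu - 1; dispersion 1 makes
        # the excess geometric.
        r = 1.0 / pore_model.dwell_dispersion
        excess = np.maximum(dwell_mu - 1.0, 1e-9)
        dwells = 1 + rng.negative_binomial(r, r / (r + excess))

        offset = rng.normal(0.0, offset_scale_jitter * pore_model.level_scale)
        scale = float(np.exp(rng.normal(0.0, offset_scale_jitter)))
        per_base = [
            offset + scale * (levels[i] + rng.normal(0.0, noise_sd, size=dwells[i]))
            for i in range(read_length)
        ]
        raw = np.concatenate(per_base).astype(np.float32)
        quals = np.clip(np.rint(rng.normal(q_mean, q_sd, size=read_length)), 2, 40)

        reads.append(
            SignalRead(
                read_id=read_id,
                contig=contig,
                ref_start=start,
                strand=strand,
                sequence=read_seq,
                raw_samples=raw,
                dwells=dwells,
                base_qualities=quals.astype(np.int64),
            )
        )

    truth_site = {
        s: {
            "selected": s in selected_set,
            "occupancy": (cnt[0] / cnt[1]) if cnt[1] else 0.0,
            "coverage": cnt[1],
        }
        for s, cnt in site_counts.items()
    }
    return SimulatedDataset(
        reference=dict(reference),
        reads=reads,
        truth_instance=truth_instance,
        truth_site=truth_site,
        pore_model=pore_model,
    )


# -- truth serialization ----------------------------------------------------

INSTANCE_TRUTH_COLUMNS = ["read_id", "contig", "pos", "strand", "label"]
SITE_TRUTH_COLUMNS = ["contig", "pos", "strand", "occupancy_percent", "coverage"]


def write_truth(dataset: SimulatedDataset, out_dir) -> tuple[Path, Path]:
    """Write instance truth and bedMethyl-like site truth TSVs; returns the
    two paths.  Positions are 0-based, matching BED convention."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inst_path = out_dir / "truth_instances.tsv"
    site_path = out_dir / "truth_sites.tsv"
    with open(inst_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(INSTANCE_TRUTH_COLUMNS)
        for (read_id, contig, pos, strand), label in sorted(
            dataset.truth_instance.items()
        ):
            w.writerow([read_id, contig, pos, strand, label])
    with open(site_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(SITE_TRUTH_COLUMNS)
        for (contig, pos, strand), rec in sorted(dataset.truth_site.items()):
            w.writerow(
                [contig, pos, strand, f"{100.0 * rec['occupancy']:.4f}", rec["coverage"]]
            )
    return inst_path, site_path


def read_instance_truth(path) -> dict[tuple, int]:
    out = {}
    with open(path) as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            out[(row["read_id"], row["contig"], int(row["pos"]), row["strand"])] = int(
                row["label"]
            )
    return out


def read_site_truth(path) -> dict[tuple, dict]:
    out = {}
    with open(path) as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            out[(row["contig"], int(row["pos"]), row["strand"])] = {
                "occupancy": float(row["occupancy_percent"]) / 100.0,
                "coverage": int(row["coverage"]),
            }
    return out


def make_reference(length: int, seed: int, n_contigs: int = 1) -> dict[str, str]:
    """Random ACGT reference split over ``n_contigs`` equal contigs."""
    rng = np.random.default_rng(seed)
    per = length // n_contigs
    return {f"contig{i:02d}": random_sequence(rng, per) for i in range(n_contigs)}
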