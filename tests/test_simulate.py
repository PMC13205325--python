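"""Simulator contracts: pore-model shape/determinism, signal moments,
dwell accounting, truth-label coherence."""

import numpy as np
import pytest
from scipy import stats

import anomod as am
from anomod.simulate import SimulationParameterError
from anomod.util import revcomp, scan_motif


class TestPoreModel:
    @pytest.mark.parametrize("k,expected", [(3, 64), (7, 16384)])
    def test_table_is_complete(self, k, expected):
        pm = am.make_pore_model(k, seed=1)
        assert len(pm) == expected
        assert all(sd > 0 for sd in pm.level_sd.values())
        assert all(d >= 1 for d in pm.dwell_mean.values())

    def test_deterministic_given_seed(self):
        a = am.make_pore_model(3, seed=1)
        b = am.make_pore_model(3, seed=1)
        assert a.level_mean == b.level_mean
        assert a.dwell_mean == b.dwell_mean
        c = am.make_pore_model(3, seed=2)
        assert a.level_mean != c.level_mean

    @pytest.mark.parametrize("k", [2, 1, 11])
    def test_bad_k_rejected(self, k):
        with pytest.raises(SimulationParameterError):
            am.make_pore_model(k, seed=1)


class TestSimulateReads:
    def test_no_modification_means_all_labels_zero(self, unmod_dataset):
        assert all(v == 0 for v in unmod_dataset.truth_instance.values())
        assert all(
            rec["occupancy"] == 0 for rec in unmod_dataset.truth_site.values()
        )

    def test_dwell_conservation(self, unmod_dataset):
        for read in unmod_dataset.reads:
            assert read.raw_samples.size == int(read.dwells.sum())

    def test_seed_determinism(self, reference, pore3):
        a = am.simulate_reads(reference, pore3, None, 5, 80, seed=9)
        b = am.simulate_reads(reference, pore3, None, 5, 80, seed=9)
        for ra, rb in zip(a.reads, b.reads):
            assert ra.sequence == rb.sequence
            np.testing.assert_array_equal(ra.raw_samples, rb.raw_samples)
            np.testing.assert_array_equal(ra.dwells, rb.dwells)

    def test_read_geometry_matches_reference(self, unmod_dataset):
        ref = unmod_dataset.reference
        for read in unmod_dataset.reads:
            frag = ref[read.contig][read.ref_start : read.ref_start + read.n_bases]
            expected = frag if read.strand == "+" else revcomp(frag)
            assert read.sequence == expected

    def test_moment_recovery(self, pore3):
        """Per-base sample mean over many draws approaches
        offset + scale * level_mean(u) within 3 standard errors."""
        ref = {"r": "ACGTA" * 40}
        ds = am.simulate_reads(
            ref, pore3, None, n_reads=6, read_length=190,
            noise_sd=2.0, offset_scale_jitter=0.15, seed=4,
        )
        # pool samples per read per k-mer; check against the per-read affine
        # transform recovered from >= 1e4 draws of one recurring k-mer
        for read in ds.reads[:3]:
            kmers = am.simulate._read_kmers(
                ds.reference, read.contig, read.ref_start, read.n_bases,
                read.strand, pore3.k,
            )
            starts = read.sample_starts()
            by_kmer = {}
            for i, u in enumerate(kmers):
                if "N" in u:
                    continue
                seg = read.raw_samples[starts[i] : starts[i] + read.dwells[i]]
                by_kmer.setdefault(u, []).append(seg)
            # solve offset/scale by least squares over k-mer means
            us = [u for u, segs in by_kmer.items() if sum(len(s) for s in segs) > 30]
            obs = np.array([np.concatenate(by_kmer[u]).mean() for u in us])
            lv = np.array([pore3.level_for(u)[0] for u in us])
            A = np.vstack([np.ones_like(lv), lv]).T
            (off, sc), *_ = np.linalg.lstsq(A, obs, rcond=None)
            for u in us:
                samples = np.concatenate(by_kmer[u])
                se = samples.std(ddof=1) / np.sqrt(len(samples)) + 1e-9
                pred = off + sc * pore3.level_for(u)[0]
                assert abs(samples.mean() - pred) < 5 * se + 0.5

    def test_full_occupancy_labels_every_cg_instance(self, mod_dataset, reference):
        """With occupancy and selection 1.0 every same-strand read instance
        over a reference CG cytosine is labeled 1 (checked against a direct
        scan of the reference)."""
        cg_plus = {
            (c, p) for c, seq in reference.items()
            for p in scan_motif(seq, "CG", 0)
        }
        assert cg_plus, "fixture reference must contain CG sites"
        seen_positive = 0
        for read in mod_dataset.reads:
            for qi, rp in read.aligned_pairs().items():
                key = (read.read_id, read.contig, rp, read.strand)
                if read.strand == "+" and (read.contig, rp) in cg_plus:
                    assert mod_dataset.truth_instance[key] == 1
                    seen_positive += 1
        assert seen_positive > 0

    def test_label_coherence(self, reference, pore3):
        """Site occupancy equals the mean of its instance labels exactly."""
        spec = am.ModificationSpec(
            motif="CG", offset=0, level_shift=1.0,
            per_site_occupancy=0.6, site_selection_rate=0.8,
        )
        ds = am.simulate_reads(reference, pore3, spec, 40, 100, seed=13)
        for (contig, pos, strand), rec in ds.truth_site.items():
            labels = [
                lab for (rid, c, p, s), lab in ds.truth_instance.items()
                if (c, p, s) == (contig, pos, strand)
            ]
            if labels:
                assert rec["occupancy"] == pytest.approx(np.mean(labels))
                assert rec["coverage"] == len(labels)

    def test_null_perturbation_indistinguishable(self, reference, pore3):
        """level_shift=0 and dwell_factor=1 leave modified instances drawn
        from the unmodified distribution (two-sample KS not significant)."""
        spec = am.ModificationSpec(
            motif="CG", offset=0, level_shift=0.0, dwell_factor=1.0,
            per_site_occupancy=1.0, site_selection_rate=1.0,
        )
        ds = am.simulate_reads(reference, pore3, spec, 60, 100, seed=14)
        ds0 = am.simulate_reads(reference, pore3, None, 60, 100, seed=15)

        cg_sites = set(ds.truth_site)

        def center_means(ds):
            out = []
            for read in ds.reads:
                starts = read.sample_starts()
                for qi, rp in read.aligned_pairs().items():
                    if (read.contig, rp, read.strand) not in cg_sites:
                        continue
                    seg = read.raw_samples[starts[qi] : starts[qi] + read.dwells[qi]]
                    out.append(seg.mean() - read.raw_samples.mean())
                if len(out) > 400:
                    break
            return np.array(out)

        a, b = center_means(ds), center_means(ds0)
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_parameter_errors(self, pore3):
        with pytest.raises(SimulationParameterError):
            am.simulate_reads({}, pore3, None, 5, 50, seed=1)
        with pytest.raises(SimulationParameterError):
            am.simulate_reads({"r": "ACGT" * 50}, pore3, None, 0, 50, seed=1)
        with pytest.raises(SimulationParameterError):
            am.ModificationSpec(motif="CG", offset=5)
        with pytest.raises(SimulationParameterError):
            am.ModificationSpec(motif="CG", offset=0, per_site_occupancy=1.5)


class TestTruthIO:
    def test_round_trip(self, mod_dataset, tmp_path):
        inst_path, site_path = am.write_truth(mod_dataset, tmp_path)
        inst = am.read_instance_truth(inst_path)
        assert inst == mod_dataset.truth_instance
        sites = am.read_site_truth(site_path)
        assert set(sites) == set(mod_dataset.truth_site)
        for key, rec in sites.items():
            assert rec["occupancy"] == pytest.approx(
                mod_dataset.truth_site[key]["occupancy"], abs=1e-4
            )
            assert 0.0 <= rec["occupancy"] <= 1.0

    def test_empty_dataset_header_only(self, reference, pore3, tmp_path):
        ds = am.simulate_reads(reference, pore3, None, 2, 60, seed=5)
        inst_path, site_path = am.write_truth(ds, tmp_path)
        assert open(inst_path).read().strip() == "\t".join(
            am.simulate.INSTANCE_TRUTH_COLUMNS
        )
        assert open(site_path).read().strip() == "\t".join(
            am.simulate.SITE_TRUTH_COLUMNS
        )
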