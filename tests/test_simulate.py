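import numpy as np
import pandas as pd
import pytest

from ribostall.simulate import (
    CONDITIONS,
    ConfigurationError,
    SimConfig,
    gen_coverage,
    gen_footprints,
    gen_peaks,
    gen_spectra,
    gen_transcripts,
)


class TestGenTranscripts:
    def test_same_seed_identical(self):
        a_t, a_truth = gen_transcripts(SimConfig(n_genes=5, seed=3))
        b_t, b_truth = gen_transcripts(SimConfig(n_genes=5, seed=3))
        assert {k: v.sequence for k, v in a_t.items()} == {
            k: v.sequence for k, v in b_t.items()}
        pd.testing.assert_frame_equal(a_truth.pauses, b_truth.pauses)
        pd.testing.assert_frame_equal(a_truth.tracts, b_truth.tracts)

    def test_zero_tract_rate_degenerate(self):
        _, truth = gen_transcripts(SimConfig(n_genes=5, tract_rate=0, seed=1))
        assert len(truth.tracts) == 0
        assert len(truth.pauses) == 0

    def test_tract_count_matches_poisson_rate(self):
        cfg = SimConfig(n_genes=50, tract_rate=2.0, seed=11)
        _, truth = gen_transcripts(cfg)
        per_gene = truth.tracts.groupby("transcript_id").size()
        mean = per_gene.reindex(truth.gene_means.transcript_id,
                                fill_value=0).mean()
        se = np.sqrt(2.0 / 50)
        assert abs(mean - 2.0) <= 2 * se

    def test_tracts_encode_configured_residues(self, small_dataset):
        transcripts, truth, _ = small_dataset
        for row in truth.tracts.itertuples(index=False):
            prot = transcripts[row.transcript_id].protein
            tract = prot[row.codon_start : row.codon_end]
            assert set(tract) <= {"E", "K"}

    def test_tracts_do_not_overlap(self, small_dataset):
        _, truth, _ = small_dataset
        for _, sub in truth.tracts.groupby("transcript_id"):
            ivs = sorted(zip(sub.codon_start, sub.codon_end))
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_cds_frame_and_pause_bounds(self, small_dataset):
        transcripts, truth, _ = small_dataset
        for t in transcripts.values():
            assert t.cds_len % 3 == 0
        for row in truth.pauses.itertuples(index=False):
            assert 0 <= row.cds_pos < transcripts[row.transcript_id].cds_len
            assert row.cds_pos == 3 * row.codon

    def test_cds_too_small_for_tracts_raises(self):
        with pytest.raises(ConfigurationError):
            gen_transcripts(SimConfig(n_genes=2, cds_len_range=(12, 15),
                                      tract_len_range=(10, 10), seed=0))


class TestGenCoverage:
    def test_nb_moments(self):
        # one long gene: mean within 1%, variance within 5% of mu + mu^2/k
        cfg = SimConfig(n_genes=1, cds_len_range=(99999, 99999),
                        tract_rate=0, pause_rate=0, expr_log_sd=0.0,
                        nb_size=5.0, n_replicates=1, seed=5)
        tr, truth = gen_transcripts(cfg)
        truth.gene_means.loc[:, "mean_coverage"] = 10.0
        vec = gen_coverage(tr, truth, cfg, "control")[0]
        x = vec.counts
        assert abs(x.mean() - 10.0) / 10.0 < 0.01
        assert abs(x.var(ddof=1) - 30.0) / 30.0 < 0.05

    def test_zero_attenuation_removes_pause_in_knockdown(self):
        cfg = SimConfig(n_genes=5, knockdown_attenuation=0.0, seed=2)
        assert cfg.pause_factor_for("knockdown") == 1.0
        assert cfg.pause_factor_for("control") == cfg.pause_factor

    def test_pause_positions_elevated_in_control(self, small_dataset):
        transcripts, truth, coverages = small_dataset
        ctrl = [v for v in coverages if v.condition == "control"]
        by_gene = {}
        for v in ctrl:
            by_gene.setdefault(v.transcript_id, []).append(v)
        ratios = []
        means = dict(zip(truth.gene_means.transcript_id,
                         truth.gene_means.mean_coverage))
        for row in truth.pauses.itertuples(index=False):
            pooled = np.mean([v.counts[row.cds_pos]
                              for v in by_gene[row.transcript_id]])
            ratios.append(pooled / means[row.transcript_id])
        # pooled pause counts sit near factor x gene mean, far above 1
        assert np.median(ratios) > 5

    def test_unknown_condition_raises(self, small_dataset):
        transcripts, truth, _ = small_dataset
        with pytest.raises(ValueError, match="unknown condition"):
            gen_coverage(transcripts, truth, SimConfig(seed=0), "mock")


class TestGenFootprints:
    def test_fixed_length_reads_sit_at_offset(self):
        cfg = SimConfig(n_genes=3, read_len_range=(30, 30),
                        true_offsets={30: 12}, init_peak_factor=1.0, seed=4)
        tr, truth = gen_transcripts(cfg)
        covs = gen_coverage(tr, truth, cfg, "control")
        reads, stats = gen_footprints(covs, tr, cfg)
        assert stats["n_init"] == 0
        cds_start = reads.chrom.map(lambda t: tr[t].cds_start)
        psites = reads.start + 12 - cds_start
        assert (reads.score == 30).all()
        assert (psites >= 0).all()

    def test_conservation_of_read_counts(self, small_dataset, small_cfg):
        transcripts, _, coverages = small_dataset
        reads, stats = gen_footprints(coverages, transcripts, small_cfg)
        total_cov = sum(int(v.counts.sum()) for v in coverages)
        assert len(reads) + stats["n_clipped"] == total_cov + stats["n_init"]

    def test_coverage_roundtrip_interior(self, small_dataset, small_cfg):
        from ribostall.coverage import OffsetTable, build_coverage

        transcripts, _, coverages = small_dataset
        reads, _ = gen_footprints(coverages, transcripts, small_cfg)
        rebuilt, excl = build_coverage(
            reads, OffsetTable(dict(small_cfg.true_offsets)), transcripts)
        by_key = {(v.transcript_id, v.library): v for v in coverages}
        assert excl["outside_cds"] == 0
        for v in rebuilt:
            orig = by_key[(v.transcript_id, v.library)]
            # position 0 carries the initiation pileup on top of coverage
            np.testing.assert_array_equal(orig.counts[1:], v.counts[1:])


class TestGenPeaks:
    def test_fixed_offset_places_center(self):
        cfg = SimConfig(n_genes=10, pause_offset_range=(2, 2), seed=9)
        tr, truth = gen_transcripts(cfg)
        gen_peaks(tr, truth, cfg)
        tracts = truth.tracts.set_index("transcript_id", drop=False)
        for row in truth.peaks.itertuples(index=False):
            t = tr[row.transcript_id]
            codon = (row.center - t.cds_start) // 3
            ends = truth.tracts[truth.tracts.transcript_id
                                == row.transcript_id].codon_end
            assert any(codon == e + 1 for e in ends)  # 2 codons past last tract codon

    def test_failing_fraction_binomial(self):
        cfg = SimConfig(n_genes=120, tract_rate=2.0,
                        peak_fraction_failing=0.5, seed=17)
        tr, truth = gen_transcripts(cfg)
        peaks = gen_peaks(tr, truth, cfg)
        surviving = ((peaks.fold_enrichment > 8) & (peaks.p_value < 1e-5)).sum()
        n = len(peaks)
        se = np.sqrt(n * 0.25)
        assert abs(surviving - 0.5 * n) <= 2 * se

    def test_no_tracts_no_peaks(self):
        cfg = SimConfig(n_genes=5, tract_rate=0, seed=1)
        tr, truth = gen_transcripts(cfg)
        assert len(gen_peaks(tr, truth, cfg)) == 0


class TestGenSpectra:
    def test_same_seed_identical(self):
        a, at = gen_spectra(10, 0.5, 2.0, seed=3)
        b, bt = gen_spectra(10, 0.5, 2.0, seed=3)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(at, bt)

    def test_zero_bias_means_fifty_percent_er(self):
        _, truth = gen_spectra(50, 0.0, 2.0, seed=3)
        assert (truth.true_percent_er == 50.0).all()

    def test_counts_poisson_about_mean(self):
        table, truth = gen_spectra(300, 0.0, 2.0, seed=8)
        mock = table[table.pool == "mock"]["count"]
        # Poisson(2): mean 2, variance 2
        assert abs(mock.mean() - 2.0) < 3 * np.sqrt(2.0 / len(mock))
        assert abs(mock.var() - 2.0) / 2.0 < 0.15
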