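import numpy as np
import pytest

from ribostall.enrichment import (
    AMINO_ACIDS,
    AnchorSet,
    charge_profile,
    overlap_enrichment,
    peaks_to_anchors,
    positional_enrichment,
    region_distribution,
)
from ribostall.io import PeakRecord, TranscriptModel
from ribostall.simulate import SimConfig, gen_peaks, gen_transcripts


def _transcript(protein_codons, utr5=30, utr3=30, tid="t1"):
    codon = {"K": "AAA", "E": "GAA", "G": "GGT", "A": "GCT", "M": "ATG",
             "R": "CGT"}
    cds = "".join(codon[a] for a in protein_codons) + "TAA"
    seq = "G" * utr5 + cds + "C" * utr3
    return TranscriptModel(id=tid, sequence=seq, cds_start=utr5,
                           cds_end=utr5 + len(cds))


class TestAnchors:
    @pytest.mark.parametrize("delta,codon", [(0, 0), (5, 1), (7, 2)])
    def test_codon_mapping(self, delta, codon):
        t = _transcript("M" + "G" * 30)
        c = t.cds_start + delta
        peak = PeakRecord("t1", c - 2, c + 2, 20.0, 1e-9)
        anchors = peaks_to_anchors([peak], {"t1": t})
        assert anchors.anchors == [("t1", codon)]

    def test_utr_center_excluded_and_tallied(self):
        t = _transcript("M" + "G" * 30)
        peak = PeakRecord("t1", len(t.sequence) - 8, len(t.sequence) - 4,
                          20.0, 1e-9)
        anchors = peaks_to_anchors([peak], {"t1": t})
        assert len(anchors) == 0
        assert anchors.n_excluded == 1


class TestPositionalEnrichment:
    def test_single_anchor_on_lysine(self):
        t = _transcript("MGGKGG" + "A" * 40)
        prof = positional_enrichment(AnchorSet([("t1", 3)], "clip_peak"),
                                     {"t1": t}, window=2, n_perm=0)
        k_idx = AMINO_ACIDS.index("K")
        assert prof.frequencies[2, k_idx] == 1.0  # offset 0 row

    def test_frequencies_sum_to_one(self):
        cfg = SimConfig(n_genes=10, seed=31)
        tr, truth = gen_transcripts(cfg)
        anchors = AnchorSet(
            [(r.transcript_id, r.codon) for r in truth.pauses.itertuples()],
            "pause_site")
        prof = positional_enrichment(anchors, tr, n_perm=0)
        sums = prof.frequencies.sum(axis=1)
        has = prof.counts_per_offset > 0
        np.testing.assert_allclose(sums[has], 1.0)

    def test_planted_tract_signal_upstream(self):
        """Peaks 2 codons past poly-E/K tract ends show charged-residue
        enrichment at upstream offsets and none far downstream."""
        cfg = SimConfig(n_genes=120, tract_len_range=(10, 10),
                        pause_offset_range=(2, 2),
                        peak_fraction_failing=0.0, seed=41)
        tr, truth = gen_transcripts(cfg)
        peaks_df = gen_peaks(tr, truth, cfg)
        peaks = [PeakRecord(r.transcript_id, int(r.start), int(r.end),
                            r.fold_enrichment, r.p_value)
                 for r in peaks_df.itertuples(index=False)]
        anchors = peaks_to_anchors(peaks, tr)
        assert len(anchors) >= 150
        prof = positional_enrichment(anchors, tr, n_perm=200, seed=0)
        ek = [AMINO_ACIDS.index(a) for a in "EK"]
        upstream = (prof.offsets >= -11) & (prof.offsets <= -3)
        downstream = prof.offsets >= 5
        combined_up = prof.log2_enrichment[np.ix_(upstream, ek)].sum(axis=1)
        assert (combined_up > 1.0).all()
        assert np.abs(
            prof.log2_enrichment[np.ix_(downstream, ek)]).mean() < 0.4

    def test_uniform_anchors_within_permutation_envelope(self):
        cfg = SimConfig(n_genes=30, tract_rate=0.0, seed=51)
        tr, _ = gen_transcripts(cfg)
        rng = np.random.default_rng(0)
        tids = sorted(tr)
        anchors = AnchorSet(
            [(tid, int(rng.integers(0, tr[tid].n_codons)))
             for tid in rng.choice(tids, 300)], "clip_peak")
        prof = positional_enrichment(anchors, tr, n_perm=300, seed=1)
        outside = ((prof.log2_enrichment > prof.perm_hi)
                   | (prof.log2_enrichment < prof.perm_lo))
        # 95% envelope: ~5% of cells outside by construction
        assert outside.mean() < 0.10

    def test_empty_anchor_set_raises(self):
        t = _transcript("M" + "G" * 30)
        with pytest.raises(ValueError):
            positional_enrichment(AnchorSet([], "clip_peak"), {"t1": t})

    def test_window_larger_than_proteins_raises(self):
        t = _transcript("MGGK")
        with pytest.raises(ValueError, match="window"):
            positional_enrichment(AnchorSet([("t1", 1)], "clip_peak"),
                                  {"t1": t}, window=30)


class TestChargeProfile:
    def test_class_additivity(self):
        t = _transcript("MKKKKEKRKG" + "G" * 30)
        prof = positional_enrichment(AnchorSet([("t1", 5)], "clip_peak"),
                                     {"t1": t}, window=3, n_perm=0)
        cp = charge_profile(prof)
        f = prof.frequencies
        k, r = AMINO_ACIDS.index("K"), AMINO_ACIDS.index("R")
        np.testing.assert_allclose(cp.positive, f[:, k] + f[:, r])
        np.testing.assert_allclose(
            cp.positive + cp.negative + cp.neutral,
            (prof.counts_per_offset > 0).astype(float))

    def test_all_glycine_is_neutral(self):
        t = _transcript("M" + "G" * 20)
        prof = positional_enrichment(AnchorSet([("t1", 10)], "clip_peak"),
                                     {"t1": t}, window=3, n_perm=0)
        cp = charge_profile(prof)
        assert (cp.positive == 0).all()
        assert (cp.negative == 0).all()
        assert (cp.neutral == 1).all()

    def test_overlapping_classes_raise(self):
        t = _transcript("M" + "G" * 20)
        prof = positional_enrichment(AnchorSet([("t1", 10)], "clip_peak"),
                                     {"t1": t}, window=2, n_perm=0)
        with pytest.raises(ValueError, match="overlap"):
            charge_profile(prof, positive={"K", "R"}, negative={"K", "D"})


class TestRegionDistribution:
    def test_cds_peak_tallied(self):
        t = _transcript("M" + "G" * 30)
        c = t.cds_start + 9
        fr, hist = region_distribution(
            [PeakRecord("t1", c - 2, c + 2, 9.0, 1e-9)], {"t1": t})
        assert fr == {"utr5": 0.0, "cds": 1.0, "utr3": 0.0}

    def test_all_peaks_at_origin(self):
        t = _transcript("M" + "G" * 30)
        peaks = [PeakRecord("t1", 0, 2, 9.0, 1e-9)] * 5
        fr, hist = region_distribution(peaks, {"t1": t})
        assert hist[0] == 5 and hist[1:].sum() == 0
        assert fr["utr5"] == 1.0

    def test_uniform_centers_pass_chi2(self):
        from scipy import stats as sps

        t = _transcript("M" + "G" * 400, utr5=50, utr3=50)
        rng = np.random.default_rng(3)
        centers = rng.integers(2, len(t.sequence) - 2, 3000)
        peaks = [PeakRecord("t1", int(c) - 2, int(c) + 2, 9.0, 1e-9)
                 for c in centers]
        _, hist = region_distribution(peaks, {"t1": t}, n_bins=20)
        p = sps.chisquare(hist).pvalue
        assert p > 0.01


class TestOverlapEnrichment:
    def test_exact_hypergeometric_example(self):
        u = set(range(10))
        a = set(range(5))
        b = {0, 1, 2, 3}
        overlap, fold, p = overlap_enrichment(a, b, u)
        assert overlap == 4
        assert p == pytest.approx(5 / 210, rel=1e-12)

    def test_independent_expectation_fold_one(self):
        u = set(range(100))
        a = set(range(50))
        b = set(range(25, 75))  # overlap 25 = 50*50/100
        overlap, fold, p = overlap_enrichment(a, b, u)
        assert fold == pytest.approx(1.0)

    def test_subset_of_universe_certain(self):
        u = set(range(10))
        _, _, p = overlap_enrichment({1, 2, 3}, u, u)
        assert p == pytest.approx(1.0)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            overlap_enrichment(set(), set(), set())


def test_enrichment_invariant_to_duplicating_transcripts():
    """Frequencies are scale-free: doubling every transcript and anchor
    leaves the profile unchanged."""
    cfg = SimConfig(n_genes=10, seed=61)
    tr, truth = gen_transcripts(cfg)
    anchors = [(r.transcript_id, r.codon) for r in truth.pauses.itertuples()]
    prof1 = positional_enrichment(AnchorSet(anchors, "pause_site"), tr,
                                  n_perm=0)
    dup = dict(tr)
    for tid, t in list(tr.items()):
        t2 = TranscriptModel(id=tid + "_copy", sequence=t.sequence,
                             cds_start=t.cds_start, cds_end=t.cds_end)
        dup[t2.id] = t2
    anchors2 = anchors + [(tid + "_copy", c) for tid, c in anchors]
    prof2 = positional_enrichment(AnchorSet(anchors2, "pause_site"), dup,
                                  n_perm=0)
    np.testing.assert_allclose(prof1.log2_enrichment, prof2.log2_enrichment,
                               atol=1e-12)
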