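"""QC metrics: length histogram, frame usage, metagene, periodicity, offset."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riboprof.annotation_io import AnnotationSet, TranscriptAnnotation
from riboprof.qc_metrics import (
    MetageneProfile,
    QCError,
    estimate_psite_offset,
    frame_usage,
    length_distribution,
    metagene,
    periodicity_score,
)
from riboprof.read_ingest import FootprintSet, read_alignments
from riboprof.synthetic_data import (
    SimulationConfig,
    simulate_footprints,
    simulate_transcriptome,
)


def make_set(fives, lengths=None, tid="tx1", label="footprint"):
    n = len(fives)
    return FootprintSet(
        transcript_ids=np.array([tid] * n, dtype=object),
        five_prime=np.asarray(fives, dtype=np.int64),
        length=np.asarray(lengths if lengths is not None else [29] * n, dtype=np.int64),
        weight=np.ones(n),
        library_label=label,
    )


@pytest.fixture
def one_tx():
    return AnnotationSet({"tx1": TranscriptAnnotation("tx1", "g1", 600, 100, 403)})


class TestLengthDistribution:
    def test_counts_and_mode(self):
        fs = make_set([0] * 10, lengths=[28] * 3 + [29] * 5 + [30] * 2)
        hist = length_distribution(fs)
        assert hist.counts == {28: 3, 29: 5, 30: 2}
        assert hist.total == 10 and hist.mode == 29

    def test_single_read(self):
        hist = length_distribution(make_set([0], lengths=[31]))
        assert hist.counts == {31: 1} and hist.mode == 31

    def test_empty_set_is_error(self):
        with pytest.raises(QCError):
            length_distribution(make_set([]))

    def test_simulated_mode_in_peak_range(self, small_study):
        assert length_distribution(small_study["fp"]).mode in {28, 29, 30}


class TestFrameUsage:
    @pytest.mark.parametrize("five,frame", [(100, 1), (101, 2), (102, 3), (88, 1)])
    def test_frame_labels(self, one_tx, five, frame):
        # 88 = cds_start - 12: an initiating ribosome's 5' end, frame 1
        usage = frame_usage(make_set([five]), one_tx)
        assert usage.counts[frame - 1] == 1

    def test_reads_outside_span_counted_separately(self, one_tx):
        # cds_start-13 and cds_end are outside [cds_start-12, cds_end)
        usage = frame_usage(make_set([87, 403, 100]), one_tx)
        assert usage.n_excluded == 2
        assert sum(usage.counts) == 1

    def test_fractions_sum_to_one(self, one_tx):
        usage = frame_usage(make_set([100, 101, 102, 103]), one_tx)
        assert abs(sum(usage.fractions) - 1.0) < 1e-9

    def test_simulated_frame1_matches_fidelity(self, small_study):
        """Frame-1 fraction tracks the configured periodicity fidelity."""
        usage = frame_usage(small_study["fp"], small_study["ann"])
        fid = small_study["config"].periodicity_fidelity
        # binomial sd at n=8000 is ~0.0034; allow 4 sigma
        assert abs(usage.fractions[0] - fid) < 0.015


class TestMetagene:
    def test_single_read_at_minus_12(self, one_tx):
        prof = metagene(make_set([88]), one_tx, "start_codon", (-20, 10))
        assert prof.count_at(-12) == 1
        assert prof.counts.sum() == 1

    def test_profile_mass_equals_in_window_records(self, small_study):
        """Raw-mode total equals an independent recount of in-window reads."""
        ann, fp = small_study["ann"], small_study["fp"]
        prof = metagene(fp, ann, "start_codon", (-40, 20))
        anchor = np.array([ann[t].cds_start for t in fp.transcript_ids])
        disp = fp.five_prime - anchor
        assert prof.counts.sum() == ((disp >= -40) & (disp < 20)).sum()
        assert prof.counts.sum() <= fp.mapped_total

    def test_stop_anchored_zero_beyond_minus_15_at_full_fidelity(self, tmp_path):
        cfg = SimulationConfig(n_genes=30, n_footprint_reads=10000,
                               periodicity_fidelity=1.0, seed=5)
        ann, seqs, truth = simulate_transcriptome(cfg)
        sam = tmp_path / "fp.sam"
        simulate_footprints(ann, seqs, truth, cfg, sam)
        fp = read_alignments(sam, ann)
        prof = metagene(fp, ann, "stop_codon", (-60, 10))
        after = prof.displacements > -15
        assert prof.counts[after].sum() == 0
        assert prof.count_at(-15) > 0

    def test_window_beyond_transcript_contributes_in_bounds_only(self):
        ann = AnnotationSet({"txS": TranscriptAnnotation("txS", "g1", 40, 5, 35)})
        prof = metagene(make_set([0], tid="txS"), ann, "start_codon", (-20, 10))
        assert prof.counts.sum() == 1  # read at displacement -5; upstream is off-transcript

    def test_per_transcript_mean_normalization_equalizes_libraries(self):
        # two transcripts, 10x abundance difference, same geometry
        ann = AnnotationSet({
            "txA": TranscriptAnnotation("txA", "gA", 600, 100, 403),
            "txB": TranscriptAnnotation("txB", "gB", 600, 100, 403),
        })
        fives = [100] * 100 + [103] * 100
        fs_a = make_set(fives, tid="txA")
        fs_b = make_set([100] * 10 + [103] * 10, tid="txB")
        combined = FootprintSet(
            transcript_ids=np.concatenate([fs_a.transcript_ids, fs_b.transcript_ids]),
            five_prime=np.concatenate([fs_a.five_prime, fs_b.five_prime]),
            length=np.concatenate([fs_a.length, fs_b.length]),
            weight=np.concatenate([fs_a.weight, fs_b.weight]),
        )
        prof = metagene(combined, ann, "start_codon", (-6, 6), normalize="per_transcript_mean")
        # each transcript contributes equally after normalization
        assert prof.count_at(0) == pytest.approx(prof.count_at(3))
        raw = metagene(combined, ann, "start_codon", (-6, 6))
        assert raw.count_at(0) == 110

    def test_empty_window_rejected(self, one_tx):
        with pytest.raises(QCError):
            metagene(make_set([100]), one_tx, "start_codon", (10, 10))


class TestPeriodicityScore:
    def _profile(self, counts, lo=0):
        return MetageneProfile("start_codon",
                               np.arange(lo, lo + len(counts)), np.asarray(counts, float))

    def test_perfect_periodicity(self):
        assert periodicity_score(self._profile([9, 0, 0, 9, 0, 0]), (0, 6)) == 1.0

    def test_uniform_signal(self):
        assert periodicity_score(self._profile([3, 3, 3, 3, 3, 3]), (0, 6)) == pytest.approx(1 / 3)

    def test_hand_computed_mixture(self):
        assert periodicity_score(self._profile([6, 2, 1, 6, 2, 1]), (0, 6)) == pytest.approx(12 / 18)

    def test_zero_counts_is_error(self):
        with pytest.raises(QCError):
            periodicity_score(self._profile([0, 0, 0]), (0, 3))

    @given(scale=st.floats(min_value=0.1, max_value=1e6))
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_scaling_and_cyclic_shift(self, scale):
        counts = [6.0, 2.0, 1.0] * 4
        base = periodicity_score(self._profile(counts), (0, 9))
        scaled = periodicity_score(self._profile([c * scale for c in counts]), (0, 9))
        assert scaled == pytest.approx(base)
        # shifting the span by one codon leaves the score unchanged
        assert periodicity_score(self._profile(counts), (3, 12)) == pytest.approx(base)


class TestEstimatePsiteOffset:
    def _profile(self, counts_by_disp):
        lo, hi = min(counts_by_disp), max(counts_by_disp)
        d = np.arange(lo, hi + 1)
        c = np.array([counts_by_disp.get(x, 0.0) for x in d])
        return MetageneProfile("start_codon", d, c)

    def test_unique_peak_recovered(self):
        prof = self._profile({d: 0.0 for d in range(-30, 10)} | {-12: 50.0})
        assert estimate_psite_offset(prof) == 12

    def test_onset_with_uniform_codon_occupancy(self):
        # equal mass at -12, -9, -6 ... (elongation plateau): onset at -12
        plateau = {d: (150.0 if d >= -12 and d % 3 == 0 else 0.0) for d in range(-30, 10)}
        assert estimate_psite_offset(self._profile(plateau)) == 12

    def test_sub_threshold_jitter_ignored(self):
        prof = self._profile(
            {d: 0.0 for d in range(-30, 10)} | {-13: 10.0, -12: 150.0, -9: 155.0}
        )
        assert estimate_psite_offset(prof) == 12

    def test_all_zero_window_is_error(self):
        with pytest.raises(QCError):
            estimate_psite_offset(self._profile({d: 0.0 for d in range(-30, 10)}))

    def test_requires_start_anchor_and_coverage(self):
        prof = MetageneProfile("stop_codon", np.arange(-20, 5), np.ones(25))
        with pytest.raises(QCError):
            estimate_psite_offset(prof)
        narrow = MetageneProfile("start_codon", np.arange(-10, 5), np.ones(15))
        with pytest.raises(QCError):
            estimate_psite_offset(narrow)

    @pytest.mark.parametrize("k", [9, 12, 15])
    def test_parameter_recovery_sweep(self, tmp_path, k):
        """Configured offset recovered from simulated libraries, fidelity 0.8."""
        cfg = SimulationConfig(n_genes=60, n_footprint_reads=20000,
                               periodicity_fidelity=0.8, psite_offset=k, seed=21)
        ann, seqs, truth = simulate_transcriptome(cfg)
        sam = tmp_path / f"fp{k}.sam"
        simulate_footprints(ann, seqs, truth, cfg, sam)
        fp = read_alignments(sam, ann)
        prof = metagene(fp, ann, "start_codon", (-40, 20))
        assert estimate_psite_offset(prof) == k
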