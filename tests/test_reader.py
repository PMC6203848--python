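"""De novo sequence read-out from simulated MS/MS spectra."""

import numpy as np
import pytest

import oligoscribe as og
from oligoscribe.simulate import random_sequence


def spectrum(seq, alph, model, **sim_kw):
    return og.simulate_spectrum(seq, alph, model, og.SimulationConfig(**sim_kw))


class TestFilterPeaks:
    def test_snr_rule(self, reader_cfg):
        pl = og.PeakList([500.0, 510.0], [600.0, 40.0], noise_level=100.0)
        kept = og.filter_peaks(pl, reader_cfg)
        assert list(kept.mz) == [500.0]

    def test_snr_zero_is_identity(self):
        cfg = og.ReaderConfig(snr_min=0.0)
        pl = og.PeakList([500.0, 510.0], [600.0, 40.0], noise_level=100.0)
        assert len(og.filter_peaks(pl, cfg)) == 2

    def test_idempotent_with_estimated_noise(self, reader_cfg):
        pl = og.PeakList(
            [100.0, 200.0, 300.0, 400.0, 500.0],
            [1.0, 2.0, 3.0, 100.0, 200.0],
        )
        once = og.filter_peaks(pl, reader_cfg)
        twice = og.filter_peaks(once, reader_cfg)
        assert once == twice


class TestAnchorSearch:
    def test_clean_pentamer_has_one_anchor_per_side(
        self, ref_alphabet, ref_model, reader_cfg
    ):
        pl = spectrum("BDFHA", ref_alphabet, ref_model)
        left, right = og.anchor_search(pl, ref_alphabet, ref_model, reader_cfg)
        assert len(left) == len(right) == 1
        assert left[0].labels == ("B",)   # first unit
        assert right[0].labels == ("A",)  # last unit

    def test_deleted_first_prefix_peak_empties_left_side(
        self, ref_alphabet, ref_model
    ):
        cfg = og.ReaderConfig(require_both_anchors=False)
        pl = spectrum("BDFHA", ref_alphabet, ref_model, delete=(("prefix", 1),))
        left, right = og.anchor_search(pl, ref_alphabet, ref_model, cfg)
        assert left == []
        assert len(right) == 1

    def test_required_anchor_missing_raises_with_side(
        self, ref_alphabet, ref_model, reader_cfg
    ):
        pl = spectrum("BDFHA", ref_alphabet, ref_model, delete=(("prefix", 1),))
        with pytest.raises(og.AnchorMissingError, match="left"):
            og.anchor_search(pl, ref_alphabet, ref_model, reader_cfg)

    def test_near_isobaric_blocks_share_an_anchor(self, ref_model):
        # two blocks 0.01 Da apart, below 2x tolerance: ambiguity must propagate
        alph = og.Alphabet(
            [og.BuildingBlock("A", 100.0), og.BuildingBlock("B", 100.01),
             og.BuildingBlock("C", 150.0)]
        )
        cfg = og.ReaderConfig(require_both_anchors=False)
        pl = spectrum("AC", alph, ref_model)
        left, _ = og.anchor_search(pl, alph, ref_model, cfg)
        assert set(left[0].labels) == {"A", "B"}


class TestLadderWalk:
    def test_clean_hexamer_left_walk_assigns_all(self, ref_alphabet, ref_model,
                                                  reader_cfg):
        seq = "ABOCND"
        pl = spectrum(seq, ref_alphabet, ref_model)
        left, _ = og.anchor_search(pl, ref_alphabet, ref_model, reader_cfg)
        walk = og.ladder_walk(pl, left[0].mz, "left", 6, ref_alphabet,
                              ref_model, reader_cfg)
        assert walk.gap_at is None and not walk.ambiguous_at
        for pos in range(2, 7):
            assert walk.candidates[pos] == frozenset(seq[pos - 1])

    def test_interior_gap_is_bridged_and_other_walk_confirms(
        self, ref_alphabet, ref_model, reader_cfg
    ):
        seq = "ABOCND"
        pl = spectrum(seq, ref_alphabet, ref_model, delete=(("prefix", 3),))
        left, right = og.anchor_search(pl, ref_alphabet, ref_model, reader_cfg)
        lw = og.ladder_walk(pl, left[0].mz, "left", 6, ref_alphabet,
                            ref_model, reader_cfg)
        # bridged: position 3 ambiguous in order, but true label is a candidate
        assert "O" in lw.candidates[3]
        rw = og.ladder_walk(pl, right[0].mz, "right", 6, ref_alphabet,
                            ref_model, reader_cfg)
        assert rw.candidates[3] == frozenset("O")

    def test_no_bridging_when_disabled(self, ref_alphabet, ref_model):
        cfg = og.ReaderConfig(max_missing_per_position=0)
        seq = "ABOCND"
        pl = spectrum(seq, ref_alphabet, ref_model, delete=(("prefix", 3),))
        left, _ = og.anchor_search(pl, ref_alphabet, ref_model, cfg)
        walk = og.ladder_walk(pl, left[0].mz, "left", 6, ref_alphabet,
                              ref_model, cfg)
        assert walk.gap_at == 3
        assert 3 not in walk.candidates


class TestReadSequence:
    def test_clean_channel_random_oligomers(self, ref_alphabet, ref_model,
                                            reader_cfg, rng):
        for _ in range(60):
            L = int(rng.integers(3, 9))
            seq = random_sequence(L, ref_alphabet, rng)
            pl = spectrum(seq, ref_alphabet, ref_model,
                          seed=int(rng.integers(2 ** 31)))
            res = og.read_sequence(pl, ref_alphabet, ref_model, L, reader_cfg)
            assert res.status == "unique"
            assert res.sequence == seq
            assert all(res.evidence[p] == "both" for p in range(1, L + 1))

    def test_octamer_survives_any_single_peak_deletion(
        self, ref_alphabet, ref_model, reader_cfg
    ):
        """The recovered-octamer scenario: one absent fragment peak, any
        position, either series, still a unique correct read."""
        seq = "ABOCNDGH"
        for series in ("prefix", "suffix"):
            for rung in range(1, 9):
                pl = spectrum(seq, ref_alphabet, ref_model,
                              delete=((series, rung),))
                res = og.read_sequence(pl, ref_alphabet, ref_model, 8, reader_cfg)
                assert res.status == "unique", (series, rung, res.reason)
                assert res.sequence == seq

    def test_isobaric_hexamers_read_distinctly(self, ref_alphabet, ref_model,
                                               reader_cfg):
        """Same composition, same precursor mass, different order: both read
        uniquely and differently."""
        h2, h5 = "AABBAB", "ABABBA"
        m2 = og.oligomer_mass(h2, ref_model, ref_alphabet)
        m5 = og.oligomer_mass(h5, ref_model, ref_alphabet)
        assert m2 == pytest.approx(m5)
        reads = []
        for s in (h2, h5):
            res = og.read_sequence(
                spectrum(s, ref_alphabet, ref_model),
                ref_alphabet, ref_model, 6, reader_cfg,
            )
            assert res.status == "unique" and res.sequence == s
            reads.append(res.sequence)
        assert reads[0] != reads[1]

    def test_subthreshold_noise_never_changes_the_read(
        self, ref_alphabet, ref_model, reader_cfg, rng
    ):
        for _ in range(15):
            L = int(rng.integers(3, 8))
            seq = random_sequence(L, ref_alphabet, rng)
            seed = int(rng.integers(2 ** 31))
            clean = spectrum(seq, ref_alphabet, ref_model, seed=seed)
            noisy = spectrum(seq, ref_alphabet, ref_model, seed=seed,
                             n_noise_peaks=200)
            a = og.read_sequence(clean, ref_alphabet, ref_model, L, reader_cfg)
            b = og.read_sequence(noisy, ref_alphabet, ref_model, L, reader_cfg)
            assert a.status == b.status == "unique"
            assert a.sequence == b.sequence == seq

    def test_reads_survive_jitter_within_half_tolerance(
        self, ref_alphabet, ref_model, reader_cfg, rng
    ):
        for _ in range(15):
            L = int(rng.integers(3, 9))
            seq = random_sequence(L, ref_alphabet, rng)
            pl = spectrum(seq, ref_alphabet, ref_model, jitter=0.009,
                          seed=int(rng.integers(2 ** 31)))
            res = og.read_sequence(pl, ref_alphabet, ref_model, L, reader_cfg)
            assert res.status == "unique" and res.sequence == seq

    def test_missing_anchor_fails_with_side_named(self, ref_alphabet, ref_model,
                                                  reader_cfg):
        # delete the first two prefix rungs: bridging cannot recover the side
        pl = spectrum("ABOCND", ref_alphabet, ref_model,
                      delete=(("prefix", 1), ("prefix", 2)))
        res = og.read_sequence(pl, ref_alphabet, ref_model, 6, reader_cfg)
        assert res.status == "failed"
        assert "left" in res.reason

    def test_one_sided_read_when_anchors_not_required(self, ref_alphabet,
                                                      ref_model):
        cfg = og.ReaderConfig(require_both_anchors=False)
        pl = spectrum("ABOCND", ref_alphabet, ref_model,
                      delete=(("prefix", 1), ("prefix", 2)))
        res = og.read_sequence(pl, ref_alphabet, ref_model, 6, cfg)
        assert res.status == "unique" and res.sequence == "ABOCND"
        assert set(res.evidence.values()) <= {"right", "both"}

    def test_wrong_precursor_fails(self, ref_alphabet, ref_model, reader_cfg):
        pl = spectrum("ABOCND", ref_alphabet, ref_model)
        shifted = og.PeakList(pl.mz, pl.intensity,
                              precursor_mz=pl.precursor_mz + 5.0,
                              noise_level=pl.noise_level)
        res = og.read_sequence(shifted, ref_alphabet, ref_model, 6, reader_cfg)
        assert res.status == "failed"
        assert "precursor" in res.reason

    def test_too_tight_alphabet_rejected_at_read_time(self, ref_model,
                                                      reader_cfg):
        alph = og.Alphabet(
            [og.BuildingBlock("A", 100.0), og.BuildingBlock("B", 100.03)]
        )
        pl = og.PeakList([200.0], [100.0], precursor_mz=400.0, noise_level=1.0)
        with pytest.raises(og.ConfigError, match="gap"):
            og.read_sequence(pl, alph, ref_model, 2, reader_cfg)

    def test_runtime_scales_linearly_in_length(self, ref_alphabet, ref_model,
                                               reader_cfg, rng):
        """Read time grows roughly linearly with L (ladder walk, not
        exhaustive enumeration): doubling L from 16 to 64 must not blow up
        superlinearly (generous 12x allowance for a 4x length ratio)."""
        import time

        def timed(L):
            seq = random_sequence(L, ref_alphabet, rng)
            pl = spectrum(seq, ref_alphabet, ref_model)
            t0 = time.perf_counter()
            for _ in range(5):
                res = og.read_sequence(pl, ref_alphabet, ref_model, L, reader_cfg)
                assert res.sequence == seq
            return time.perf_counter() - t0

        t16, t64 = timed(16), timed(64)
        assert t64 < 12 * max(t16, 1e-3)


class TestEvidenceBookkeeping:
    def test_matched_peaks_cover_all_positions(self, ref_alphabet, ref_model,
                                               reader_cfg):
        seq = "ABOCN"
        pl = spectrum(seq, ref_alphabet, ref_model)
        res = og.read_sequence(pl, ref_alphabet, ref_model, 5, reader_cfg)
        assert set(res.matched_peaks) == set(range(1, 6))

    def test_clean_spectrum_fully_explained(self, ref_alphabet, ref_model,
                                            reader_cfg):
        pl = spectrum("ABOCN", ref_alphabet, ref_model)
        res = og.read_sequence(pl, ref_alphabet, ref_model, 5, reader_cfg)
        assert res.unexplained_peaks == []

    def test_above_threshold_rogue_peak_is_reported(self, ref_alphabet,
                                                    ref_model, reader_cfg):
        pl = spectrum("ABOCN", ref_alphabet, ref_model)
        rogue = 333.333
        spiked = og.PeakList(
            np.append(pl.mz, rogue), np.append(pl.intensity, 100.0),
            precursor_mz=pl.precursor_mz, noise_level=pl.noise_level,
        )
        res = og.read_sequence(spiked, ref_alphabet, ref_model, 5, reader_cfg)
        assert res.status == "unique"
        assert res.unexplained_peaks == [pytest.approx(rogue)]
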