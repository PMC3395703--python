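"""In-silico digestion, fingerprint prediction, emulation and matching."""

import numpy as np
import pytest

from pyrotagger.contig_assembly import Contig
from pyrotagger.insilico_trflp import (MSPI, TRF, ElectrophoresisParams,
                                       Fingerprint, RestrictionEnzyme, digest,
                                       emulate_electropherogram,
                                       match_fingerprints, predict_fingerprint,
                                       read_fingerprint, write_fingerprint)


def _random_dna(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))


def _seq_with_sites(length, sites, rng):
    """Random sequence with CCGG exactly at the given 0-based positions."""
    while True:
        s = _random_dna(length, rng)
        t = s.replace("CCGG", "ATGG")
        while "CCGG" in t:
            t = t.replace("CCGG", "ATGG")
        for p in sites:
            t = t[:p] + "CCGG" + t[p + 4:]
        if [i for i in range(len(t)) if t.startswith("CCGG", i)] == list(sites):
            return t


class TestDigest:
    def test_primary_and_pseudo_at_208_and_285(self, rng):
        seq = _seq_with_sites(520, [207, 284], rng)
        frags = digest(seq, MSPI)
        assert [(t.length_bp, t.pseudo) for t in frags] == [(208, False), (285, True)]
        assert frags[1].parent_length_bp == 208

    def test_uncut_sequence_gives_full_length_fragment(self):
        frags = digest("A" * 500)
        assert len(frags) == 1
        assert frags[0].length_bp == 500 and not frags[0].pseudo

    def test_pseudo_fragments_can_be_suppressed(self, rng):
        seq = _seq_with_sites(400, [99, 199, 299], rng)
        assert len(digest(seq, include_pseudo=False)) == 1
        assert len(digest(seq, include_pseudo=True)) == 3

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            digest("")

    @pytest.mark.parametrize("seed", range(5))
    def test_against_bruteforce_position_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = _random_dna(2000, rng)
        frags = digest(seq, MSPI)
        positions = [i for i in range(len(seq)) if seq.startswith("CCGG", i)]
        if not positions:
            assert [t.length_bp for t in frags] == [2000]
        else:
            assert [t.length_bp for t in frags] == [p + 1 for p in positions]
            assert [t.pseudo for t in frags] == [False] + [True] * (len(positions) - 1)

    def test_cut_offset_convention(self, rng):
        seq = _seq_with_sites(300, [100], rng)
        enz = RestrictionEnzyme("test", "CCGG", cut_offset=2)
        assert digest(seq, enz)[0].length_bp == 102


def _contig(cid, seq, n_reads):
    return Contig(cid, seq, [f"{cid}_r{i}" for i in range(n_reads)],
                  n_reads - 1, 1)


class TestPredictFingerprint:
    def _primered(self, sites, rng, length=500):
        from pyrotagger.read_qc import BA27F
        body = _seq_with_sites(length, sites, rng)
        return BA27F.sequence.replace("M", "A") + body[20:]

    def test_read_weighted_abundances(self, rng):
        c1 = _contig("c1", self._primered([149], rng), 60)
        c2 = _contig("c2", self._primered([249], rng), 40)
        fp = predict_fingerprint([c1, c2])
        primary = {t.length_bp: t.abundance for t in fp.primary()}
        assert primary == {150: pytest.approx(60.0), 250: pytest.approx(40.0)}

    def test_equal_lengths_merge(self, rng):
        c1 = _contig("c1", self._primered([149], rng), 30)
        c2 = _contig("c2", self._primered([149], rng), 20)
        fp = predict_fingerprint([c1, c2])
        assert len(fp.primary()) == 1
        assert fp.primary()[0].abundance == pytest.approx(100.0)

    def test_abundances_sum_to_hundred(self, rng):
        contigs = [_contig(f"c{i}", self._primered([100 + 37 * i], rng), 10 + i)
                   for i in range(5)]
        fp = predict_fingerprint(contigs)
        assert sum(t.abundance for t in fp.trfs) == pytest.approx(100.0, abs=1e-6)

    def test_unanchored_contig_skipped(self, rng):
        good = _contig("good", self._primered([99], rng), 10)
        bad = _contig("bad", _random_dna(400, rng), 10)
        fp = predict_fingerprint([good, bad])
        assert fp.skipped == 1
        assert len(fp.primary()) == 1


class TestEmulateAndMatch:
    def _truth(self):
        return Fingerprint("s", [
            TRF(129, 40.0), TRF(159, 35.0), TRF(486, 25.0),
        ], rfu_threshold=0.0)

    def test_zero_drift_zero_noise_is_identity(self):
        params = ElectrophoresisParams(drift_bp=0, signal_per_read=1.0,
                                       noise_sd=0.0)
        obs = emulate_electropherogram(self._truth(), params, seed=1,
                                       rfu_threshold=0.0)
        assert [(t.length_bp, t.abundance) for t in obs.trfs] == \
            [(129, 40.0), (159, 35.0), (486, 25.0)]

    def test_sub_threshold_peaks_vanish(self):
        params = ElectrophoresisParams(drift_bp=0, signal_per_read=3.0,
                                       noise_sd=0.0)
        obs = emulate_electropherogram(self._truth(), params, seed=1,
                                       rfu_threshold=100.0)
        # 25% * 3 = 75 RFU < 100 -> the 486 bp peak disappears
        assert obs.lengths() == [129, 159]

    def test_fixed_seed_reproducible(self):
        p = ElectrophoresisParams()
        a = emulate_electropherogram(self._truth(), p, seed=7)
        b = emulate_electropherogram(self._truth(), p, seed=7)
        assert [(t.length_bp, t.abundance) for t in a.trfs] == \
            [(t.length_bp, t.abundance) for t in b.trfs]

    def test_roundtrip_zero_drift_matches_everything(self):
        params = ElectrophoresisParams(drift_bp=0, signal_per_read=10.0,
                                       noise_sd=0.0)
        obs = emulate_electropherogram(self._truth(), params, seed=1,
                                       rfu_threshold=0.0)
        res = match_fingerprints(obs, self._truth(), tolerance_bp=0)
        assert len(res.pairs) == 3
        assert not res.unmatched_observed and not res.unmatched_predicted

    def test_single_pair_delta(self):
        obs = Fingerprint("o", [TRF(129, 500.0, origin="in_vivo")])
        pred = Fingerprint("p", [TRF(127, 50.0)], rfu_threshold=0.0)
        res = match_fingerprints(obs, pred, tolerance_bp=3)
        assert len(res.pairs) == 1
        assert res.pairs[0][2] == 2

    def test_282_bp_flagged_as_pseudo_of_208(self):
        obs = Fingerprint("o", [TRF(282, 900.0, origin="in_vivo")])
        pred = Fingerprint("p", [TRF(208, 100.0),
                                 TRF(285, 0.0, pseudo=True, parent_length_bp=208)],
                          rfu_threshold=0.0)
        res = match_fingerprints(obs, pred, tolerance_bp=3)
        assert not res.pairs
        assert res.pseudo_flags == [(obs.trfs[0], 208)]

    def test_empty_prediction_leaves_all_observed_unmatched(self):
        obs = Fingerprint("o", [TRF(100, 200.0), TRF(200, 300.0)])
        res = match_fingerprints(obs, Fingerprint("p", []), tolerance_bp=3)
        assert len(res.unmatched_observed) == 2 and not res.pairs

    def test_partial_digestion_emits_flaggable_pseudo_fragment(self):
        truth = Fingerprint("s", [
            TRF(208, 60.0), TRF(150, 40.0),
            TRF(285, 0.0, pseudo=True, parent_length_bp=208),
        ], rfu_threshold=0.0)
        params = ElectrophoresisParams(drift_bp=0, signal_per_read=10.0,
                                       noise_sd=0.0, partial_digest_fraction=0.3)
        obs = emulate_electropherogram(truth, params, seed=1, rfu_threshold=100.0)
        assert 285 in obs.lengths()  # 0.3 * 600 = 180 RFU
        res = match_fingerprints(obs, truth, tolerance_bp=3)
        assert res.pseudo_flags == [(next(t for t in obs.trfs if t.length_bp == 285), 208)]

    def test_fingerprint_tsv_roundtrip(self, tmp_path, rng):
        fp = self._truth()
        write_fingerprint(fp, tmp_path / "fp.tsv")
        back = read_fingerprint(tmp_path / "fp.tsv", "s", rfu_threshold=0.0)
        assert back.lengths() == fp.lengths()
        assert [t.abundance for t in back.trfs] == [t.abundance for t in fp.trfs]
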