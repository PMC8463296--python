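"""Synthetic reference/SV/read generators: determinism and self-consistency."""

import numpy as np
import pysam
import pytest
from scipy import stats

from dualmap.alignment_model import parse_cigar, reverse_complement
from dualmap.ed_profile import build_profile
from dualmap.errors import DuplicatePrimary, InconsistentManifest, OutOfBounds, OverlapError
from dualmap.fixtures import (
    FixtureManifest,
    SamSpec,
    SvSpec,
    distinct_e_manifest,
    implant_svs,
    make_reference_sequence,
    make_sam_fixture,
    simulate_reads,
    write_fasta,
)


class TestReference:
    def test_seed_determinism(self):
        a = make_reference_sequence(10_000, 0.5, 42)
        b = make_reference_sequence(10_000, 0.5, 42)
        assert a == b
        assert a != make_reference_sequence(10_000, 0.5, 43)

    def test_degenerate_gc(self):
        seq = make_reference_sequence(10_000, 1.0, 7)
        assert set(seq) <= {"G", "C"}

    def test_gc_within_binomial_bounds(self):
        seq = make_reference_sequence(10_000, 0.4, 7)
        gc = sum(seq.count(b) for b in "GC")
        lo, hi = stats.binom.interval(0.99, 10_000, 0.4)
        assert lo <= gc <= hi

    def test_fasta_wrapping(self, tmp_path):
        path = write_fasta({"c": make_reference_sequence(1000, 0.5, 1)},
                           tmp_path / "r.fasta")
        lines = path.read_text().splitlines()
        assert lines[0] == ">c"
        assert all(len(l) <= 60 for l in lines[1:])


class TestImplantSvs:
    REF = make_reference_sequence(10_000, 0.45, 99)

    def test_del_length_arithmetic(self):
        alt, truth = implant_svs(self.REF, [SvSpec("DEL", 1000, 100)])
        assert len(alt) == 9_900
        assert truth[0]["end"] == 1100

    def test_ins_and_payload(self):
        payload = "A" * 60
        alt, _ = implant_svs(self.REF, [SvSpec("INS", 500, 60, payload=payload)])
        assert len(alt) == 10_060
        assert alt[500:560] == payload

    def test_inv_is_involution(self):
        sv = [SvSpec("INV", 2000, 80)]
        once, _ = implant_svs(self.REF, sv)
        twice, _ = implant_svs(once, sv)
        assert twice == self.REF

    def test_dup_tandem_copy(self):
        alt, _ = implant_svs(self.REF, [SvSpec("DUP", 3000, 60)])
        assert len(alt) == 10_060
        assert alt[3000:3060] == alt[3060:3120] == self.REF[3000:3060]

    def test_tra_swaps_blocks(self):
        alt, _ = implant_svs(
            self.REF, [SvSpec("TRA", 1000, 50, partner_position=5000)]
        )
        assert len(alt) == len(self.REF)
        assert alt[1000:1050] == self.REF[5000:5050]
        assert alt[5000:5050] == self.REF[1000:1050]

    def test_validation_errors(self):
        with pytest.raises(OverlapError):
            implant_svs(self.REF, [SvSpec("DEL", 100, 100), SvSpec("INV", 150, 100)])
        with pytest.raises(OutOfBounds):
            implant_svs(self.REF, [SvSpec("DEL", 9_990, 100)])
        with pytest.raises(ValueError):
            SvSpec("DEL", 0, 49)  # below the 50 bp SV definition
        with pytest.raises(ValueError):
            SvSpec("INS", 0, 60, payload="A" * 10)


class TestSimulateReads:
    REF = make_reference_sequence(20_000, 0.45, 5)

    def test_zero_error_reads_are_substrings(self):
        reads, truths = simulate_reads(self.REF, 20, 400, 0.0, 0.0, seed=1)
        for (name, seq, _), t in zip(reads, truths):
            origin = self.REF[t.start : t.end]
            expected = reverse_complement(origin) if t.strand == "-" else origin
            assert seq == expected
            assert t.nm == 0 and t.cigar == "400M"

    def test_empty_and_determinism(self):
        assert simulate_reads(self.REF, 0, 100, 0.1, 0.1, seed=2) == ([], [])
        a = simulate_reads(self.REF, 10, 300, 0.05, 0.02, seed=3)
        b = simulate_reads(self.REF, 10, 300, 0.05, 0.02, seed=3)
        assert a == b

    def test_truth_cigar_consistent_with_read(self):
        reads, truths = simulate_reads(self.REF, 30, 250, 0.05, 0.05, seed=4)
        for (name, seq, _), t in zip(reads, truths):
            tuples = parse_cigar(t.cigar)
            qlen = sum(n for op, n in tuples if op in (0, 1))
            rlen = sum(n for op, n in tuples if op in (0, 2))
            assert qlen == len(seq) == t.read_length
            assert rlen == t.end - t.start
            # nm equals inserted + deleted bases plus recorded substitutions
            indel_bases = sum(n for op, n in tuples if op in (1, 2))
            assert t.nm >= indel_bases

    def test_mean_edit_count_matches_binomial(self):
        """sub-only errors: mean edits/read within 3 sigma of n*p."""
        n, L, s = 1000, 1000, 0.1
        _, truths = simulate_reads(self.REF, n, L, s, 0.0, seed=6)
        edits = np.array([t.nm for t in truths])
        mean_expected = L * s
        sigma_mean = np.sqrt(L * s * (1 - s) / n)
        assert abs(edits.mean() - mean_expected) <= 3 * sigma_mean


class TestSamFixture:
    def test_prescribed_e_values_roundtrip(self, tmp_path):
        path = make_sam_fixture(distinct_e_manifest(100), tmp_path / "fx.sam")
        with pysam.AlignmentFile(str(path)) as sam:
            prof = build_profile(sam)
        assert sorted(e for _, e in prof.entries) == pytest.approx(
            [i / 100 for i in range(100)]
        )

    def test_secondaries_do_not_enter_profile(self, tmp_path):
        manifest = distinct_e_manifest(100)
        manifest.records += [
            SamSpec(name=r.name, cigar="100M", nm=90, flag=0x100)
            for r in manifest.records[:100]
        ]
        path = make_sam_fixture(manifest, tmp_path / "fx2.sam")
        with pysam.AlignmentFile(str(path)) as sam:
            prof = build_profile(sam)
        assert len(prof) == 100 and prof.n_secondary == 100

    def test_duplicate_primary_detected(self, tmp_path):
        manifest = FixtureManifest(seed=0, records=[
            SamSpec("dup", "100M", nm=0),
            SamSpec("dup", "100M", nm=1),
        ])
        path = make_sam_fixture(manifest, tmp_path / "fx3.sam")
        with pysam.AlignmentFile(str(path)) as sam:
            with pytest.raises(DuplicatePrimary):
                build_profile(sam)

    def test_inconsistent_manifest_rejected(self, tmp_path):
        manifest = FixtureManifest(seed=0, records=[
            SamSpec("bad", "100M", nm=0, sequence="ACGT"),
        ])
        with pytest.raises(InconsistentManifest):
            make_sam_fixture(manifest, tmp_path / "fx4.sam")

    def test_byte_identical_regeneration(self, tmp_path):
        m = distinct_e_manifest(50, seed=9)
        p1 = make_sam_fixture(m, tmp_path / "a.sam")
        p2 = make_sam_fixture(m, tmp_path / "b.sam")
        assert p1.read_bytes() == p2.read_bytes()
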