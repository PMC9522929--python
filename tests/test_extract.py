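"""Read-pair parsing, V assignment, junction delimitation, tabulation."""

import numpy as np
import pytest

from tcrumi.extract import (
    MoleculeRecord,
    ParseStats,
    RawObservation,
    Rejection,
    assign_v,
    delimit_junction,
    parse_read_pair,
    process_fastq,
    tabulate_molecules,
)
from tcrumi.germline import GermlineSegment, GermlineSet
from tcrumi.layout import ReadLayout, revcomp
from tcrumi.simulate import SimConfig, simulate_sample

LAYOUT = ReadLayout()


def build_pair(umi: str, transcript: str, stagger1: str = "ACGT", stagger2: str = "TTAA"):
    """Assemble a read pair exactly as the library layout dictates."""
    block = umi[0:4] + "T" + umi[4:8] + "T" + umi[8:12] + "T"
    r1 = stagger1 + LAYOUT.upm_s + LAYOUT.tso_anchor + block + "CTT" + "GGGGG" + transcript
    full = transcript + LAYOUT.constant_stub_by_locus["TRB"] + revcomp(LAYOUT.gsp_by_locus["TRB"])
    r2 = stagger2 + revcomp(full)
    return r1, r2


def make_transcript(gset, v_id="TBV2", j_id="TBJ1", insert="GGG", v_trim=0, j_trim=0):
    v, j = gset.v(v_id), gset.j(j_id)
    return v.seq_nt[: len(v.seq_nt) - v_trim] + insert + j.seq_nt[j_trim:]


class TestParseReadPair:
    def test_umi_slots(self, trb):
        r1, r2 = build_pair("ACGGTTACGGCA", make_transcript(trb))
        obs = parse_read_pair(r1, r2, LAYOUT, "TRB")
        assert isinstance(obs, RawObservation)
        assert obs.umi == "ACGGTTACGGCA"

    def test_separator_mismatch_rejected(self, trb):
        r1, r2 = build_pair("ACGGTTACGGCA", make_transcript(trb))
        i = r1.find("ACGGT") + 4  # first separator T
        bad = r1[:i] + "A" + r1[i + 1 :]
        assert parse_read_pair(bad, r2, LAYOUT, "TRB") == Rejection("umi_pattern_mismatch")

    def test_anchor_absent_rejected(self, trb):
        _r1, r2 = build_pair("ACGGTTACGGCA", make_transcript(trb))
        junk = "A" * 150
        assert parse_read_pair(junk, r2, LAYOUT, "TRB") == Rejection("tso_anchor_not_found")

    def test_anchor_single_mismatch_tolerated(self, trb):
        r1, r2 = build_pair("ACGGTTACGGCA", make_transcript(trb))
        i = r1.find(LAYOUT.tso_anchor) + 5
        r1 = r1[:i] + ("A" if r1[i] != "A" else "C") + r1[i + 1 :]
        obs = parse_read_pair(r1, r2, LAYOUT, "TRB")
        assert isinstance(obs, RawObservation)

    def test_gsp_absent_rejected(self, trb):
        r1, _r2 = build_pair("ACGGTTACGGCA", make_transcript(trb))
        assert parse_read_pair(r1, "C" * 150, LAYOUT, "TRB") == Rejection("gsp_not_found")

    def test_three_prime_in_transcript_orientation(self, trb):
        tr = make_transcript(trb)
        r1, r2 = build_pair("ACGGTTACGGCA", tr)
        obs = parse_read_pair(r1, r2, LAYOUT, "TRB")
        assert obs.three_prime_fragment.startswith(tr)


class TestAssignV:
    def test_zero_noise_exact(self, trb):
        tr = make_transcript(trb, v_id="TBV2")
        r1, r2 = build_pair("ACGGTTACGGCA", tr)
        obs = parse_read_pair(r1, r2, LAYOUT, "TRB")
        assert assign_v(obs, trb) == "TBV2"

    def test_random_fragment_unassigned(self, trb):
        rng = np.random.default_rng(0)
        frag = "".join("ACGT"[i] for i in rng.integers(0, 4, size=120))
        obs = RawObservation("A" * 12, frag, frag)
        assert assign_v(obs, trb) == Rejection("v_unassigned")

    def test_lexicographic_tie_break(self):
        # two V segments sharing the fragment verbatim: identical identity
        seq = "ACCGGTTACGATCGGATCCGGAATTCGATCGTTGTGCCAGCGGATCCGAATTCGGATGTGCCAGC"
        segs = tuple(
            GermlineSegment(v_id, "TRB", "V", seq, len(seq) - 9)
            for v_id in ("TV1", "TV3")
        )
        j = GermlineSegment("TJ1", "TRB", "J", "TACTTTGGCGCAGGCACC", 3)
        gset = GermlineSet("TRB", segs, (j,))
        obs = RawObservation("A" * 12, seq[:40], seq[:40])
        assert assign_v(obs, gset) == "TV1"

    def test_identity_threshold(self, trb):
        v = trb.v("TBV1").seq_nt
        # 58/63 identity < 0.90 -> rejected
        corrupt = list(v)
        for i in (2, 10, 20, 30, 40, 50, 60):
            corrupt[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[corrupt[i]]
        obs = RawObservation("A" * 12, "".join(corrupt), v)
        assert assign_v(obs, trb) == Rejection("v_unassigned")


class TestDelimitJunction:
    def _obs(self, trb, **kw):
        tr = make_transcript(trb, **kw)
        r1, r2 = build_pair("ACGGTTACGGCA", tr)
        return parse_read_pair(r1, r2, LAYOUT, "TRB")

    def test_in_frame_example(self, trb):
        v, j = trb.v("TBV2"), trb.j("TBJ1")
        obs = self._obs(trb, v_id="TBV2", j_id="TBJ1", insert="GGG")
        junction, cdr3, j_id = delimit_junction(obs, "TBV2", trb)
        assert j_id == "TBJ1"
        v_tail = v.seq_nt[v.anchor_offset :]
        assert junction == v_tail + "GGG" + j.seq_nt
        assert cdr3 == v_tail + "GGG" + j.seq_nt[: j.anchor_offset + 3]
        assert len(cdr3) % 3 == 0

    def test_out_of_frame_when_insert_shrinks(self, trb):
        obs = self._obs(trb, insert="GG")
        _junction, cdr3, _ = delimit_junction(obs, "TBV2", trb)
        assert len(cdr3) % 3 != 0

    @pytest.mark.parametrize("v_trim,j_trim", [(0, 0), (2, 1), (3, 3)])
    def test_trimmed_junctions_recovered(self, trb, v_trim, j_trim):
        v, j = trb.v("TBV3"), trb.j("TBJ2")
        obs = self._obs(trb, v_id="TBV3", j_id="TBJ2", insert="ACGTA", v_trim=v_trim, j_trim=j_trim)
        junction, cdr3, j_id = delimit_junction(obs, "TBV3", trb)
        assert j_id == "TBJ2"
        expected = v.seq_nt[v.anchor_offset : len(v.seq_nt) - v_trim] + "ACGTA" + j.seq_nt[j_trim:]
        assert junction == expected

    def test_no_j_rejected(self, trb):
        v = trb.v("TBV1")
        obs = RawObservation("A" * 12, v.seq_nt, v.seq_nt + "ACGTACGTACGTACGTACGT")
        assert delimit_junction(obs, "TBV1", trb) == Rejection("j_not_found")

    def test_missing_v_tail_rejected(self, trb):
        j = trb.j("TBJ1")
        frag = "ACGTACGTACGTACGTACGT" + j.seq_nt + "ACGTACGT"
        obs = RawObservation("A" * 12, frag, frag)
        assert delimit_junction(obs, "TBV1", trb) == Rejection("v_tail_not_found")

    def test_single_mismatch_in_j_tolerated(self, trb):
        tr = make_transcript(trb, v_id="TBV2", j_id="TBJ1", insert="GGG")
        mutated = tr[:-4] + ("A" if tr[-4] != "A" else "C") + tr[-3:]
        r1, r2 = build_pair("ACGGTTACGGCA", mutated)
        obs = parse_read_pair(r1, r2, LAYOUT, "TRB")
        junction, _cdr3, j_id = delimit_junction(obs, "TBV2", trb)
        assert j_id == "TBJ1"
        assert len(junction) == len(trb.v("TBV2").seq_nt) - trb.v("TBV2").anchor_offset + 3 + 18


class TestTabulate:
    def test_grouping_and_counts(self):
        obs = [
            ("AAAACCCCGGGG", "TBV1", "TBJ1", "TGTAAATTT", "TGTAAATTT"),
        ] * 3 + [
            ("CCCCAAAAGGGG", "TBV2", "TBJ1", "TGTCCCTTT", "TGTCCCTTT"),
        ] * 2
        records = tabulate_molecules(obs)
        assert [(r.read_count, r.v_id) for r in records] == [(3, "TBV1"), (2, "TBV2")]

    def test_empty_input(self):
        assert tabulate_molecules([]) == []

    def test_read_conservation_and_order_invariance(self):
        rng = np.random.default_rng(1)
        obs = []
        for i in range(50):
            key = (f"{'ACGT'[i % 4] * 12}"[:12], f"TBV{i % 3 + 1}", "TBJ1", "TGT" + "ACG" * (i % 5 + 1) + "TTT", "TGT" + "ACG" * (i % 5 + 1) + "TTT")
            obs.extend([key] * (i % 4 + 1))
        a = tabulate_molecules(obs)
        shuffled = list(obs)
        rng.shuffle(shuffled)
        b = tabulate_molecules(shuffled)
        assert a == b
        assert sum(r.read_count for r in a) == len(obs)


class TestFullExtraction:
    def test_zero_noise_round_trip_exact(self, trb, tmp_path):
        cfg = SimConfig(
            n_clonotypes=100, n_molecules=400, min_depth=2, depth_mean=3,
            seq_error_rate=0.0, pcr_error_rate=0.0, seed=7,
        )
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        truth, manifest = simulate_sample(cfg, trb, r1, r2)
        records, stats = process_fastq(r1, r2, trb)
        assert stats.pairs_in == manifest["n_read_pairs"]
        assert stats.junction_delimited == stats.pairs_in
        by_id = truth.clone_by_id()
        expected = {}
        for m in truth.molecules:
            c = by_id[m.clone_id]
            expected[(m.umi, c.v_id, c.junction_nt)] = (m.n_reads, c.j_id, c.cdr3_nt)
        got = {r.key: (r.read_count, r.j_id, r.cdr3_nt) for r in records}
        assert got == expected

    def test_parse_stats_conservation(self, trb, tmp_path):
        cfg = SimConfig(
            n_clonotypes=100, n_molecules=300, seq_error_rate=0.01, pcr_error_rate=0.001, seed=9,
        )
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        simulate_sample(cfg, trb, r1, r2)
        _records, stats = process_fastq(r1, r2, trb)
        assert stats.pairs_in == stats.junction_delimited + sum(
            stats.rejected_by_reason.values()
        )
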