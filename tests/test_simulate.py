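"""Simulator properties: determinism, layout fidelity, error statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from tcrumi.extract import iter_read_pairs
from tcrumi.simulate import (
    SimConfig,
    SimTruth,
    emit_fastq,
    sample_repertoire,
    simulate_sample,
    tag_molecules,
)
from tcrumi.layout import ReadLayout


def _noiseless(**kw) -> SimConfig:
    base = dict(
        n_clonotypes=20,
        n_molecules=60,
        min_depth=2,
        depth_mean=2,
        seq_error_rate=0.0,
        pcr_error_rate=0.0,
        seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"seq_error_rate": -0.1},
            {"out_of_frame_fraction": 1.5},
            {"min_depth": 0},
            {"depth_mean": 1.0, "min_depth": 2},
            {"clone_abundance": "pareto"},
            {"read_length": 50},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


class TestSampleRepertoire:
    def test_seeded_determinism(self, trb):
        cfg = _noiseless(n_clonotypes=5)
        a = sample_repertoire(cfg, trb, np.random.default_rng(1))
        b = sample_repertoire(cfg, trb, np.random.default_rng(1))
        assert a == b

    def test_clones_distinct_and_anchored(self, trb):
        clones = sample_repertoire(_noiseless(n_clonotypes=200), trb, np.random.default_rng(0))
        keys = {(c.v_id, c.junction_nt) for c in clones}
        assert len(keys) == 200
        for c in clones:
            assert c.junction_nt[:3] in ("TGT", "TGC")  # starts at the V Cys codon
            j = trb.j(c.j_id)
            # junction ends with the (possibly 5'-trimmed) J through its last base
            assert any(
                c.junction_nt.endswith(j.seq_nt[t:]) for t in range(j.anchor_offset + 1)
            )
            assert c.junction_nt.startswith(c.cdr3_nt)
            assert c.frame_flag == (len(c.cdr3_nt) % 3 == 0)

    def test_all_in_frame_when_fraction_zero(self, trb):
        clones = sample_repertoire(
            _noiseless(n_clonotypes=300, out_of_frame_fraction=0.0),
            trb,
            np.random.default_rng(2),
        )
        assert all(len(c.cdr3_nt) % 3 == 0 for c in clones)

    def test_out_of_frame_fraction_within_binomial_ci(self, trb):
        n, p = 2000, 0.12
        clones = sample_repertoire(
            _noiseless(n_clonotypes=n, out_of_frame_fraction=p),
            trb,
            np.random.default_rng(3),
        )
        k = sum(not c.frame_flag for c in clones)
        lo, hi = sps.binom.interval(0.99, n, p)
        assert lo <= k <= hi

    def test_zipf_abundance_monotone(self, trb):
        clones = sample_repertoire(
            _noiseless(n_clonotypes=1000, clone_abundance="zipf", zipf_s=1.5),
            trb,
            np.random.default_rng(4),
        )
        assert clones[0].abundance > clones[99].abundance
        assert abs(sum(c.abundance for c in clones) - 1.0) < 1e-9

    def test_abundances_normalised(self, trb):
        clones = sample_repertoire(
            _noiseless(n_clonotypes=100, clone_abundance="lognormal"),
            trb,
            np.random.default_rng(5),
        )
        assert abs(sum(c.abundance for c in clones) - 1.0) < 1e-9


class TestTagMolecules:
    def test_single_molecule(self, trb):
        cfg = _noiseless(n_clonotypes=3, n_molecules=1)
        rng = np.random.default_rng(0)
        clones = sample_repertoire(cfg, trb, rng)
        mols = tag_molecules(clones, cfg, rng)
        assert len(mols) == 1

    def test_umi_alphabet_and_length(self, trb):
        cfg = _noiseless(n_clonotypes=10, n_molecules=500)
        rng = np.random.default_rng(1)
        mols = tag_molecules(sample_repertoire(cfg, trb, rng), cfg, rng)
        assert all(len(m.umi) == 12 and set(m.umi) <= set("ACGT") for m in mols)

    def test_uniform_multinomial_counts_within_4sd(self, trb):
        # 10 clones, 10,000 molecules: per-clone counts ~ Bin(10000, 0.1)
        cfg = _noiseless(n_clonotypes=10, n_molecules=10_000)
        rng = np.random.default_rng(2)
        clones = sample_repertoire(cfg, trb, rng)
        mols = tag_molecules(clones, cfg, rng)
        counts = {c.clone_id: 0 for c in clones}
        for m in mols:
            counts[m.clone_id] += 1
        sd = np.sqrt(10_000 * 0.1 * 0.9)
        assert all(abs(k - 1000) <= 4 * sd for k in counts.values())


class TestEmitFastq:
    def test_zero_noise_pair_count_and_verbatim_umi(self, trb, tmp_path):
        cfg = _noiseless(n_clonotypes=30, n_molecules=100, min_depth=3, depth_mean=3)
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        truth, manifest = simulate_sample(cfg, trb, r1, r2)
        assert manifest["n_read_pairs"] == 300
        assert sum(m.n_reads for m in truth.molecules) == 300
        umi_by_mol = {m.molecule_id: m.umi for m in truth.molecules}
        for read_id, s1, _s2 in iter_read_pairs(r1, r2):
            umi = umi_by_mol[read_id.split(":")[0]]
            block = umi[0:4] + "T" + umi[4:8] + "T" + umi[8:12] + "T"
            assert block in s1

    def test_same_seed_byte_identical(self, trb, tmp_path):
        cfg = _noiseless(n_clonotypes=10, n_molecules=30, seq_error_rate=0.01)
        out = []
        for tag in ("a", "b"):
            r1, r2 = tmp_path / f"{tag}1.fastq", tmp_path / f"{tag}2.fastq"
            simulate_sample(cfg, trb, r1, r2)
            out.append((r1.read_bytes(), r2.read_bytes()))
        assert out[0] == out[1]

    def test_sequencing_error_rate_binomial(self, trb, tmp_path):
        # compare constant-side reads against templates rebuilt from truth:
        # substitutions over all bases ~ Bin(total, rate)
        from tcrumi.layout import ReadLayout, revcomp

        rate = 0.01
        layout = ReadLayout()
        cfg = _noiseless(n_clonotypes=50, n_molecules=500, seq_error_rate=rate)
        r1, r2 = tmp_path / "n1.fastq", tmp_path / "n2.fastq"
        truth, _ = simulate_sample(cfg, trb, r1, r2)
        clone_by_id = truth.clone_by_id()
        mol_by_id = {m.molecule_id: m for m in truth.molecules}
        mismatches = total = 0
        for read_id, _s1, s2 in iter_read_pairs(r1, r2):
            mol = mol_by_id[read_id.split(":")[0]]
            clone = clone_by_id[mol.clone_id]
            v = trb.v(clone.v_id)
            transcript = (
                v.seq_nt[: v.anchor_offset]
                + clone.junction_nt
                + layout.constant_stub_by_locus["TRB"]
                + revcomp(layout.gsp_by_locus["TRB"])
            )
            tmpl = revcomp(transcript)
            stagger = len(s2) - len(tmpl)
            assert layout.stagger_min <= stagger <= layout.stagger_max
            mismatches += sum(x != y for x, y in zip(s2[stagger:], tmpl))
            total += len(tmpl)
        sd = np.sqrt(total * rate * (1 - rate))
        assert abs(mismatches - total * rate) < 4 * sd

    def test_truth_tsv_round_trip(self, trb, tmp_path):
        cfg = _noiseless()
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        truth, _ = simulate_sample(cfg, trb, r1, r2, truth_prefix=tmp_path / "truth")
        back = SimTruth.read_tsv(tmp_path / "truth.clones.tsv", tmp_path / "truth.molecules.tsv")
        assert back.clones == truth.clones
        assert back.molecules == truth.molecules

    def test_gzip_output(self, trb, tmp_path):
        cfg = _noiseless(n_clonotypes=5, n_molecules=10)
        r1, r2 = tmp_path / "r1.fastq.gz", tmp_path / "r2.fastq.gz"
        simulate_sample(cfg, trb, r1, r2)
        pairs = list(iter_read_pairs(r1, r2))
        assert len(pairs) == 20
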