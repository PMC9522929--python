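"""Synthetic 5'RACE-UMI TCR library generator with ground truth.

Generates a latent repertoire of clonotypes (V + junction), tags sampled
cDNA molecules with independent 12-nt UMIs, and writes paired 300 bp reads
with the library architecture of the UMI-tagged 5'RACE protocol (TSO/UPM
cassette with split-UMI block on one mate, nested constant-region primer
with random stagger on the other).  Substitution errors are applied in two
layers: a single PCR pass per amplified molecule copy (shared by the two
mates of a read pair) and i.i.d. per-base sequencing errors per read.

The emitted ground truth (:class:`SimTruth`) lets every downstream stage —
parsing, V assignment, junction delimitation, UMI collapse, repertoire
statistics — be tested by exact or statistical recovery.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .germline import GermlineSet
from .layout import ReadLayout, revcomp

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    ``n_clonotypes`` is the size of the latent clone pool; clones that
    receive no molecules simply do not appear in the sample, so the pool
    may exceed ``n_molecules`` (a diverse naive repertoire is far larger
    than the number of mRNA molecules captured from it).
    """

    n_clonotypes: int = 1000
    n_molecules: int = 2000
    clone_abundance: str = "uniform"  # uniform | zipf | lognormal
    zipf_s: float = 1.5
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    out_of_frame_fraction: float = 0.0
    insert_p: float = 0.25  # geometric(p) insert length, truncated
    max_insert: int = 12
    v_trim_max: int = 3
    j_trim_max: int = 3
    min_depth: int = 2
    depth_mean: float = 10.0  # per-molecule reads: min_depth + Poisson
    seq_error_rate: float = 0.002
    pcr_error_rate: float = 0.0005
    read_length: int = 300
    locus: str = "TRB"
    seed: int = 0
    #: optional per-id sampling weights; uniform when None
    v_usage: dict | None = None
    j_usage: dict | None = None

    def __post_init__(self) -> None:
        for name in ("out_of_frame_fraction", "insert_p", "seq_error_rate", "pcr_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.n_clonotypes < 1 or self.n_molecules < 1:
            raise ValueError("n_clonotypes and n_molecules must be positive")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.depth_mean < self.min_depth:
            raise ValueError("depth_mean must be >= min_depth")
        if self.clone_abundance not in ("uniform", "zipf", "lognormal"):
            raise ValueError(f"unknown clone_abundance {self.clone_abundance!r}")
        if self.read_length < ReadLayout().min_read_length():
            raise ValueError(
                f"read_length {self.read_length} below layout minimum "
                f"{ReadLayout().min_read_length()}"
            )


@dataclass(frozen=True)
class SimClone:
    clone_id: str
    v_id: str
    j_id: str
    junction_nt: str  # V Cys codon start -> last nt of J
    cdr3_nt: str  # V Cys codon -> J Phe codon inclusive
    frame_flag: bool
    abundance: float


@dataclass(frozen=True)
class SimMolecule:
    molecule_id: str
    clone_id: str
    umi: str
    n_reads: int


@dataclass
class SimTruth:
    """Ground-truth clones and molecules behind an emitted library."""

    clones: list[SimClone]
    molecules: list[SimMolecule]

    def clone_by_id(self) -> dict[str, SimClone]:
        return {c.clone_id: c for c in self.clones}

    def molecule_keys(self) -> set[tuple[str, str, str]]:
        """(umi, v_id, junction_nt) keys of all truth molecules."""
        by_id = self.clone_by_id()
        return {
            (m.umi, by_id[m.clone_id].v_id, by_id[m.clone_id].junction_nt)
            for m in self.molecules
        }

    def write_tsv(self, clones_path: str | Path, molecules_path: str | Path) -> None:
        pd.DataFrame([asdict(c) for c in self.clones]).to_csv(
            clones_path, sep="\t", index=False
        )
        pd.DataFrame([asdict(m) for m in self.molecules]).to_csv(
            molecules_path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, clones_path: str | Path, molecules_path: str | Path) -> "SimTruth":
        cdf = pd.read_csv(clones_path, sep="\t")
        mdf = pd.read_csv(molecules_path, sep="\t")
        clones = [SimClone(**{**r, "frame_flag": bool(r["frame_flag"])}) for r in cdf.to_dict("records")]
        mols = [SimMolecule(**r) for r in mdf.to_dict("records")]
        return cls(clones, mols)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _weighted_ids(items, usage: dict | None, rng: np.random.Generator):
    ids = [s.id for s in items]
    if usage is None:
        return ids[int(rng.integers(0, len(ids)))]
    w = np.array([usage.get(i, 0.0) for i in ids], dtype=float)
    w /= w.sum()
    return ids[int(rng.choice(len(ids), p=w))]


def _abundances(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_clonotypes
    if config.clone_abundance == "uniform":
        a = np.ones(n)
    elif config.clone_abundance == "zipf":
        a = np.arange(1, n + 1, dtype=float) ** -config.zipf_s
    else:  # lognormal
        a = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=n)
    return a / a.sum()


def sample_repertoire(
    config: SimConfig, germline: GermlineSet, rng: np.random.Generator
) -> list[SimClone]:
    """Draw ``n_clonotypes`` distinct (V, junction) clones.

    Junctions are built as V tail (0..v_trim_max nt trimmed from the 3'
    end, never into the Cys codon) + random N insert + J (0..j_trim_max nt
    trimmed from the 5' end, never into the Phe codon).  The insert length
    is nudged by 1-2 nt so each clone lands in its assigned frame class;
    clone abundances follow the configured law, normalised to 1.
    """
    for v in germline.v_segments:
        if config.v_trim_max > len(v.seq_nt) - v.anchor_offset - 3:
            raise ValueError(
                f"v_trim_max {config.v_trim_max} would trim into the Cys codon of {v.id}"
            )
    for j in germline.j_segments:
        if config.j_trim_max > j.anchor_offset:
            raise ValueError(
                f"j_trim_max {config.j_trim_max} would trim into the Phe codon of {j.id}"
            )

    abund = _abundances(config, rng)
    clones: list[SimClone] = []
    seen: set[tuple[str, str]] = set()
    for idx in range(config.n_clonotypes):
        # the frame class is drawn once per clone and kept across
        # junction-uniqueness retries, so collisions (most likely among
        # short-insert in-frame junctions) cannot bias the realized
        # out-of-frame fraction
        want_out = rng.random() < config.out_of_frame_fraction
        target_mod = int(rng.integers(1, 3)) if want_out else 0
        for _attempt in range(10_000):
            v_id = _weighted_ids(germline.v_segments, config.v_usage, rng)
            j_id = _weighted_ids(germline.j_segments, config.j_usage, rng)
            v = germline.v(v_id)
            j = germline.j(j_id)
            vt = int(rng.integers(0, config.v_trim_max + 1))
            jt = int(rng.integers(0, config.j_trim_max + 1))
            ins_len = min(int(rng.geometric(config.insert_p)) - 1, config.max_insert)

            v_part = len(v.seq_nt) - v.anchor_offset - vt
            cdr3_len = v_part + ins_len + (j.anchor_offset - jt) + 3
            delta = (target_mod - cdr3_len) % 3
            if delta:
                if ins_len + delta <= config.max_insert + 2:
                    ins_len += delta
                else:
                    ins_len -= 3 - delta

            insert = _random_seq(rng, ins_len)
            junction = v.seq_nt[v.anchor_offset : len(v.seq_nt) - vt] + insert + j.seq_nt[jt:]
            key = (v_id, junction)
            if key not in seen:
                break
        else:
            raise RuntimeError(
                "could not generate enough distinct clonotypes; "
                "enlarge the germline or insert space"
            )
        seen.add(key)
        cdr3 = junction[: v_part + ins_len + (j.anchor_offset - jt) + 3]
        clones.append(
            SimClone(
                clone_id=f"C{idx:06d}",
                v_id=v_id,
                j_id=j_id,
                junction_nt=junction,
                cdr3_nt=cdr3,
                frame_flag=len(cdr3) % 3 == 0,
                abundance=float(abund[idx]),
            )
        )
    return clones


def tag_molecules(
    clones: list[SimClone], config: SimConfig, rng: np.random.Generator
) -> list[SimMolecule]:
    """Assign molecules to clones multinomially and tag each with a UMI.

    UMIs are independent uniform 12-mers (4^12 space), so collisions are
    rare but possible, exactly as in the protocol.  Per-molecule read
    depth is ``min_depth`` plus a Poisson excess.
    """
    if not clones:
        raise ValueError("clones must be non-empty")
    p = np.array([c.abundance for c in clones])
    p = p / p.sum()
    counts = rng.multinomial(config.n_molecules, p)
    excess = config.depth_mean - config.min_depth
    molecules: list[SimMolecule] = []
    for clone, k in zip(clones, counts):
        for _ in range(int(k)):
            depth = config.min_depth + (int(rng.poisson(excess)) if excess > 0 else 0)
            molecules.append(
                SimMolecule(
                    molecule_id=f"M{len(molecules):07d}",
                    clone_id=clone.clone_id,
                    umi=_random_seq(rng, 12),
                    n_reads=depth,
                )
            )
    return molecules


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. per-base substitutions at the given rate."""
    if rate <= 0.0 or not seq:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for i in pos:
        old = chars[i]
        alt = _BASES[int(rng.integers(0, 3))]
        # shift past the original base so the substitution is real
        chars[i] = alt if alt != old else _BASES[(_BASES.index(old) + 3) % 4]
    return "".join(chars)


def _open_out(path: str | Path) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def _umi_block(umi: str) -> str:
    return umi[0:4] + "T" + umi[4:8] + "T" + umi[8:12] + "T"


def emit_fastq(
    truth: SimTruth,
    layout: ReadLayout,
    config: SimConfig,
    germline: GermlineSet,
    rng: np.random.Generator,
    out_r1: str | Path,
    out_r2: str | Path,
) -> dict:
    """Write paired FASTQ for every truth molecule; return a manifest.

    Mate R1 (UMI side) carries stagger + UPM_S + TSO anchor + split UMI
    block + CTT + G-run + the transcript 5' end.  Mate R2 (constant side)
    carries stagger + GSP2 and then reads the reverse complement of the
    transcript: constant stub, entire J, junction, V 3' end.  PCR errors
    are one substitution pass per molecule copy (each read pair sequences
    one amplified fragment, so the pass is shared by its two mates but
    independent between read pairs of the same molecule); sequencing
    substitutions are i.i.d. per base per read.  Qualities are constant
    Q30 (the pipeline's rules are count-based).
    """
    clone_by_id = truth.clone_by_id()
    gsp = layout.gsp_by_locus[config.locus]
    c_stub = layout.constant_stub_by_locus[config.locus]
    qchar = chr(30 + 33)
    n_pairs = 0
    with _open_out(out_r1) as f1, _open_out(out_r2) as f2:
        for mol in truth.molecules:
            clone = clone_by_id[mol.clone_id]
            v = germline.v(clone.v_id)
            transcript = (
                v.seq_nt[: v.anchor_offset]
                + clone.junction_nt
                + c_stub
                + revcomp(gsp)
            )
            cdna0 = mol.umi + transcript
            for r in range(mol.n_reads):
                # one PCR substitution pass per amplified copy, shared by
                # the two mates of this pair
                cdna = _mutate(cdna0, config.pcr_error_rate, rng)
                umi_m, transcript_m = cdna[:12], cdna[12:]
                tmpl5 = (
                    layout.upm_s
                    + layout.tso_anchor
                    + _umi_block(umi_m)
                    + "CTT"
                    + "GGGGG"
                    + transcript_m
                )
                tmpl3 = revcomp(transcript_m)
                s1 = _random_seq(rng, int(rng.integers(layout.stagger_min, layout.stagger_max + 1)))
                s2 = _random_seq(rng, int(rng.integers(layout.stagger_min, layout.stagger_max + 1)))
                r1 = _mutate((s1 + tmpl5)[: config.read_length], config.seq_error_rate, rng)
                r2 = _mutate((s2 + tmpl3)[: config.read_length], config.seq_error_rate, rng)
                name = f"{mol.molecule_id}:{r}"
                f1.write(f"@{name}/1\n{r1}\n+\n{qchar * len(r1)}\n")
                f2.write(f"@{name}/2\n{r2}\n+\n{qchar * len(r2)}\n")
                n_pairs += 1
    return {
        "n_molecules": len(truth.molecules),
        "n_read_pairs": n_pairs,
        "locus": config.locus,
        "seed": config.seed,
        "read_length": config.read_length,
    }


def simulate_sample(
    config: SimConfig,
    germline: GermlineSet,
    out_r1: str | Path,
    out_r2: str | Path,
    layout: ReadLayout | None = None,
    truth_prefix: str | Path | None = None,
) -> tuple[SimTruth, dict]:
    """End-to-end sample generation: repertoire -> molecules -> FASTQ."""
    layout = layout or ReadLayout()
    rng = np.random.default_rng(config.seed)
    clones = sample_repertoire(config, germline, rng)
    molecules = tag_molecules(clones, config, rng)
    truth = SimTruth(clones, molecules)
    manifest = emit_fastq(truth, layout, config, germline, rng, out_r1, out_r2)
    if truth_prefix is not None:
        prefix = str(truth_prefix)
        truth.write_tsv(prefix + ".clones.tsv", prefix + ".molecules.tsv")
        with open(prefix + ".manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return truth, manifest
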