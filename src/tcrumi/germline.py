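"""Germline V/J segment references and their CDR3 anchor annotations.

The CDR3 of a rearranged TCR chain is delimited by two conserved residues:
the C-terminal cysteine of the V segment and the characteristic
phenylalanine of the J segment (the F of the F-G-X-G junction motif).
Every germline segment therefore carries, besides its nucleotide sequence,
the 0-based offset of the first base of its anchor codon.  Anchors are
primary data (loaded from a sidecar table); :func:`detect_anchor` is a
deterministic fallback for references that lack the annotation.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Locus = Literal["TRA", "TRB"]
Kind = Literal["V", "J"]

CYS_CODONS = ("TGT", "TGC")
PHE_CODONS = ("TTT", "TTC")

#: F-G-X-G motif at the end of a J segment: Phe codon, Gly codon,
#: any codon, Gly codon (12 nt total starting at the Phe anchor).
_FGXG_RE = re.compile(r"(?:TTT|TTC)GG.{4}GG.")

_DNA_RE = re.compile(r"^[ACGT]+$")


class GermlineError(ValueError):
    """Raised when a germline segment or set violates its invariants."""


@dataclass(frozen=True)
class GermlineSegment:
    """A germline V or J reference with its CDR3 anchor codon position.

    ``anchor_offset`` is the 0-based index of the first nucleotide of the
    anchor codon: the conserved Cys (TGT/TGC) for V segments, the
    conserved Phe (TTT/TTC) for J segments.
    """

    id: str
    locus: Locus
    kind: Kind
    seq_nt: str
    anchor_offset: int

    def __post_init__(self) -> None:
        if not self.seq_nt or not _DNA_RE.match(self.seq_nt):
            raise GermlineError(
                f"segment {self.id!r}: sequence must be non-empty ACGT"
            )
        if not (0 <= self.anchor_offset <= len(self.seq_nt) - 3):
            raise GermlineError(
                f"segment {self.id!r}: anchor offset {self.anchor_offset} "
                f"outside sequence of length {len(self.seq_nt)}"
            )
        codon = self.anchor_codon
        if self.kind == "V" and codon not in CYS_CODONS:
            raise GermlineError(
                f"segment {self.id!r}: V anchor codon {codon} is not Cys (TGT/TGC)"
            )
        if self.kind == "J" and codon not in PHE_CODONS:
            raise GermlineError(
                f"segment {self.id!r}: J anchor codon {codon} is not Phe (TTT/TTC)"
            )

    @property
    def anchor_codon(self) -> str:
        return self.seq_nt[self.anchor_offset : self.anchor_offset + 3]


@dataclass(frozen=True)
class GermlineSet:
    """Validated collection of V and J segments for one locus."""

    locus: Locus
    v_segments: tuple[GermlineSegment, ...]
    j_segments: tuple[GermlineSegment, ...]
    # lazily built caches (not part of equality)
    _v_by_id: dict = field(default_factory=dict, repr=False, compare=False)
    _j_by_id: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.v_segments or not self.j_segments:
            raise GermlineError("germline set needs at least one V and one J")
        ids = [s.id for s in self.v_segments + self.j_segments]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise GermlineError(f"duplicate segment ids: {sorted(dupes)}")
        for seg in self.v_segments + self.j_segments:
            if seg.locus != self.locus:
                raise GermlineError(
                    f"segment {seg.id!r} locus {seg.locus} != set locus {self.locus}"
                )
        self._v_by_id.update({s.id: s for s in self.v_segments})
        self._j_by_id.update({s.id: s for s in self.j_segments})

    def v(self, v_id: str) -> GermlineSegment:
        return self._v_by_id[v_id]

    def j(self, j_id: str) -> GermlineSegment:
        return self._j_by_id[j_id]


def detect_anchor(seq_nt: str, kind: Kind) -> int:
    """Locate the CDR3 anchor codon in a germline segment.

    V: start of the last TGT/TGC codon within the final 15 nt (the
    conserved Cys sits close to the 3' end of the V region); candidate
    codons are scanned left-to-right without overlap, so the TGC buried
    inside the common TGTGC... Cys context does not shadow the true codon.
    J: start of the first TTT/TTC that opens the F-G-X-G motif
    (``(TTT|TTC)GG.{4}GG.``) when such a site exists, otherwise the first
    TTT/TTC anywhere.

    Raises :class:`GermlineError` when no candidate codon is found.
    """
    seq_nt = seq_nt.upper()
    if kind == "V":
        tail_start = max(0, len(seq_nt) - 15)
        best = -1
        i = tail_start
        while i <= len(seq_nt) - 3:
            if seq_nt[i : i + 3] in CYS_CODONS:
                best = i
                i += 3
            else:
                i += 1
        if best == -1:
            raise GermlineError("no anchor codon (Cys) in V tail")
        return best
    if kind == "J":
        m = _FGXG_RE.search(seq_nt)
        if m:
            return m.start()
        for i in range(len(seq_nt) - 2):
            if seq_nt[i : i + 3] in PHE_CODONS:
                return i
        raise GermlineError("no anchor codon (Phe) in J")
    raise ValueError(f"kind must be V or J, got {kind!r}")


def _strip_gaps(seq: str) -> str:
    # IMGT gapped alignment dialects pad with '.'
    return seq.replace(".", "").upper()


def read_germline_fasta(
    fasta_path: str | Path,
    anchors_path: str | Path,
    locus: Locus,
) -> GermlineSet:
    """Load a germline set from FASTA plus a two-column anchor TSV.

    The anchors file maps segment id to the 0-based anchor codon offset;
    the segment kind (V or J) is inferred from the anchor codon itself
    (Cys -> V, Phe -> J).  IMGT gap dots are stripped before validation.
    """
    anchors: dict[str, int] = {}
    with open(anchors_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, off = line.split("\t")[:2]
            if name in anchors:
                raise GermlineError(f"duplicate anchor entry for {name!r}")
            anchors[name] = int(off)

    v_segments: list[GermlineSegment] = []
    j_segments: list[GermlineSegment] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise GermlineError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        if rec.id not in anchors:
            raise GermlineError(f"no anchor annotation for segment {rec.id!r}")
        seq = _strip_gaps(str(rec.seq))
        off = anchors[rec.id]
        codon = seq[off : off + 3]
        if codon in CYS_CODONS:
            kind: Kind = "V"
        elif codon in PHE_CODONS:
            kind = "J"
        else:
            raise GermlineError(
                f"segment {rec.id!r}: anchor codon {codon!r} at offset {off} "
                "is neither Cys (V) nor Phe (J)"
            )
        seg = GermlineSegment(rec.id, locus, kind, seq, off)
        (v_segments if kind == "V" else j_segments).append(seg)
    return GermlineSet(locus, tuple(v_segments), tuple(j_segments))


def write_germline_fasta(
    gset: GermlineSet,
    fasta_path: str | Path,
    anchors_path: str | Path,
) -> None:
    """Write a germline set back to FASTA + anchors TSV (lossless round trip)."""
    records = [
        SeqRecord(Seq(s.seq_nt), id=s.id, description="")
        for s in gset.v_segments + gset.j_segments
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(anchors_path, "w") as fh:
        for s in gset.v_segments + gset.j_segments:
            fh.write(f"{s.id}\t{s.anchor_offset}\n")


# ---------------------------------------------------------------------------
# Bundled deterministic toy germline set
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _toy_rng_seq(rng, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def toy_germline(locus: Locus = "TRB") -> GermlineSet:
    """Deterministic toy germline set for tests and demonstrations.

    Four V segments (63 nt, Cys codon 9 nt from the 3' end) and three J
    segments (18 nt, Phe anchor at offset 3 opening an F-G-X-G motif).
    Sequences are generated from a fixed per-locus seed and are stable
    across runs and platforms; each segment is checked against
    :func:`detect_anchor` at construction.
    """
    import numpy as np

    seed = {"TRA": 101, "TRB": 202}[locus]
    rng = np.random.default_rng(seed)
    prefix = locus[2]  # A or B

    v_segments = []
    for i in range(1, 5):
        for _attempt in range(100):
            body = _toy_rng_seq(rng, 54)
            anchor = "TGT" if i % 2 else "TGC"
            # 6 nt after the Cys codon, free of TG[TC] so the Cys stays the
            # last candidate in the 15-nt tail
            tail = _toy_rng_seq(rng, 6)
            seq = body + anchor + tail
            off = len(seq) - 9
            try:
                if detect_anchor(seq, "V") != off:
                    continue
                seg = GermlineSegment(f"T{prefix}V{i}", locus, "V", seq, off)
            except GermlineError:
                continue
            v_segments.append(seg)
            break
        else:  # pragma: no cover - generation is effectively always quick
            raise RuntimeError("could not generate toy V segment")

    j_segments = []
    for i in range(1, 4):
        for _attempt in range(100):
            lead = _toy_rng_seq(rng, 3)
            phe = "TTT" if i % 2 else "TTC"
            mid = "GG" + _toy_rng_seq(rng, 1) + _toy_rng_seq(rng, 3) + "GG" + _toy_rng_seq(rng, 1)
            tail = _toy_rng_seq(rng, 3)
            seq = lead + phe + mid + tail
            try:
                if detect_anchor(seq, "J") != 3:
                    continue
                seg = GermlineSegment(f"T{prefix}J{i}", locus, "J", seq, 3)
            except GermlineError:
                continue
            j_segments.append(seg)
            break
        else:  # pragma: no cover
            raise RuntimeError("could not generate toy J segment")

    return GermlineSet(locus, tuple(v_segments), tuple(j_segments))
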