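"""Parse read pairs into (UMI, V, junction) observations and molecule records.

Each read pair yields at most one observation: the UMI-side mate provides
the 12-nt UMI (split N4-T-N4-T-N4-T block behind the TSO anchor) and the
V 5' fragment; the constant-side mate, reverse-complemented into
transcript orientation, provides the junction.  The two mates are never
merged — V assignment uses the 5' fragment alone, junction delimitation
the 3' fragment alone.

A molecule is a unique combination of UMI, V and junction (the junction
runs from the V Cys codon through the last base of the J segment, so the
entire J is part of the key); its read count is the number of read pairs
that produced that exact key.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator

import edlib
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .germline import GermlineSet
from .layout import ReadLayout, revcomp


@dataclass(frozen=True)
class Rejection:
    """A read pair dropped at some stage, with a machine-readable reason."""

    reason: str


@dataclass(frozen=True)
class RawObservation:
    umi: str
    five_prime_fragment: str  # V 5' side, transcript orientation
    three_prime_fragment: str  # ...V 3' + insert + J + constant stub
    read_id: str = ""

    def __post_init__(self) -> None:
        if len(self.umi) != 12:
            raise ValueError("UMI must be 12 nt")
        if not self.five_prime_fragment or not self.three_prime_fragment:
            raise ValueError("fragments must be non-empty")


@dataclass(frozen=True)
class MoleculeRecord:
    """One inferred cDNA molecule: unique (UMI, V, junction) with read support."""

    umi: str
    v_id: str
    j_id: str
    junction_nt: str
    cdr3_nt: str
    read_count: int

    def __post_init__(self) -> None:
        if len(self.umi) != 12:
            raise ValueError("UMI must be 12 nt")
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if not self.junction_nt.startswith(self.cdr3_nt):
            raise ValueError("cdr3_nt must be a prefix of junction_nt")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.umi, self.v_id, self.junction_nt)


@dataclass
class ParseStats:
    pairs_in: int = 0
    umi_found: int = 0
    v_assigned: int = 0
    junction_delimited: int = 0
    rejected_by_reason: dict = field(default_factory=dict)

    def reject(self, reason: str) -> Rejection:
        self.rejected_by_reason[reason] = self.rejected_by_reason.get(reason, 0) + 1
        return Rejection(reason)

    def as_dict(self) -> dict:
        return {
            "pairs_in": self.pairs_in,
            "umi_found": self.umi_found,
            "v_assigned": self.v_assigned,
            "junction_delimited": self.junction_delimited,
            "rejected_by_reason": dict(self.rejected_by_reason),
        }


def _find_approx(hay: str, needle: str, max_mismatch: int, end: int | None = None) -> int:
    """First position where ``needle`` matches ``hay`` with <= k substitutions."""
    n = len(needle)
    limit = (len(hay) if end is None else min(end, len(hay))) - n
    for p in range(limit + 1):
        mm = 0
        seg = hay[p : p + n]
        for a, b in zip(seg, needle):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return p
    return -1


def parse_read_pair(
    mate_a: str,
    mate_b: str,
    layout: ReadLayout,
    locus: str,
    read_id: str = "",
) -> RawObservation | Rejection:
    """Slot a read pair into the library layout.

    Returns a :class:`RawObservation` or a :class:`Rejection` whose reason
    is one of ``tso_anchor_not_found``, ``umi_pattern_mismatch``,
    ``g_run_missing``, ``gsp_not_found``, ``fragment_too_short``.
    """
    umi_mate, const_mate = (mate_a, mate_b) if layout.umi_side_mate == "R1" else (mate_b, mate_a)
    umi_mate = umi_mate.upper()
    const_mate = const_mate.upper()

    anchor = layout.tso_anchor
    a = umi_mate.find(anchor)
    if a == -1 and layout.anchor_max_mismatch > 0:
        a = _find_approx(umi_mate, anchor, layout.anchor_max_mismatch)
    if a == -1:
        return Rejection("tso_anchor_not_found")
    e = a + len(anchor)

    block = umi_mate[e : e + 15]
    if len(block) < 15:
        return Rejection("fragment_too_short")
    if block[4] != "T" or block[9] != "T" or block[14] != "T":
        return Rejection("umi_pattern_mismatch")
    if umi_mate[e + 15 : e + 18] != "CTT":
        return Rejection("umi_pattern_mismatch")
    umi = block[0:4] + block[5:9] + block[10:14]

    g = e + 18
    g_end = g
    while g_end < len(umi_mate) and umi_mate[g_end] == "G":
        g_end += 1
    if g_end - g < 3:
        return Rejection("g_run_missing")
    five_prime = umi_mate[g_end:]
    if len(five_prime) < 12:
        return Rejection("fragment_too_short")

    gsp = layout.gsp_by_locus[locus]
    search_end = layout.stagger_max + len(gsp) + 2
    p = const_mate.find(gsp, 0, search_end)
    if p == -1 and layout.anchor_max_mismatch > 0:
        p = _find_approx(const_mate, gsp, layout.anchor_max_mismatch, end=search_end)
    if p == -1:
        return Rejection("gsp_not_found")
    three_prime = revcomp(const_mate[p + len(gsp) :])
    if len(three_prime) < 20:
        return Rejection("fragment_too_short")

    return RawObservation(umi, five_prime, three_prime, read_id)


# ---------------------------------------------------------------------------
# V assignment
# ---------------------------------------------------------------------------

_SEED_K = 12


@lru_cache(maxsize=8)
def _v_seed_index(gset: GermlineSet) -> dict:
    index: dict[str, list[tuple[str, int]]] = {}
    for v in gset.v_segments:
        for p in range(len(v.seq_nt) - _SEED_K + 1):
            index.setdefault(v.seq_nt[p : p + _SEED_K], []).append((v.id, p))
    return index


def assign_v(
    obs: RawObservation,
    gset: GermlineSet,
    min_identity: float = 0.90,
    min_aligned: int = 30,
) -> str | Rejection:
    """Best V by ungapped identity extended from a shared 12-mer seed.

    Accepts only if identity >= ``min_identity`` over >= ``min_aligned``
    aligned nt; ties are broken by lexicographic V id so the call is
    deterministic.
    """
    frag = obs.five_prime_fragment
    index = _v_seed_index(gset)
    diagonals: set[tuple[str, int]] = set()
    for p in range(len(frag) - _SEED_K + 1):
        for v_id, vp in index.get(frag[p : p + _SEED_K], ()):
            diagonals.add((v_id, p - vp))
    if not diagonals:
        return Rejection("v_unassigned")

    best: tuple[float, str] | None = None
    for v_id, diag in diagonals:
        v_seq = gset.v(v_id).seq_nt
        v_start = max(0, -diag)
        f_start = v_start + diag
        length = min(len(frag) - f_start, len(v_seq) - v_start)
        if length < min_aligned:
            continue
        matches = sum(
            1
            for a, b in zip(frag[f_start : f_start + length], v_seq[v_start : v_start + length])
            if a == b
        )
        ident = matches / length
        if ident < min_identity:
            continue
        if best is None or ident > best[0] or (ident == best[0] and v_id < best[1]):
            best = (ident, v_id)
    if best is None:
        return Rejection("v_unassigned")
    return best[1]


# ---------------------------------------------------------------------------
# Junction delimitation
# ---------------------------------------------------------------------------


def delimit_junction(
    obs: RawObservation,
    v_id: str,
    gset: GermlineSet,
    j_max_mismatch: int = 1,
    v_tail_max_mismatch: int = 1,
) -> tuple[str, str, str] | Rejection:
    """Delimit the junction in the 3' fragment given the called V.

    The best J (allowing 5' trimming down to, but never into, its Phe
    anchor, and up to ``j_max_mismatch`` errors) fixes the junction end at
    the last base of the J; the V germline tail located upstream fixes the
    Cys codon.  Returns ``(junction_nt, cdr3_nt, j_id)``: the CDR3 runs
    from the Cys codon through the Phe codon inclusive, the junction from
    the Cys codon through the end of the J (constant-region bases are
    excluded from the key).
    """
    frag = obs.three_prime_fragment

    # --- J: candidates ordered by (mismatches, trim, j_id) ---
    best_j: tuple[int, int, str, int, int] | None = None  # mm, t, j_id, start, end
    for j in sorted(gset.j_segments, key=lambda s: s.id):
        for t in range(j.anchor_offset + 1):
            sub = j.seq_nt[t:]
            pos = frag.rfind(sub)
            if pos != -1:
                cand = (0, t, j.id, pos, pos + len(sub))
                if best_j is None or cand[:3] < best_j[:3]:
                    best_j = cand
    if best_j is None and j_max_mismatch > 0:
        for j in sorted(gset.j_segments, key=lambda s: s.id):
            for t in range(j.anchor_offset + 1):
                sub = j.seq_nt[t:]
                aln = edlib.align(sub, frag, mode="HW", task="locations", k=j_max_mismatch)
                if aln["editDistance"] == -1:
                    continue
                start, end = aln["locations"][-1]
                cand = (aln["editDistance"], t, j.id, start, end + 1)
                if best_j is None or cand[:3] < best_j[:3]:
                    best_j = cand
    if best_j is None:
        return Rejection("j_not_found")
    _, j_trim, j_id, j_start, j_end = best_j
    j_seg = gset.j(j_id)
    phe_end = j_start + (j_seg.anchor_offset - j_trim) + 3

    # --- V tail upstream of the J: window ending at the trim point ---
    v = gset.v(v_id)
    cys = v.anchor_offset
    L = len(v.seq_nt)
    max_trim = L - cys - 3  # never trim into the Cys codon
    cys_pos = -1
    for t in range(max_trim + 1):
        w_end = L - t
        w_start = max(0, min(cys, w_end - 12))
        window = v.seq_nt[w_start:w_end]
        if len(window) < 9:
            break
        pos = frag.rfind(window, 0, j_start)
        if pos != -1:
            cys_pos = pos + (cys - w_start)
            break
    if cys_pos == -1 and v_tail_max_mismatch > 0:
        upstream = frag[:j_start]
        for t in range(max_trim + 1):
            w_end = L - t
            w_start = max(0, min(cys, w_end - 12))
            window = v.seq_nt[w_start:w_end]
            if len(window) < 9:
                break
            aln = edlib.align(window, upstream, mode="HW", task="locations", k=v_tail_max_mismatch)
            if aln["editDistance"] == -1:
                continue
            start, _end = aln["locations"][-1]
            cys_pos = start + (cys - w_start)
            break
    if cys_pos == -1 or cys_pos + 3 > phe_end:
        return Rejection("v_tail_not_found")

    junction = frag[cys_pos:j_end]
    cdr3 = frag[cys_pos:phe_end]
    return junction, cdr3, j_id


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------


def tabulate_molecules(
    observations: Iterable[tuple[str, str, str, str, str]],
) -> list[MoleculeRecord]:
    """Group accepted observations into molecule records.

    ``observations`` yields ``(umi, v_id, j_id, junction_nt, cdr3_nt)``
    tuples; the read count of a record is the number of observations
    sharing its (UMI, V, junction) key.  Output order is deterministic:
    descending read count, then key — independent of input order.
    """
    groups: dict[tuple[str, str, str], list] = {}
    for umi, v_id, j_id, junction, cdr3 in observations:
        key = (umi, v_id, junction)
        if key in groups:
            groups[key][0] += 1
        else:
            groups[key] = [1, j_id, cdr3]
    records = [
        MoleculeRecord(umi, v_id, j_id, junction, cdr3, count)
        for (umi, v_id, junction), (count, j_id, cdr3) in groups.items()
    ]
    records.sort(key=lambda r: (-r.read_count, r.key))
    return records


def _open_fastq(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_read_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, seq1, seq2) from a FASTQ pair (gzipped or plain)."""
    with _open_fastq(r1_path) as f1, _open_fastq(r2_path) as f2:
        for (n1, s1, _q1), (_n2, s2, _q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            yield n1.split()[0], s1, s2


def process_read_pairs(
    pairs: Iterable[tuple[str, str, str]],
    gset: GermlineSet,
    layout: ReadLayout | None = None,
    locus: str | None = None,
    min_identity: float = 0.90,
    min_aligned: int = 30,
    j_max_mismatch: int = 1,
    v_tail_max_mismatch: int = 1,
) -> tuple[list[MoleculeRecord], ParseStats]:
    """Run parse -> assign_v -> delimit_junction -> tabulate over read pairs."""
    layout = layout or ReadLayout()
    locus = locus or gset.locus
    stats = ParseStats()
    accepted: list[tuple[str, str, str, str, str]] = []
    for read_id, s1, s2 in pairs:
        stats.pairs_in += 1
        obs = parse_read_pair(s1, s2, layout, locus, read_id)
        if isinstance(obs, Rejection):
            stats.reject(obs.reason)
            continue
        stats.umi_found += 1
        v_id = assign_v(obs, gset, min_identity, min_aligned)
        if isinstance(v_id, Rejection):
            stats.reject(v_id.reason)
            continue
        stats.v_assigned += 1
        delim = delimit_junction(obs, v_id, gset, j_max_mismatch, v_tail_max_mismatch)
        if isinstance(delim, Rejection):
            stats.reject(delim.reason)
            continue
        stats.junction_delimited += 1
        junction, cdr3, j_id = delim
        accepted.append((obs.umi, v_id, j_id, junction, cdr3))
    return tabulate_molecules(accepted), stats


def process_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    gset: GermlineSet,
    layout: ReadLayout | None = None,
    locus: str | None = None,
    **kwargs,
) -> tuple[list[MoleculeRecord], ParseStats]:
    """Extract molecule records from a paired FASTQ sample."""
    return process_read_pairs(
        iter_read_pairs(r1_path, r2_path), gset, layout, locus, **kwargs
    )
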