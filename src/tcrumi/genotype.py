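"""In-silico utilities for the transgene genotyping assay.

The thymoma-associated point mutation replaces TG by AT within the
plus-strand hexamer GCTGGC of the Gtf2i delta-isoform cDNA, converting a
leucine codon (CTG) into histidine (CAT) and — because the mutated
hexamer reads GCATGC — creating an SphI restriction site.  Genotyping
therefore amplifies an 880 bp cDNA fragment and digests it with SphI: the
wild-type amplicon is resistant, the mutant is cut into 320 + 560 bp
fragments.

This module provides the pieces of that assay as composable operations:
in-silico PCR, the TG>AT mutation with ORF-aware residue reporting, SphI
digestion, and longest-ORF translation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq

from .layout import revcomp

#: genotyping primers flanking the mutated region of the Gtf2i cDNA
OBG_7 = "CACCCACCAAGAGGCTAAAG"
OBG_14 = "GAGCCCTTCCACATACAGAAA"

SPHI_SITE = "GCATGC"
_STOPS = {"TAA", "TAG", "TGA"}
_DNA_RE = re.compile(r"^[ACGT]+$")


class GenotypeError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerPair:
    name: str
    fwd: str  # 5'->3' plus strand
    rev: str  # 5'->3'; anneals to the plus strand as its reverse complement

    def __post_init__(self) -> None:
        if len(self.fwd) < 15 or len(self.rev) < 15:
            raise GenotypeError("primers must be >= 15 nt")


#: the published genotyping pair for the mutated-transcript assay
GENOTYPING_PAIR = PrimerPair("OBG_7/OBG_14", OBG_7, OBG_14)


@dataclass(frozen=True)
class DigestResult:
    site_positions: tuple[int, ...]  # 0-based site starts
    fragment_lengths: tuple[int, ...]  # sorted ascending, sums to input length


@dataclass(frozen=True)
class MutationResult:
    mutated_cdna: str
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    protein_position: int  # 1-based residue index in the longest ORF


def _check_dna(seq: str) -> str:
    seq = seq.upper()
    if not _DNA_RE.match(seq):
        raise GenotypeError("sequence must be non-empty ACGT")
    return seq


def insilico_pcr(
    template: str,
    primer_pair: "PrimerPair | tuple[str, str]",
    max_mismatch: int = 0,
) -> str:
    """Amplicon from a linear template: fwd primer site through the end of
    the reverse-primer site (inclusive).

    ``primer_pair`` may be a :class:`PrimerPair` or a bare ``(fwd, rev)``
    tuple (handy for toy constructs below the 15-nt primer floor).  Raises
    ``no_amplicon`` when no (fwd, rev) arrangement exists and
    ``multiple_amplicons`` when the priming is ambiguous.
    """
    template = _check_dna(template)
    if max_mismatch != 0:
        raise NotImplementedError("mismatch-tolerant priming is not modelled")
    if isinstance(primer_pair, tuple):
        fwd_raw, rev_raw = primer_pair
    else:
        fwd_raw, rev_raw = primer_pair.fwd, primer_pair.rev
    fwd, rev_site = fwd_raw.upper(), revcomp(rev_raw.upper())
    fwd_hits = [m.start() for m in re.finditer(re.escape(fwd), template)]
    rev_hits = [m.start() for m in re.finditer(re.escape(rev_site), template)]
    products = [
        (f, r + len(rev_site))
        for f in fwd_hits
        for r in rev_hits
        if r >= f + len(fwd)
    ]
    if not products:
        raise GenotypeError("no_amplicon")
    if len(products) > 1:
        raise GenotypeError("multiple_amplicons")
    start, end = products[0]
    return template[start:end]


def _orf_spans(seq: str) -> list[tuple[int, int]]:
    """All ATG-initiated, stop-terminated ORF spans (start, end-exclusive
    incl. stop) on the plus strand."""
    spans = []
    for frame in range(3):
        starts: list[int] = []
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG":
                starts.append(i)
            elif codon in _STOPS:
                for s in starts:
                    spans.append((s, i + 3))
                starts = []
    return spans


def translate_longest_orf(sequence: str, min_codons: int = 30) -> str:
    """Protein of the longest ATG-initiated plus-strand ORF (leftmost on ties)."""
    seq = _check_dna(sequence)
    spans = _orf_spans(seq)
    if not spans:
        raise GenotypeError(f"no ORF of >= {min_codons} codons")
    spans.sort(key=lambda se: (-(se[1] - se[0]), se[0]))
    start, end = spans[0]
    if (end - start) // 3 < min_codons:
        raise GenotypeError(f"no ORF of >= {min_codons} codons")
    return str(Seq(seq[start : end - 3]).translate())


def apply_tg_at_mutation(cdna: str) -> MutationResult:
    """Introduce the TG>AT substitution that creates the SphI site.

    Scans the longest ORF for the unique leucine codon CTG sitting in the
    plus-strand hexamer context GCTGGC; mutating TG->AT there yields
    GCATGC (the SphI recognition site) and changes the codon to CAT
    (Leu -> His).  Exactly two nucleotides change.  Zero or multiple
    qualifying sites raise ``site_not_found`` / ``ambiguous_site``.
    """
    seq = _check_dna(cdna)
    spans = _orf_spans(seq)
    if not spans:
        raise GenotypeError("site_not_found")
    spans.sort(key=lambda se: (-(se[1] - se[0]), se[0]))
    start, end = spans[0]
    hits = []
    for i in range(start, end - 3, 3):
        if seq[i : i + 3] == "CTG" and seq[i - 1 : i + 5] == "GCTGGC":
            hits.append(i)
    if not hits:
        raise GenotypeError("site_not_found")
    if len(hits) > 1:
        raise GenotypeError("ambiguous_site")
    i = hits[0]
    mutated = seq[: i + 1] + "AT" + seq[i + 3 :]
    return MutationResult(
        mutated_cdna=mutated,
        codon_before="CTG",
        codon_after="CAT",
        aa_before="L",
        aa_after="H",
        protein_position=(i - start) // 3 + 1,
    )


def digest(sequence: str, recognition: str = SPHI_SITE, cut_offset: int = 5) -> DigestResult:
    """Restriction digest of a linear sequence.

    SphI cleaves GCATGC after the fifth base of the top strand
    (``cut_offset`` = 5); gel fragment lengths ignore overhang chemistry.
    A sequence without sites yields a single full-length fragment.
    """
    seq = _check_dna(sequence)
    sites = [m.start() for m in re.finditer(re.escape(recognition.upper()), seq)]
    cuts = [s + cut_offset for s in sites]
    bounds = [0] + cuts + [len(seq)]
    lengths = tuple(sorted(b - a for a, b in zip(bounds, bounds[1:])))
    return DigestResult(tuple(sites), lengths)


# ---------------------------------------------------------------------------
# Synthetic stand-in template
# ---------------------------------------------------------------------------

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@lru_cache(maxsize=1)
def synthetic_transgene_cdna() -> str:
    """Deterministic SYNTHETIC stand-in for the Gtf2i delta-isoform cDNA.

    This is not the GenBank record (which requires a download); it is a
    constructed sequence reproducing the geometry of the published assay:
    OBG_7/OBG_14 priming sites 880 bp apart, a single in-frame CTG in
    GCTGGC context at residue 384 of the longest ORF, no SphI site in the
    wild-type amplicon, and SphI-site placement such that the mutated
    amplicon digests into 320 + 560 bp fragments.  Useful for exercising
    and validating the full genotyping tool-chain offline.
    """
    # layout (all offsets relative to the ORF start):
    #   fwd primer at 833, mutation hexamer at 1148 (codon 384 at 1149),
    #   rev priming site at 1692 -> amplicon 880 bp with the SphI cut
    #   falling 320 bp into it.
    n_res = 419  # ATG + 418 internal codons + stop = 1260 nt
    for seed in range(100):
        rng = np.random.default_rng(7_000 + seed)

        def rand_seq(n: int) -> str:
            return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

        utr5 = rand_seq(60).replace("ATG", "ACG")
        codons = [
            _NONSTOP_CODONS[i]
            for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_res - 1)
        ]
        codons[381] = "AAG"  # residue 383, ends in G
        codons[382] = "CTG"  # residue 384: the Leu to be mutated
        codons[383] = "GCA"  # residue 385, opens with GC -> hexamer GCTGGC
        orf = list("ATG" + "".join(codons) + "TAA")
        orf[833:853] = OBG_7
        utr3 = list(rand_seq(480).replace("ATG", "ACG"))
        utr3[432:453] = revcomp(OBG_14)
        cdna = utr5 + "".join(orf) + "".join(utr3)

        # validate the construct end to end; retry with the next seed on
        # any accidental motif collision
        try:
            protein = translate_longest_orf(cdna)
            if len(protein) != n_res or protein[383] != "L":
                continue
            wt_amp = insilico_pcr(cdna, GENOTYPING_PAIR)
            if len(wt_amp) != 880 or SPHI_SITE in wt_amp:
                continue
            mut = apply_tg_at_mutation(cdna)
            if mut.protein_position != 384:
                continue
            mut_amp = insilico_pcr(mut.mutated_cdna, GENOTYPING_PAIR)
            if digest(mut_amp).fragment_lengths != (320, 560):
                continue
        except GenotypeError:
            continue
        return cdna
    raise RuntimeError("could not build a valid synthetic template")
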