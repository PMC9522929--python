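"""Read architecture of the UMI-tagged 5'RACE TCR amplicon library.

The library is built by SMARTer 5'RACE with a template-switch oligo (TSO)
carrying a 12-nt UMI split into three N4 blocks separated by single T's
(sequenced image of the NNNNU-NNNNU-NNNNU pattern), followed by CTT and a
riboG run, and amplified with a universal primer (UPM) on the 5' side and
nested constant-region gene-specific primers (GSPs) on the 3' side.  Both
second-round primers carry 4-7 nt random staggers for sequencer diversity.

The UMI-side mate therefore reads, 5'->3':

    [stagger] [UPM_S] [TSO anchor] [N4 T N4 T N4 T] [CTT] [GGGGG] [V 5'...]

and the constant-side mate reads from the constant region across the entire
J segment and junction into the V 3' end (reverse complement of the
transcript).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: universal primer (short form) appended 5' of the TSO anchor
UPM_S = "CTAATACGACTCACTATAGGGC"
#: 3' DNA portion of the template-switch oligo, as sequenced
TSO_ANCHOR = "AAGCAGTGGTATCAACGCAGAGT"
#: second-round constant-region gene-specific primers (3' target-annealing
#: portions of OBG_141 / OBG_137)
GSP2_BY_LOCUS = {
    "TRA": "CAGGTTCTGGGTTCTGGATGT",
    "TRB": "GGAGTCACATTTCTCAGATCC",
}
#: constant-region stub between the J end and the GSP2 annealing site
#: (toy constant exon 5' ends; only its length and determinism matter)
CONSTANT_STUB_BY_LOCUS = {
    "TRA": "AGGATCTGAGAAATGTGACT",
    "TRB": "AGGATCTGAGAAATGTGACT",
}


@dataclass(frozen=True)
class ReadLayout:
    """Where the UMI, primers and fragments sit within a read pair."""

    tso_anchor: str = TSO_ANCHOR
    upm_s: str = UPM_S
    gsp_by_locus: dict = field(
        default_factory=lambda: dict(GSP2_BY_LOCUS)
    )
    constant_stub_by_locus: dict = field(
        default_factory=lambda: dict(CONSTANT_STUB_BY_LOCUS)
    )
    stagger_min: int = 4
    stagger_max: int = 7  # inclusive
    umi_side_mate: str = "R1"
    #: mismatches tolerated when locating the TSO anchor / GSP
    anchor_max_mismatch: int = 1

    def __post_init__(self) -> None:
        if not self.tso_anchor or not self.upm_s:
            raise ValueError("anchor and UPM sequences must be non-empty")
        for locus, gsp in self.gsp_by_locus.items():
            if not gsp:
                raise ValueError(f"empty GSP for locus {locus}")
        if self.stagger_min >= self.stagger_max + 1 or self.stagger_min < 0:
            raise ValueError("degenerate stagger range")
        if self.umi_side_mate not in ("R1", "R2"):
            raise ValueError("umi_side_mate must be R1 or R2")

    @property
    def umi_block_len(self) -> int:
        # N4 T N4 T N4 T
        return 15

    def min_read_length(self) -> int:
        """Smallest read that can still contain the full UMI cassette."""
        return (
            self.stagger_max
            + len(self.upm_s)
            + len(self.tso_anchor)
            + self.umi_block_len
            + 3  # CTT
            + 3  # minimal G run
            + 12  # some transcript
        )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]
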