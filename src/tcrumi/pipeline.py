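"""End-to-end sample processing: extract -> collapse -> clonotypes -> profile."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .collapse import CollapseConfig, collapse
from .extract import MoleculeRecord, ParseStats, process_fastq
from .germline import GermlineSet
from .layout import ReadLayout
from .repstats import ClonotypeRecord, RepertoireProfile, build_clonotypes, profile


@dataclass
class SampleResult:
    molecules_raw: list[MoleculeRecord]
    molecules: list[MoleculeRecord]
    clonotypes: list[ClonotypeRecord]
    profile: RepertoireProfile
    parse_stats: ParseStats
    collapse_report: dict


def run_sample(
    r1_path: str | Path,
    r2_path: str | Path,
    germline: GermlineSet,
    layout: ReadLayout | None = None,
    collapse_config: CollapseConfig | None = None,
    sample_id: str = "sample",
) -> SampleResult:
    """Full pipeline on one paired-FASTQ sample.

    Extraction tabulates (UMI, V, junction) molecule records with read
    counts; the collapse stage applies the >=2-read filter and the
    near-duplicate merge; clonotypes are then keyed by (V, junction) with
    UMI counts as clone sizes and summarised into a repertoire profile.
    """
    raw, stats = process_fastq(r1_path, r2_path, germline, layout)
    collapsed, report = collapse(raw, collapse_config or CollapseConfig())
    clonotypes = build_clonotypes(collapsed)
    prof = profile(clonotypes, sample_id)
    return SampleResult(raw, collapsed, clonotypes, prof, stats, report)
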