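"""Read-support filtering and near-duplicate error collapse.

Two clean-up rules are applied to the molecule table, in this order:

1. a (UMI, V, junction) combination is kept only if supported by at least
   ``min_reads`` reads (default 2) — singleton reads are treated as
   artefacts;
2. records whose UMIs lie within Hamming distance 1 *and* whose CDR3s lie
   within Levenshtein distance 2 of an already-retained record are
   considered PCR/sequencing errors of that record; only the variant with
   the highest read count is retained.

The merge is a greedy pass over records sorted by descending read count
(ties broken by key), each incoming record being absorbed by the first
retained record it is mergeable with.  ``brute_force_collapse`` recomputes
the same result from the full pairwise distance matrix and serves as an
independent oracle in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import edlib

from .extract import MoleculeRecord

_BASES = "ACGT"


@dataclass(frozen=True)
class CollapseConfig:
    min_reads: int = 2
    umi_max_dist: int = 1  # Hamming
    cdr3_max_dist: int = 2  # Levenshtein
    require_same_v: bool = True
    absorb_reads: bool = True

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.umi_max_dist < 0 or self.cdr3_max_dist < 0:
            raise ValueError("distances must be >= 0")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y)


def levenshtein(a: str, b: str, k: int | None = None) -> int:
    """Edit distance via edlib; -1 if a cutoff ``k`` is given and exceeded."""
    return edlib.align(a, b, mode="NW", task="distance", k=-1 if k is None else k)[
        "editDistance"
    ]


def filter_min_reads(
    records: list[MoleculeRecord], config: CollapseConfig
) -> tuple[list[MoleculeRecord], int]:
    """Drop records supported by fewer than ``min_reads`` reads."""
    kept = [r for r in records if r.read_count >= config.min_reads]
    return kept, len(records) - len(kept)


def _sorted_records(records: list[MoleculeRecord]) -> list[MoleculeRecord]:
    return sorted(records, key=lambda r: (-r.read_count, r.key))


def _mergeable(r: MoleculeRecord, kept: MoleculeRecord, config: CollapseConfig) -> bool:
    if config.require_same_v and r.v_id != kept.v_id:
        return False
    if hamming(r.umi, kept.umi) > config.umi_max_dist:
        return False
    if abs(len(r.cdr3_nt) - len(kept.cdr3_nt)) > config.cdr3_max_dist:
        return False
    return levenshtein(r.cdr3_nt, kept.cdr3_nt, k=config.cdr3_max_dist) != -1


def _umi_neighbourhood(umi: str) -> list[str]:
    out = [umi]
    for i, c in enumerate(umi):
        for b in _BASES:
            if b != c:
                out.append(umi[:i] + b + umi[i + 1 :])
    return out


def merge_errors(
    records: list[MoleculeRecord], config: CollapseConfig
) -> list[MoleculeRecord]:
    """Greedy near-duplicate merge; returns retained records in sorted order.

    Equivalent to :func:`brute_force_collapse` but uses a UMI
    neighbourhood index (when ``umi_max_dist <= 1``) so only candidate
    records within Hamming reach are compared.
    """
    ordered = _sorted_records(records)
    retained: list[MoleculeRecord] = []
    absorbed_into: list[int] = []  # parallel to retained: extra reads
    use_index = config.umi_max_dist <= 1
    umi_index: dict[str, list[int]] = {}

    for rec in ordered:
        if use_index:
            cand_idx = sorted(
                {i for u in _umi_neighbourhood(rec.umi) for i in umi_index.get(u, ())}
            )
        else:
            cand_idx = range(len(retained))
        target = None
        for i in cand_idx:
            if _mergeable(rec, retained[i], config):
                target = i
                break
        if target is None:
            umi_index.setdefault(rec.umi, []).append(len(retained))
            retained.append(rec)
            absorbed_into.append(0)
        elif config.absorb_reads:
            absorbed_into[target] += rec.read_count

    out = [
        replace(r, read_count=r.read_count + extra) if extra else r
        for r, extra in zip(retained, absorbed_into)
    ]
    return _sorted_records(out)


def brute_force_collapse(
    records: list[MoleculeRecord], config: CollapseConfig
) -> list[MoleculeRecord]:
    """Oracle: replay the greedy merge from an explicit pairwise distance matrix.

    Restricted to <= 500 records; must agree exactly with
    :func:`merge_errors` on any input.
    """
    if len(records) > 500:
        raise ValueError("brute_force_collapse is limited to 500 records")
    ordered = _sorted_records(records)
    n = len(ordered)
    mergeable = [[False] * n for _ in range(n)]
    for i, j in product(range(n), range(n)):
        if i == j:
            continue
        a, b = ordered[i], ordered[j]
        ok = (not config.require_same_v or a.v_id == b.v_id) and hamming(
            a.umi, b.umi
        ) <= config.umi_max_dist
        if ok:
            d = levenshtein(a.cdr3_nt, b.cdr3_nt)
            ok = d <= config.cdr3_max_dist
        mergeable[i][j] = ok

    retained_idx: list[int] = []
    extra = {}
    for i in range(n):
        target = next((j for j in retained_idx if mergeable[i][j]), None)
        if target is None:
            retained_idx.append(i)
            extra[i] = 0
        elif config.absorb_reads:
            extra[target] += ordered[i].read_count
    out = [
        replace(ordered[i], read_count=ordered[i].read_count + extra[i])
        if extra[i]
        else ordered[i]
        for i in retained_idx
    ]
    return _sorted_records(out)


def collapse(
    records: list[MoleculeRecord], config: CollapseConfig | None = None
) -> tuple[list[MoleculeRecord], dict]:
    """filter_min_reads followed by merge_errors, with a summary report."""
    config = config or CollapseConfig()
    reads_before = sum(r.read_count for r in records)
    kept, n_discarded = filter_min_reads(records, config)
    merged = merge_errors(kept, config)
    report = {
        "n_in": len(records),
        "n_discarded_min_reads": n_discarded,
        "n_merged": len(kept) - len(merged),
        "n_out": len(merged),
        "reads_before": reads_before,
        "reads_after_filter": sum(r.read_count for r in kept),
        "reads_out": sum(r.read_count for r in merged),
        "min_reads": config.min_reads,
        "umi_max_dist": config.umi_max_dist,
        "cdr3_max_dist": config.cdr3_max_dist,
    }
    return merged, report
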