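"""Clonotype construction and repertoire statistics.

A clonotype is a unique (V, junction) class; its clone size is the number
of distinct UMIs (= inferred cDNA molecules) supporting it.  The module
computes the descriptive statistics of a repertoire profile — V/J usage
fractions over clonotypes, CDR3 length histogram with its 3-nt
periodicity, in-frame fraction, clone-size histogram and singleton
fraction — plus the two-sided t-test (pooled or Welch, selected by an
F-test on the variances) with Bonferroni correction used for
between-genotype comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from Bio.Seq import Seq

from .extract import MoleculeRecord


@dataclass(frozen=True)
class ClonotypeRecord:
    v_id: str
    j_id: str
    junction_nt: str
    cdr3_nt: str
    umi_count: int  # clone size: number of distinct UMIs
    read_count: int
    in_frame: bool

    def __post_init__(self) -> None:
        if self.umi_count < 1:
            raise ValueError("umi_count must be >= 1")
        if self.in_frame != (len(self.cdr3_nt) % 3 == 0):
            raise ValueError("in_frame flag inconsistent with CDR3 length")

    @property
    def productive(self) -> bool:
        """In frame and free of internal stop codons (not used by the
        length-periodicity statistics, which classify by frame alone)."""
        if not self.in_frame:
            return False
        aa = str(Seq(self.cdr3_nt).translate())
        return "*" not in aa


@dataclass
class RepertoireProfile:
    sample_id: str
    n_clonotypes: int
    n_molecules: int
    v_usage: dict
    j_usage: dict
    cdr3_length_hist: dict
    in_frame_fraction: float
    clone_size_hist: dict
    singleton_fraction: float
    #: per-molecule variant: fraction of molecules in singleton clonotypes
    singleton_molecule_fraction: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RepertoireProfile":
        with open(path) as fh:
            d = json.load(fh)
        d.pop("provenance", None)
        for key in ("cdr3_length_hist", "clone_size_hist"):
            d[key] = {int(k): v for k, v in d[key].items()}
        return cls(**d)


def build_clonotypes(records: list[MoleculeRecord]) -> list[ClonotypeRecord]:
    """Group molecule records into clonotypes keyed by (V, junction).

    Clone size is the number of distinct UMIs in the group; read counts
    are summed.  Output sorted by descending clone size, then key.
    """
    groups: dict[tuple[str, str], dict] = {}
    for r in records:
        key = (r.v_id, r.junction_nt)
        g = groups.setdefault(key, {"umis": set(), "reads": 0, "j_id": r.j_id, "cdr3": r.cdr3_nt})
        g["umis"].add(r.umi)
        g["reads"] += r.read_count
    out = [
        ClonotypeRecord(
            v_id=v_id,
            j_id=g["j_id"],
            junction_nt=junction,
            cdr3_nt=g["cdr3"],
            umi_count=len(g["umis"]),
            read_count=g["reads"],
            in_frame=len(g["cdr3"]) % 3 == 0,
        )
        for (v_id, junction), g in groups.items()
    ]
    out.sort(key=lambda c: (-c.umi_count, c.v_id, c.junction_nt))
    return out


def usage_fractions(clonotypes: list[ClonotypeRecord], element: str) -> dict:
    """Fraction of clonotypes containing each V (or J) element.

    Unweighted by clone size; fractions sum to 1.
    """
    if not clonotypes:
        raise ValueError("usage_fractions requires a non-empty clonotype list")
    if element not in ("V", "J"):
        raise ValueError("element must be 'V' or 'J'")
    ids = [c.v_id if element == "V" else c.j_id for c in clonotypes]
    n = len(ids)
    counts: dict[str, int] = {}
    for i in ids:
        counts[i] = counts.get(i, 0) + 1
    return {i: counts[i] / n for i in sorted(counts)}


def cdr3_length_histogram(clonotypes: list[ClonotypeRecord]) -> dict:
    """Counts of clonotypes by CDR3 nucleotide length."""
    hist: dict[int, int] = {}
    for c in clonotypes:
        hist[len(c.cdr3_nt)] = hist.get(len(c.cdr3_nt), 0) + 1
    return dict(sorted(hist.items()))


def inframe_fraction(clonotypes: list[ClonotypeRecord]) -> float:
    """Proportion of clonotypes whose CDR3 length is a multiple of 3."""
    if not clonotypes:
        raise ValueError("inframe_fraction requires a non-empty clonotype list")
    return sum(c.in_frame for c in clonotypes) / len(clonotypes)


def clone_size_stats(clonotypes: list[ClonotypeRecord]) -> tuple[dict, float]:
    """Clone-size histogram and singleton fraction.

    The singleton fraction is the share of clonotypes supported by exactly
    one UMI; a reduced value indicates clonal or homeostatic expansion.
    """
    if not clonotypes:
        raise ValueError("clone_size_stats requires a non-empty clonotype list")
    hist: dict[int, int] = {}
    for c in clonotypes:
        hist[c.umi_count] = hist.get(c.umi_count, 0) + 1
    return dict(sorted(hist.items())), hist.get(1, 0) / len(clonotypes)


def profile(clonotypes: list[ClonotypeRecord], sample_id: str = "sample") -> RepertoireProfile:
    """Full per-sample repertoire summary."""
    if not clonotypes:
        return RepertoireProfile(sample_id, 0, 0, {}, {}, {}, float("nan"), {}, float("nan"), float("nan"))
    size_hist, singleton = clone_size_stats(clonotypes)
    n_molecules = sum(c.umi_count for c in clonotypes)
    singleton_mol = size_hist.get(1, 0) / n_molecules
    return RepertoireProfile(
        sample_id=sample_id,
        n_clonotypes=len(clonotypes),
        n_molecules=n_molecules,
        v_usage=usage_fractions(clonotypes, "V"),
        j_usage=usage_fractions(clonotypes, "J"),
        cdr3_length_hist=cdr3_length_histogram(clonotypes),
        in_frame_fraction=inframe_fraction(clonotypes),
        clone_size_hist=size_hist,
        singleton_fraction=singleton,
        singleton_molecule_fraction=singleton_mol,
    )


def compare_usage(profile_a: RepertoireProfile, profile_b: RepertoireProfile, element: str = "V") -> pd.DataFrame:
    """Paired usage table (id, fraction_a, fraction_b, abs_diff).

    Elements present in only one profile get fraction 0 on the other side
    (points off the identity line of a usage scatter).
    """
    ua = profile_a.v_usage if element == "V" else profile_a.j_usage
    ub = profile_b.v_usage if element == "V" else profile_b.j_usage
    ids = sorted(set(ua) | set(ub))
    rows = [
        {
            "id": i,
            "fraction_a": ua.get(i, 0.0),
            "fraction_b": ub.get(i, 0.0),
            "abs_diff": abs(ua.get(i, 0.0) - ub.get(i, 0.0)),
        }
        for i in ids
    ]
    return pd.DataFrame(rows, columns=["id", "fraction_a", "fraction_b", "abs_diff"])


def total_variation(usage_a: dict, usage_b: dict) -> float:
    """Total-variation distance between two usage distributions."""
    ids = set(usage_a) | set(usage_b)
    return 0.5 * sum(abs(usage_a.get(i, 0.0) - usage_b.get(i, 0.0)) for i in ids)


# ---------------------------------------------------------------------------
# Significance testing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # t_equal_var | t_unequal_var
    n_comparisons: int
    p_bonferroni: float
    f_p_value: float


def ttest_two_sided(sample_x, sample_y, n_comparisons: int = 1, f_alpha: float = 0.05) -> TestResult:
    """Two-sided two-sample t-test with F-test variance selection.

    An F-test on the sample variances (two-sided, alpha 0.05) decides
    between the pooled (equal-variance) and Welch (unequal-variance)
    statistic.  ``p_bonferroni = min(1, p * n_comparisons)`` implements
    the conservative Bonferroni correction for multiple testing.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("degenerate input: both samples have zero variance")
    if vx == 0.0 or vy == 0.0:
        # F-test undefined; fall back to Welch, which remains well-posed
        f_p = 0.0
        equal_var = False
    else:
        f = vx / vy
        cdf = sps.f.cdf(f, len(x) - 1, len(y) - 1)
        f_p = 2.0 * min(cdf, 1.0 - cdf)
        equal_var = f_p > f_alpha
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return TestResult(
        statistic=float(t),
        p_value=float(p),
        method="t_equal_var" if equal_var else "t_unequal_var",
        n_comparisons=n_comparisons,
        p_bonferroni=min(1.0, float(p) * n_comparisons),
        f_p_value=float(f_p),
    )


# ---------------------------------------------------------------------------
# AIRR export
# ---------------------------------------------------------------------------

AIRR_COLUMNS = [
    "sequence_id",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "duplicate_count",
    "consensus_count",
]


def write_airr(clonotypes: list[ClonotypeRecord], path: str | Path, sample_id: str = "sample") -> None:
    """Write clonotypes as an AIRR-style rearrangement TSV.

    ``duplicate_count`` carries the UMI count (clone size) and
    ``consensus_count`` the total read support, following the AIRR
    Rearrangement convention for molecule- and read-level counts.
    ``junction``/``junction_aa`` hold the CDR3 (Cys..Phe inclusive).
    """
    rows = []
    for i, c in enumerate(clonotypes):
        aa = str(Seq(c.cdr3_nt).translate()) if c.in_frame else ""
        rows.append(
            {
                "sequence_id": f"{sample_id}_{i:06d}",
                "v_call": c.v_id,
                "j_call": c.j_id,
                "junction": c.cdr3_nt,
                "junction_aa": aa,
                "productive": "T" if c.productive else "F",
                "duplicate_count": c.umi_count,
                "consensus_count": c.read_count,
            }
        )
    pd.DataFrame(rows, columns=AIRR_COLUMNS).to_csv(path, sep="\t", index=False)
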