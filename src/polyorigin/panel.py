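"""Call-matrix plumbing: pseudosequences, panel merging, and the
three-step marker filter.

A call matrix is a pandas DataFrame with unique marker ids as the index,
sample ids as columns, and single-character IUPAC genotype codes as cells
(``N`` = missing). The analysis-ready panel is produced by merging the
dissected-subgenome call sets into the wild reference panel on the shared
marker set and then filtering in three steps: keep polymorphic markers,
drop markers with minor allele frequency below a threshold (strictly
below 0.05 by default), and drop markers exceeding a missing-data cap
(3% by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .iupac import MISSING, VALID_CALLS, alleles


@dataclass
class FilterConfig:
    maf_threshold: float = 0.05  # drop markers with MAF strictly below
    max_missing_fraction: float = 0.03  # drop markers strictly above
    missing_axis: str = "marker"  # or "sample"

    def __post_init__(self) -> None:
        if not 0 <= self.maf_threshold <= 1:
            raise ValueError("maf_threshold must be in [0, 1]")
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.missing_axis not in ("marker", "sample"):
            raise ValueError("missing_axis must be 'marker' or 'sample'")


@dataclass
class FilterReport:
    """Marker counts surviving each filter step, with dropped ids."""

    n_input: int = 0
    n_after_polymorphic: int = 0
    n_after_maf: int = 0
    n_after_missing: int = 0
    dropped: dict[str, list[str]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_polymorphic": self.n_after_polymorphic,
            "n_after_maf": self.n_after_maf,
            "n_after_missing": self.n_after_missing,
            "n_dropped": {step: len(ids) for step, ids in self.dropped.items()},
        }


def validate_matrix(matrix: pd.DataFrame) -> None:
    if not matrix.index.is_unique:
        raise ValueError("marker ids are not unique")
    bad = set(matrix.to_numpy().ravel()) - VALID_CALLS
    if bad:
        raise ValueError(f"invalid genotype codes in matrix: {sorted(bad)}")


def read_calls(path: str) -> pd.DataFrame:
    """Read a calls TSV (rows = markers, columns = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = "probe_id"
    return df


def write_calls(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def build_pseudosequence(matrix: pd.DataFrame, sample: str) -> str:
    """Concatenated calls of one sample in marker order (``N`` missing)."""
    if sample not in matrix.columns:
        raise KeyError(f"unknown sample {sample!r}")
    return "".join(matrix[sample].tolist())


def pseudosequences(matrix: pd.DataFrame) -> dict[str, str]:
    return {s: build_pseudosequence(matrix, s) for s in matrix.columns}


def write_pseudo_fasta(matrix: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for sample in matrix.columns:
            fh.write(f">{sample}\n{build_pseudosequence(matrix, sample)}\n")


def merge_panels(panel: pd.DataFrame, additions: pd.DataFrame) -> pd.DataFrame:
    """Append sample columns on the intersection of marker sets.

    Marker order follows the panel; sample ids must be disjoint.
    """
    dup = set(panel.columns) & set(additions.columns)
    if dup:
        raise ValueError(f"duplicate sample ids: {sorted(dup)}")
    shared = [m for m in panel.index if m in set(additions.index)]
    if not shared:
        raise ValueError("no shared markers between panel and additions")
    merged = pd.concat(
        [panel.loc[shared], additions.loc[shared]], axis=1
    )
    merged.index.name = panel.index.name
    return merged


def _marker_allele_counts(row: pd.Series) -> dict[str, int]:
    """Allele copy counts of one marker (hom = 2 copies, het = 1 + 1)."""
    counts: dict[str, int] = {}
    for call in row:
        if call == MISSING:
            continue
        for a in alleles(call):
            counts[a] = counts.get(a, 0) + 1
    return counts


def filter_polymorphic(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop markers with fewer than two distinct non-missing calls.

    Distinctness is at the call-code level, so a heterozygote against a
    homozygote counts as polymorphism.
    """
    keep = []
    dropped = []
    for marker, row in matrix.iterrows():
        distinct = set(row) - {MISSING}
        (keep if len(distinct) >= 2 else dropped).append(marker)
    return matrix.loc[keep], dropped


def filter_maf(
    matrix: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Drop markers with minor allele frequency strictly below the
    threshold; markers with more than two observed alleles are dropped
    with a distinct reason."""
    cfg = cfg or FilterConfig()
    keep, dropped_maf, dropped_multi = [], [], []
    for marker, row in matrix.iterrows():
        counts = _marker_allele_counts(row)
        if len(counts) > 2:
            dropped_multi.append(marker)
            continue
        total = sum(counts.values())
        minor = min(counts.values()) if len(counts) == 2 else 0
        maf = minor / total if total else 0.0
        (dropped_maf if maf < cfg.maf_threshold else keep).append(marker)
    return matrix.loc[keep], dropped_maf, dropped_multi


def filter_missing(
    matrix: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Drop markers (or samples, per ``missing_axis``) whose missing
    fraction exceeds the cap."""
    cfg = cfg or FilterConfig()
    if cfg.missing_axis == "marker":
        frac = (matrix == MISSING).mean(axis=1)
        dropped = frac.index[frac > cfg.max_missing_fraction].tolist()
        return matrix.drop(index=dropped), dropped
    frac = (matrix == MISSING).mean(axis=0)
    dropped = frac.index[frac > cfg.max_missing_fraction].tolist()
    return matrix.drop(columns=dropped), dropped


def run_filter_pipeline(
    matrix: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Polymorphic -> MAF -> missing-data filters, in that order."""
    cfg = cfg or FilterConfig()
    report = FilterReport(n_input=len(matrix))
    matrix, dropped = filter_polymorphic(matrix)
    report.dropped["polymorphic"] = dropped
    report.n_after_polymorphic = len(matrix)
    matrix, dropped_maf, dropped_multi = filter_maf(matrix, cfg)
    report.dropped["maf"] = dropped_maf
    report.dropped["multiallelic"] = dropped_multi
    report.n_after_maf = len(matrix)
    matrix, dropped = filter_missing(matrix, cfg)
    report.dropped["missing"] = dropped
    report.n_after_missing = len(matrix)
    return matrix, report
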