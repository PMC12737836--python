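"""Lineage-specific variant classification and windowed density counts.

Variants live in a single reference coordinate system (e.g. the cultivated
genome's subgenome-A pseudomolecules) with one haploid genotype column per
compared lineage. A variant is *lineage-specific* for a focal lineage when
the focal lineage is explicitly called as an alternate allele and the
comparator lineage is explicitly called as the reference allele; a missing
call in either role disqualifies the site. Counts are reported in fixed
half-open windows tiled from coordinate 0, optionally restricted to genic
regions given as BED intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

MISSING_GT = None  # genotype sentinel for '.'


@dataclass(frozen=True)
class VariantRecord:
    """One reference-coordinate variant with per-lineage haploid genotypes.

    ``genotypes`` maps lineage name to 0 (reference), an alternate index
    >= 1, or ``None`` (missing / not explicitly called).
    """

    chrom: str
    pos: int  # 1-based reference position
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref_allele:
            raise ValueError("ref_allele must be non-empty")
        for lineage, gt in self.genotypes.items():
            if gt is not None and not 0 <= gt <= len(self.alt_alleles):
                raise ValueError(
                    f"genotype index {gt} for {lineage} exceeds "
                    f"{len(self.alt_alleles)} alternate allele(s)"
                )


@dataclass
class WindowConfig:
    """Window tiling parameters.

    window_size defaults to 2 Mb (the coarse genome-wide resolution); a
    100 kb size is conventionally used for fine-grained views.
    """

    window_size: int = 2_000_000
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    regions: list[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


def _gt_from_sample(sample) -> int | None:
    """Haploid genotype index from a pysam sample record.

    Accepts haploid calls and diploid-homozygous calls; heterozygous
    diploid calls are rejected because the compared lineages are haploid
    assemblies.
    """
    gt = sample.get("GT")
    if gt is None:
        return None
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return None
    if len(set(alleles)) > 1:
        raise ValueError(f"heterozygous genotype {gt} in haploid-lineage VCF")
    return alleles[0]


def read_vcf(path: str) -> list[VariantRecord]:
    """Read a multi-lineage VCF into VariantRecords.

    Multiallelic records are preserved as-is; ``.`` genotypes become
    missing.
    """
    records = []
    with pysam.VariantFile(path) as vcf:
        lineages = list(vcf.header.samples)
        for rec in vcf:
            genotypes = {
                name: _gt_from_sample(rec.samples[name]) for name in lineages
            }
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=tuple(rec.alts or ()),
                    genotypes=genotypes,
                )
            )
    return records


def classify_lineage_specific(
    variants: list[VariantRecord], focal: str, other: str
) -> list[VariantRecord]:
    """Variants where ``focal`` is explicitly an alternate allele and
    ``other`` is explicitly the reference allele.

    Missing genotypes in either lineage exclude the variant ("explicitly
    called" in both roles).
    """
    kept = []
    for v in variants:
        gf = v.genotypes.get(focal)
        go = v.genotypes.get(other)
        if gf is not None and gf >= 1 and go == 0:
            kept.append(v)
    return kept


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.append((chrom, int(start), int(end)))
    return intervals


def write_bed(intervals: list[tuple[str, int, int]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def _merged_boundaries(
    intervals: list[tuple[str, int, int]],
) -> dict[str, np.ndarray]:
    """Per-chromosome flattened boundaries of the merged interval union."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if start >= end:
            raise ValueError(f"interval with start >= end: {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end))
    flat = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        flat[chrom] = np.array([b for iv in merged for b in iv])
    return flat


def restrict_to_regions(
    variants: list[VariantRecord], bed: list[tuple[str, int, int]]
) -> list[VariantRecord]:
    """Keep variants whose start (pos-1, 0-based) lies inside a BED
    interval on the same chromosome.

    Multi-bp variants are assigned by their start position.
    """
    if not bed:
        return []
    flat = _merged_boundaries(bed)
    kept = []
    for v in variants:
        bounds = flat.get(v.chrom)
        if bounds is None:
            continue
        idx = np.searchsorted(bounds, v.pos - 1, side="right")
        if idx % 2 == 1:  # inside a [start, end) interval
            kept.append(v)
    return kept


def window_counts(
    variants: list[VariantRecord], cfg: WindowConfig
) -> pd.DataFrame:
    """Count variants per half-open window of ``cfg.window_size``.

    Windows tile each declared chromosome from 0; the last window is
    truncated at the chromosome length. Every window is emitted, zero
    counts included. A variant belongs to the window containing pos-1.
    """
    rows = []
    counts: dict[str, np.ndarray] = {}
    for chrom, length in cfg.chrom_lengths.items():
        n_win = max(1, -(-length // cfg.window_size))
        counts[chrom] = np.zeros(n_win, dtype=int)
    for v in variants:
        if v.chrom not in counts:
            raise ValueError(f"no declared length for chromosome {v.chrom}")
        if v.pos > cfg.chrom_lengths[v.chrom]:
            raise ValueError(
                f"variant at {v.chrom}:{v.pos} beyond declared length "
                f"{cfg.chrom_lengths[v.chrom]}"
            )
        counts[v.chrom][(v.pos - 1) // cfg.window_size] += 1
    for chrom, length in cfg.chrom_lengths.items():
        for i, c in enumerate(counts[chrom]):
            start = i * cfg.window_size
            rows.append(
                (chrom, start, min(start + cfg.window_size, length), int(c))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def aggregate_windows(
    fine: pd.DataFrame, coarse_size: int, fine_size: int | None = None
) -> pd.DataFrame:
    """Sum fine-window counts into coarse windows of ``coarse_size``.

    The coarse size must be a multiple of the fine window size (inferred
    from the table unless given; the last window of a chromosome may be
    truncated); the result equals direct counting at the coarse size.
    """
    if fine.empty:
        return fine.copy()
    if fine_size is None:
        fine_size = int((fine["end"] - fine["start"]).max())
    if coarse_size % fine_size != 0:
        raise ValueError(
            f"coarse size {coarse_size} is not a multiple of fine size {fine_size}"
        )
    rows = []
    for chrom, grp in fine.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        bin_idx = grp["start"] // coarse_size
        for b, sub in grp.groupby(bin_idx, sort=True):
            rows.append(
                (
                    chrom,
                    int(b) * coarse_size,
                    int(sub["end"].max()),
                    int(sub["count"].sum()),
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def max_variant_span(variants: list[VariantRecord]) -> int:
    """Largest reference span (length of the reference allele) of any
    variant; 0 with a warning for an empty set."""
    if not variants:
        warnings.warn("no variants: max span is 0", stacklevel=2)
        return 0
    return max(len(v.ref_allele) for v in variants)


def write_vcf(
    variants: list[VariantRecord],
    lineages: list[str],
    path: str,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write VariantRecords as a minimal VCF v4.2 with haploid GT columns."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(lineages)
            + "\n"
        )
        for v in variants:
            alts = ",".join(v.alt_alleles) if v.alt_alleles else "."
            gts = [
                "." if v.genotypes.get(s) is None else str(v.genotypes[s])
                for s in lineages
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{alts}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
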