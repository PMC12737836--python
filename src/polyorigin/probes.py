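"""In-silico SNP-array genotyping of genome assemblies.

Each array marker is a probe: two 35 bp flanking arms around a central
biallelic SNP, written ``LEFT[X/Y]RIGHT`` (71 bp total by default). A probe
is expanded into its two allele sequences and placed on a genome by an
exhaustive ungapped search on both strands. A placement is valid when the
central base exactly equals one of the two alleles and each flank arm
carries at most a configured number of mismatches (one by default); indels
are excluded by construction. A genotype is called only when exactly one
valid placement survives; zero placements code as *absent* and two or more
as *ambiguous*, both emitting the missing sentinel.

For allopolyploids the chromosomes are partitioned into subgenomes and each
partition is searched separately, so the homoeologous copy on the sister
subgenome cannot veto a marker (subgenome dissection).

The search is seeded by pigeonholing: the probe is split into
``max_total_mismatches + 1`` segments, so any placement within the mismatch
budget matches at least one segment exactly. Seeding is an implementation
detail; results are identical to a full scan of every offset and strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "N"

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")

# base byte -> 2-bit code (255 = invalid)
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def revcomp(seq: str | bytes) -> str | bytes:
    """Reverse complement of an ACGT sequence."""
    if isinstance(seq, str):
        return seq.encode()[::-1].translate(_COMPLEMENT).decode()
    return seq[::-1].translate(_COMPLEMENT)


@dataclass(frozen=True)
class ProbeRecord:
    """One array marker: two flanks plus the two allele bases."""

    probe_id: str
    left_flank: str
    allele1: str
    allele2: str
    right_flank: str

    def __post_init__(self) -> None:
        for flank in (self.left_flank, self.right_flank):
            if not re.fullmatch(r"[ACGT]*", flank):
                raise ValueError(f"non-ACGT flank in probe {self.probe_id}")
        for a in (self.allele1, self.allele2):
            if a not in "ACGT" or len(a) != 1:
                raise ValueError(f"bad allele {a!r} in probe {self.probe_id}")
        if self.allele1 == self.allele2:
            raise ValueError(f"identical alleles in probe {self.probe_id}")

    @property
    def length(self) -> int:
        return len(self.left_flank) + 1 + len(self.right_flank)

    @property
    def sequence(self) -> str:
        """Bracket notation, e.g. ``CAGTCAGT[A/C]CAGTCAGT``."""
        return (
            f"{self.left_flank}[{self.allele1}/{self.allele2}]"
            f"{self.right_flank}"
        )


@dataclass
class AlignConfig:
    """Placement filter parameters.

    ``mismatch_scope`` selects how the flank-mismatch budget is applied:
    ``per_arm`` allows up to ``max_flank_mismatch_per_arm`` in *each* arm
    (the default reading of a per-site mismatch cap recorded as separate
    left/right counts); ``total`` caps the summed flank mismatches at the
    same value.
    """

    max_flank_mismatch_per_arm: int = 1
    require_unique: bool = True
    mismatch_scope: str = "per_arm"

    def __post_init__(self) -> None:
        if self.max_flank_mismatch_per_arm < 0:
            raise ValueError("max_flank_mismatch_per_arm must be >= 0")
        if self.mismatch_scope not in ("per_arm", "total"):
            raise ValueError(f"unknown mismatch_scope {self.mismatch_scope!r}")

    @property
    def max_total_mismatches(self) -> int:
        if self.mismatch_scope == "per_arm":
            return 2 * self.max_flank_mismatch_per_arm
        return self.max_flank_mismatch_per_arm


@dataclass(frozen=True)
class ProbeHit:
    """A filtered placement of a probe on a genome.

    ``pos`` is the 1-based forward-strand coordinate of the SNP base;
    ``called_allele`` is reported in probe orientation.
    """

    probe_id: str
    target_id: str
    chrom: str
    pos: int
    strand: str
    called_allele: str
    left_mm: int
    right_mm: int


@dataclass(frozen=True)
class NoCall:
    """Absent (no valid placement) or ambiguous (several placements)."""

    reason: str  # "absent" | "ambiguous"


_BRACKET_RE = re.compile(r"^([A-Za-z]*)\[([A-Za-z])/([A-Za-z])\]([A-Za-z]*)$")


def parse_probe_sequence(probe_id: str, sequence: str) -> ProbeRecord:
    """Parse one ``LEFT[X/Y]RIGHT`` bracket-notation sequence."""
    m = _BRACKET_RE.match(sequence.strip())
    if m is None:
        raise ValueError(f"malformed bracket syntax in probe {probe_id}: {sequence!r}")
    left, a1, a2, right = (g.upper() for g in m.groups())
    return ProbeRecord(probe_id, left, a1, a2, right)


def parse_probes(path: str, flank_length: int = 35) -> list[ProbeRecord]:
    """Read a probe TSV (``probe_id<TAB>sequence``).

    Records sharing a probe_id are all dropped, as are probes whose flanks
    are not exactly ``flank_length`` bp (non-full-length); removal counts
    are logged.
    """
    raw: list[ProbeRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            probe_id, sequence = line.split("\t")[:2]
            raw.append(parse_probe_sequence(probe_id, sequence))
    counts: dict[str, int] = {}
    for p in raw:
        counts[p.probe_id] = counts.get(p.probe_id, 0) + 1
    deduped = [p for p in raw if counts[p.probe_id] == 1]
    n_dup = len(raw) - len(deduped)
    kept = [
        p
        for p in deduped
        if len(p.left_flank) == flank_length and len(p.right_flank) == flank_length
    ]
    n_short = len(deduped) - len(kept)
    if n_dup or n_short:
        logger.info(
            "parse_probes: dropped %d duplicate and %d non-full-length of %d probes",
            n_dup,
            n_short,
            len(raw),
        )
    return kept


def write_probes(probes: list[ProbeRecord], path: str) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f"{p.probe_id}\t{p.sequence}\n")


def expand_alleles(probe: ProbeRecord) -> tuple[str, str]:
    """The two full-length allele sequences of a probe."""
    return (
        probe.left_flank + probe.allele1 + probe.right_flank,
        probe.left_flank + probe.allele2 + probe.right_flank,
    )


def _encode(seq: bytes) -> np.ndarray:
    codes = _BASE_CODE[np.frombuffer(seq, dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("genome sequence contains non-ACGT characters")
    return codes


def _segment_bounds(length: int, n_segments: int) -> list[tuple[int, int]]:
    """Split [0, length) into n_segments near-equal contiguous segments."""
    if length < n_segments:
        raise ValueError(f"probe length {length} shorter than {n_segments} segments")
    bounds = []
    start = 0
    for i in range(n_segments):
        size = length // n_segments + (1 if i < length % n_segments else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def _kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit Horner hash of every k-mer (injective for fixed k <= 31)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    h = codes[:n].astype(np.int64)
    for j in range(1, k):
        h = h * 4 + codes[j : j + n]
    return h


class GenomeIndex:
    """Sorted k-mer position index over a set of chromosomes.

    Supports the pigeonhole seeding of :func:`find_placements`; one index
    serves all probes of a single length under a fixed segment count.
    """

    def __init__(
        self, chroms: dict[str, bytes], probe_length: int, n_segments: int
    ) -> None:
        self.chrom_names = list(chroms)
        self.probe_length = probe_length
        self.bounds = _segment_bounds(probe_length, n_segments)
        self.codes = {name: _encode(seq) for name, seq in chroms.items()}
        self.seqs = dict(chroms)
        self._tables: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for k in {e - s for s, e in self.bounds}:
            hashes, chrom_idx, positions = [], [], []
            for ci, name in enumerate(self.chrom_names):
                h = _kmer_hashes(self.codes[name], k)
                hashes.append(h)
                chrom_idx.append(np.full(len(h), ci, dtype=np.int32))
                positions.append(np.arange(len(h), dtype=np.int64))
            h = np.concatenate(hashes) if hashes else np.empty(0, dtype=np.int64)
            ci = np.concatenate(chrom_idx) if chrom_idx else np.empty(0, np.int32)
            po = np.concatenate(positions) if positions else np.empty(0, np.int64)
            order = np.argsort(h, kind="stable")
            self._tables[k] = (h[order], ci[order], po[order])

    def _lookup(self, seg: bytes) -> list[tuple[int, int]]:
        k = len(seg)
        codes = _BASE_CODE[np.frombuffer(seg, dtype=np.uint8)].astype(np.int64)
        h = 0
        for c in codes:
            h = h * 4 + int(c)
        hs, ci, po = self._tables[k]
        lo = np.searchsorted(hs, h, side="left")
        hi = np.searchsorted(hs, h, side="right")
        return [(int(ci[i]), int(po[i])) for i in range(lo, hi)]

    def candidate_starts(self, seq: bytes) -> set[tuple[int, int]]:
        """All (chrom_idx, start) where some probe segment matches exactly."""
        out: set[tuple[int, int]] = set()
        for s, e in self.bounds:
            for ci, p in self._lookup(seq[s:e]):
                start = p - s
                if 0 <= start <= len(self.codes[self.chrom_names[ci]]) - len(seq):
                    out.add((ci, start))
        return out


def _hamming(a: bytes, b: bytes) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_placements(
    probe: ProbeRecord,
    genome: dict[str, bytes],
    cfg: AlignConfig | None = None,
    *,
    target_id: str = "genome",
    index: GenomeIndex | None = None,
) -> list[ProbeHit]:
    """All full-length ungapped placements of either probe allele, both
    strands, passing the centre-base and flank-mismatch filters.

    The result is identical to an exhaustive scan of every offset and
    strand (completeness contract); an ``index`` built over the same
    chromosomes may be supplied to amortise the search across probes.
    """
    cfg = cfg or AlignConfig()
    flank = len(probe.left_flank)
    if len(probe.right_flank) != flank:
        raise ValueError("find_placements requires equal-length flanks")
    plen = probe.length
    if index is None:
        index = GenomeIndex(genome, plen, cfg.max_total_mismatches + 1)
    elif index.probe_length != plen:
        raise ValueError("index was built for a different probe length")

    left_b = probe.left_flank.encode()
    right_b = probe.right_flank.encode()
    rc_left = revcomp(left_b)
    rc_right = revcomp(right_b)

    hits = []
    seen: set[tuple[int, int, str]] = set()
    for allele in (probe.allele1, probe.allele2):
        fwd = (probe.left_flank + allele + probe.right_flank).encode()
        rev = revcomp(fwd)
        for strand, query in (("+", fwd), ("-", rev)):
            for ci, start in index.candidate_starts(query):
                key = (ci, start, strand)
                if key in seen:
                    continue
                chrom = index.chrom_names[ci]
                window = index.seqs[chrom][start : start + plen]
                if window[flank : flank + 1] != query[flank : flank + 1]:
                    continue
                if strand == "+":
                    left_mm = _hamming(window[:flank], left_b)
                    right_mm = _hamming(window[flank + 1 :], right_b)
                else:
                    # reverse orientation: the genome's left window arm is
                    # the reverse complement of the probe's right flank
                    right_mm = _hamming(window[:flank], rc_right)
                    left_mm = _hamming(window[flank + 1 :], rc_left)
                if cfg.mismatch_scope == "per_arm":
                    ok = (
                        left_mm <= cfg.max_flank_mismatch_per_arm
                        and right_mm <= cfg.max_flank_mismatch_per_arm
                    )
                else:
                    ok = left_mm + right_mm <= cfg.max_flank_mismatch_per_arm
                if not ok:
                    continue
                seen.add(key)
                hits.append(
                    ProbeHit(
                        probe_id=probe.probe_id,
                        target_id=target_id,
                        chrom=chrom,
                        pos=start + flank + 1,
                        strand=strand,
                        called_allele=allele,
                        left_mm=left_mm,
                        right_mm=right_mm,
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.pos, h.strand))
    return hits


def call_probe(hits: list[ProbeHit], cfg: AlignConfig | None = None) -> ProbeHit | NoCall:
    """Single surviving placement -> the call; zero -> absent; several ->
    ambiguous (unless uniqueness is waived, when the fewest-mismatch hit
    wins)."""
    cfg = cfg or AlignConfig()
    if not hits:
        return NoCall("absent")
    if len(hits) == 1:
        return hits[0]
    if cfg.require_unique:
        return NoCall("ambiguous")
    return min(hits, key=lambda h: (h.left_mm + h.right_mm, h.chrom, h.pos, h.strand))


def partition_by_prefix(chrom_names: list[str], labels: tuple[str, ...] = ("A", "B")) -> dict[str, str]:
    """Default subgenome partition: leading character of the chromosome name."""
    partition = {}
    for name in chrom_names:
        if not name or name[0] not in labels:
            raise ValueError(f"cannot infer subgenome of chromosome {name!r}")
        partition[name] = name[0]
    return partition


def single_partition(chrom_names: list[str], label: str = "A") -> dict[str, str]:
    """Whole-genome (diploid) partition under one label."""
    return {name: label for name in chrom_names}


def read_partition(path: str) -> dict[str, str]:
    """Read a ``chrom<TAB>label`` partition TSV."""
    partition = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, label = line.split("\t")[:2]
            partition[chrom] = label
    return partition


def genotype_genome(
    probes: list[ProbeRecord],
    genome: dict[str, bytes],
    partition: dict[str, str],
    cfg: AlignConfig | None = None,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Genotype every probe against each subgenome partition separately.

    Returns a marker x column call matrix with one column per subgenome
    label, named ``<sample>_<label>``. Assemblies are haploid, so each
    call is a homozygous base or the missing sentinel. Uniqueness is
    evaluated within each partition, not across the whole genome.
    """
    cfg = cfg or AlignConfig()
    missing = set(genome) - set(partition)
    if missing:
        raise ValueError(f"chromosomes absent from partition: {sorted(missing)}")
    labels = sorted(set(partition[c] for c in genome))
    columns = {}
    n_ambiguous = 0
    for label in labels:
        chroms = {c: s for c, s in genome.items() if partition[c] == label}
        by_len: dict[int, GenomeIndex] = {}
        calls = []
        for probe in probes:
            idx = by_len.get(probe.length)
            if idx is None:
                idx = GenomeIndex(chroms, probe.length, cfg.max_total_mismatches + 1)
                by_len[probe.length] = idx
            hits = find_placements(
                probe, chroms, cfg, target_id=f"{sample_id}_{label}", index=idx
            )
            call = call_probe(hits, cfg)
            if isinstance(call, NoCall):
                if call.reason == "ambiguous":
                    n_ambiguous += 1
                calls.append(MISSING)
            else:
                calls.append(call.called_allele)
        columns[f"{sample_id}_{label}"] = calls
    if n_ambiguous:
        logger.info(
            "genotype_genome(%s): %d ambiguous probe placements -> missing",
            sample_id,
            n_ambiguous,
        )
    df = pd.DataFrame(columns, index=[p.probe_id for p in probes])
    df.index.name = "probe_id"
    return df


def hits_to_frame(hits: list[ProbeHit]) -> pd.DataFrame:
    """Hits as a TSV-ready table."""
    return pd.DataFrame(
        [
            (h.probe_id, h.target_id, h.chrom, h.pos, h.strand, h.called_allele, h.left_mm, h.right_mm)
            for h in hits
        ],
        columns=["probe_id", "target", "chrom", "pos", "strand", "allele", "left_mm", "right_mm"],
    )
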