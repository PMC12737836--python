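"""Synthetic allopolyploid study generator with known ground truth.

The generative model mirrors the statistical structure that the downstream
analyses assume. A random proto-genome diverges by independent
substitutions (no indels, so coordinates stay homologous panel-wide) into
an A-lineage and a B-lineage ancestor; each ancestor radiates into several
diploid species (a star), and each species into several accessions
(another star). One allotetraploid then forms by a single hybridization:
the genome of one chosen A accession (chromosomes renamed ``A01..``) joined
with one chosen B accession (``B01..``), followed by a small amount of
post-hybridization mutation and, optionally, homoeologous-exchange
replacements between subgenomes. Several tetraploid individuals may share
that one origin, each accumulating its own mutations.

Array probes are designed at sites segregating within each diploid pool,
with flanks copied from the pool ancestor and guaranteed unique there.
Array genotype calls are the true bases at the probe sites, degraded by a
configurable missing rate and allele-flip error rate. A TruthSet records
the parents, the generating tree, true variants, and genic intervals, so
parameter recovery can be scored exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .probes import ProbeRecord
from .windows import VariantRecord, read_bed, read_vcf, write_bed, write_vcf

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_LETTER = "ACGT"

Genome = dict[str, np.ndarray]  # chrom -> uint8 base codes 0..3


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic panel.

    Divergences are expected substitutions per site along the respective
    branches: ``proto_divergence`` separates the A and B pool ancestors
    (half per branch), ``species_divergence`` is the pool-ancestor to
    species branch, ``accession_divergence`` the species to accession
    branch, and ``tetraploid_mutation`` accrues after hybridization.
    ``he_segments`` lists homoeologous-exchange replacements as
    ``(subgenome_from, chrom_index, start, end)`` half-open 0-based spans
    copied onto the sister subgenome at homologous coordinates.
    """

    seed: int = 0
    n_chrom_per_subgenome: int = 2
    chrom_length: int = 200_000
    proto_divergence: float = 0.03
    n_species_a: int = 4
    n_species_b: int = 2
    species_divergence: float = 0.01
    n_accessions_per_species: int = 5
    accession_divergence: float = 0.002
    tetraploid_mutation: float = 0.0005
    n_tetraploids: int = 2
    he_segments: tuple[tuple[str, int, int, int], ...] = ()
    n_probes_per_subgenome: int = 800
    flank_length: int = 35
    array_missing_rate: float = 0.01
    array_error_rate: float = 0.0
    genic_fraction: float = 0.3

    def __post_init__(self) -> None:
        rates = {
            "proto_divergence": self.proto_divergence,
            "species_divergence": self.species_divergence,
            "accession_divergence": self.accession_divergence,
            "tetraploid_mutation": self.tetraploid_mutation,
            "array_missing_rate": self.array_missing_rate,
            "array_error_rate": self.array_error_rate,
            "genic_fraction": self.genic_fraction,
        }
        for name, r in rates.items():
            if not 0 <= r < 1:
                raise ValueError(f"{name} must be in [0, 1), got {r}")
        if self.chrom_length <= 2 * self.flank_length + 1:
            raise ValueError("chrom_length must exceed the probe length")
        seen: dict[tuple[str, int], list[tuple[int, int]]] = {}
        for sub, ci, start, end in self.he_segments:
            if sub not in ("A", "B"):
                raise ValueError(f"he_segment subgenome must be A or B, got {sub!r}")
            if not 1 <= ci <= self.n_chrom_per_subgenome:
                raise ValueError(f"he_segment chromosome index {ci} out of range")
            if not 0 <= start < end <= self.chrom_length:
                raise ValueError(f"he_segment span [{start}, {end}) out of range")
            for s, e in seen.setdefault((sub, ci), []):
                if start < e and s < end:
                    raise ValueError("overlapping he_segments")
            seen[(sub, ci)].append((start, end))


@dataclass
class TruthSet:
    """Ground truth of one simulated study."""

    parent_a_id: str
    parent_b_id: str
    true_tree: str  # Newick over diploid accessions + dissected tetraploid tips
    true_variants: list[VariantRecord]
    variant_lineages: list[str]
    genic_bed: list[tuple[str, int, int]]
    probe_truth: dict[str, tuple[str, int, str, str]]  # id -> (chrom, pos, anc, der)
    chrom_lengths: dict[str, int] = field(default_factory=dict)


def _mutate(genome: Genome, rate: float, rng: np.random.Generator) -> Genome:
    """Substitution-only mutation: each site changes with probability
    ``rate`` to one of the three other bases, uniformly."""
    out = {}
    for chrom, codes in genome.items():
        codes = codes.copy()
        mask = rng.random(codes.size) < rate
        n = int(mask.sum())
        if n:
            codes[mask] = (codes[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
        out[chrom] = codes
    return out


def genome_to_bytes(genome: Genome) -> dict[str, bytes]:
    """Letter-sequence view consumed by the probe genotyper."""
    return {chrom: _BASES[codes].tobytes() for chrom, codes in genome.items()}


def write_fasta(genome: Genome, path: str) -> None:
    records = [
        SeqRecord(Seq(_BASES[codes].tobytes().decode()), id=chrom, description="")
        for chrom, codes in genome.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, bytes]:
    return {
        rec.id: str(rec.seq).upper().encode() for rec in SeqIO.parse(path, "fasta")
    }


def _kmer_counts(codes_list: list[np.ndarray], k: int) -> dict[int, int]:
    """Occurrence counts of every k-mer, forward and reverse complement.

    Hashes are 2-bit Horner codes wrapped mod 2**64 (k may exceed 32
    bases); a wrap collision can only over-count, i.e. conservatively
    reject a candidate flank as non-unique.
    """
    counts: dict[int, int] = {}
    for codes in codes_list:
        for strand in (codes, (3 - codes)[::-1]):
            n = strand.size - k + 1
            h = strand[:n].astype(np.uint64)
            four = np.uint64(4)
            for j in range(1, k):
                h = h * four + strand[j : j + n]
            uniq, cnt = np.unique(h, return_counts=True)
            for u, c in zip(uniq.tolist(), cnt.tolist()):
                counts[u] = counts.get(u, 0) + c
    return counts


def _hash(codes: np.ndarray) -> int:
    h = 0
    for c in codes:
        h = (h * 4 + int(c)) & 0xFFFFFFFFFFFFFFFF
    return h


def _design_probes(
    pool: str,
    ancestor: Genome,
    accessions: dict[str, Genome],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[ProbeRecord], dict[str, tuple[str, int, str, str]]]:
    """Probes at biallelic sites segregating within one diploid pool.

    Flanks come from the pool ancestor and must be unique there (forward
    plus reverse complement); probe footprints never overlap.
    """
    flank = cfg.flank_length
    kcounts = _kmer_counts(list(ancestor.values()), flank)
    stacks = {
        chrom: np.stack([g[chrom] for g in accessions.values()])
        for chrom in ancestor
    }
    candidates = []
    for chrom, arr in stacks.items():
        lo = arr.min(axis=0)
        hi = arr.max(axis=0)
        anc = ancestor[chrom]
        biallelic = (
            (lo != hi)
            & ((arr == lo) | (arr == hi)).all(axis=0)
            & ((anc == lo) | (anc == hi))
        )
        positions = np.flatnonzero(biallelic)
        positions = positions[(positions >= flank) & (positions < arr.shape[1] - flank)]
        candidates.extend((chrom, int(p)) for p in positions)
    rng.shuffle(candidates)

    probes: list[ProbeRecord] = []
    truth: dict[str, tuple[str, int, str, str]] = {}
    occupied: dict[str, list[int]] = {chrom: [] for chrom in ancestor}
    span = 2 * flank  # two sites closer than this have overlapping footprints
    for chrom, p in candidates:
        if len(probes) == cfg.n_probes_per_subgenome:
            break
        if any(abs(p - q) <= span for q in occupied[chrom]):
            continue
        anc = ancestor[chrom]
        left = anc[p - flank : p]
        right = anc[p + 1 : p + 1 + flank]
        if kcounts[_hash(left)] != 1 or kcounts[_hash(right)] != 1:
            continue
        arr = stacks[chrom][:, p]
        alleles = sorted(set(arr.tolist()))
        ancestral = int(anc[p])
        derived = alleles[0] if alleles[1] == ancestral else alleles[1]
        probe_id = f"{pool}_{chrom}_{p + 1}"
        probes.append(
            ProbeRecord(
                probe_id=probe_id,
                left_flank=_BASES[left].tobytes().decode(),
                allele1=_LETTER[ancestral],
                allele2=_LETTER[derived],
                right_flank=_BASES[right].tobytes().decode(),
            )
        )
        truth[probe_id] = (chrom, p + 1, _LETTER[ancestral], _LETTER[derived])
        occupied[chrom].append(p)
    if len(probes) < cfg.n_probes_per_subgenome:
        raise ValueError(
            f"pool {pool}: requested {cfg.n_probes_per_subgenome} probes but only "
            f"{len(probes)} placeable segregating sites"
        )
    return probes, truth


def _genic_intervals(
    chrom_lengths: dict[str, int], fraction: float, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Alternating genic/intergenic spans covering ~``fraction`` of the genome."""
    if fraction == 0:
        return []
    genic_mean = 2000.0
    inter_mean = genic_mean * (1 - fraction) / fraction
    intervals = []
    for chrom, length in chrom_lengths.items():
        pos = int(rng.exponential(inter_mean / 2))
        while pos < length:
            span = max(200, int(rng.exponential(genic_mean)))
            end = min(pos + span, length)
            intervals.append((chrom, pos, end))
            pos = end + max(200, int(rng.exponential(inter_mean)))
    return intervals


def _true_tree(
    accession_ids: dict[str, dict[str, list[str]]],
    parent_a: str,
    parent_b: str,
    tet_tips: dict[str, list[str]],
    cfg: SimulationConfig,
) -> str:
    """Generating topology as Newick; the tetraploid subgenome tips attach
    at the parent accession (single shared origin)."""

    def acc_clause(pool: str, acc: str) -> str:
        parent = parent_a if pool == "A" else parent_b
        if acc == parent:
            tets = ",".join(
                f"{t}:{cfg.tetraploid_mutation}" for t in tet_tips[pool]
            )
            return f"({acc}:0.0,{tets}):{cfg.accession_divergence}"
        return f"{acc}:{cfg.accession_divergence}"

    pool_clauses = []
    for pool in ("A", "B"):
        species_clauses = []
        for sp, accs in accession_ids[pool].items():
            inner = ",".join(acc_clause(pool, a) for a in accs)
            species_clauses.append(f"({inner}):{cfg.species_divergence}")
        pool_clauses.append(
            f"({','.join(species_clauses)}):{cfg.proto_divergence / 2}"
        )
    return f"({pool_clauses[0]},{pool_clauses[1]});"


def simulate_panel(config: SimulationConfig):
    """Generate genomes, probes, array calls and truth for one study.

    Returns ``(genomes, probes, array_calls, truth)`` where genomes maps
    sample id to a chromosome dict, ``array_calls`` is a marker x diploid
    sample DataFrame of IUPAC calls (``N`` missing), and truth is a
    :class:`TruthSet`. Byte-identical for identical config and seed.
    """
    import pandas as pd

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom_per_subgenome)]
    proto = {c: rng.integers(0, 4, cfg.chrom_length, dtype=np.uint8) for c in chroms}
    ancestors = {
        pool: _mutate(proto, cfg.proto_divergence / 2, rng) for pool in ("A", "B")
    }

    n_species = {"A": cfg.n_species_a, "B": cfg.n_species_b}
    accession_ids: dict[str, dict[str, list[str]]] = {"A": {}, "B": {}}
    genomes: dict[str, Genome] = {}
    for pool in ("A", "B"):
        for si in range(1, n_species[pool] + 1):
            sp_id = f"{pool}{si}"
            sp_genome = _mutate(ancestors[pool], cfg.species_divergence, rng)
            accs = []
            for ai in range(1, cfg.n_accessions_per_species + 1):
                acc_id = f"{pool}{si}_acc{ai}"
                genomes[acc_id] = _mutate(sp_genome, cfg.accession_divergence, rng)
                accs.append(acc_id)
            accession_ids[pool][sp_id] = accs

    diploid_ids = [a for pool in ("A", "B") for sp in accession_ids[pool].values() for a in sp]
    a_accs = [a for sp in accession_ids["A"].values() for a in sp]
    b_accs = [a for sp in accession_ids["B"].values() for a in sp]
    parent_a = str(rng.choice(a_accs))
    parent_b = str(rng.choice(b_accs))

    # one hybridization event; each tetraploid then mutates independently
    hybrid: Genome = {}
    for i, c in enumerate(chroms, start=1):
        hybrid[f"A{i:02d}"] = genomes[parent_a][c]
        hybrid[f"B{i:02d}"] = genomes[parent_b][c]
    tet_ids = [f"tet{i + 1}" for i in range(cfg.n_tetraploids)]
    for tid in tet_ids:
        tet = _mutate(hybrid, cfg.tetraploid_mutation, rng)
        for sub, ci, start, end in cfg.he_segments:
            src = f"{sub}{ci:02d}"
            dst = f"{'B' if sub == 'A' else 'A'}{ci:02d}"
            tet[dst][start:end] = tet[src][start:end]
        genomes[tid] = tet

    # probes per pool, then array calls for the diploid panel
    pool_accessions = {
        "A": {a: genomes[a] for a in a_accs},
        "B": {a: genomes[a] for a in b_accs},
    }
    probes: list[ProbeRecord] = []
    probe_truth: dict[str, tuple[str, int, str, str]] = {}
    for pool in ("A", "B"):
        p, t = _design_probes(pool, ancestors[pool], pool_accessions[pool], cfg, rng)
        probes.extend(p)
        probe_truth.update(t)

    calls = np.empty((len(probes), len(diploid_ids)), dtype="<U1")
    sites = [(probe_truth[p.probe_id][0], probe_truth[p.probe_id][1] - 1) for p in probes]
    for j, acc in enumerate(diploid_ids):
        g = genomes[acc]
        calls[:, j] = [_LETTER[g[chrom][pos]] for chrom, pos in sites]
    # allele-flip errors (only where the true base is a probe allele), then missingness
    if cfg.array_error_rate > 0:
        flip = rng.random(calls.shape) < cfg.array_error_rate
        for i, probe in enumerate(probes):
            for j in np.flatnonzero(flip[i]):
                if calls[i, j] == probe.allele1:
                    calls[i, j] = probe.allele2
                elif calls[i, j] == probe.allele2:
                    calls[i, j] = probe.allele1
    miss = rng.random(calls.shape) < cfg.array_missing_rate
    calls[miss] = "N"
    array_calls = pd.DataFrame(
        calls, index=[p.probe_id for p in probes], columns=diploid_ids
    )
    array_calls.index.name = "probe_id"

    # truth: variants of two A-pool candidate lineages vs the first
    # tetraploid's A subgenome, in tetraploid-A coordinates
    parent_sp = next(
        sp for sp, accs in accession_ids["A"].items() if parent_a in accs
    )
    other_pool = [a for sp, accs in accession_ids["A"].items() if sp != parent_sp for a in accs]
    other_lineage = str(rng.choice(other_pool))
    lineages = [parent_a, other_lineage]
    ref_tet = genomes[tet_ids[0]]
    a_chrom_lengths = {
        f"A{i:02d}": cfg.chrom_length for i in range(1, cfg.n_chrom_per_subgenome + 1)
    }
    true_variants: list[VariantRecord] = []
    for i, c in enumerate(chroms, start=1):
        tchrom = f"A{i:02d}"
        ref = ref_tet[tchrom]
        lin = [genomes[l][c] for l in lineages]
        diff = np.flatnonzero((lin[0] != ref) | (lin[1] != ref))
        for p in diff.tolist():
            r = int(ref[p])
            alts: list[str] = []
            gts: dict[str, int | None] = {}
            for name, g in zip(lineages, lin):
                b = int(g[p])
                if b == r:
                    gts[name] = 0
                else:
                    letter = _LETTER[b]
                    if letter not in alts:
                        alts.append(letter)
                    gts[name] = alts.index(letter) + 1
            true_variants.append(
                VariantRecord(tchrom, p + 1, _LETTER[r], tuple(alts), gts)
            )

    genic = _genic_intervals(a_chrom_lengths, cfg.genic_fraction, rng)
    tet_tips = {
        "A": [f"{t}_A" for t in tet_ids],
        "B": [f"{t}_B" for t in tet_ids],
    }
    tree = _true_tree(accession_ids, parent_a, parent_b, tet_tips, cfg)
    truth = TruthSet(
        parent_a_id=parent_a,
        parent_b_id=parent_b,
        true_tree=tree,
        true_variants=true_variants,
        variant_lineages=lineages,
        genic_bed=genic,
        probe_truth=probe_truth,
        chrom_lengths=a_chrom_lengths,
    )
    return genomes, probes, array_calls, truth


def write_truth(truth: TruthSet, outdir: str) -> None:
    """Persist the truth bundle (Newick, VCF v4.2, BED3, TSVs)."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "true_tree.nwk"), "w") as fh:
        fh.write(truth.true_tree + "\n")
    write_vcf(
        truth.true_variants,
        truth.variant_lineages,
        os.path.join(outdir, "true_variants.vcf"),
        contig_lengths=truth.chrom_lengths,
    )
    write_bed(truth.genic_bed, os.path.join(outdir, "genic.bed"))
    with open(os.path.join(outdir, "parents.tsv"), "w") as fh:
        fh.write(f"parent_A\t{truth.parent_a_id}\nparent_B\t{truth.parent_b_id}\n")
    with open(os.path.join(outdir, "probe_truth.tsv"), "w") as fh:
        fh.write("probe_id\tchrom\tpos\tancestral\tderived\n")
        for pid, (chrom, pos, anc, der) in truth.probe_truth.items():
            fh.write(f"{pid}\t{chrom}\t{pos}\t{anc}\t{der}\n")
    with open(os.path.join(outdir, "chrom_lengths.tsv"), "w") as fh:
        for chrom, length in truth.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_truth(outdir: str) -> TruthSet:
    """Parse a truth bundle written by :func:`write_truth`."""
    with open(os.path.join(outdir, "true_tree.nwk")) as fh:
        tree = fh.read().strip()
    parents = {}
    with open(os.path.join(outdir, "parents.tsv")) as fh:
        for line in fh:
            key, val = line.strip().split("\t")
            parents[key] = val
    probe_truth = {}
    with open(os.path.join(outdir, "probe_truth.tsv")) as fh:
        next(fh)
        for line in fh:
            pid, chrom, pos, anc, der = line.strip().split("\t")
            probe_truth[pid] = (chrom, int(pos), anc, der)
    chrom_lengths = {}
    with open(os.path.join(outdir, "chrom_lengths.tsv")) as fh:
        for line in fh:
            chrom, length = line.strip().split("\t")
            chrom_lengths[chrom] = int(length)
    vcf_path = os.path.join(outdir, "true_variants.vcf")
    variants = read_vcf(vcf_path)
    lineages = []
    with open(vcf_path) as fh:
        for line in fh:
            if line.startswith("#CHROM"):
                lineages = line.rstrip("\n").split("\t")[9:]
                break
    return TruthSet(
        parent_a_id=parents["parent_A"],
        parent_b_id=parents["parent_B"],
        true_tree=tree,
        true_variants=variants,
        variant_lineages=lineages,
        genic_bed=read_bed(os.path.join(outdir, "genic.bed")),
        probe_truth=probe_truth,
        chrom_lengths=chrom_lengths,
    )
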