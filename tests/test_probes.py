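"""Tests of probe parsing and the in-silico placement search."""

import numpy as np
import pytest

from _oracles import brute_force_placements
from polyorigin.iupac import MISSING
from polyorigin.probes import (
    AlignConfig,
    GenomeIndex,
    NoCall,
    ProbeHit,
    ProbeRecord,
    call_probe,
    expand_alleles,
    find_placements,
    genotype_genome,
    parse_probe_sequence,
    parse_probes,
    partition_by_prefix,
    revcomp,
    single_partition,
)

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


def random_probe(rng, flank=35, probe_id="p"):
    a1, a2 = rng.choice(list(BASES), size=2, replace=False)
    return ProbeRecord(
        probe_id, random_seq(rng, flank), str(a1), str(a2), random_seq(rng, flank)
    )


def plant(genome_str, probe, offset, allele=1, mutations=()):
    """Insert an allele sequence at ``offset`` with optional 0-based
    substitutions (position within the 71-mer, replacement base)."""
    seq = list(expand_alleles(probe)[allele - 1])
    for pos, base in mutations:
        seq[pos] = base
    seq = "".join(seq)
    return genome_str[:offset] + seq + genome_str[offset + len(seq):]


# ---------------------------------------------------------------- parsing


def test_parse_bracket_notation_and_expansion():
    p = parse_probe_sequence("AX-1", "CAGTCAGT[A/C]CAGTCAGT")
    assert (p.left_flank, p.allele1, p.allele2, p.right_flank) == (
        "CAGTCAGT", "A", "C", "CAGTCAGT",
    )
    assert expand_alleles(p) == ("CAGTCAGTACAGTCAGT", "CAGTCAGTCCAGTCAGT")


def test_expand_empty_flanks():
    p = parse_probe_sequence("p", "[A/C]")
    assert expand_alleles(p) == ("A", "C")


def test_expansion_reverse_complement_symmetry():
    rng = np.random.default_rng(0)
    p = random_probe(rng, flank=10)
    rc_probe = ProbeRecord(
        "rc",
        revcomp(p.right_flank),
        revcomp(p.allele1),
        revcomp(p.allele2),
        revcomp(p.left_flank),
    )
    assert revcomp(expand_alleles(p)[0]) == expand_alleles(rc_probe)[0]


def test_parse_probes_drops_duplicates_and_short_flanks(tmp_path):
    rng = np.random.default_rng(1)
    good = random_probe(rng, 35, "keep")
    dup = random_probe(rng, 35, "twice")
    short = random_probe(rng, 20, "short")
    path = tmp_path / "probes.tsv"
    path.write_text(
        "".join(
            f"{p.probe_id}\t{p.sequence}\n" for p in (good, dup, dup, short)
        )
    )
    kept = parse_probes(str(path), flank_length=35)
    assert [p.probe_id for p in kept] == ["keep"]


def test_parse_errors():
    with pytest.raises(ValueError, match="malformed"):
        parse_probe_sequence("p", "ACGTACGT")
    with pytest.raises(ValueError, match="malformed"):
        parse_probe_sequence("p", "AC[GT]AC")
    with pytest.raises(ValueError, match="non-ACGT"):
        parse_probe_sequence("p", "ACNT[A/C]ACGT")
    with pytest.raises(ValueError, match="identical"):
        parse_probe_sequence("p", "ACGT[A/A]ACGT")


# ---------------------------------------------------------------- placement


def test_exact_planting_coordinates():
    rng = np.random.default_rng(2)
    probe = random_probe(rng)
    genome = {"A01": plant(random_seq(rng, 5000), probe, 1000).encode()}
    hits = find_placements(probe, genome)
    assert len(hits) == 1
    h = hits[0]
    assert (h.chrom, h.pos, h.strand, h.called_allele) == ("A01", 1036, "+", probe.allele1)
    assert (h.left_mm, h.right_mm) == (0, 0)


def test_minus_strand_planting():
    rng = np.random.default_rng(3)
    probe = random_probe(rng)
    seq2 = expand_alleles(probe)[1]
    base = random_seq(rng, 5000)
    genome = {"chr": (base[:2000] + revcomp(seq2) + base[2071:]).encode()}
    hits = find_placements(probe, genome)
    assert len(hits) == 1
    h = hits[0]
    assert (h.pos, h.strand, h.called_allele) == (2036, "-", probe.allele2)


def test_two_flank_mismatches_in_one_arm_rejected():
    rng = np.random.default_rng(4)
    probe = random_probe(rng)
    mut = [(i, _other(probe, i)) for i in (3, 7)]  # both in the left arm
    genome = {"c": plant(random_seq(rng, 3000), probe, 500, mutations=mut).encode()}
    assert find_placements(probe, genome) == []
    assert find_placements(probe, genome) == brute_force_placements(probe, genome)


def test_one_mismatch_per_arm_accepted_but_not_under_total_scope():
    rng = np.random.default_rng(5)
    probe = random_probe(rng)
    mut = [(3, _other(probe, 3)), (40, _other(probe, 40))]  # one per arm
    genome = {"c": plant(random_seq(rng, 3000), probe, 500, mutations=mut).encode()}
    hits = find_placements(probe, genome)
    assert len(hits) == 1
    assert (hits[0].left_mm, hits[0].right_mm) == (1, 1)
    total = AlignConfig(max_flank_mismatch_per_arm=1, mismatch_scope="total")
    assert find_placements(probe, genome, total) == []


def _other(probe, i):
    seq = expand_alleles(probe)[0]
    return "C" if seq[i] != "C" else "G"


def test_multi_locus_planting_yields_two_hits_then_no_call():
    rng = np.random.default_rng(6)
    probe = random_probe(rng)
    g = random_seq(rng, 6000)
    g = plant(plant(g, probe, 300), probe, 4200, allele=2)
    genome = {"c": g.encode()}
    hits = find_placements(probe, genome)
    assert len(hits) == 2
    assert hits == brute_force_placements(probe, genome)
    assert call_probe(hits) == NoCall("ambiguous")


def test_call_probe_absent_and_single():
    assert call_probe([]) == NoCall("absent")
    h = ProbeHit("p", "g", "c", 36, "+", "A", 0, 0)
    assert call_probe([h]) is h


def test_placements_match_exhaustive_scan_on_random_probes():
    """Randomized agreement with the exhaustive-scan oracle, including
    planted 0/1/2-mismatch and reverse-strand cases."""
    rng = np.random.default_rng(7)
    genome_str = random_seq(rng, 2000)
    for trial in range(30):
        probe = random_probe(rng, probe_id=f"p{trial}")
        g = genome_str
        kind = trial % 5
        if kind == 1:
            g = plant(g, probe, 700)
        elif kind == 2:
            g = plant(g, probe, 700, mutations=[(2, _other(probe, 2))])
        elif kind == 3:
            g = plant(g, probe, 700, mutations=[(2, _other(probe, 2)), (5, _other(probe, 5))])
        elif kind == 4:
            seq = expand_alleles(probe)[1]
            g = g[:700] + revcomp(seq) + g[700 + len(seq):]
        genome = {"c1": g.encode(), "c2": random_seq(rng, 1500).encode()}
        expected = brute_force_placements(probe, genome)
        assert find_placements(probe, genome) == expected
        for h in expected:
            assert h.left_mm <= 1 and h.right_mm <= 1


def test_prepending_novel_sequence_shifts_positions():
    rng = np.random.default_rng(8)
    probe = random_probe(rng)
    g = plant(random_seq(rng, 4000), probe, 1500)
    prefix = random_seq(rng, 1000)
    hits = find_placements(probe, {"c": g.encode()})
    shifted = find_placements(probe, {"c": (prefix + g).encode()})
    assert [(h.pos + 1000, h.strand) for h in hits] == [
        (h.pos, h.strand) for h in shifted
    ]


def test_strand_invariance_of_genotyping():
    """Reverse-complementing every chromosome leaves the emitted calls
    unchanged."""
    rng = np.random.default_rng(9)
    probes = [random_probe(rng, probe_id=f"p{i}") for i in range(8)]
    g = random_seq(rng, 8000)
    for i, p in enumerate(probes[:4]):
        g = plant(g, p, 200 + 400 * i, allele=1 + i % 2)
    genome = {"A01": g.encode()}
    flipped = {"A01": revcomp(g).encode()}
    part = single_partition(["A01"])
    calls_fwd = genotype_genome(probes, genome, part, sample_id="s")
    calls_rev = genotype_genome(probes, flipped, part, sample_id="s")
    assert calls_fwd.equals(calls_rev)
    assert (calls_fwd["s_A"] != MISSING).sum() >= 4


def test_subgenome_dissection_independence():
    """A probe placing once in each subgenome is ambiguous genome-wide
    but calls cleanly in both columns under dissection."""
    rng = np.random.default_rng(10)
    probe = random_probe(rng)
    ga = plant(random_seq(rng, 3000), probe, 500)
    gb = plant(random_seq(rng, 3000), probe, 1200, allele=2)
    genome = {"A01": ga.encode(), "B01": gb.encode()}
    whole = genotype_genome([probe], genome, single_partition(["A01", "B01"], "G"), sample_id="t")
    assert whole.loc[probe.probe_id, "t_G"] == MISSING
    split = genotype_genome([probe], genome, partition_by_prefix(["A01", "B01"]), sample_id="t")
    assert split.loc[probe.probe_id, "t_A"] == probe.allele1
    assert split.loc[probe.probe_id, "t_B"] == probe.allele2


def test_partition_must_cover_fasta():
    rng = np.random.default_rng(11)
    probe = random_probe(rng)
    genome = {"A01": random_seq(rng, 500).encode(), "Z9": random_seq(rng, 500).encode()}
    with pytest.raises(ValueError, match="absent from partition"):
        genotype_genome([probe], genome, {"A01": "A"})


def test_index_rejects_wrong_probe_length():
    rng = np.random.default_rng(12)
    genome = {"c": random_seq(rng, 500).encode()}
    idx = GenomeIndex(genome, probe_length=71, n_segments=3)
    short = random_probe(rng, flank=10)
    with pytest.raises(ValueError, match="different probe length"):
        find_placements(short, genome, index=idx)
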