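# Methods

`polyorigin` answers one question: given an allopolyploid whose genome is
the union of two diverged subgenomes (A and B), which accessions in a
panel of wild diploids are the closest living relatives of each
subgenome? The package implements the full inference chain — in-silico
array genotyping of assemblies, subgenome dissection, concordance
checking, panel merging and filtering, identity-by-state (IBS) and PCA
relatedness, distance trees with bootstrap support, and windowed
lineage-specific variant counts — and ships a synthetic study generator
with known ground truth so the whole chain can be validated end to end.

## In-silico array genotyping

An array marker is modelled as a 71 bp probe: a central biallelic SNP
written `[X/Y]` with two 35 bp flanking arms. To genotype a genome
assembly, each probe is expanded into its two allele sequences and every
full-length, ungapped placement on either strand is enumerated. A
placement is valid when

* the central base exactly equals one of the two alleles (allele
  mismatches are rejected),
* each flank arm carries at most `max_flank_mismatch_per_arm` mismatches
  (default 1), and
* indels are excluded by construction (the model is ungapped).

A genotype is called only when exactly one valid placement survives.
Zero placements code as *absent*, two or more as *ambiguous*; both emit
the missing sentinel `N` but are distinguished in logs. For each call
the allele, 1-based SNP position, strand, and left/right arm mismatch
counts are recorded.

The per-site mismatch cap is read as *per arm* (left ≤ 1 AND right ≤ 1),
consistent with recording separate left/right counts; a `total` scope is
available as a configuration switch for the stricter reading.

The search is implemented as seed-and-verify: the probe is split into
`max_total_mismatches + 1` contiguous segments, so by pigeonhole any
placement within the budget matches at least one segment exactly.
Segment positions are looked up in a sorted 2-bit k-mer index of the
target chromosomes and candidates verified literally. The contract — not
the mechanism — is normative: results are identical to an exhaustive
scan of every offset and strand, and the test suite checks this
equivalence against an independent sliding-window implementation on
randomized and adversarially planted probes.

**Subgenome dissection.** For a polyploid, chromosomes are partitioned
into subgenomes (by default the leading `A`/`B` of the chromosome name)
and each partition is searched separately, emitting one call column per
subgenome (`<sample>_A`, `<sample>_B`). Uniqueness is evaluated *within*
a partition: at realistic A–B divergence a large fraction of probes also
place on the homoeologous chromosome, and whole-genome uniqueness would
veto most markers in the polyploid while dissection retains them.

## Concordance

Two call sets for the same accession (in-silico vs array) are compared
on the intersection of their markers. A marker matches iff the IUPAC
codes are identical; pairs with either call missing are excluded from
the denominator. This denominator choice makes the zero-noise identity
exact: placements that legitimately fail the flank filters produce `N`,
not disagreement. A partial-credit mode (shared allele = 0.5) exists but
is off by default.

## Panel merging and the three-step filter

The wild reference panel (array calls) and the dissected polyploid
columns are merged on the shared marker set, panel order preserved.
Pseudosequences are positionally defined over this shared ordered marker
list, so per-sample "alignment" is the identity by construction and no
realignment step is needed. Filtering then proceeds in three steps:

1. **polymorphic** — drop markers with fewer than two distinct
   non-missing calls (het vs hom counts as polymorphism, since assembly
   columns are haploid while array columns may be heterozygous);
2. **MAF** — drop markers whose minor allele frequency (allele copies:
   hom = 2, het = 1 + 1, missing skipped) is *strictly below* 0.05;
   markers with more than two observed alleles are dropped with a
   distinct reason code;
3. **missing data** — drop markers whose missing fraction exceeds 3%.
   A sample-axis mode is provided as a switch because "missing data per
   sample" is the other defensible reading; the marker axis is the
   default since the analysis-ready object is a marker set.

The filter report records the surviving count after each step and the
dropped ids per step; the pipeline is idempotent on its own output.

## Relatedness

Calls are encoded as dosage of the per-marker major allele (ties break
to the lexicographically smaller base — the choice only relabels the
axis and provably leaves all pairwise distances unchanged). Missing
dosages are mean-imputed per marker *for PCA only*; IBS and trees always
use raw calls, keeping the headline nearest-relative readout
imputation-free.

PCA "based on Euclidean distances" is computed by classical scaling:
Gower double-centering of −D²/2 and eigendecomposition. Because the
distances are Euclidean over real dosage vectors, this coincides with
ordinary PCA of the centered dosage matrix — eigenvalues exactly, scores
up to sign — and the test suite asserts that equivalence to 1e-8 against
a direct covariance eigendecomposition. Variance percentages are taken
over the positive eigenvalues; the number of retained components is the
smallest k whose cumulative variance strictly exceeds 80%.

IBS scores a marker pair as shared-allele count / 2 from the unordered
allele pairs of the IUPAC codes (A vs A → 1, A vs M → 0.5, A vs C → 0),
averaged over markers where both calls are non-missing. Nearest-neighbor
tables exclude all query samples from the candidate pool and break ties
by sample id.

## Trees

Tree distances are the complement of the mean IBS site score, sharing
the site scoring with the similarity matrix so the two readouts cannot
disagree about what a difference is. Trees are inferred by canonical
neighbor joining (Q-criterion, Studier–Keppler updates), which is exact
on additive matrices — the property the test oracle exploits by
reconstructing randomly generated trees from their path-length matrices.
Negative branch-length estimates are clamped to zero (the deficit moves
to the sibling branch so the joined path length is preserved) and the
clamp count is logged.

Support values are nonparametric bootstraps: marker columns are
resampled with replacement, a replicate tree is built per resample, and
each internal edge's support is the fraction of replicates containing
the same bipartition. At panel scale, distance methods are adequate
for SNP pseudosequences with shallow divergence, and NJ admits the exact
additive-case oracle above; this is the package's one deliberate
methodological substitution for likelihood-based tree inference with
SH-like supports, whose support values are not numerically comparable —
only the qualitative maximal-support readout carries over.

`find_sister` reports, for a focal tip set that forms one side of an
edge, the smallest subtree meeting the stem edge on the far side (ties
by tip names). The pipeline's headline readout uses the related
*origin-clade* query: the smallest bipartition side containing the
dissected tips plus at least one wild accession, with that edge's
support. The origin clade is the right object for acceptance because the
polyploid individuals share a single origin: their post-hybridization
mutations are private, so the tips-only bipartition has true internal
length zero and its resolution is arbitrary, while the origin-clade edge
(tips + parent accession versus everything else) carries real signal.

## Lineage-specific variants in windows

Variants live in one reference coordinate system with a haploid genotype
column per compared lineage. A variant is focal-lineage-specific when
the focal lineage is explicitly called as an alternate allele and the
comparator explicitly as reference; missing calls disqualify in either
role, which makes the two directional classifications disjoint. Windows
tile each chromosome from 0 in half-open steps (2 Mb default, 100 kb for
fine grain), the last window truncated at the chromosome length; every
window is emitted, zeros included. Multi-bp variants are assigned to
regions and windows by their start position (pos − 1, 0-based) — one
unambiguous rule applied consistently, so genic restriction commutes
with counting. The largest-variant readout is the maximum reference-
allele span.

## The synthetic study generator

The generator reproduces the statistical structure the analysis assumes,
not the demographic history of any real system:

* a uniform-random proto-genome diverges by **substitutions only** into
  an A and a B pool ancestor (`proto_divergence` 0.03 split across the
  two branches), so coordinates stay homologous panel-wide and no
  alignment step is needed anywhere downstream;
* each pool ancestor radiates into species (star; `species_divergence`
  0.01 per branch; 4 A species, 2 B species) and each species into
  accessions (star; `accession_divergence` 0.002; 5 accessions each) —
  a star-of-stars, sufficient to create the nested clade structure the
  tree and IBS stages must recover, and *not* a coalescent model;
* one hybridization event joins a randomly chosen A accession and B
  accession into a tetraploid (chromosomes renamed `A01..`/`B01..`);
  each of the 2 tetraploid individuals then accumulates its own
  `tetraploid_mutation` 0.0005 substitutions per site, and optional
  homoeologous-exchange segments are copied across subgenomes at
  homologous coordinates;
* probes (800 per subgenome, 35 bp flanks) are designed at biallelic
  sites segregating within a pool, flanks copied from the pool ancestor
  and required to be unique there (forward + reverse complement), with
  non-overlapping footprints — isolating the aligner's multi-hit logic
  to dedicated tests;
* array calls are the true bases at probe sites per diploid accession,
  flipped to the other probe allele with probability `array_error_rate`
  (0 by default; flips only apply where the true base is a probe allele,
  matching biallelic array chemistry) and masked missing with
  probability `array_missing_rate` (0.01);
* the truth bundle records the parent ids, the generating tree (Newick),
  true variants of two candidate A-lineages against the first
  tetraploid's A subgenome (1-based VCF in tetraploid coordinates),
  genic intervals covering ~30% of the subgenome (alternating
  exponential genic/intergenic spans, mean genic span 2 kb), and each
  probe's true locus and alleles.

Default sizes are 2 chromosomes of 200 kb per subgenome — large enough
that divergences measured in the percent range give thousands of
segregating sites and stable recovery statistics, small enough that a
full study (simulation, dissected genotyping, filtering, IBS, PCA, and a
200-resample bootstrap tree) runs in a few seconds on one CPU. All
randomness flows from a single seeded generator; identical config and
seed give byte-identical outputs.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real data: recombination and incomplete lineage
sorting, indels and structural variants (coordinates are homologous by
construction), probe-design ascertainment bias, heterozygosity in the
wild panel (simulated diploids are fully selfed/homozygous), and
assembly errors. The zero-noise concordance identity, in particular, is
a property of the simulator's error model, not a claim about wet-lab
arrays.

One behaviour of the default conditions is worth knowing: at the default
divergences roughly 10% of probe×accession placements legitimately fail
the one-mismatch-per-arm flank filter, and roughly half the probes of
one subgenome also genotype the homoeologous partition of the tetraploid.
Both are features of the model being exercised (they are why the
concordance denominator excludes missing calls and why dissection is
per-partition), and they make the missing-data filter bite: a default
study retains a few hundred of the 1600 raw markers, which is ample for
parent recovery with maximal support.

## Numerical choices and degenerate inputs

* Placement search: 2-bit k-mer hashes are exact (injective) for the
  segment lengths in use; probe-design flank-uniqueness hashing wraps
  mod 2⁶⁴, where a collision can only conservatively reject a site.
* PCoA keeps eigenvalues above `1e-12·max(λ₁, 1)`; for genuinely
  Euclidean input the discarded negatives are numerical noise.
* NJ agglomeration breaks Q-ties by first scan position — deterministic
  under a fixed taxon order; bootstrap replicates reuse the input order.
* Bootstrap replicate pairs with zero comparable sites fall back to the
  largest distance in the replicate matrix (the full-data matrix must
  have all pairs comparable, or it is an error).
* Pairs with zero shared non-missing markers get a NaN similarity and
  are flagged via `n_compared`; empty marker intersections are errors.
* Empty variant sets: `max_variant_span` returns 0 with a warning;
  window tables always emit the full tiling.

## Known limitations

* The star-of-stars generator cannot produce discordant gene trees, so
  bootstrap supports on simulated data are optimistic relative to
  panels with introgression or lineage sorting.
* NJ with IBS-complement distances ignores rate heterogeneity among
  sites; supports are bootstrap proportions, not approximate-likelihood
  test values, and the two are not numerically comparable.
* The in-silico genotyper models assemblies as haploid: heterozygous
  calls can enter only through the array side of the panel.
* The orchestrated pipeline runs on simulated studies; real data flows
  through the per-stage CLI commands (`genotype-insilico`,
  `merge-filter`, `pca`, `ibs`, `tree`, `winvars`), which accept the
  standard formats (FASTA, probe TSV, calls TSV, VCF, BED, Newick).
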