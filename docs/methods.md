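# Methods

## Scope and data model

The package starts from *called* variants: a VCF 4.x with per-sample GT
plus a sidecar annotation TSV supplying gene symbol, deleterious class
(NS = non-synonymous, SS = splice acceptor/donor, Indel) and the
upstream caller's regional copy-number estimate. Read alignment, SNP
and CNV calling are upstream concerns. Coordinates are 1-based
inclusive; catalog membership is allele-aware on normalized
(chrom, pos, alt) keys, with indel alleles trimmed/left-aligned first —
the strictest reproducible matching rule, since position-only matching
would silently over-remove.

Pedigrees are loop-free (inbreeding loops are rejected at
construction); the exact likelihood machinery depends on that.

## Variant QC

A record is removed when any of four criteria fire: consensus quality
< 20; regional copy-number estimate ≥ 2 (a repeat/paralog proxy taken
from the input, never recomputed from reads); distance to the nearest
adjacent called SNP < 5 bp, evaluated within each carrier sample's call
set with *both* members of a too-close pair removed (the symmetric
reading); depth < 4 or > 500. Boundary values sit exactly as the
inequalities are written: quality 20, depth 4/500 and distance 5 are
retained, copy number 2.0 is removed. Records with missing QC metrics
are retained and flagged rather than guessed at. Counts are reported
per criterion (a record may increment several) and removal is counted
once, so the filter is idempotent.

## Novelty cascade and candidate-gene models

Stages are an ordered list of catalogs; each stage's survivors are the
records whose key the catalog lacks. Because stage filtering is set
subtraction, the *final* survivor set is order-independent while
per-stage counts are not — both properties are tested. After every
stage the report recounts, per affected sample and jointly:
NS/SS/Indel records carried (≥1 alt allele), homozygote records,
shared records (every affected carries), shared homozygotes (every
affected hom-alt), and compound-het records. "Observed in each
affected individual" is read as *alt-carrying*, not genotype-identical.
Records with class `other` (unannotated) never enter the cascade.

The compound-heterozygote rule is minimal by design: a gene qualifies
with ≥ 2 distinct records each heterozygous in all affected samples.
When parental genotypes are available (parents present as table
samples, or an explicit genotype map) the gene is kept only if a
*trans* configuration is possible — every parent carries at least one
of the gene's variants and no parent carries all of them; without
parental data the gene is flagged phase-unknown rather than dropped.

Unaffected relatives deliberately play no role in the cascade; their
evidence enters through the separate co-segregation check (mirroring a
study design where the cascade uses the sequenced affected siblings
and segregation is confirmed by Sanger typing of the whole family).
The shared-count column is an intersection at every row including the
input row.

## Co-segregation checks

Under the recessive model a single variant co-segregates when every
affected member is homozygous alternate and no unaffected or
unknown-status member is; the compound-het form requires every
affected heterozygous at both sites and no unaffected heterozygous at
both. Missing genotypes are uninformative, so adding a missing
genotype can never flip a verdict from true to false (tested as a
monotonicity property). Mendelian consistency of a biallelic site is
checked first; missing genotypes never violate.

## Linkage

**Disease model.** Autosomal recessive with disease allele frequency
1e-4 and penetrances (0, 0, 0.95) for 0/1/2 disease alleles. The
heterozygote penetrance and phenocopy rate are 0 by default but
configurable.

**Engine.** A Lander–Green HMM over inheritance vectors: one bit per
meiosis (two per non-founder) recording grandparental origin; 2^m
states for m meioses, bounded at 14 meioses by default. Marker
emission sums founder-allele assignments (restricted to assignments
compatible with observed founder genotypes) weighted by allele
frequencies; the disease locus is a latent biallelic locus whose
emission is the affection-status likelihood through the penetrance
vector. Transitions flip each bit independently with the interval's
recombination fraction; map distances convert via the sex-averaged
Haldane function θ = (1 − e^(−2d/100))/2. Likelihoods are accumulated
with per-locus rescaling in linear space and log10 bookkeeping; a zero
likelihood is reported as −∞ LOD, never an exception, and a marker
configuration with zero likelihood at θ = 1/2 (a Mendelian
inconsistency) raises a dedicated error.

**Two-point.** LOD(θ) = log10 L(θ) − log10 L(1/2) over the grid
{0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5}; LOD(1/2) is identically zero
because both terms are the same computation.

**Multipoint.** For each evaluation position (marker positions plus
interval midpoints by default) the disease locus is inserted into the
locus sequence and a full forward pass is run; the baseline is
P(markers) · P(phenotypes). A single-marker map reduces exactly to the
two-point score at that marker.

**Oracle.** An independent brute-force enumeration
(`mendelseek.bruteforce`) sums over founder multilocus diplotypes and
per-meiosis transmission patterns with genotype pruning (leaf
individuals are summed locally — plain distributivity). The HMM is
tested against it at 1e-9 relative tolerance on random small
pedigrees; the two share only the locus container.

**Closed form.** For the discovery-family shape (carrier × carrier
parents, four affected homozygous children, one unaffected carrier
child) with a fully informative co-segregating marker, the two-point
LOD at θ = 0 has the hand-derived closed form
3·log10 4 + log10(4/3.05) ≈ 1.9240: each affected child contributes
log10 4, the unaffected child log10(4/3.05) (3.05 = 0.05 + 1 + 1 + 1
summing the four transmission cases' unaffected weights), and the
phase-sum prefactor ¼ cancels one affected term. Parental disease
genotypes other than carrier × carrier enter at relative order of the
disease allele frequency, hence the 1e-3 test tolerance.

**Candidate region.** The maximal contiguous run of evaluation
positions attaining the maximum LOD (within 1e-6 by default), reported
with the nearest flanking markers and its cM width. The end-to-end
report uses a 1e-3 plateau tolerance instead: inheritance
configurations that are exactly tied under full informativeness differ
numerically at the order of the disease allele frequency (second-order
founder-genotype terms ~1e-6–1e-4 in LOD), far below any meaningful
LOD difference, and a tolerance below that scale fragments the plateau
arbitrarily.

**Founder allele frequencies.** Estimated by counting alleles over
genotyped founders. If every declared allele was seen, plain empirical
frequencies; otherwise one pseudocount is added to every declared
allele (one genotyped A/A founder with B declared gives 3/4, 1/4).
With no genotyped founder the caller must supply frequencies (the CLI
falls back to uniform).

## CNV co-segregation

Non-diploid segments are clustered across individuals by single-linkage
under reciprocal overlap ≥ 0.5 (configurable) with matching direction
(loss CN < 2 vs gain CN > 2); a cluster co-segregates when every
affected member contributes a segment and no unaffected genotyped
member does. The clustering rule is the package's own choice — array
CNV callers emit near-identical boundaries for the same event, which
single linkage handles well. For partially overlapping calls,
single-linkage splitting means the screen is only guaranteed monotone
in the overlap threshold for array-style (identical-or-disjoint)
segments; the monotonicity test generates exactly those.

## HGVS consequences

`c.<pos><ref>><alt>` substitutions (also the terser journal dialect
`c.493CT`); deletions/insertions/duplications are rejected as
unsupported. Codon arithmetic: position p lies in codon ⌈p/3⌉ at
within-codon offset ((p−1) mod 3)+1. Ref and alt codons translate by
the standard genetic code; a stop gain reports the truncated length
(codon index − 1). The bundled CDS is a *synthetic* 303-codon
transcript (not the real reference sequence) whose codons
130/147/165/207/236 are AAC/TGG/CTC/TAC/AGC — the codons consistent
with the five published substitution/protein pairs; for codon 130 both
AAC and AAT are consistent and AAC was chosen. A real CDS may be
supplied by path and is validated (ATG start, terminal stop, no
internal in-frame stop, length divisible by 3; overridable).

The printed-family fixtures encode each parent of the compound-het
families as a carrier of exactly one of the two variants — the only
configuration compatible with complete co-segregation under a fully
penetrant recessive model; parental genotypes were not tabulated in
the source, so this is an explicit assumption. The discovery family is
encoded non-consanguineous as drawn.

## Synthetic data generator

The generator reproduces the statistical structure the analyses
assume, not sequencing data. Defaults describe the emulated study:
the discovery-family template (2 founders, 5 offspring, 4 affected),
2000 background NS/SS/Indel variants, four catalogs with fractions
0.25 each, an 11-marker map spanning 20 cM (2 cM spacing) on one
chromosome with the disease locus mid-map at 10 cM, genotyping error
rate 0.

* **Ascertained templates** fix disease genotypes (parents carriers,
  affected children homozygous, unaffected children carriers) — this
  is conditioning on how such families come to clinical attention. The
  unascertained nuclear mode transmits freely and draws affection from
  penetrance; the penetrance-frequency property test (affected fraction
  0.25·0.95 among 10,000 carrier×carrier offspring) uses that mode.
* **Markers** default to 4 equifrequent alleles drawn per founder
  haplotype; transmission bits are walked outward from the disease
  locus with Haldane-model switch probabilities, which yields the
  correct Markov joint conditioned on the disease-locus transmission.
  The `fully_informative_markers` mode fixes distinct alleles per
  founder (CEPH-reference-style markers), making every grandparental
  origin observable; localization properties are stated under that
  mode, since with moderately informative markers a small family
  genuinely cannot always localize (founders homozygous at the
  flanking markers erase the signal — an honest feature of the design,
  not a defect).
* **Catalog membership**: if the per-catalog fractions sum to 1, every
  background variant is assigned to exactly one catalog (full
  coverage), which guarantees the planted gene is the unique
  shared-homozygote candidate after the last stage; otherwise
  membership is independent Bernoulli per catalog.
* **QC metrics** are drawn to pass by default; `qc_noise` plants
  failures of each criterion to exercise the filter.
* Compound-het planting puts one variant on each parent's disease
  haplotype, and a heterozygous child's carried variant follows its
  actual disease-locus transmission bit.

What the generator does *not* emulate: linkage disequilibrium between
background variants, allele-frequency spectra (genotypes are iid
Binomial with per-variant frequency 0.05–0.5), read-level artifacts,
population stratification in the catalogs. Passing tests therefore
show the *logic* of the pipeline is right under the stated model, not
that it is robust to real-data artifacts outside that model.

All randomness flows from one seeded generator; fixture bundles are
byte-identical per seed and carry a SHA-256 manifest.

## Problem sizes

The test suite and acceptance script run the cascade at 200–2000
background variants, linkage on the 7-member family (10 meioses, 1024
inheritance vectors) over 11-marker maps, engine-vs-enumeration checks
on ≤6-meiosis pedigrees with ≤3 markers plus the disease locus, and
recombination/penetrance calibrations at 10,000 meioses/offspring —
sizes at which every computation is exact and the whole suite runs in
well under a minute.

## Known limitations

Loop-free pedigrees only; ≤14 meioses for exact linkage; biallelic
variant records (multi-allelic sites must be split upstream);
substitution-only HGVS support; presence/absence database filtering
(no allele-frequency thresholds, matching the emulated design); no
sex-specific recombination maps.
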