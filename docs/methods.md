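# Methods

This note documents the models behind `ciliomap`, the calibration of the
synthetic-data generators, the numerical conventions, and the design
choices that were genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Study design being modelled

The pipeline targets a positional-cloning design for a perinatal-lethal
autosomal recessive ciliopathy segregating in two unrelated sheep flocks:
carrier rams backcrossed to carrier ewes produce affected lambs that are
homozygous by descent for a shared ancestral segment; a medium-density
SNP chip (54,241 biallelic markers) locates that segment as a region of
concordant homozygosity across affected animals; whole-genome variant
calls inside the region are reduced to a candidate missense pair by a
recessive segregation filter; a PCR-RFLP assay genotypes the flock at the
causal site; and functional evidence comes from zebrafish morpholino
rescue scoring and primary-cilium morphometry.

## Genotype simulation

`gen_snp_panel` places markers uniformly at random per chromosome
(largest-remainder allocation of the 54,241 defaults over 26 autosomes of
approximately ovine lengths, ~2.45 Gb total) and draws a per-marker
alternate-allele frequency uniformly from `maf_range` (default
0.05-0.5).

*Causal haplotype.* Each animal carries 0, 1 or 2 copies of the ancestral
haplotype. Fixed-composition categories pin the copy number
(affected = 2, carrier = 1, unaffected control = 0); the `lambs` category
draws copies 1:2:1 as offspring of a carrier x carrier mating and labels
homozygous mutants affected with probability `penetrance`. The penetrance
default is 0.482 = 4 x 37/307, back-calculated so that the expected
affected fraction among lambs equals the observed 37/307 ~ 0.12 under
Mendelian transmission. Within each planted segment the ancestral
haplotype carries the alternate allele at every SNP, so two copies give
homozygosity across the whole segment; the remaining haplotypes draw from
the background frequencies.

*Background modes.* The default `"hwe"` background draws unlinked
Hardy-Weinberg genotypes — adequate because the mapper is purely
positional and needs runs, not linkage-disequilibrium structure. The
`"heterozygous"` mode sets every background call heterozygous; it is the
reconstruction configuration in which planted segments are recoverable
exactly (under an HWE background, loci flanking a segment can be
homozygous in all affected animals by chance, legitimately extending the
detected region — real data behave the same way, which is why the chip's
marker density, not the detector, bounds resolution).

*Genotyping error* flips each call independently to one of the other two
codes with the configured probability (default 0). Two-generation
transmission is modelled; deeper pedigree structure (the real flocks span
a decade of matings) is not, because only the copy number of the shared
segment matters to every downstream operation.

## Homozygosity mapping

A locus is *shared-homozygous* when every affected animal's call is
homozygous; under the default `neutral` missing policy a missing call
never breaks a run but at most `max_consecutive_missing` (default 1)
consecutive missing loci may sit inside one, and runs must start and end
on fully typed concordant loci. The `break` policy terminates runs at any
missing call. The 8-SNP minimum follows the threshold used to define a
candidate region in this design. `ibd_identical` is true when all
affected animals share one homozygous allele at every region SNP; it is
deliberately a flag rather than part of the region definition, since the
window-percentage statistic in the source design is ambiguous between
"homozygous" and "homozygous for the same allele" — the region criterion
uses homozygosity, identity is reported.

*Sliding window and relaxed mode.* The window track (window = 8, matching
the SNP threshold; the source design does not state its window size)
reports the fraction of window loci concordantly homozygous. Relaxed
regions are unions of windows at or above `window_concordance_min`
(default 0.9), with one addition: qualifying window spans separated by at
most `max_bridge_loci` loci (default 1) are merged. The bridge is needed
because a single bad call drops all eight covering windows to 7/8 = 0.875,
below the 0.9 threshold, so without it no threshold above 0.875 could ever
tolerate even one isolated error. The price is that relaxed regions may
contain — and may bridge across — a small number of internal discordant
loci; that is their purpose, and strict mode remains the default
reporting path.

*Carrier exclusion and flock intersection.* A region across which any
designated carrier is homozygous (on its typed calls) is flagged
`carrier_fixed` and excluded; a carrier with no typed call in the region
contributes no evidence. Cross-flock intersection keeps base-pair/index
intersections (>= 1 shared SNP) of regions present in every flock and
reports flock-private regions separately; all flocks must be genotyped on
the same marker grid (assembly remapping is out of scope).

## Variant filtering

The segregation filter requires homozygous-alternate in every affected,
heterozygous in every carrier, and no alternate homozygote among
unaffected animals. Missing genotypes never disqualify (call-rate
realism), but a variant missing in more than 20% of affected animals is
flagged `low_confidence`. Consequence annotation maps genomic position to
coding position through the exon model (c.1 = A of the initiator ATG,
codon = ceil(cdna/3)); minus-strand transcripts complement the alleles
into coding space; a reference-base mismatch against the transcript is an
error, not a silent skip.

Deleteriousness is a transparent proxy for black-box web predictors:
Grantham's physico-chemical distance, computed from the published
composition/polarity/volume constants (alpha = 1.833, beta = 0.1018,
gamma = 0.000399, scale 50.723 normalising the 190-pair mean to 100), must
reach 100, and the fraction of non-gap ortholog-alignment rows matching
the reference residue must reach 0.8. The defaults admit strongly
non-conservative substitutions at vertebrate-conserved residues (the
fixture pair scores 149 and 142 at fully conserved columns) while
rejecting conservative changes and residues conserved only in mammals;
both thresholds are exposed. The two causal changes are treated as one
haplotype candidate — the design cannot attribute pathogenicity to either
alone.

## RFLP simulation

PCR is exact-substring matching of the forward primer and the
reverse-complemented reverse primer (>= 15 nt); zero or multiple products
raise an assay-design error. Mismatch-tolerant annealing and partial
digestion are not modelled. Digestion scans the top strand for the IUPAC
recognition pattern and cuts at the pattern's offset; only enzymes whose
pattern is its own reverse complement are accepted (ApoI's R^AATTY is),
which makes the single-strand scan complete. Band calls match observed
band sets against the wild-type, mutant and union patterns exactly by
default, with an optional bp tolerance for parsing real gel tables.

The fixture places the amplicon's constant 140-bp fragment 5-prime (the
source material shows the site only graphically, so the fragment order
along the amplicon is a fixture convention), with ApoI sites cutting 140
and 348 bp from the amplicon start; the causal T>A at the second site's
AATT core abolishes it. The coding coordinates are self-consistent
(c.2042 in codon 681, c.2068-equivalent at c.2060 in codon 687, 18 nt
apart); the historically reported c.2050/I681 pairing is arithmetically
inconsistent under c.1 = A-of-ATG and is not reproduced.

## Phenotype statistics

*Fisher test.* Two-tailed p by full enumeration of tables with the
observed margins under the hypergeometric null, summing probabilities no
greater than the observed table's ("small-p" rule — the common convention
when only "two-tailed Fisher exact" is specified), with a 1e-7 relative
tolerance for ties; a zero margin returns p = 1 with a warning.

*Grade generator defaults are fixtures, not measurements.* No per-grade
counts are printed for the rescue assay, so the default probability
vectors were set by a normal-approximation power calculation and verified
by Monte Carlo before being frozen: at 100 embryos per condition the
morpholino-alone (20% normal) vs wild-type-rescue (60% normal) contrast
reaches p < 1e-4 with ~97% probability, and the morpholino-alone vs
mutant-rescue (24% normal) contrast stays above p = 0.05 with ~92%
probability — consistent with a strongly significant wild-type rescue and
a non-significant mutant rescue. Embryos dying at grade 4 count as
morphant, per the grade definition.

*Cilium lengths* are lognormal (positive, right-skewed, with occasional
very long cilia, matching the reported morphology). The generator is
moment-matched to the published summary statistics, reading the printed
"mean +- value" as mean +- SEM with the SEM taken across the 31 fields of
view — the same unit this package uses when reporting incidence SEM, and
the natural unit given that the published n is "\>= 50 cilia from 31
fields". The per-cilium SD is therefore SEM x sqrt(31): 10.0 um about a
15.1 um mean (affected) and 5.6 um about 8.3 um (unaffected). Incidence
defaults are 0.49 (affected) and 0.45 (unaffected). The two-sample test
defaults to Welch on log lengths; a Mann-Whitney alternative is exposed
because the source design does not name its test (and its text threshold
p < 0.01 disagrees with a figure-legend p < 0.001; the package targets
p < 0.01).

## What the generators do and do not emulate

Passing tests demonstrate that the algorithms recover planted truth under
the stated statistical structure: unlinked background markers, a clean
two-generation pedigree, error-free or independently perturbed genotypes,
multinomial grade counts, lognormal lengths. They do not demonstrate
robustness to linkage disequilibrium, population structure, genotyping
batch effects, segmental duplications or mapping artefacts, pedigree
errors, or scoring drift between embryo graders — all of which real data
contain. The property-based checks (brute-force interval oracle,
exact-arithmetic Fisher oracle, IUPAC expansion oracle) certify the
implementations, not the biology.

## Problem sizes and numerics

The test suite and acceptance script run reconstruction panels of
800-2,000 markers (the full 54,241-marker default is exercised for chip
conformance) with the default flock composition (6 + 14 affected, 40
animals in flock B), 10,000-lamb draws for the Mendelian/penetrance
checks, 100-seed recovery and filter precision/recall sweeps, 200-seed
power checks, 10,000 random micro-panels for the interval oracle and
1,000 random tables/sequences for the Fisher and digest oracles — sizes
chosen so the whole suite completes in well under a minute per module
while keeping Monte-Carlo standard errors far from the asserted bounds.
Floating-point conventions: the Fisher enumeration returns exactly 1.0
when every margin-consistent table is included; degenerate length
comparisons (zero variance in both groups) return p = 1 when the groups
are identical.

## Known limitations

* Strict regions are defined by homozygosity, not allele identity; a
  region mosaic of different homozygous alleles is reported with
  `ibd_identical = False` rather than split.
* Relaxed regions may bridge short genuinely discordant gaps
  (< window size) between two nearby homozygous stretches.
* The deleteriousness proxy is intentionally simple; it is not a
  reimplementation of SIFT/PolyPhen/A-GVGD and should not be used as one.
* Only exonic SNVs are annotated; splice, regulatory and structural
  effects are out of scope.
* PCR has no thermodynamic model; primer specificity is exact string
  matching.
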