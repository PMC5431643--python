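# ciliomap

Mapping a lethal recessive hepatorenal ciliopathy in sheep flocks, as a
tested, reusable pipeline. The package implements the computational side of
a positional-cloning study design: multi-animal concordant-homozygosity
(autozygosity/IBD) mapping on SNP-chip genotypes, segregation-based
candidate-variant filtering with a conservation + Grantham deleteriousness
proxy, in-silico PCR-RFLP genotype assay simulation, and the phenotype
statistics used for zebrafish morpholino rescue assays and primary-cilium
morphometry. A first-class synthetic-data generator stands in for the real
flocks, for which no genotype data are publicly deposited.

It is written for geneticists and bioinformaticians who map recessive
traits in livestock or other pedigreed populations and want each step —
from genotype matrix to candidate missense pair to a gel-pattern genotype
assay — as a scriptable, unit-tested operation.

## The method

**Homozygosity mapping.** Affected animals born to carrier x carrier
matings are homozygous by descent across the segment carrying the causal
allele. On an ordered grid of biallelic SNPs, the mapper finds maximal
intervals where *every* affected animal is homozygous at *every* SNP,
keeping intervals of at least `min_snps` consecutive markers (default 8).
A region is flagged `ibd_identical` when all affected animals share the
same homozygous allele at every SNP. Two controls guard against artefacts:
regions across which a known carrier is also homozygous are excluded
(fixed in the flock, not disease-associated), and regions are intersected
across independently ascertained flocks. A sliding window (default 8 SNPs)
reports the fraction of window SNPs concordantly homozygous, and an
error-tolerant "relaxed" mode merges windows above a concordance threshold
(default 0.9), bridging isolated bad calls.

**Variant filtering.** Variants inside candidate regions survive when they
are homozygous-alternate in every affected animal, heterozygous in every
obligate carrier, and never alternate-homozygous in unaffected controls.
Survivors are annotated against a transcript model (codon =
ceil(cdna/3), standard genetic code, strand-aware) and classified with a
documented proxy for web-based pathogenicity predictors: a candidate must
be missense with Grantham distance >= 100 and ortholog-alignment
conservation >= 0.8 at its residue.

**RFLP assay.** The causal T>A change destroys an internal ApoI site
(R^AATTY) in a 612-bp amplicon. In-silico PCR plus digestion yields
140/208/264 bp for the wild-type allele and 140/472 bp for the mutant;
a heterozygote shows the union. Band-set pattern matching calls each
animal U (unaffected pattern), C (carrier) or A (affected).

**Phenotype statistics.** Embryo grade tables (grade 0 = normal to 4 =
severe/dead) are collapsed to normal-vs-morphant 2x2 tables and compared
with a two-tailed Fisher exact test computed by full hypergeometric
enumeration (small-p tail rule). Cilium samples are summarised as
incidence (percent, SEM across fields of view) and length (mean +- SEM,
um), compared with a Welch test on log lengths (rank-based alternative
available).

## Worked example

```python
import ciliomap as cm
from ciliomap.roh import MappingConfig
from ciliomap.variants import filter_chain

# Simulate two flocks on a 2,000-marker chip with the default planted
# 26-SNP (chr9) and 8-SNP (chr11) ancestral segments.
panel = cm.gen_snp_panel(cm.SimConfig(n_snps=2000, seed=1,
                                      background_mode="heterozygous"))
regions = cm.shared_concordant_regions(
    panel, panel.ids_with_status("affected"), MappingConfig(min_snps=8))
for r in regions:
    print(r.chrom, r.n_snps, r.ibd_identical)
# chr9 26 True
# chr11 8 True

# Variant filtering inside the mapped regions
seg = panel.attrs["planted_segments"][0]
fx = cm.default_transcript_fixture(chrom=seg["chrom"],
                                   cds_start_bp=seg["start_bp"] + 1000)
vs = cm.gen_variant_calls(panel, fx, n_decoys=50, seed=2)
aln = cm.default_ortholog_alignment(fx)
candidates, _ = filter_chain(vs, panel, regions, alignment=aln)
for v in candidates:
    print(v.ref_aa, v.codon_number, v.alt_aa, "grantham", v.grantham)
# I 681 N grantham 149
# I 687 S grantham 142

# RFLP assay over the 40-animal flock B
flock_b = panel.subset_samples(
    [s.id for s in panel.samples if s.flock == "B"])
calls, summary = cm.genotype_cohort(flock_b, fx)
print(summary["genotype_concordant"], "/", summary["n_samples"])
# 40 / 40
```

The two candidates are the planted missense pair: isoleucine-to-asparagine
at residue 681 (Grantham 149) and isoleucine-to-serine at residue 687
(Grantham 142), homozygous in all affected animals and heterozygous in all
carriers; the RFLP calls agree with the simulated genotypes in all 40
flock-B animals.

A CLI mirrors the library: `ciliomap simulate`, `ciliomap roh-map`,
`ciliomap variant-filter`, `ciliomap rflp`, `ciliomap rescue-stats`,
`ciliomap cilia-stats` (see `--help` on each).

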