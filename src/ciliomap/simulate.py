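"""Synthetic flock, variant, amplicon and phenotype data generators.

The generators emulate the study design the mapping pipeline assumes:

* a biallelic SNP chip of 54,241 evenly distributed markers over 26 autosomes;
* two flocks whose affected lambs descend from carrier x carrier matings and
  share an ancestral homozygous segment (one 26-SNP and one 8-SNP segment on
  separate chromosomes by default) carrying a causal missense pair;
* reduced penetrance of the homozygous-mutant genotype (default 0.482, so
  that the expected affected fraction among lambs is 0.25 x 0.482 ~ 0.12);
* a 612-bp exonic amplicon whose wild-type allele carries two ApoI sites and
  whose mutant allele destroys the internal site;
* graded morphant/rescue embryo counts and lognormal cilium lengths.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ciliomap.panel import GenotypePanel, Sample, Status
from ciliomap.variants import Transcript, Variant, VariantSet, OrthologAlignment
from ciliomap.rflp import PrimerPair, find_sites, APOI


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# Approximate ovine autosome lengths (bp); 26 autosomes summing to ~2.45 Gb.
# Marker counts are allocated proportionally to these lengths.
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 276_000_000, "chr2": 249_000_000, "chr3": 224_000_000,
    "chr4": 119_000_000, "chr5": 108_000_000, "chr6": 117_000_000,
    "chr7": 100_000_000, "chr8": 91_000_000, "chr9": 95_000_000,
    "chr10": 86_000_000, "chr11": 62_000_000, "chr12": 79_000_000,
    "chr13": 83_000_000, "chr14": 63_000_000, "chr15": 81_000_000,
    "chr16": 71_000_000, "chr17": 72_000_000, "chr18": 68_000_000,
    "chr19": 61_000_000, "chr20": 51_000_000, "chr21": 50_000_000,
    "chr22": 51_000_000, "chr23": 62_000_000, "chr24": 42_000_000,
    "chr25": 45_000_000, "chr26": 44_000_000,
}

DEFAULT_FLOCK_SIZES: dict[str, dict[str, int]] = {
    "A": {"affected": 6, "carrier": 4, "unaffected": 10},
    "B": {"affected": 14, "carrier": 6, "unaffected": 20},
}


@dataclass
class SimConfig:
    """Configuration of the flock genotype simulator.

    ``flock_sizes`` maps a flock label to counts per category.  Categories
    ``affected``/``carrier``/``unaffected`` fix the causal-haplotype copy
    number (2/1/0); the extra category ``lambs`` draws offspring of a
    carrier x carrier mating unconditionally (Mendelian 1:2:1) and labels
    homozygous-mutant lambs affected with probability ``penetrance``.

    ``background_mode`` controls genotypes outside the planted segments:
    ``"hwe"`` draws Hardy-Weinberg genotypes from per-marker allele
    frequencies in ``maf_range``; ``"heterozygous"`` sets every background
    call heterozygous, which makes planted segments exactly recoverable and
    is the configuration used for reconstruction-style analyses.
    """

    n_snps: int = 54_241
    chrom_lengths: dict[str, int] = dc_field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    maf_range: tuple[float, float] = (0.05, 0.5)
    flock_sizes: dict[str, dict[str, int]] = dc_field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FLOCK_SIZES.items()})
    penetrance: float = 0.482
    genotyping_error_rate: float = 0.0
    seed: int = 0
    planted_segments: list[tuple[str, int]] = dc_field(
        default_factory=lambda: [("chr9", 26), ("chr11", 8)])
    background_mode: str = "hwe"

    def __post_init__(self) -> None:
        if not (0 < self.penetrance <= 1):
            raise ConfigError("penetrance must be in (0, 1]")
        if not (0 <= self.genotyping_error_rate < 1):
            raise ConfigError("genotyping_error_rate must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf bounds must satisfy 0 < lo <= hi <= 0.5")
        for chrom, n in self.planted_segments:
            if n < 1:
                raise ConfigError("planted segment SNP counts must be >= 1")
            if chrom not in self.chrom_lengths:
                raise ConfigError(f"planted segment on unknown chromosome {chrom!r}")
        for flock, counts in self.flock_sizes.items():
            for cat, n in counts.items():
                if n < 0:
                    raise ConfigError(f"negative count for {flock}/{cat}")
        if self.background_mode not in ("hwe", "heterozygous"):
            raise ConfigError("background_mode must be 'hwe' or 'heterozygous'")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")


def _allocate_markers(n_snps: int, chrom_lengths: dict[str, int]) -> dict[str, int]:
    """Largest-remainder allocation of marker counts proportional to length."""
    total = sum(chrom_lengths.values())
    raw = {c: n_snps * L / total for c, L in chrom_lengths.items()}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n_snps - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _marker_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions roughly uniform over [1, length]."""
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.05) + 8))
    while pos.size < n:
        pos = np.union1d(pos, rng.integers(1, length + 1, size=n))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_lamb_genotypes(
    n: int, penetrance: float, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Offspring of carrier x carrier matings.

    Returns a frame with columns ``causal_copies`` (Mendelian 1:2:1 draw of
    the causal haplotype copy number) and ``affected`` (True for homozygous
    mutants that express the phenotype, Bernoulli(penetrance)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    copies = rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25])
    affected = (copies == 2) & (rng.random(n) < penetrance)
    return pd.DataFrame({"causal_copies": copies, "affected": affected})


def gen_snp_panel(config: SimConfig) -> GenotypePanel:
    """Simulate a flock genotype panel with planted autozygous segments.

    Markers are placed uniformly per chromosome and sorted.  Each planted
    segment is a run of consecutive markers (centred on its chromosome) at
    which the shared ancestral haplotype carries the alternate allele; an
    animal with two copies of the ancestral haplotype is therefore
    homozygous-alternate across every segment SNP.  Background markers are
    unlinked.  Genotyping errors flip calls independently at the configured
    rate.  Identical seeds give identical panels.
    """
    rng = np.random.default_rng(config.seed)
    counts = _allocate_markers(config.n_snps, config.chrom_lengths)

    loci_parts = []
    segment_meta: list[dict] = []
    chrom_offsets: dict[str, int] = {}
    offset = 0
    planted = dict(config.planted_segments)
    for chrom, length in config.chrom_lengths.items():
        n = counts[chrom]
        if chrom in planted and planted[chrom] > n:
            raise ConfigError(
                f"planted segment of {planted[chrom]} SNPs exceeds the "
                f"{n} markers on {chrom}")
        pos = _marker_positions(rng, length, n)
        loci_parts.append(pd.DataFrame({
            "chrom": chrom, "pos_bp": pos, "alleleA": "A", "alleleB": "B"}))
        chrom_offsets[chrom] = offset
        if chrom in planted:
            seg_n = planted[chrom]
            start_idx = (n - seg_n) // 2
            end_idx = start_idx + seg_n - 1
            segment_meta.append({
                "chrom": chrom,
                "start_idx": start_idx, "end_idx": end_idx,
                "start_bp": int(pos[start_idx]), "end_bp": int(pos[end_idx]),
                "n_snps": seg_n,
            })
        offset += n
    loci = pd.concat(loci_parts, ignore_index=True)

    # Per-marker alternate-allele frequency for the HWE background.
    lo, hi = config.maf_range
    freq = rng.uniform(lo, hi, size=config.n_snps)

    samples: list[Sample] = []
    copies_list: list[int] = []
    for flock, cats in config.flock_sizes.items():
        for cat in ("affected", "carrier", "unaffected"):
            c = {"affected": 2, "carrier": 1, "unaffected": 0}[cat]
            for k in range(cats.get(cat, 0)):
                samples.append(Sample(
                    id=f"{flock}_{cat[:3]}{k + 1}", flock=flock,
                    status=cat, causal_copies=c))
                copies_list.append(c)
        n_lambs = cats.get("lambs", 0)
        if n_lambs:
            lambs = simulate_lamb_genotypes(n_lambs, config.penetrance, rng)
            for k in range(n_lambs):
                c = int(lambs["causal_copies"].iat[k])
                aff = bool(lambs["affected"].iat[k])
                samples.append(Sample(
                    id=f"{flock}_lamb{k + 1}", flock=flock,
                    status=Status.AFFECTED if aff else Status.UNAFFECTED,
                    causal_copies=c))
                copies_list.append(c)
    copies = np.array(copies_list, dtype=np.int8)
    n_samples = len(samples)

    if config.background_mode == "hwe":
        geno = rng.binomial(2, freq[None, :], size=(n_samples, config.n_snps))
    else:
        geno = np.ones((n_samples, config.n_snps), dtype=np.int64)

    # Overwrite planted segments: c ancestral copies contribute c alternate
    # alleles; the remaining (2 - c) haplotypes draw from the background
    # frequency ("hwe") or carry the reference allele ("heterozygous").
    for seg in segment_meta:
        s = chrom_offsets[seg["chrom"]] + seg["start_idx"]
        e = chrom_offsets[seg["chrom"]] + seg["end_idx"] + 1
        if config.background_mode == "hwe":
            other = np.array([rng.binomial(2 - c, freq[s:e]) for c in copies])
            geno[:, s:e] = copies[:, None] + other
        else:
            geno[:, s:e] = copies[:, None]

    if config.genotyping_error_rate > 0:
        err = rng.random(geno.shape) < config.genotyping_error_rate
        shift = rng.integers(1, 3, size=geno.shape)
        geno = np.where(err, (geno + shift) % 3, geno)

    panel = GenotypePanel(
        loci=loci,
        samples=samples,
        genotypes=geno.astype(np.int8),
        attrs={
            "planted_segments": segment_meta,
            "penetrance": config.penetrance,
            "seed": config.seed,
            "background_mode": config.background_mode,
        },
    )
    return panel


# ---------------------------------------------------------------------------
# Transcript fixture
# ---------------------------------------------------------------------------

@dataclass
class TranscriptFixture:
    """A single-CDS transcript carrying the causal missense pair.

    ``causal_variants`` holds tuples ``(cdna_pos, ref_base, alt_base,
    expected_ref_aa, expected_alt_aa, expected_residue)``.  The default
    fixture places isoleucine codons at residues 681 and 687 so that a T>A
    change at the second codon position of residue 681 gives Ile->Asn and a
    T>G change at the second position of residue 687 gives Ile->Ser; the two
    coding positions are 18 nt apart.  The c.2041..2043 Ile codon sits inside
    an ApoI recognition site (GAATTC at c.2039..2044) that the first variant
    abolishes.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_sequence: str
    cds_start_bp: int
    causal_variants: list[tuple[int, str, str, str, str, int]]

    def __post_init__(self) -> None:
        if len(self.cds_sequence) % 3:
            raise ConfigError("CDS length must be divisible by 3")
        if self.strand not in "+-":
            raise ConfigError("strand must be '+' or '-'")
        for cdna, ref, alt, ref_aa, alt_aa, residue in self.causal_variants:
            if self.cds_sequence[cdna - 1] != ref:
                raise ConfigError(f"reference base mismatch at c.{cdna}")
            codon_i = (cdna - 1) // 3
            if codon_i + 1 != residue:
                raise ConfigError(
                    f"c.{cdna} lies in codon {codon_i + 1}, not {residue}")
            codon = self.cds_sequence[codon_i * 3:codon_i * 3 + 3]
            if str(Seq(codon).translate()) != ref_aa:
                raise ConfigError(f"codon {residue} does not encode {ref_aa}")
            mutant = list(codon)
            mutant[(cdna - 1) % 3] = alt
            if str(Seq("".join(mutant)).translate()) != alt_aa:
                raise ConfigError(f"alt codon at {residue} does not encode {alt_aa}")

    @property
    def cds_end_bp(self) -> int:
        return self.cds_start_bp + len(self.cds_sequence) - 1

    def genomic_pos(self, cdna_pos: int) -> int:
        """Genomic coordinate of a coding position (single-exon model)."""
        if self.strand == "+":
            return self.cds_start_bp + cdna_pos - 1
        return self.cds_end_bp - cdna_pos + 1

    def to_transcript(self) -> Transcript:
        return Transcript(
            gene_id=self.gene_id,
            chrom=self.chrom,
            strand=self.strand,
            exons=[(self.cds_start_bp, self.cds_end_bp)],
            cds_sequence=self.cds_sequence,
        )

    def protein(self) -> str:
        return str(Seq(self.cds_sequence).translate())


_SAFE_CODONS = [
    "GCT", "GCC", "GCA", "GCG",  # Ala
    "CTG", "CTC", "TTG",         # Leu
    "GTG", "GTC", "GTT",         # Val
    "ACC", "ACA", "ACT",         # Thr
    "GGC", "GGT",                # Gly (GGA reserved for the site context)
    "TCC", "TCT", "AGC",         # Ser
    "CAG", "GAG", "GAC", "AAC",  # Gln/Glu/Asp/Asn
    "CGC", "CGG",                # Arg
    "TTC", "TAC", "CAC",         # Phe/Tyr/His
    "ATC", "ATG",                # Ile/Met
]

#: cDNA interval of the RFLP amplicon within the fixture CDS (1-based incl.).
AMPLICON_CDNA_START = 1692
AMPLICON_CDNA_END = 2303
PRIMER_LEN = 22


def default_transcript_fixture(
    gene_id: str = "TMEM67",
    chrom: str = "chr9",
    cds_start_bp: int = 1_000_000,
    n_codons: int = 900,
) -> TranscriptFixture:
    """Build the default causal-gene fixture.

    The CDS is a deterministic pseudo-random coding sequence with these
    constraints: start codon ATG; a single terminal stop; Ile codons (ATT)
    at residues 681 and 687; ApoI sites (R^AATTY) at c.1831..1836 and
    c.2039..2044 and nowhere else within the amplicon interval
    c.1692..2303; the first causal change (c.2042 T>A) destroys the
    internal site without creating a new one; the amplicon-end 22-mers used
    as PCR primers occur exactly once in the CDS.
    """
    if n_codons < 770:
        raise ConfigError("fixture CDS must cover at least 770 codons")
    rng = np.random.default_rng(681_687)
    for _attempt in range(200):
        codons = [_SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS),
                                                        size=n_codons)]
        codons[0] = "ATG"
        codons[-1] = "TAA"
        # ApoI site 1: GAA TTC at codons 611-612 (c.1831..1836).
        codons[610] = "GAA"
        codons[611] = "TTC"
        # ApoI site 2 spanning codons 680-682: GGA ATT CTG puts GAATTC at
        # c.2039..2044 with the causal Ile codon (681) inside it.
        codons[679] = "GGA"
        codons[680] = "ATT"
        codons[681] = "CTG"
        # Second causal Ile codon at residue 687.
        codons[686] = "ATT"
        cds = "".join(codons)

        amplicon = cds[AMPLICON_CDNA_START - 1:AMPLICON_CDNA_END]
        if find_sites(amplicon, APOI) != [139, 347]:
            continue
        mutant = cds[:2041] + "A" + cds[2042:]
        mut_amp = mutant[AMPLICON_CDNA_START - 1:AMPLICON_CDNA_END]
        if find_sites(mut_amp, APOI) != [139]:
            continue
        mutant2 = mutant[:2059] + "G" + mutant[2060:]
        if find_sites(mutant2[AMPLICON_CDNA_START - 1:AMPLICON_CDNA_END],
                      APOI) != [139]:
            continue
        fwd = amplicon[:PRIMER_LEN]
        rev_rc = amplicon[-PRIMER_LEN:]
        if cds.count(fwd) != 1 or cds.count(rev_rc) != 1:
            continue
        rc = str(Seq(cds).reverse_complement())
        if rc.count(fwd) or rc.count(rev_rc):
            continue
        return TranscriptFixture(
            gene_id=gene_id,
            chrom=chrom,
            strand="+",
            cds_sequence=cds,
            cds_start_bp=cds_start_bp,
            causal_variants=[
                (2042, "T", "A", "I", "N", 681),
                (2060, "T", "G", "I", "S", 687),
            ],
        )
    raise ConfigError("could not satisfy fixture sequence constraints")


def default_ortholog_alignment(
    fixture: TranscriptFixture,
    window: tuple[int, int] = (661, 700),
) -> OrthologAlignment:
    """Eleven-way ortholog alignment fixture around the causal residues.

    Vertebrate rows are identical to the reference in the window (isoleucine
    fully conserved at residues 681 and 687); the invertebrate rows diverge
    at scattered non-causal columns, emulating conservation that holds in
    vertebrates but not beyond.
    """
    start, end = window
    ref = fixture.protein()[start - 1:end]
    species = ["sheep", "human", "cattle", "dog", "mouse", "rat",
               "chicken", "lamprey", "zebrafish", "xenopus", "medaka"]
    rows = {sp: list(ref) for sp in species}
    rng = np.random.default_rng(4_0)
    causal_cols = {r - start for _, _, _, _, _, r in fixture.causal_variants}
    for sp in ("lamprey", "medaka"):
        for col in rng.choice(len(ref), size=6, replace=False):
            if col in causal_cols:
                continue
            rows[sp][col] = "AGSTVLNDE"[rng.integers(0, 9)]
    return OrthologAlignment(
        species=species,
        rows=["".join(rows[sp]) for sp in species],
        ref_residue_start=start,
    )


# ---------------------------------------------------------------------------
# Variant-call generator
# ---------------------------------------------------------------------------

_DECOY_CLASSES = (
    "synonymous",
    "intergenic",
    "missense_outside_region",
    "missense_in_region_het_in_affected",
)

_FOURFOLD_PREFIXES = {"GC", "GT", "TC", "AC", "GG", "CG", "CT", "CC"}


def gen_variant_calls(
    panel: GenotypePanel,
    fixture: TranscriptFixture,
    n_decoys: int,
    seed: int,
) -> VariantSet:
    """Emit the two causal variants plus labelled decoy variants.

    The causal variants' genotypes equal each sample's causal-haplotype copy
    number, so they are homozygous-alternate in every affected animal and
    heterozygous in every carrier.  Decoys cycle through four truth classes:
    synonymous-in-gene, intergenic-in-region, missense-outside-region (in a
    small decoy transcript on another chromosome), and
    missense-in-region-but-heterozygous-in-an-affected.  The generating
    class of every variant is recorded as ``truth_class``.
    """
    segments = panel.attrs.get("planted_segments", [])
    seg = next(
        (s for s in segments
         if s["chrom"] == fixture.chrom
         and s["start_bp"] <= fixture.cds_start_bp
         and fixture.cds_end_bp <= s["end_bp"]),
        None,
    )
    if seg is None:
        raise ConfigError("fixture gene does not lie inside a planted segment")

    rng = np.random.default_rng(seed)
    sample_ids = [s.id for s in panel.samples]
    copies = np.array(
        [s.causal_copies if s.causal_copies is not None else 0
         for s in panel.samples], dtype=np.int8)
    affected_rows = [i for i, s in enumerate(panel.samples)
                     if s.status == Status.AFFECTED]

    variants: list[Variant] = []
    for cdna, ref, alt, _ra, _aa, _res in fixture.causal_variants:
        variants.append(Variant(
            chrom=fixture.chrom,
            pos_bp=fixture.genomic_pos(cdna),
            ref_base=ref, alt_base=alt,
            genotypes=copies.copy(),
            truth_class="causal",
        ))

    decoy_tx = None
    if n_decoys:
        other_chrom = next(
            c for c in panel.chromosomes if c != fixture.chrom
            and c not in {s["chrom"] for s in segments})
        decoy_tx = default_transcript_fixture(
            gene_id="DECOY1", chrom=other_chrom,
            cds_start_bp=500_000, n_codons=780)

    used_pos: set[tuple[str, int]] = {(v.chrom, v.pos_bp) for v in variants}
    cds = fixture.cds_sequence

    def hwe_genotypes() -> np.ndarray:
        q = rng.uniform(0.05, 0.5)
        return rng.binomial(2, q, size=len(sample_ids)).astype(np.int8)

    def synonymous_site() -> tuple[int, str, str]:
        while True:
            codon_i = int(rng.integers(1, len(cds) // 3 - 1))
            codon = cds[codon_i * 3:codon_i * 3 + 3]
            if codon[:2] in _FOURFOLD_PREFIXES:
                cdna = codon_i * 3 + 3
                ref = cds[cdna - 1]
                alt = rng.choice([b for b in "ACGT" if b != ref])
                return cdna, ref, str(alt)

    def missense_site(tx_cds: str) -> tuple[int, str, str]:
        while True:
            codon_i = int(rng.integers(1, len(tx_cds) // 3 - 1))
            codon = tx_cds[codon_i * 3:codon_i * 3 + 3]
            cdna = codon_i * 3 + 2   # second codon position
            ref = tx_cds[cdna - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                mut = codon[0] + alt + codon[2]
                aa0 = str(Seq(codon).translate())
                aa1 = str(Seq(mut).translate())
                if aa1 != aa0 and aa1 != "*" and aa0 != "*":
                    return cdna, ref, alt

    for k in range(n_decoys):
        cls = _DECOY_CLASSES[k % len(_DECOY_CLASSES)]
        if cls == "synonymous":
            cdna, ref, alt = synonymous_site()
            chrom, pos = fixture.chrom, fixture.genomic_pos(cdna)
            geno = hwe_genotypes()
        elif cls == "intergenic":
            chrom = fixture.chrom
            pos = int(rng.integers(seg["start_bp"], fixture.cds_start_bp))
            ref, alt = "G", "T"
            geno = hwe_genotypes()
        elif cls == "missense_outside_region":
            assert decoy_tx is not None
            cdna, ref, alt = missense_site(decoy_tx.cds_sequence)
            chrom, pos = decoy_tx.chrom, decoy_tx.genomic_pos(cdna)
            geno = hwe_genotypes()
        else:  # missense_in_region_het_in_affected
            cdna, ref, alt = missense_site(cds)
            chrom, pos = fixture.chrom, fixture.genomic_pos(cdna)
            geno = hwe_genotypes()
            if affected_rows:
                geno[affected_rows] = 1
        if (chrom, pos) in used_pos:
            continue
        used_pos.add((chrom, pos))
        variants.append(Variant(
            chrom=chrom, pos_bp=pos, ref_base=ref, alt_base=alt,
            genotypes=geno, truth_class=cls))

    transcripts = {fixture.gene_id: fixture.to_transcript()}
    if decoy_tx is not None:
        transcripts[decoy_tx.gene_id] = decoy_tx.to_transcript()
    variants.sort(key=lambda v: (v.chrom, v.pos_bp))
    return VariantSet(sample_ids=sample_ids, variants=variants,
                      transcripts=transcripts)


# ---------------------------------------------------------------------------
# RFLP templates
# ---------------------------------------------------------------------------

def gen_rflp_templates(
    fixture: TranscriptFixture | None = None,
) -> tuple[str, str, PrimerPair]:
    """Wild-type and mutant PCR templates plus the primer pair.

    The two templates are the fixture CDS and the same sequence with the
    single site-destroying substitution (the c.2042-equivalent T>A); they
    differ at exactly one base.  The amplicon delimited by the primers is
    612 bp on both templates; the wild-type amplicon carries ApoI sites
    cutting 140 and 348 bp from the amplicon start (fragments 140, 208,
    264 bp) and the mutant allele retains only the first site (fragments
    140, 472 bp).
    """
    if fixture is None:
        fixture = default_transcript_fixture()
    wild = fixture.cds_sequence
    cdna, ref, alt, _, _, _ = fixture.causal_variants[0]
    assert wild[cdna - 1] == ref
    mutant = wild[:cdna - 1] + alt + wild[cdna:]
    amplicon = wild[AMPLICON_CDNA_START - 1:AMPLICON_CDNA_END]
    primers = PrimerPair(
        forward=amplicon[:PRIMER_LEN],
        reverse=str(Seq(amplicon[-PRIMER_LEN:]).reverse_complement()),
    )
    return wild, mutant, primers


# ---------------------------------------------------------------------------
# Zebrafish embryo grades
# ---------------------------------------------------------------------------

GRADE_COLUMNS = ("normal", "grade1", "grade2", "grade3", "grade4")

#: Default per-condition grade probabilities.  These are simulator fixtures,
#: not literature values: no per-grade counts are printed for the rescue
#: assay, so the vectors were set by a power calculation such that at
#: n = 100 embryos/condition the morpholino-alone vs wild-type-rescue
#: contrast is significant at p < 1e-4 with >= 90% power while the
#: morpholino-alone vs mutant-rescue contrast stays above p = 0.05 with
#: >= 80% probability (see docs/methods.md).
DEFAULT_GRADE_PROBS: dict[str, tuple[float, ...]] = {
    "uninjected": (0.92, 0.04, 0.02, 0.01, 0.01),
    "MO": (0.20, 0.28, 0.25, 0.17, 0.10),
    "MO+WT": (0.60, 0.18, 0.12, 0.06, 0.04),
    "MO+MT": (0.24, 0.27, 0.24, 0.16, 0.09),
}


@dataclass
class GradeGeneratorParams:
    condition: str
    n_embryos: int = 100
    probs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.probs:
            if self.condition not in DEFAULT_GRADE_PROBS:
                raise ConfigError(
                    f"no default grade probabilities for {self.condition!r}")
            self.probs = DEFAULT_GRADE_PROBS[self.condition]
        if len(self.probs) != 5:
            raise ConfigError("probs must have 5 entries (normal, g1..g4)")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ConfigError("probs must sum to 1")
        if self.n_embryos < 0:
            raise ConfigError("n_embryos must be >= 0")

    @classmethod
    def defaults(cls, n_embryos: int = 100) -> list["GradeGeneratorParams"]:
        return [cls(condition=c, n_embryos=n_embryos)
                for c in DEFAULT_GRADE_PROBS]


def gen_embryo_grades(
    params: list[GradeGeneratorParams], seed: int
) -> pd.DataFrame:
    """Multinomial embryo grade counts, one row per injection condition."""
    rng = np.random.default_rng(seed)
    rows = {}
    for p in params:
        rows[p.condition] = rng.multinomial(p.n_embryos, p.probs)
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(GRADE_COLUMNS))
    table.index.name = "condition"
    return table


# ---------------------------------------------------------------------------
# Cilia measurements
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match (mu, sigma) of a lognormal to an arithmetic mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    return math.log(mean) - sigma2 / 2, math.sqrt(sigma2)


#: Published summary statistics the cilium-length generator is calibrated to:
#: mean +- SEM in micrometres, with the SEM taken across the 31 fields of
#: view, so the per-cilium SD is SEM * sqrt(31).
CILIA_DEFAULTS = {
    "affected": {"incidence": 0.49, "mean_um": 15.1, "sem_um": 1.8},
    "unaffected": {"incidence": 0.45, "mean_um": 8.3, "sem_um": 1.0},
}
N_FIELDS_DEFAULT = 31


@dataclass
class CiliaGeneratorParams:
    condition: str
    n_cells: int = 110
    incidence: float = 0.0
    length_mean_um: float = 0.0
    length_sd_um: float = 0.0
    n_fields: int = N_FIELDS_DEFAULT

    def __post_init__(self) -> None:
        if self.condition in CILIA_DEFAULTS:
            d = CILIA_DEFAULTS[self.condition]
            if self.incidence == 0.0:
                self.incidence = d["incidence"]
            if self.length_mean_um == 0.0:
                self.length_mean_um = d["mean_um"]
            if self.length_sd_um == 0.0:
                self.length_sd_um = d["sem_um"] * math.sqrt(N_FIELDS_DEFAULT)
        if not (0 <= self.incidence <= 1):
            raise ConfigError("incidence must be in [0, 1]")
        if self.length_mean_um <= 0 or self.length_sd_um <= 0:
            raise ConfigError("length parameters must be positive")
        if self.n_cells < 0 or self.n_fields < 1:
            raise ConfigError("n_cells must be >= 0 and n_fields >= 1")

    @classmethod
    def affected(cls, **kw) -> "CiliaGeneratorParams":
        return cls(condition="affected", **kw)

    @classmethod
    def unaffected(cls, **kw) -> "CiliaGeneratorParams":
        return cls(condition="unaffected", **kw)


def gen_cilia_measurements(
    params: list[CiliaGeneratorParams], seed: int
):
    """Per-cell ciliation flags and lognormal cilium lengths.

    Returns a list of :class:`ciliomap.stats.CiliaSample`, one per parameter
    set.  Cells are assigned to fields of view round-robin; each cell is
    ciliated with probability ``incidence`` and ciliated cells get a
    lognormal length moment-matched to (``length_mean_um``,
    ``length_sd_um``).
    """
    from ciliomap.stats import CiliaSample

    rng = np.random.default_rng(seed)
    out = []
    for p in params:
        ciliated = rng.random(p.n_cells) < p.incidence
        mu, sigma = _lognormal_params(p.length_mean_um, p.length_sd_um)
        lengths = np.full(p.n_cells, np.nan)
        lengths[ciliated] = rng.lognormal(mu, sigma, size=int(ciliated.sum()))
        cells = pd.DataFrame({
            "cell_id": [f"{p.condition}_c{i + 1}" for i in range(p.n_cells)],
            "field_id": [i % p.n_fields for i in range(p.n_cells)],
            "ciliated": ciliated,
            "length_um": lengths,
        })
        out.append(CiliaSample(condition=p.condition, cells=cells))
    return out
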