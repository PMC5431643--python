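"""Candidate-variant reduction inside mapped regions.

Variants in candidate regions are filtered by the recessive segregation
pattern (homozygous-alternate in every affected animal, heterozygous in
every obligate carrier, no alternate homozygote among unaffected
non-carriers), annotated against a transcript model, and scored with a
conservation + Grantham-distance deleteriousness proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from ciliomap.grantham import grantham_distance
from ciliomap.panel import GenotypePanel, Status


@dataclass
class Transcript:
    """A minimal coding transcript model: ordered CDS exon intervals.

    Exons are genomic 1-based inclusive intervals in ascending genomic
    order; ``cds_sequence`` is the spliced coding-strand sequence (for '-'
    strand transcripts it is the reverse complement of the concatenated
    exon sequence).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        span = sum(e - s + 1 for s, e in self.exons)
        if span != len(self.cds_sequence):
            raise ValueError("exon span does not match CDS length")
        if len(self.cds_sequence) % 3:
            raise ValueError("CDS length must be divisible by 3")

    def cdna_position(self, pos_bp: int) -> int | None:
        """1-based coding position of a genomic coordinate, None if outside."""
        offset = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= pos_bp <= e:
                    return offset + (pos_bp - s) + 1
                offset += e - s + 1
        else:
            for s, e in reversed(self.exons):
                if s <= pos_bp <= e:
                    return offset + (e - pos_bp) + 1
                offset += e - s + 1
        return None


@dataclass
class Variant:
    """A biallelic SNV call with per-sample genotype codes {0, 1, 2, -1}."""

    chrom: str
    pos_bp: int
    ref_base: str
    alt_base: str
    genotypes: np.ndarray
    truth_class: str | None = None   # recorded by the simulator

    # annotation, filled in by the pipeline
    region_id: str | None = None
    consequence: str | None = None   # missense|synonymous|stop_gained|noncoding
    gene_id: str | None = None
    cdna_pos: int | None = None
    codon_number: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    grantham: int | None = None
    conservation: float | None = None
    verdict: str | None = None       # "candidate" or "rejected:<reason>"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos_bp, self.ref_base, self.alt_base)


@dataclass
class VariantSet:
    sample_ids: list[str]
    variants: list[Variant]
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.variants:
            if len(v.genotypes) != len(self.sample_ids):
                raise ValueError(
                    f"variant {v.chrom}:{v.pos_bp} has {len(v.genotypes)} "
                    f"genotypes for {len(self.sample_ids)} samples")


@dataclass
class OrthologAlignment:
    """Gapped ortholog protein alignment around a region of interest.

    ``rows`` are equal-length aligned sequences (gap character '-'); the
    first row is the reference species.  ``ref_residue_start`` is the
    reference residue number of the first non-gap reference column, from
    which the column -> residue-number map is built.
    """

    species: list[str]
    rows: list[str]
    ref_residue_start: int

    def __post_init__(self) -> None:
        if len(self.species) != len(self.rows):
            raise ValueError("one species label per row required")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")
        ref = self.rows[0]
        self._col_of_residue: dict[int, int] = {}
        residue = self.ref_residue_start
        for col, aa in enumerate(ref):
            if aa != "-":
                self._col_of_residue[residue] = col
                residue += 1

    def column_for_residue(self, residue_number: int) -> int | None:
        return self._col_of_residue.get(residue_number)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_by_region(variants: list[Variant], regions) -> tuple[list[Variant], list[Variant]]:
    """Split variants into (inside, outside) any region, 1-based inclusive.

    ``regions`` is an iterable of objects with ``chrom``, ``start_bp``,
    ``end_bp`` attributes (e.g. :class:`ciliomap.roh.SharedRegion`).
    Rejected variants get ``verdict="rejected:outside_region"``.
    """
    regs = list(regions)
    _check_non_overlapping(regs)
    kept, rejected = [], []
    for v in variants:
        hit = next(
            (r for r in regs
             if r.chrom == v.chrom and r.start_bp <= v.pos_bp <= r.end_bp),
            None)
        if hit is None:
            v.verdict = "rejected:outside_region"
            rejected.append(v)
        else:
            v.region_id = f"{hit.chrom}:{hit.start_bp}-{hit.end_bp}"
            kept.append(v)
    return kept, rejected


def _check_non_overlapping(regions) -> None:
    by_chrom: dict[str, list] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for rs in by_chrom.values():
        rs = sorted(rs, key=lambda r: r.start_bp)
        for a, b in zip(rs[:-1], rs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError("candidate regions overlap")


def segregation_filter(
    variants: list[Variant],
    panel: GenotypePanel,
    max_missing_affected: float = 0.2,
) -> tuple[list[Variant], list[Variant]]:
    """Keep variants matching the recessive segregation pattern.

    A variant survives when it is homozygous-alternate in every affected
    animal, heterozygous in every carrier, and no unaffected animal is an
    alternate homozygote.  Missing genotypes never disqualify, but a
    variant with more than ``max_missing_affected`` missing calls among
    affected animals is flagged ``low_confidence``.
    """
    rows_by_status = {
        st: [i for i, s in enumerate(panel.samples) if s.status == st]
        for st in (Status.AFFECTED, Status.CARRIER, Status.UNAFFECTED)
    }
    panel_ids = [s.id for s in panel.samples]

    kept, rejected = [], []
    for v in variants:
        if len(v.genotypes) != len(panel_ids):
            raise ValueError(
                f"variant {v.chrom}:{v.pos_bp}: genotype vector does not "
                "match panel samples")
        g = v.genotypes
        aff = g[rows_by_status[Status.AFFECTED]]
        car = g[rows_by_status[Status.CARRIER]]
        una = g[rows_by_status[Status.UNAFFECTED]]
        reason = None
        if np.any((aff != 2) & (aff != -1)):
            reason = "not_hom_in_affected"
        elif np.any((car != 1) & (car != -1)):
            reason = "not_het_in_carriers"
        elif np.any(una == 2):
            reason = "present_in_controls"
        if len(aff) and np.mean(aff == -1) > max_missing_affected:
            v.flags.append("low_confidence")
        if reason is None:
            kept.append(v)
        else:
            v.verdict = f"rejected:{reason}"
            rejected.append(v)
    return kept, rejected


# ---------------------------------------------------------------------------
# Consequence annotation
# ---------------------------------------------------------------------------

class ReferenceMismatchError(ValueError):
    """The variant's reference base disagrees with the transcript sequence."""


def annotate_consequence(variant: Variant, transcript: Transcript | None) -> Variant:
    """Annotate cDNA/codon mapping and consequence class in place.

    The codon number is ceil(cdna_pos / 3) with c.1 the A of the initiator
    ATG; ref and alt codons are translated with the standard genetic code.
    '-' strand transcripts are handled by complementing the variant alleles
    into coding-strand space.  A variant outside the transcript CDS (or with
    no transcript) is ``noncoding``.
    """
    cdna = None
    if transcript is not None and transcript.chrom == variant.chrom:
        cdna = transcript.cdna_position(variant.pos_bp)
    if cdna is None:
        variant.consequence = "noncoding"
        return variant

    ref = variant.ref_base.upper()
    alt = variant.alt_base.upper()
    if transcript.strand == "-":
        ref = str(Seq(ref).complement())
        alt = str(Seq(alt).complement())
    cds = transcript.cds_sequence
    if cds[cdna - 1] != ref:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos_bp} ref {variant.ref_base} does "
            f"not match transcript {transcript.gene_id} at c.{cdna}")

    codon_number = (cdna + 2) // 3
    codon_start = (codon_number - 1) * 3
    codon = cds[codon_start:codon_start + 3]
    within = (cdna - 1) % 3
    alt_codon = codon[:within] + alt + codon[within + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    variant.gene_id = transcript.gene_id
    variant.cdna_pos = cdna
    variant.codon_number = codon_number
    variant.ref_aa = ref_aa
    variant.alt_aa = alt_aa
    if alt_aa == "*" and ref_aa != "*":
        variant.consequence = "stop_gained"
    elif alt_aa == ref_aa:
        variant.consequence = "synonymous"
    else:
        variant.consequence = "missense"
    if variant.consequence == "missense":
        variant.grantham = grantham_distance(ref_aa, alt_aa)
    return variant


def annotate_all(variant_set: VariantSet) -> None:
    """Annotate every variant against the transcript covering it, if any."""
    for v in variant_set.variants:
        tx = next(
            (t for t in variant_set.transcripts.values()
             if t.chrom == v.chrom and t.cdna_position(v.pos_bp) is not None),
            None)
        annotate_consequence(v, tx)


def conservation_score(
    alignment: OrthologAlignment, residue_number: int
) -> float | None:
    """Fraction of non-gap alignment rows matching the reference residue.

    Returns None (undefined) when the residue is not covered by the
    alignment or every row is gapped at its column.
    """
    col = alignment.column_for_residue(residue_number)
    if col is None:
        return None
    ref_aa = alignment.rows[0][col]
    observed = [r[col] for r in alignment.rows if r[col] != "-"]
    if not observed:
        return None
    return sum(aa == ref_aa for aa in observed) / len(observed)


def classify_deleterious(
    v: Variant,
    grantham_min: int = 100,
    conservation_min: float = 0.8,
    alignment: OrthologAlignment | None = None,
) -> str:
    """Final candidate/rejected verdict from consequence, Grantham score
    and residue conservation.

    This is a documented proxy for web-based pathogenicity predictors:
    candidate iff missense AND grantham >= grantham_min AND
    conservation >= conservation_min.  An undefined conservation score
    (residue not covered by the alignment) rejects with
    ``no_conservation_data``.
    """
    if v.consequence != "missense":
        v.verdict = f"rejected:not_missense:{v.consequence}"
        return v.verdict
    if alignment is not None and v.codon_number is not None:
        v.conservation = conservation_score(alignment, v.codon_number)
    if v.grantham is None:
        v.grantham = grantham_distance(v.ref_aa, v.alt_aa)
    if v.grantham < grantham_min:
        v.verdict = f"rejected:low_grantham:{v.grantham}"
    elif v.conservation is None:
        v.verdict = "rejected:no_conservation_data"
    elif v.conservation < conservation_min:
        v.verdict = f"rejected:low_conservation:{v.conservation:.2f}"
    else:
        v.verdict = "candidate"
    return v.verdict


def filter_chain(
    variant_set: VariantSet,
    panel: GenotypePanel,
    regions,
    alignment: OrthologAlignment | None = None,
    grantham_min: int = 100,
    conservation_min: float = 0.8,
) -> tuple[list[Variant], list[Variant]]:
    """Full pipeline: region -> segregation -> consequence -> classification.

    Returns (candidates, rejected); every rejected variant carries a
    ``verdict`` of the form ``rejected:<reason>``.
    """
    annotate_all(variant_set)
    in_region, rejected = filter_by_region(variant_set.variants, regions)
    segregating, rej2 = segregation_filter(in_region, panel)
    rejected += rej2
    candidates = []
    for v in segregating:
        verdict = classify_deleterious(
            v, grantham_min=grantham_min, conservation_min=conservation_min,
            alignment=alignment)
        if verdict == "candidate":
            candidates.append(v)
        else:
            rejected.append(v)
    return candidates, rejected
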