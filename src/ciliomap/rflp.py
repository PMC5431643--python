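"""In-silico PCR-RFLP genotyping: PCR, restriction digestion, band calls.

The assay distinguishes the wild-type and mutant alleles of a biallelic site
by an allele-destroying restriction site inside a PCR amplicon.  With the
default ApoI fixture the wild-type 612-bp amplicon digests to 140/208/264 bp,
the mutant allele to 140/472 bp, and a heterozygote shows the union of both
band sets.
"""

from __future__ import annotations

from dataclasses import dataclass

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AssayDesignError(ValueError):
    """PCR produced zero or multiple products."""


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease with an IUPAC recognition pattern.

    ``cut_offset`` is the number of bases from the pattern start to the
    top-strand cut on the 5' side, e.g. ApoI = R^AATTY has offset 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        bad = set(self.recognition) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes in pattern: {sorted(bad)}")
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ValueError("cut_offset outside the recognition pattern")

    def is_self_reverse_complement(self) -> bool:
        """True when the IUPAC pattern equals its own reverse complement.

        For such enzymes (ApoI: RAATTY) a single top-strand scan finds every
        double-stranded recognition site.
        """
        return revcomp(self.recognition) == self.recognition


APOI = Enzyme(name="ApoI", recognition="RAATTY", cut_offset=1)
ECORI = Enzyme(name="EcoRI", recognition="GAATTC", cut_offset=1)

ENZYMES = {e.name: e for e in (APOI, ECORI)}


def find_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """0-based start positions of every top-strand recognition-site match."""
    seq = sequence.upper()
    pat = enzyme.recognition
    m = len(pat)
    hits = []
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in IUPAC[pat[j]] for j in range(m)):
            hits.append(i)
    return hits


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if len(p) < 15:
                raise ValueError("primers must be >= 15 nt")
            if set(p.upper()) - set("ACGT"):
                raise ValueError("primers must be unambiguous ACGT sequences")


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    template_start: int   # 0-based, inclusive
    template_end: int     # 0-based, exclusive

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestProfile:
    """Restriction-fragment lengths of one allele's amplicon."""

    allele_label: str
    fragment_lengths: tuple[int, ...]   # sorted descending

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fragment_lengths):
            raise ValueError("fragment lengths must be positive")
        if tuple(sorted(self.fragment_lengths, reverse=True)) != self.fragment_lengths:
            raise ValueError("fragment lengths must be sorted descending")

    @property
    def total_length(self) -> int:
        return sum(self.fragment_lengths)


@dataclass
class RflpCall:
    sample_id: str
    observed_bands: frozenset[int]
    call: str   # "U", "C", "A" or "fail"


def in_silico_pcr(template: str, primers: PrimerPair) -> Amplicon:
    """Exact-match PCR: returns the unique product, primers included.

    The forward primer must match the template top strand and the reverse
    primer's reverse complement must match downstream of it; zero or more
    than one (forward, reverse) product is an assay-design error.
    """
    seq = template.upper()
    fwd = primers.forward.upper()
    rev_rc = revcomp(primers.reverse.upper())

    fwd_hits = _find_all(seq, fwd)
    rev_hits = _find_all(seq, rev_rc)
    products = [
        (f, r + len(rev_rc))
        for f in fwd_hits
        for r in rev_hits
        if r + len(rev_rc) > f + len(fwd)
    ]
    if len(products) != 1:
        raise AssayDesignError(
            f"expected exactly 1 PCR product, found {len(products)} "
            f"(forward hits at {fwd_hits}, reverse hits at {rev_hits})")
    start, end = products[0]
    return Amplicon(sequence=seq[start:end], template_start=start,
                    template_end=end)


def _find_all(seq: str, sub: str) -> list[int]:
    hits, i = [], seq.find(sub)
    while i != -1:
        hits.append(i)
        i = seq.find(sub, i + 1)
    return hits


def digest(amplicon: Amplicon | str, enzyme: Enzyme,
           allele_label: str = "") -> DigestProfile:
    """Digest an amplicon; fragments sorted descending, summing to its length.

    Only enzymes whose IUPAC pattern is its own reverse complement are
    supported, so that one top-strand scan finds all double-stranded sites.
    """
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon
    if not seq:
        raise ValueError("amplicon is empty")
    if not enzyme.is_self_reverse_complement():
        raise ValueError(
            f"{enzyme.name}: pattern {enzyme.recognition} is not its own "
            "reverse complement; double-stranded scanning is not implemented")
    cuts = sorted(s + enzyme.cut_offset for s in find_sites(seq, enzyme))
    cuts = [c for c in cuts if 0 < c < len(seq)]
    bounds = [0] + cuts + [len(seq)]
    frags = tuple(sorted(
        (b - a for a, b in zip(bounds[:-1], bounds[1:])), reverse=True))
    return DigestProfile(allele_label=allele_label, fragment_lengths=frags)


def genotype_from_bands(
    observed: set[int],
    wild_bands: set[int] | None = None,
    mutant_bands: set[int] | None = None,
    tolerance_bp: int = 0,
) -> str:
    """Call U/C/A from a band set; anything else is ``fail``.

    Defaults to the fixture reference patterns ({140, 208, 264} wild-type,
    {140, 472} mutant).  ``tolerance_bp`` allows near-matches when parsing
    real gel tables; the in-silico default is exact integer matching.
    """
    wild = frozenset(wild_bands) if wild_bands is not None else frozenset({140, 208, 264})
    mut = frozenset(mutant_bands) if mutant_bands is not None else frozenset({140, 472})
    het = wild | mut
    obs = frozenset(observed)

    def matches(a: frozenset, b: frozenset) -> bool:
        if tolerance_bp == 0:
            return a == b
        return (
            len(a) == len(b)
            and all(any(abs(x - y) <= tolerance_bp for y in b) for x in a)
            and all(any(abs(x - y) <= tolerance_bp for x in a) for y in b)
        )

    for call, ref in (("C", het), ("U", wild), ("A", mut)):
        if matches(obs, ref):
            return call
    return "fail"


_CALL_FOR_COPIES = {0: "U", 1: "C", 2: "A"}


def genotype_cohort(
    panel,
    fixture=None,
    enzyme: Enzyme = APOI,
    templates_by_sample: dict[str, tuple[str, str]] | None = None,
):
    """PCR-RFLP genotype every panel sample and report concordance.

    Each sample's two allele templates are built from its causal-haplotype
    copy number (0, 1 or 2 mutant alleles); each allele is amplified and
    digested, the band sets are unioned, and the pattern is called U/C/A.
    ``templates_by_sample`` lets a test inject per-sample templates (e.g. a
    primer-site mutation); a PCR failure is recorded as ``call="fail"`` and
    removed from the concordance denominator.

    Returns ``(calls, summary)`` where summary counts call-genotype and
    call-phenotype concordance and lists every discordant sample.
    """
    from ciliomap.simulate import gen_rflp_templates

    wild, mutant, primers = gen_rflp_templates(fixture)
    profiles: dict[str, frozenset[int]] = {}
    for label, template in (("wild", wild), ("mutant", mutant)):
        amp = in_silico_pcr(template, primers)
        profiles[label] = frozenset(
            digest(amp, enzyme, allele_label=label).fragment_lengths)
    wild_bands, mut_bands = profiles["wild"], profiles["mutant"]

    calls: list[RflpCall] = []
    n_geno_conc = n_pheno_conc = n_called = 0
    discordant_genotype: list[str] = []
    discordant_phenotype: list[str] = []
    for s in panel.samples:
        copies = s.causal_copies
        if copies is None:
            raise ValueError(f"sample {s.id} has no known causal-site genotype")
        if templates_by_sample and s.id in templates_by_sample:
            alleles = templates_by_sample[s.id]
        else:
            alleles = (wild, wild) if copies == 0 else (
                (wild, mutant) if copies == 1 else (mutant, mutant))
        try:
            bands: set[int] = set()
            for allele in alleles:
                amp = in_silico_pcr(allele, primers)
                bands |= set(digest(amp, enzyme).fragment_lengths)
            call = genotype_from_bands(bands, wild_bands, mut_bands)
        except AssayDesignError:
            bands, call = set(), "fail"
        calls.append(RflpCall(sample_id=s.id,
                              observed_bands=frozenset(bands), call=call))
        if call == "fail":
            continue
        n_called += 1
        if call == _CALL_FOR_COPIES[copies]:
            n_geno_conc += 1
        else:
            discordant_genotype.append(s.id)
        # Phenotype concordance: affected <=> A pattern.  Carriers and
        # non-carriers are phenotypically indistinguishable, so a
        # non-affected animal is discordant only when it shows the A
        # pattern (e.g. a non-penetrant homozygote).
        if (s.status == "affected") == (call == "A"):
            n_pheno_conc += 1
        else:
            discordant_phenotype.append(s.id)

    summary = {
        "n_samples": len(panel.samples),
        "n_called": n_called,
        "n_fail": len(panel.samples) - n_called,
        "genotype_concordant": n_geno_conc,
        "phenotype_concordant": n_pheno_conc,
        "discordant_genotype": discordant_genotype,
        "discordant_phenotype": discordant_phenotype,
    }
    return calls, summary
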