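"""Runs of homozygosity and cross-animal concordant (IBD) region mapping.

The mapper works purely positionally on the ordered SNP grid: per-animal
maximal runs of consecutive homozygous loci, cross-animal regions where
every affected animal is homozygous at every SNP (with an 8-SNP minimum by
default), a sliding-window concordance track for error tolerance, a
carrier-fixation exclusion step, and cross-flock interval intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ciliomap.panel import GenotypePanel

# Per-locus states used by the run scanner.
_GOOD, _MISS, _BAD = 0, 1, 2


@dataclass
class MappingConfig:
    """Thresholds of the homozygosity mapper.

    ``min_snps`` is the minimum run length for a candidate region (default
    8 SNPs).  ``missing_policy`` controls missing calls: ``"neutral"``
    lets up to ``max_consecutive_missing`` consecutive missing loci sit
    inside a run without breaking it; ``"break"`` terminates runs at any
    missing call.  The sliding window (``window_size``, default equal to
    the SNP threshold) reports the fraction of window loci homozygous and
    allele-concordant across all affected animals; windows at or above
    ``window_concordance_min`` seed relaxed (error-tolerant) regions, and
    qualifying window spans separated by at most ``max_bridge_loci``
    discordant loci are merged.
    """

    min_snps: int = 8
    window_size: int = 8
    window_concordance_min: float = 0.9
    missing_policy: str = "neutral"
    max_consecutive_missing: int = 1
    max_bridge_loci: int = 1

    def __post_init__(self) -> None:
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not (0 < self.window_concordance_min <= 1):
            raise ValueError("window_concordance_min must be in (0, 1]")
        if self.missing_policy not in ("neutral", "break"):
            raise ValueError("missing_policy must be 'neutral' or 'break'")
        if self.max_consecutive_missing < 0 or self.max_bridge_loci < 0:
            raise ValueError("missing/bridge allowances must be >= 0")


@dataclass
class HomozygosityRun:
    sample_id: str
    chrom: str
    start_index: int   # per-chromosome locus index, inclusive
    end_index: int
    n_snps: int
    start_bp: int
    end_bp: int


@dataclass
class SharedRegion:
    """A chromosome interval concordantly homozygous across affected animals."""

    chrom: str
    start_index: int
    end_index: int
    n_snps: int
    start_bp: int
    end_bp: int
    concordance_track: np.ndarray | None = None
    ibd_identical: bool | None = None
    carrier_fixed: bool | None = None
    flock: str | None = None
    relaxed: bool = False

    def interval(self) -> tuple[int, int]:
        return (self.start_index, self.end_index)


# ---------------------------------------------------------------------------
# Run scanning
# ---------------------------------------------------------------------------

def _scan_runs(states: np.ndarray, min_snps: int,
               max_consecutive_missing: int) -> list[tuple[int, int]]:
    """Maximal (start, end) index runs of non-BAD loci.

    Runs are split where more than ``max_consecutive_missing`` consecutive
    MISS loci occur, trimmed so both endpoints are GOOD, and discarded when
    shorter than ``min_snps``.
    """
    runs: list[tuple[int, int]] = []
    n = len(states)
    i = 0
    while i < n:
        if states[i] == _BAD:
            i += 1
            continue
        j = i
        while j < n and states[j] != _BAD:
            j += 1
        # [i, j) is BAD-free; split on over-long MISS stretches.
        block_start = i
        k = i
        while k < j:
            if states[k] == _MISS:
                m = k
                while m < j and states[m] == _MISS:
                    m += 1
                if m - k > max_consecutive_missing:
                    _emit(runs, states, block_start, k - 1, min_snps)
                    block_start = m
                k = m
            else:
                k += 1
        _emit(runs, states, block_start, j - 1, min_snps)
        i = j
    return runs


def _emit(runs: list, states: np.ndarray, start: int, end: int,
          min_snps: int) -> None:
    while start <= end and states[start] != _GOOD:
        start += 1
    while end >= start and states[end] != _GOOD:
        end -= 1
    if end - start + 1 >= min_snps:
        runs.append((start, end))


def _sample_states(geno: np.ndarray, policy: str) -> np.ndarray:
    """Per-locus state for one sample's chromosome genotype vector."""
    states = np.full(geno.shape, _BAD, dtype=np.int8)
    states[(geno == 0) | (geno == 2)] = _GOOD
    states[geno == -1] = _MISS if policy == "neutral" else _BAD
    return states


def _shared_states(geno: np.ndarray, policy: str) -> np.ndarray:
    """Per-locus state across affected animals (rows of ``geno``).

    GOOD: every animal homozygous; MISS: no heterozygote but at least one
    missing call (neutral policy); BAD: any heterozygote, or any missing
    call under the break policy.
    """
    any_het = np.any(geno == 1, axis=0)
    any_miss = np.any(geno == -1, axis=0)
    states = np.full(geno.shape[1], _GOOD, dtype=np.int8)
    if policy == "neutral":
        states[any_miss] = _MISS
    else:
        states[any_miss] = _BAD
    states[any_het] = _BAD
    return states


def call_homozygosity_runs(
    panel: GenotypePanel, sample_id: str, config: MappingConfig | None = None
) -> list[HomozygosityRun]:
    """Maximal runs of consecutive homozygous loci for one animal.

    Runs never span chromosomes; runs shorter than ``config.min_snps`` are
    discarded; missing calls are handled per ``config.missing_policy``.
    """
    config = config or MappingConfig()
    row = panel.sample_index(sample_id)
    out: list[HomozygosityRun] = []
    for chrom in panel.chromosomes:
        sl = panel.chrom_slice(chrom)
        geno = panel.genotypes[row, sl]
        pos = panel.chrom_positions(chrom)
        states = _sample_states(geno, config.missing_policy)
        for s, e in _scan_runs(states, config.min_snps,
                               config.max_consecutive_missing):
            out.append(HomozygosityRun(
                sample_id=sample_id, chrom=chrom,
                start_index=s, end_index=e, n_snps=e - s + 1,
                start_bp=int(pos[s]), end_bp=int(pos[e])))
    return out


def _ibd_identical(geno: np.ndarray) -> bool:
    """True when, at every locus, all non-missing calls share one
    homozygous code."""
    for col in geno.T:
        vals = np.unique(col[col != -1])
        if len(vals) > 1 or (len(vals) == 1 and vals[0] == 1):
            return False
    return True


def shared_concordant_regions(
    panel: GenotypePanel,
    affected_ids: list[str],
    config: MappingConfig | None = None,
) -> list[SharedRegion]:
    """Maximal intervals where every affected animal is homozygous at every
    SNP, at least ``min_snps`` long (strict detection).

    Each region carries ``ibd_identical``: True when at every SNP all
    affected animals share the same homozygous allele.
    """
    config = config or MappingConfig()
    if len(affected_ids) < 2:
        raise ValueError("at least 2 affected animals are required")
    regions: list[SharedRegion] = []
    for chrom in panel.chromosomes:
        geno = panel.chrom_genotypes(chrom, affected_ids)
        pos = panel.chrom_positions(chrom)
        states = _shared_states(geno, config.missing_policy)
        track = _window_track(geno, config.window_size)
        for s, e in _scan_runs(states, config.min_snps,
                               config.max_consecutive_missing):
            sub = geno[:, s:e + 1]
            if track is not None and e - s + 1 >= config.window_size:
                region_track = track[s:e - config.window_size + 2]
            else:
                region_track = None
            regions.append(SharedRegion(
                chrom=chrom, start_index=s, end_index=e, n_snps=e - s + 1,
                start_bp=int(pos[s]), end_bp=int(pos[e]),
                concordance_track=region_track,
                ibd_identical=_ibd_identical(sub)))
    regions.sort(key=lambda r: (r.chrom, r.start_index))
    return regions


# ---------------------------------------------------------------------------
# Sliding-window concordance
# ---------------------------------------------------------------------------

def _concordant_loci(geno: np.ndarray) -> np.ndarray:
    """Boolean per-locus vector: every typed affected call homozygous
    (missing calls tolerated, heterozygotes not).

    Concordance here means concordant homozygosity, matching the strict
    region criterion; allele identity across animals is reported
    separately as the ``ibd_identical`` flag.
    """
    any_het = np.any(geno == 1, axis=0)
    any_typed = np.any(geno != -1, axis=0)
    return ~any_het & any_typed


def _window_track(geno: np.ndarray, window: int) -> np.ndarray | None:
    conc = _concordant_loci(geno).astype(float)
    if len(conc) < window:
        return None
    csum = np.concatenate([[0.0], np.cumsum(conc)])
    return (csum[window:] - csum[:-window]) / window


def sliding_window_concordance(
    panel: GenotypePanel,
    affected_ids: list[str],
    config: MappingConfig | None = None,
) -> dict[str, np.ndarray]:
    """Per-chromosome track: for each window start, the fraction of the
    window's SNPs at which every affected animal is homozygous
    (concordant homozygosity; allele identity is reported separately as
    the ``ibd_identical`` flag on regions).

    Chromosomes with fewer SNPs than the window are skipped with a warning.
    """
    config = config or MappingConfig()
    if len(affected_ids) < 2:
        raise ValueError("at least 2 affected animals are required")
    tracks: dict[str, np.ndarray] = {}
    for chrom in panel.chromosomes:
        geno = panel.chrom_genotypes(chrom, affected_ids)
        track = _window_track(geno, config.window_size)
        if track is None:
            warnings.warn(
                f"{chrom}: fewer SNPs than window size "
                f"{config.window_size}; skipped", stacklevel=2)
            continue
        tracks[chrom] = track
    return tracks


def relaxed_regions(
    panel: GenotypePanel,
    affected_ids: list[str],
    config: MappingConfig | None = None,
) -> list[SharedRegion]:
    """Error-tolerant candidate regions from the sliding-window track.

    Spans of windows whose concordance is at or above
    ``window_concordance_min`` are unioned; spans separated by at most
    ``max_bridge_loci`` loci are merged (tolerating isolated bad calls);
    region endpoints are trimmed to concordant loci.  Relaxed regions may
    therefore contain a small number of internal discordant loci -- that is
    their purpose.
    """
    config = config or MappingConfig()
    if len(affected_ids) < 2:
        raise ValueError("at least 2 affected animals are required")
    w = config.window_size
    out: list[SharedRegion] = []
    for chrom in panel.chromosomes:
        geno = panel.chrom_genotypes(chrom, affected_ids)
        pos = panel.chrom_positions(chrom)
        track = _window_track(geno, w)
        if track is None:
            continue
        seeds = np.flatnonzero(track >= config.window_concordance_min)
        if seeds.size == 0:
            continue
        conc = _concordant_loci(geno)
        # Union of qualifying window spans, merging near-adjacent spans.
        spans: list[list[int]] = []
        for s in seeds:
            lo, hi = int(s), int(s) + w - 1
            if spans and lo <= spans[-1][1] + 1 + config.max_bridge_loci:
                spans[-1][1] = max(spans[-1][1], hi)
            else:
                spans.append([lo, hi])
        for lo, hi in spans:
            while lo <= hi and not conc[lo]:
                lo += 1
            while hi >= lo and not conc[hi]:
                hi -= 1
            if hi - lo + 1 < config.min_snps:
                continue
            sub = geno[:, lo:hi + 1]
            out.append(SharedRegion(
                chrom=chrom, start_index=lo, end_index=hi,
                n_snps=hi - lo + 1,
                start_bp=int(pos[lo]), end_bp=int(pos[hi]),
                concordance_track=track[lo:max(lo, hi - w + 2)],
                ibd_identical=_ibd_identical(sub),
                relaxed=True))
    out.sort(key=lambda r: (r.chrom, r.start_index))
    return out


# ---------------------------------------------------------------------------
# Carrier fixation and cross-flock intersection
# ---------------------------------------------------------------------------

def carrier_fixation_filter(
    regions: list[SharedRegion],
    panel: GenotypePanel,
    carrier_ids: list[str],
) -> tuple[list[SharedRegion], list[SharedRegion]]:
    """Exclude regions across which a designated carrier is homozygous.

    A region where the causal haplotype truly segregates must leave every
    obligate carrier heterozygous somewhere inside it; a region homozygous
    in a carrier is fixed in the flock rather than disease-associated.
    Returns (retained, excluded).  A carrier with no typed call in a region
    contributes no evidence; if no carrier has evidence the region is
    retained with ``carrier_fixed=None`` and a warning.
    """
    if not carrier_ids:
        warnings.warn("no carriers designated; regions returned unchanged",
                      stacklevel=2)
        return list(regions), []
    for cid in carrier_ids:
        panel.sample_index(cid)   # raises on unknown id
    retained, excluded = [], []
    for region in regions:
        geno = panel.chrom_genotypes(region.chrom, carrier_ids)
        sub = geno[:, region.start_index:region.end_index + 1]
        fixed = None
        any_evidence = False
        for row in sub:
            typed = row[row != -1]
            if typed.size == 0:
                continue
            any_evidence = True
            if np.all((typed == 0) | (typed == 2)):
                fixed = True
                break
        if fixed is None and any_evidence:
            fixed = False
        region.carrier_fixed = fixed
        if fixed:
            excluded.append(region)
        else:
            if fixed is None:
                warnings.warn(
                    f"region {region.chrom}:{region.start_bp}-{region.end_bp}:"
                    " all carrier genotypes missing; fixation undetermined",
                    stacklevel=2)
            retained.append(region)
    return retained, excluded


def cross_flock_intersection(
    regions_by_flock: dict[str, list[SharedRegion]],
) -> tuple[list[SharedRegion], list[SharedRegion]]:
    """Intersect candidate regions across flocks on the shared locus grid.

    Returns (candidates, excluded): candidates are interval intersections
    (at least one shared SNP) present in every flock; regions private to a
    subset of flocks are excluded.  All flocks must be mapped on the same
    panel locus grid.
    """
    flocks = list(regions_by_flock)
    if not flocks:
        return [], []
    if len(flocks) == 1:
        return list(regions_by_flock[flocks[0]]), []

    def intersect(a: SharedRegion, b: SharedRegion) -> SharedRegion | None:
        if a.chrom != b.chrom:
            return None
        s = max(a.start_index, b.start_index)
        e = min(a.end_index, b.end_index)
        if e < s:
            return None
        return SharedRegion(
            chrom=a.chrom, start_index=s, end_index=e, n_snps=e - s + 1,
            start_bp=max(a.start_bp, b.start_bp),
            end_bp=min(a.end_bp, b.end_bp),
            ibd_identical=(
                None if a.ibd_identical is None or b.ibd_identical is None
                else a.ibd_identical and b.ibd_identical),
            carrier_fixed=(
                None if a.carrier_fixed is None and b.carrier_fixed is None
                else bool(a.carrier_fixed) or bool(b.carrier_fixed)),
        )

    candidates = list(regions_by_flock[flocks[0]])
    for f in flocks[1:]:
        candidates = [
            c for a in candidates for b in regions_by_flock[f]
            if (c := intersect(a, b)) is not None
        ]

    # A source region is excluded when it overlaps no final candidate.
    excluded = []
    for f in flocks:
        for r in regions_by_flock[f]:
            if not any(
                c.chrom == r.chrom
                and c.start_index <= r.end_index
                and r.start_index <= c.end_index
                for c in candidates
            ):
                excluded.append(r)
    candidates.sort(key=lambda r: (r.chrom, r.start_index))
    return candidates, excluded
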