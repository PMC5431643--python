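"""Genotype panel container: samples x SNP loci with phenotype labels.

Genotype codes: 0 = homozygous reference (allele A), 1 = heterozygous,
2 = homozygous alternate (allele B), -1 = missing.  Locus coordinates are
1-based inclusive internally; BED output downstream is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

VALID_CODES = frozenset({-1, 0, 1, 2})


class Status:
    """Phenotype status labels."""

    AFFECTED = "affected"
    CARRIER = "carrier"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"

    ALL = (AFFECTED, CARRIER, UNAFFECTED, UNKNOWN)


@dataclass
class Sample:
    id: str
    flock: str
    status: str
    # True copy number of the causal (ancestral) haplotype, recorded by the
    # simulator when the sample is synthetic; None for real data.
    causal_copies: int | None = None


@dataclass
class GenotypePanel:
    """Samples x loci genotype matrix with per-sample phenotype labels.

    Parameters
    ----------
    loci : pandas.DataFrame
        One row per locus with columns ``chrom``, ``pos_bp`` (1-based),
        ``alleleA``, ``alleleB``; sorted by (chrom, pos_bp) with strictly
        increasing positions per chromosome.
    samples : list of Sample
    genotypes : numpy.ndarray, shape (n_samples, n_loci), int8
        Codes in {-1, 0, 1, 2}.
    attrs : dict
        Free-form metadata; the simulator records the planted segments here
        under ``"planted_segments"`` as a list of dicts with keys ``chrom``,
        ``start_idx``, ``end_idx``, ``start_bp``, ``end_bp`` (indices are
        per-chromosome locus indices, inclusive).
    """

    loci: pd.DataFrame
    samples: list[Sample]
    genotypes: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        bad = set(np.unique(self.genotypes)) - VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        self._validate_loci()
        self._index = {s.id: i for i, s in enumerate(self.samples)}
        if len(self._index) != len(self.samples):
            raise ValueError("duplicate sample ids")

    def _validate_loci(self) -> None:
        required = {"chrom", "pos_bp", "alleleA", "alleleB"}
        if not required.issubset(self.loci.columns):
            raise ValueError(f"loci table must have columns {sorted(required)}")
        for chrom, sub in self.loci.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- accessors -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.loci["chrom"]))

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def sample(self, sample_id: str) -> Sample:
        return self.samples[self.sample_index(sample_id)]

    def ids_with_status(self, status: str, flock: str | None = None) -> list[str]:
        return [
            s.id
            for s in self.samples
            if s.status == status and (flock is None or s.flock == flock)
        ]

    def flocks(self) -> list[str]:
        return list(dict.fromkeys(s.flock for s in self.samples))

    def chrom_slice(self, chrom: str) -> slice:
        """Column slice of the genotype matrix for one chromosome."""
        idx = np.flatnonzero((self.loci["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no loci on chromosome {chrom!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chrom_genotypes(self, chrom: str, sample_ids: Iterable[str]) -> np.ndarray:
        """Genotype sub-matrix (samples x chromosome loci)."""
        rows = [self.sample_index(s) for s in sample_ids]
        return self.genotypes[np.ix_(rows, range(*self.chrom_slice(chrom).indices(self.n_loci)))]

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.loci["pos_bp"].to_numpy()[self.chrom_slice(chrom)]

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypePanel":
        rows = [self.sample_index(s) for s in sample_ids]
        return GenotypePanel(
            loci=self.loci,
            samples=[self.samples[r] for r in rows],
            genotypes=self.genotypes[rows, :],
            attrs=dict(self.attrs),
        )
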