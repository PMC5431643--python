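"""Shared fixtures: hand-built toy panels and the default gene fixture."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from ciliomap.panel import GenotypePanel, Sample
from ciliomap.simulate import SimConfig, default_transcript_fixture, gen_snp_panel

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_panel(codes_by_sample: dict[str, list[int]],
               statuses: dict[str, str] | None = None,
               flocks: dict[str, str] | None = None,
               chroms: list[str] | None = None) -> GenotypePanel:
    """Build a toy panel from per-sample genotype code lists.

    All samples share one locus grid; ``chroms`` optionally assigns a
    chromosome label per locus (default: all on chr1, 1 kb spacing).
    """
    n = len(next(iter(codes_by_sample.values())))
    chroms = chroms or ["chr1"] * n
    pos, counter = [], {}
    for c in chroms:
        counter[c] = counter.get(c, 0) + 1
        pos.append(counter[c] * 1000)
    loci = pd.DataFrame({
        "chrom": chroms, "pos_bp": pos, "alleleA": "A", "alleleB": "B"})
    samples = [
        Sample(id=sid,
               flock=(flocks or {}).get(sid, "A"),
               status=(statuses or {}).get(sid, "unknown"))
        for sid in codes_by_sample
    ]
    geno = np.array(list(codes_by_sample.values()), dtype=np.int8)
    return GenotypePanel(loci=loci, samples=samples, genotypes=geno)


@pytest.fixture(scope="session")
def fixture_transcript():
    return default_transcript_fixture()


@pytest.fixture(scope="session")
def small_sim_panel():
    """Default-composition flocks on a 2,000-marker chip (HWE background)."""
    return gen_snp_panel(SimConfig(n_snps=2000, seed=11))


@pytest.fixture(scope="session")
def het_background_panel():
    """Reconstruction-style panel: heterozygous background, planted 26- and
    8-SNP segments exactly recoverable."""
    return gen_snp_panel(
        SimConfig(n_snps=2000, seed=11, background_mode="heterozygous"))


def fixture_for_panel(panel, base_fixture):
    """Re-anchor the session transcript fixture inside the panel's first
    planted segment."""
    seg = panel.attrs["planted_segments"][0]
    return dataclasses.replace(
        base_fixture, chrom=seg["chrom"], cds_start_bp=seg["start_bp"] + 1000)
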