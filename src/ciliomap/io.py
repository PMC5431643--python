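"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as PLINK-style text .ped/.map or a TSV dialect; regions as
BED (0-based half-open) plus a TSV report; variant sets as VCF v4.2 text;
templates as FASTA; grade and cilia tables as TSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ciliomap.panel import GenotypePanel, Sample
from ciliomap.roh import SharedRegion
from ciliomap.stats import CiliaSample, GRADE_COLUMNS
from ciliomap.variants import Variant, VariantSet

_PED_CODE = {0: "{a} {a}", 1: "{a} {b}", 2: "{b} {b}", -1: "0 0"}
_STATUS_PHENO = {"unaffected": "1", "affected": "2", "carrier": "1",
                 "unknown": "0"}


# ---------------------------------------------------------------------------
# PLINK-style PED/MAP
# ---------------------------------------------------------------------------

def write_ped_map(panel: GenotypePanel, prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``.

    PED columns: family (= flock), individual id, paternal, maternal, sex,
    phenotype (1 unaffected/carrier, 2 affected, 0 unknown), then two
    space-separated alleles per locus.  MAP columns: chrom, snp id, genetic
    distance (0), bp position.
    """
    ped_path, map_path = f"{prefix}.ped", f"{prefix}.map"
    loci = panel.loci
    with open(map_path, "w") as fh:
        for i, row in enumerate(loci.itertuples(index=False)):
            fh.write(f"{row.chrom}\tsnp{i + 1}\t0\t{row.pos_bp}\n")
    a = loci["alleleA"].to_numpy()
    b = loci["alleleB"].to_numpy()
    with open(ped_path, "w") as fh:
        for s, geno in zip(panel.samples, panel.genotypes):
            fields = [s.flock, s.id, "0", "0", "0", _STATUS_PHENO[s.status]]
            alleles = [
                _PED_CODE[int(g)].format(a=a[j], b=b[j])
                for j, g in enumerate(geno)
            ]
            fh.write(" ".join(fields + alleles) + "\n")
    return ped_path, map_path


def read_ped_map(prefix: str,
                 status_by_id: dict[str, str] | None = None) -> GenotypePanel:
    """Read a ``.ped``/``.map`` pair written by :func:`write_ped_map`.

    PED phenotype 2 maps to affected and 1 to unaffected; carrier labels
    are not representable in PED and may be supplied via ``status_by_id``.
    """
    map_rows = []
    with open(f"{prefix}.map") as fh:
        for line in fh:
            chrom, _snp, _cm, pos = line.split()
            map_rows.append((chrom, int(pos)))
    loci = pd.DataFrame(map_rows, columns=["chrom", "pos_bp"])
    loci["alleleA"] = "A"
    loci["alleleB"] = "B"

    samples: list[Sample] = []
    genos: list[list[int]] = []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            flock, sid, _, _, _, pheno = parts[:6]
            alleles = parts[6:]
            row = []
            allele_a = loci["alleleA"].to_numpy()
            for j in range(len(loci)):
                pair = {alleles[2 * j], alleles[2 * j + 1]}
                if pair == {"0"}:
                    row.append(-1)
                elif pair == {allele_a[j]}:
                    row.append(0)
                elif len(pair) == 2:
                    row.append(1)
                else:
                    row.append(2)
            status = {"2": "affected", "1": "unaffected"}.get(pheno, "unknown")
            if status_by_id and sid in status_by_id:
                status = status_by_id[sid]
            samples.append(Sample(id=sid, flock=flock, status=status))
            genos.append(row)
    return GenotypePanel(loci=loci, samples=samples,
                         genotypes=np.array(genos, dtype=np.int8))


# ---------------------------------------------------------------------------
# TSV genotype dialect
# ---------------------------------------------------------------------------

def write_genotype_tsv(panel: GenotypePanel, prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.genotypes.tsv`` and ``<prefix>.loci.tsv``.

    The genotype table has columns ``sample_id``, ``flock``, ``status``
    followed by one ``chrom:pos`` column per locus holding codes
    {-1, 0, 1, 2}.  The loci sidecar lists chrom, pos_bp, alleleA, alleleB.
    """
    loci_path = f"{prefix}.loci.tsv"
    geno_path = f"{prefix}.genotypes.tsv"
    panel.loci.to_csv(loci_path, sep="\t", index=False)
    cols = [f"{r.chrom}:{r.pos_bp}" for r in panel.loci.itertuples(index=False)]
    df = pd.DataFrame(panel.genotypes, columns=cols)
    df.insert(0, "status", [s.status for s in panel.samples])
    df.insert(0, "flock", [s.flock for s in panel.samples])
    df.insert(0, "sample_id", [s.id for s in panel.samples])
    df.to_csv(geno_path, sep="\t", index=False)
    return geno_path, loci_path


def read_genotype_tsv(prefix: str) -> GenotypePanel:
    loci = pd.read_csv(f"{prefix}.loci.tsv", sep="\t")
    df = pd.read_csv(f"{prefix}.genotypes.tsv", sep="\t")
    samples = [
        Sample(id=str(r.sample_id), flock=str(r.flock), status=str(r.status))
        for r in df.itertuples(index=False)
    ]
    geno = df.drop(columns=["sample_id", "flock", "status"]).to_numpy(np.int8)
    return GenotypePanel(loci=loci, samples=samples, genotypes=geno)


# ---------------------------------------------------------------------------
# Regions: BED + TSV report
# ---------------------------------------------------------------------------

def write_regions_bed(regions: list[SharedRegion], path: str) -> str:
    """BED (0-based half-open) of region bp intervals."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t"
                     f"n_snps={r.n_snps}\n")
    return path


def write_regions_tsv(regions: list[SharedRegion], path: str) -> str:
    rows = []
    for r in regions:
        track = r.concordance_track
        rows.append({
            "chrom": r.chrom,
            "start_bp": r.start_bp,
            "end_bp": r.end_bp,
            "start_index": r.start_index,
            "end_index": r.end_index,
            "n_snps": r.n_snps,
            "ibd_identical": r.ibd_identical,
            "carrier_fixed": r.carrier_fixed,
            "relaxed": r.relaxed,
            "mean_window_concordance": (
                float(np.mean(track)) if track is not None and len(track)
                else float("nan")),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# VCF v4.2
# ---------------------------------------------------------------------------

_GT_STRING = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
_GT_CODE = {(".", "."): -1, ("0", "0"): 0, ("0", "1"): 1, ("1", "0"): 1,
            ("1", "1"): 2}


def write_vcf(vs: VariantSet, path: str) -> str:
    """Write a variant set as uncompressed VCF v4.2 with GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v.chrom for v in vs.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##INFO=<ID=TRUTH,Number=1,Type=String,'
                 'Description="Simulator truth class">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vs.sample_ids) + "\n")
        for v in vs.variants:
            info = f"TRUTH={v.truth_class}" if v.truth_class else "."
            gts = "\t".join(_GT_STRING[int(g)] for g in v.genotypes)
            fh.write(f"{v.chrom}\t{v.pos_bp}\t.\t{v.ref_base}\t{v.alt_base}"
                     f"\t.\t.\t{info}\tGT\t{gts}\n")
    return path


def read_vcf(path: str) -> VariantSet:
    """Read an uncompressed VCF with GT fields into a VariantSet."""
    sample_ids: list[str] = []
    variants: list[Variant] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alt, _q, _f, info = parts[:8]
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            genos = []
            for field in parts[9:]:
                gt = field.split(":")[gt_i].replace("|", "/")
                genos.append(_GT_CODE.get(tuple(gt.split("/")), -1))
            truth = None
            for kv in info.split(";"):
                if kv.startswith("TRUTH="):
                    truth = kv[6:]
            variants.append(Variant(
                chrom=chrom, pos_bp=int(pos), ref_base=ref, alt_base=alt,
                genotypes=np.array(genos, dtype=np.int8), truth_class=truth))
    return VariantSet(sample_ids=sample_ids, variants=variants)


# ---------------------------------------------------------------------------
# FASTA, transcripts, phenotype tables
# ---------------------------------------------------------------------------

def write_fasta(records: dict[str, str], path: str) -> str:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="")
         for name, seq in records.items()],
        path, "fasta")
    return path


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_grade_table(table: pd.DataFrame, path: str) -> str:
    table.to_csv(path, sep="\t")
    return path


def read_grade_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="condition")
    missing = set(GRADE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"grade table missing columns {sorted(missing)}")
    return table


def write_cilia_samples(samples: list[CiliaSample], path: str) -> str:
    frames = []
    for s in samples:
        df = s.cells.copy()
        df.insert(0, "condition", s.condition)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    return path


def read_cilia_samples(path: str) -> list[CiliaSample]:
    df = pd.read_csv(path, sep="\t")
    return [
        CiliaSample(condition=cond, cells=sub.drop(columns=["condition"])
                    .reset_index(drop=True))
        for cond, sub in df.groupby("condition", sort=False)
    ]


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
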