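"""Readers and writers for the standard text formats the toolkit exchanges.

FASTA goes through Biopython; VCF reading uses cyvcf2 when available (the
writer emits plain VCF v4.2 text with GT-only FORMAT fields, which is all
the genotype matrix carries). Tabular formats (sample sheets, bedGraph,
BED, TIP/support tables, alignment-block TSVs) go through pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variants import MISSING, GenotypeMatrix

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_GT_CODE = {v: k for k, v in _GT_STRING.items()}


# --- FASTA -----------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_te_library(entries, path: str | Path) -> Path:
    """TE library FASTA with RepeatMasker-style ``>id#family`` headers."""
    path = Path(path)
    records = [SeqRecord(Seq(seq), id=f"te{i + 1}#{family}", description="")
               for i, (family, seq) in enumerate(entries)]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_te_library(path: str | Path) -> list[tuple[str, str]]:
    """Parse ``>id#family`` headers into (family, sequence) pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        family = rec.id.split("#", 1)[1] if "#" in rec.id else rec.id
        out.append((family, str(rec.seq).upper()))
    return out


# --- VCF -------------------------------------------------------------------

def write_vcf(m: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal VCF v4.2 with GT fields only."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, grp in m.sites.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "\t".join(m.samples["sample_id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        gt = np.vectorize(_GT_STRING.get)(m.genotypes)
        for i, row in enumerate(m.sites.itertuples(index=False)):
            fields = [row.chrom, str(int(row.pos)), ".", row.ref, row.alt,
                      f"{float(row.qual):g}", "PASS", ".", "GT"]
            fh.write("\t".join(fields + list(gt[i])) + "\n")
    return path


def read_vcf(path: str | Path, sample_sheet: pd.DataFrame) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a GenotypeMatrix.

    ``sample_sheet`` must provide sex and group for every VCF sample. Uses
    cyvcf2 when importable and falls back to a plain-text GT reader
    otherwise; multi-allelic records are rejected.
    """
    path = str(path)
    try:
        from cyvcf2 import VCF
    except ImportError:
        VCF = None
    if VCF is not None:
        vcf = VCF(path)
        vcf_samples = list(vcf.samples)
        rows, genos = [], []
        for v in vcf:
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                raise ValueError(f"non-biallelic-SNP record at {v.CHROM}:{v.POS}")
            # cyvcf2 gt_types: 0=hom_ref 1=het 2=unknown 3=hom_alt
            codes = np.select(
                [v.gt_types == 0, v.gt_types == 1, v.gt_types == 3],
                [0, 1, 2], default=MISSING).astype(np.int8)
            rows.append((v.CHROM, v.POS, v.REF, v.ALT[0],
                         v.QUAL if v.QUAL is not None else 60.0, None))
            genos.append(codes)
    else:
        vcf_samples, rows, genos = _read_vcf_text(path)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual",
                                        "region_label"])
    sheet = sample_sheet.set_index("sample_id").loc[vcf_samples].reset_index()
    return GenotypeMatrix(sites, sheet[["sample_id", "sex", "group"]],
                          np.array(genos, dtype=np.int8))


def _read_vcf_text(path: str):
    vcf_samples, rows, genos = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                vcf_samples = fields[9:]
                continue
            chrom, pos, _, ref, alt, qual = fields[:6]
            if "," in alt or len(ref) != 1 or len(alt) != 1:
                raise ValueError(f"non-biallelic-SNP record at {chrom}:{pos}")
            fmt = fields[8].split(":")
            gt_i = fmt.index("GT")
            codes = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_i].replace("|", "/")
                codes.append(_GT_CODE.get(gt, MISSING))
            rows.append((chrom, int(pos), ref, alt,
                         float(qual) if qual != "." else 60.0, None))
            genos.append(np.array(codes, dtype=np.int8))
    return vcf_samples, rows, genos


# --- tabular ---------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> Path:
    return write_tsv(samples[["sample_id", "sex", "group"]], path)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = {"sample_id", "sex", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    return df


def write_bedgraph(bins: pd.DataFrame, values, path: str | Path) -> Path:
    df = bins[["chrom", "start", "end"]].copy()
    df["value"] = np.asarray(values)
    df.to_csv(path, sep="\t", index=False, header=False)
    return Path(path)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"])


def write_bed(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, sep="\t", index=False, header=False)
    return Path(path)


def read_bed(path: str | Path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


# --- alignment blocks ------------------------------------------------------

BLOCK_COLUMNS = ["qry_chrom", "qry_start", "qry_end", "strand",
                 "ref_chrom", "ref_start", "ref_end", "identity"]


def write_blocks(blocks, path: str | Path) -> Path:
    """PAF-like TSV of alignment blocks (qname, qstart, qend, strand, tname,
    tstart, tend, identity)."""
    rows = [(b.qry_chrom, b.qry_start, b.qry_end, b.strand,
             b.ref_chrom, b.ref_start, b.ref_end, b.identity) for b in blocks]
    return write_tsv(pd.DataFrame(rows, columns=BLOCK_COLUMNS), path)


def read_blocks(path: str | Path):
    """Read precomputed alignment blocks (the production input path)."""
    from .tips import AlignmentBlock

    df = pd.read_csv(path, sep="\t")
    missing = set(BLOCK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"block file lacks columns: {sorted(missing)}")
    return [AlignmentBlock(ref_chrom=r.ref_chrom, qry_chrom=r.qry_chrom,
                           ref_start=int(r.ref_start), ref_end=int(r.ref_end),
                           qry_start=int(r.qry_start), qry_end=int(r.qry_end),
                           strand=r.strand, identity=float(r.identity))
            for r in df.itertuples(index=False)]


# --- gene models -----------------------------------------------------------

def read_gene_models_bed12(path: str | Path):
    """BED12 gene models; blocks are taken as CDS exons, one transcript per
    record."""
    from .variants import GeneModel

    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            genes.append(GeneModel(name, chrom, strand, exons))
    return genes


def read_gene_models_gff3(path: str | Path):
    """GFF3 gene models: CDS features grouped by Parent (first transcript per
    gene when several share a Parent)."""
    from .variants import GeneModel

    by_tx: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            parent = attrs.get("Parent") or attrs.get("ID") or "tx"
            tx = by_tx.setdefault(parent, {"chrom": f[0], "strand": f[6], "exons": []})
            tx["exons"].append((int(f[3]) - 1, int(f[4])))  # GFF is 1-based closed
    return [GeneModel(name, tx["chrom"], tx["strand"], tuple(sorted(tx["exons"])))
            for name, tx in by_tx.items()]
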