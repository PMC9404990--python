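"""Genotype matrices, site filtering, fully sex-linked SNP classification,
cross-group sharing, and SNP functional-effect annotation.

A *fully sex-linked* SNP, on a Y-chromosome reference in an XY system, is a
biallelic site that is heterozygous (0/1) in every male and homozygous for
the alternate allele (1/1) in every female: the reference (Y) allele is
carried only by the Y haplotype, so it cosegregates perfectly with sex.

Genotypes are encoded as small integers throughout:

====  ==================
code  meaning
====  ==================
0     hom_ref (0/0)
1     het (0/1)
2     hom_alt (1/1)
-1    missing (./.)
====  ==================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .utils import percentage_table

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "region_label"]
SAMPLE_COLUMNS = ["sample_id", "sex", "group"]


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid genotype codes with site and sample metadata.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom, pos (1-based), ref, alt, qual,
        region_label`` (``region_label`` may be None). Positions must be
        strictly increasing within each chromosome.
    samples
        DataFrame with columns ``sample_id, sex ('F'/'M'), group``.
    genotypes
        ``(n_sites, n_samples)`` int8 array of codes 0/1/2/-1.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    genotypes: np.ndarray
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype table is {self.genotypes.shape}, expected "
                f"({len(self.sites)}, {len(self.samples)})"
            )
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id")
        if not self.samples["sex"].isin(["F", "M"]).all():
            raise ValueError("sample sex must be 'F' or 'M'")
        for _, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("site positions must be strictly increasing per chromosome")
        bad = self.sites["ref"] == self.sites["alt"]
        if bad.any():
            raise ValueError("biallelic sites require ref != alt")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_ids(self) -> list[tuple[str, int]]:
        """Site identifiers as (chrom, 1-based pos) tuples."""
        return list(zip(self.sites["chrom"], self.sites["pos"].astype(int)))

    def subset_samples(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            keep = self.samples["sample_id"].isin(mask).to_numpy()
        else:
            keep = mask
        return GenotypeMatrix(self.sites.copy(), self.samples.loc[keep],
                              self.genotypes[:, keep])

    def by_group(self, group: str) -> "GenotypeMatrix":
        return self.subset_samples((self.samples["group"] == group).to_numpy())

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(self.sites.loc[mask], self.samples.copy(),
                              self.genotypes[mask, :])

    def dosage(self) -> np.ndarray:
        """Alternate-allele dosage in {0, 1, 2} with NaN for missing."""
        d = self.genotypes.astype(float)
        d[self.genotypes == MISSING] = np.nan
        return d

    def allele_stats(self) -> pd.DataFrame:
        """Per-site called counts, alt-allele frequency, MAF and MAC
        computed over non-missing genotypes only."""
        g = self.genotypes
        called = (g != MISSING).sum(axis=1)
        alt_count = np.where(g == HET, 1, 0).sum(axis=1) + 2 * (g == HOM_ALT).sum(axis=1)
        total_alleles = 2 * called
        with np.errstate(invalid="ignore", divide="ignore"):
            alt_freq = np.where(total_alleles > 0, alt_count / total_alleles, np.nan)
        maf = np.minimum(alt_freq, 1 - alt_freq)
        mac = np.minimum(alt_count, total_alleles - alt_count)
        return pd.DataFrame({
            "called": called,
            "alt_freq": alt_freq,
            "maf": maf,
            "mac": mac,
            "call_rate": np.where(self.n_samples > 0, called / self.n_samples, np.nan),
        })


@dataclass(frozen=True)
class EffectAnnotation:
    """Functional classification of one SNP against gene models."""

    site_id: tuple
    category: str          # exonic | intronic | intergenic
    coding_effect: str     # synonymous | nonsynonymous | stopgain | stoploss | none

    def __post_init__(self) -> None:
        if (self.coding_effect != "none") != (self.category == "exonic"):
            raise ValueError("coding_effect != 'none' iff category == 'exonic'")


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript protein-coding gene model.

    ``exons`` are CDS exons as 0-based half-open intervals, sorted by start;
    the concatenated exon length must be divisible by 3.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def filter_sites(m: GenotypeMatrix, maf_min: float = 0.05, mac_min: int = 4,
                 qual_min: float = 30, min_call_rate: float = 0.9) -> GenotypeMatrix:
    """Quality/frequency site filtering of a genotype matrix.

    Retains sites with minor-allele frequency strictly above ``maf_min``,
    minor-allele count >= ``mac_min``, site quality >= ``qual_min`` and call
    rate >= ``min_call_rate`` (all boundaries inclusive except MAF, whose
    exclusion of rare alleles is strict; frequencies are computed over
    called genotypes only). Per-criterion removal counts are recorded in
    ``filter_log`` of the returned matrix. Removing every site yields an
    empty matrix, not an error.
    """
    if m.n_sites == 0:
        raise ValueError("empty genotype matrix")
    stats = m.allele_stats()
    maf = stats["maf"].to_numpy()
    pass_maf = np.nan_to_num(maf, nan=0.0) > maf_min
    pass_mac = np.nan_to_num(stats["mac"].to_numpy(), nan=0) >= mac_min
    qual = m.sites["qual"].to_numpy(dtype=float)
    pass_qual = qual >= qual_min
    pass_call = stats["call_rate"].to_numpy() >= min_call_rate
    keep = pass_maf & pass_mac & pass_qual & pass_call
    log = {
        "input_sites": int(m.n_sites),
        "removed_maf": int((~pass_maf).sum()),
        "removed_mac": int((~pass_mac).sum()),
        "removed_qual": int((~pass_qual).sum()),
        "removed_call_rate": int((~pass_call).sum()),
        "retained": int(keep.sum()),
    }
    out = m.subset_sites(keep)
    out.filter_log = log
    if log["retained"] == 0:
        import warnings

        warnings.warn("all sites removed by filters", stacklevel=2)
    return out


def _sex_masks(m: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    males = (m.samples["sex"] == "M").to_numpy()
    females = (m.samples["sex"] == "F").to_numpy()
    if males.sum() == 0 or females.sum() == 0:
        raise ValueError("sex-linkage classification requires both males and females")
    return males, females


def classify_fully_sex_linked_snps(m: GenotypeMatrix,
                                   allowed_missing: int = 0) -> list[tuple[str, int]]:
    """Sites heterozygous in all males and homozygous-alternate in all females.

    A sample with a missing genotype at a site disqualifies the site unless
    at most ``allowed_missing`` samples per sex are missing (default strict:
    0); all *called* genotypes must conform in either mode. Returns site ids
    as ``(chrom, pos)`` tuples.
    """
    males, females = _sex_masks(m)
    g = m.genotypes
    gm, gf = g[:, males], g[:, females]
    ok_m = ((gm == HET) | (gm == MISSING)).all(axis=1) & \
        ((gm == MISSING).sum(axis=1) <= allowed_missing)
    ok_f = ((gf == HOM_ALT) | (gf == MISSING)).all(axis=1) & \
        ((gf == MISSING).sum(axis=1) <= allowed_missing)
    keep = ok_m & ok_f
    ids = m.site_ids()
    return [ids[i] for i in np.flatnonzero(keep)]


def sharing_proportion(linked_sites: Sequence[tuple[str, int]], m_b: GenotypeMatrix,
                       allowed_missing: int = 0) -> float:
    """Fraction of group-A fully sex-linked sites that are also fully
    sex-linked in group B; positions absent from B count as unshared."""
    if len(linked_sites) == 0:
        raise ValueError("linked_sites is empty")
    linked_b = set(classify_fully_sex_linked_snps(m_b, allowed_missing=allowed_missing))
    return sum(1 for s in linked_sites if tuple(s) in linked_b) / len(linked_sites)


def _cds_index(gene: GeneModel, pos0: int) -> int | None:
    """0-based index of a genomic position within the gene's spliced CDS,
    in transcription order; None if the position falls in an intron."""
    exons = sorted(gene.exons)
    offset = 0
    plus_index = None
    for s, e in exons:
        if s <= pos0 < e:
            plus_index = offset + (pos0 - s)
            break
        offset += e - s
    if plus_index is None:
        return None
    if gene.strand == "+":
        return plus_index
    return gene.cds_length - 1 - plus_index


def annotate_effect(site, gene_models: Iterable[GeneModel],
                    genome_sequence: Mapping[str, str] | str) -> EffectAnnotation:
    """Classify a biallelic SNP as exonic/intronic/intergenic and, for exonic
    sites, call the coding effect from the reference vs alternate codon.

    ``site`` needs attributes/keys ``chrom, pos (1-based), ref, alt``. The
    standard genetic code is used, strand-aware: identical amino acids give
    ``synonymous``, sense-to-stop ``stopgain``, stop-to-sense ``stoploss``,
    any other change ``nonsynonymous``. The first gene model containing the
    position is used.
    """
    chrom = site["chrom"] if isinstance(site, (dict, pd.Series)) else site.chrom
    pos = int(site["pos"] if isinstance(site, (dict, pd.Series)) else site.pos)
    ref = site["ref"] if isinstance(site, (dict, pd.Series)) else site.ref
    alt = site["alt"] if isinstance(site, (dict, pd.Series)) else site.alt
    seq = genome_sequence if isinstance(genome_sequence, str) else genome_sequence[chrom]
    pos0 = pos - 1
    site_id = (chrom, pos)

    gene = next((g for g in gene_models
                 if g.chrom == chrom and g.start <= pos0 < g.end), None)
    if gene is None:
        return EffectAnnotation(site_id, "intergenic", "none")
    if gene.cds_length % 3 != 0:
        raise ValueError(f"CDS length of transcript {gene.gene_id} not divisible by 3")

    idx = _cds_index(gene, pos0)
    if idx is None:
        return EffectAnnotation(site_id, "intronic", "none")

    if seq[pos0].upper() != ref.upper():
        raise ValueError(
            f"reference base at {chrom}:{pos} is {seq[pos0]!r}, site says {ref!r}")

    cds = "".join(seq[s:e] for s, e in sorted(gene.exons)).upper()
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    codon_i, within = divmod(idx, 3)
    codon_ref = cds[3 * codon_i: 3 * codon_i + 3]
    alt_base = alt.upper() if gene.strand == "+" else str(Seq(alt.upper()).complement())
    codon_alt = codon_ref[:within] + alt_base + codon_ref[within + 1:]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    if aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "stopgain"
    elif aa_ref == "*":
        effect = "stoploss"
    else:
        effect = "nonsynonymous"
    return EffectAnnotation(site_id, "exonic", effect)


def summarize_effects(annotations: Sequence[EffectAnnotation],
                      total_sites: int | None = None) -> pd.DataFrame:
    """Counts and percentages of effect categories.

    Percentages are over ``total_sites`` (default: the number of
    annotations, i.e. all classified SNPs in the region of interest),
    rounded half-even to two decimals. An empty list gives an all-zero
    table.
    """
    categories = ["exonic", "intronic", "intergenic"]
    effects = ["synonymous", "nonsynonymous", "stopgain", "stoploss"]
    counts = {c: 0 for c in categories + effects}
    for a in annotations:
        counts[a.category] += 1
        if a.coding_effect != "none":
            counts[a.coding_effect] += 1
    if total_sites is None:
        total_sites = len(annotations)
    return percentage_table(counts, total=max(total_sites, 1) if annotations else 1)
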