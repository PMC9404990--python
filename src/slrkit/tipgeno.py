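"""TIP genotyping from junction support and fully sex-linked TIP calling.

A TIP segregates as a biallelic presence/absence variant. Upstream read
mapping against a *TE reference* (insertion sequence plus 1-kb flanks vs
joined flanks) yields, per sample, counts of reads supporting the presence
and absence alleles; this module turns those counts into genotypes, applies
the MAF/missingness filters, and classifies fully sex-linked TIPs.

Genotype codes: 2 = presence/presence, 1 = presence/absence,
0 = absence/absence, -1 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PRESENT, HET, ABSENT, MISSING = 2, 1, 0, -1


@dataclass(frozen=True)
class TEReference:
    """Presence and absence alleles of one TIP for junction-read mapping.

    The presence allele is the insertion plus up to ``flank_len`` bp of
    upstream and downstream flank; the absence allele joins the two flanks.
    Flanks truncated at chromosome ends are recorded.
    """

    tip_id: str
    presence_allele: str
    absence_allele: str
    flank_len: int
    upstream_truncated: bool = False
    downstream_truncated: bool = False

    def __post_init__(self) -> None:
        ins = len(self.presence_allele) - len(self.absence_allele)
        if ins <= 0:
            raise ValueError("presence allele must exceed absence allele by the insertion")


def build_te_reference(tip, genome: Mapping[str, str] | str,
                       flank_len: int = 1000) -> TEReference:
    """Extract the presence/absence allele pair for one TIP.

    ``tip`` needs ``tip_id, chrom, start, end`` (0-based half-open insertion
    coordinates on the host chromosome). ``flank_len = 0`` degenerates to
    the insertion sequence itself as presence allele.
    """
    seq = genome if isinstance(genome, str) else genome[tip.chrom]
    if not (0 <= tip.start < tip.end <= len(seq)):
        raise ValueError(
            f"TIP {tip.tip_id} at [{tip.start}, {tip.end}) outside chromosome "
            f"of length {len(seq)}")
    up_start = max(0, tip.start - flank_len)
    down_end = min(len(seq), tip.end + flank_len)
    upstream = seq[up_start:tip.start]
    insertion = seq[tip.start:tip.end]
    downstream = seq[tip.end:down_end]
    return TEReference(
        tip_id=tip.tip_id,
        presence_allele=upstream + insertion + downstream,
        absence_allele=upstream + downstream,
        flank_len=flank_len,
        upstream_truncated=len(upstream) < flank_len,
        downstream_truncated=len(downstream) < flank_len,
    )


def genotype_tip(support: tuple[int, int], min_support: int = 2) -> int:
    """Call one presence/absence genotype from junction support counts.

    ``support`` is ``(presence_reads, absence_reads)``. Both alleles at or
    above ``min_support`` give a heterozygote; exactly one allele supported
    (the other at zero) gives the corresponding homozygote; anything else -
    total support below ``min_support`` or conflicting sub-threshold
    evidence - is missing.
    """
    p, a = support
    if p < 0 or a < 0:
        raise ValueError("support counts must be >= 0")
    if p >= min_support and a >= min_support:
        return HET
    if p >= min_support and a == 0:
        return PRESENT
    if a >= min_support and p == 0:
        return ABSENT
    return MISSING


@dataclass
class TIPGenotypeTable:
    """TIPs x samples presence/absence genotypes with per-cell support."""

    tips: pd.DataFrame      # tip_id, side, chrom, start, end (+ extras)
    samples: pd.DataFrame   # sample_id, sex, group
    genotypes: np.ndarray   # (n_tips, n_samples) codes 2/1/0/-1
    support: np.ndarray | None = None  # (n_tips, n_samples, 2)
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tips = self.tips.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.tips), len(self.samples)):
            raise ValueError("genotype table dimensions inconsistent")

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def by_group(self, group: str) -> "TIPGenotypeTable":
        keep = (self.samples["group"] == group).to_numpy()
        return TIPGenotypeTable(self.tips.copy(), self.samples.loc[keep],
                                self.genotypes[:, keep],
                                None if self.support is None else self.support[:, keep])


def genotype_table(tips: pd.DataFrame, samples: pd.DataFrame,
                   support: pd.DataFrame, min_support: int = 2) -> TIPGenotypeTable:
    """Assemble a TIPGenotypeTable from a long-format junction-support table
    (columns ``tip_id, sample_id, presence_reads, absence_reads``)."""
    tip_ids = list(tips["tip_id"])
    sample_ids = list(samples["sample_id"])
    ti = {t: i for i, t in enumerate(tip_ids)}
    si = {s: j for j, s in enumerate(sample_ids)}
    geno = np.full((len(tip_ids), len(sample_ids)), MISSING, dtype=np.int8)
    sup = np.zeros((len(tip_ids), len(sample_ids), 2), dtype=int)
    for row in support.itertuples(index=False):
        i, j = ti.get(row.tip_id), si.get(row.sample_id)
        if i is None or j is None:
            continue
        sup[i, j] = (row.presence_reads, row.absence_reads)
        geno[i, j] = genotype_tip((row.presence_reads, row.absence_reads), min_support)
    return TIPGenotypeTable(tips.copy(), samples.copy(), geno, sup)


def filter_tip_genotypes(table: TIPGenotypeTable, maf_max_excl: float = 0.05,
                         missing_max: float = 0.08,
                         sample_missing_max: float = 0.5) -> TIPGenotypeTable:
    """Remove high-missing samples, then low-MAF / high-missing TIPs.

    Samples whose overall missing rate exceeds ``sample_missing_max`` are
    dropped first. A TIP is then removed if its minor (presence/absence)
    allele frequency over called samples is <= ``maf_max_excl`` or its
    missing rate is >= ``missing_max``; removal applies when *either*
    condition holds. Counts go to ``filter_log``.
    """
    g = table.genotypes
    sample_missing = (g == MISSING).mean(axis=0)
    keep_samples = sample_missing <= sample_missing_max
    if not keep_samples.any():
        raise ValueError("all samples removed by the missing-rate filter")
    g = g[:, keep_samples]

    called = (g != MISSING).sum(axis=1)
    presence_alleles = np.where(g == HET, 1, 0).sum(axis=1) + 2 * (g == PRESENT).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, presence_alleles / (2 * called), np.nan)
    maf = np.minimum(p, 1 - p)
    missing_rate = (g == MISSING).mean(axis=1)
    pass_maf = np.nan_to_num(maf, nan=0.0) > maf_max_excl
    pass_missing = missing_rate < missing_max
    keep_tips = pass_maf & pass_missing

    out = TIPGenotypeTable(
        table.tips.loc[keep_tips], table.samples.loc[keep_samples],
        g[keep_tips, :],
        None if table.support is None
        else table.support[np.ix_(keep_tips, keep_samples)])
    out.filter_log = {
        "input_tips": int(table.n_tips),
        "input_samples": int(table.n_samples),
        "removed_samples": int((~keep_samples).sum()),
        "removed_maf": int((~pass_maf).sum()),
        "removed_missing": int((~pass_missing).sum()),
        "retained_tips": int(keep_tips.sum()),
    }
    return out


def classify_fully_sex_linked_tips(table: TIPGenotypeTable,
                                   sides: Mapping[str, str] | None = None,
                                   allowed_missing: int = 0) -> list[str]:
    """TIP ids whose genotypes cosegregate perfectly with sex.

    An X-TIP is fully sex-linked iff every female is presence/presence and
    every male presence/absence; a Y-TIP iff every female is
    absence/absence and every male presence/absence. Missing genotypes
    disqualify a TIP unless at most ``allowed_missing`` per sex (strict by
    default). ``sides`` maps tip_id to "X"/"Y" (default: taken from the
    table's ``side`` column, accepting "X"/"X-TIP" style values).
    """
    males = (table.samples["sex"] == "M").to_numpy()
    females = (table.samples["sex"] == "F").to_numpy()
    if males.sum() == 0 or females.sum() == 0:
        raise ValueError("classification requires both males and females")
    if sides is None:
        sides = {row.tip_id: row.side for row in table.tips.itertuples(index=False)}

    out = []
    for i, tip_id in enumerate(table.tips["tip_id"]):
        side = str(sides[tip_id])[0].upper()
        gm = table.genotypes[i, males]
        gf = table.genotypes[i, females]
        female_target = PRESENT if side == "X" else ABSENT
        ok_m = (((gm == HET) | (gm == MISSING)).all()
                and (gm == MISSING).sum() <= allowed_missing)
        ok_f = (((gf == female_target) | (gf == MISSING)).all()
                and (gf == MISSING).sum() <= allowed_missing)
        if ok_m and ok_f:
            out.append(tip_id)
    return out
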