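"""Synthetic XY sex-chromosome population generator with full ground truth.

Emulates, at desk scale, the architecture of a dioecious plant XY pair:

* a pseudoautosomal backbone shared by X and Y (PAR1/PAR2),
* an inversion segment (IV) carried in reverse-complement orientation on Y,
* a Y-duplication region (YDR) present only on the Y haplotype,
* transposable-element insertions planted on exactly one haplotype each
  (the ground-truth TE insertion polymorphisms, TIPs),
* three diverging populations of XX females and XY males, two of which share
  the sex-linked haplotype structure (fully sex-linked SNPs/TIPs) while the
  third does not,
* per-sample read-depth tracks whose female depth is depleted only over the
  YDR, and per-TIP junction support counts.

Every stage is deterministic given ``SimConfig.seed``: stage-level child
seeds are derived from one top-level ``numpy.random.SeedSequence`` so that
downstream stages can be re-run independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import Region, RegionMap, broad_label
from .variants import GenotypeMatrix, HET, HOM_ALT, MISSING

_BASES = np.array(list("ACGT"))

# stage keys for per-component child seeds
_STAGE_REFERENCE, _STAGE_GENOTYPES, _STAGE_COVERAGE, _STAGE_SUPPORT = range(4)

X_CHROM, Y_CHROM = "chrX_sim", "chrY_sim"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GroupConfig:
    """One population: sample sizes, divergence from the ancestral reference
    (per-site substitution probability of the group consensus), and whether
    the group shares the sex-linked haplotype structure."""

    name: str
    n_females: int
    n_males: int
    divergence: float
    shares_slr: bool


DEFAULT_GROUPS = (
    GroupConfig("oleracea_like", 10, 10, 0.0, True),
    GroupConfig("turkestanica_like", 10, 10, 0.02, True),
    GroupConfig("tetrandra_like", 10, 10, 0.20, False),
)

DEFAULT_LAYOUT = (("PAR1", 800_000), ("IV", 500_000), ("YDR", 500_000), ("PAR2", 200_000))

DEFAULT_TE_FAMILIES = (("LTR/Copia", 300), ("LTR/Gypsy", 450), ("DNA/hAT", 220))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults give a 2-Mb chromosome with proportionally scaled PAR/IV/YDR,
    three populations of 10 females + 10 males each, ~10x depth, and clean
    (noise-free) genotypes; see docs/methods.md for the rationale behind
    each default.
    """

    chrom_length: int = 2_000_000
    region_layout: tuple = DEFAULT_LAYOUT
    n_te_insertions_x: int = 15
    n_te_insertions_y: int = 15
    n_te_insertions_ydr: int = 0
    te_families: tuple = DEFAULT_TE_FAMILIES
    te_copy_divergence: float = 0.10   # per-base substitution of each inserted copy vs consensus
    n_te_with_gap: int = 0             # planted insertions carrying an embedded assembly N-run
    gap_run_length: int = 60
    xy_snp_rate: float = 0.001         # X-vs-Y background substitution rate outside insertions
    snp_density: float = 0.005         # segregating sites per bp on the Y reference
    fully_linked_fraction: float = 0.05
    within_diversity: float = 0.30     # prob. a site is polymorphic within a group
    missing_rate: float = 0.0
    slr_divergence_scale: float = 0.30  # divergence multiplier inside IV+YDR
    groups: tuple = DEFAULT_GROUPS
    depth_mean: float = 20.0
    coverage_bin_size: int = 20_000
    female_ydr_dose: float = 0.0
    male_ydr_dose: float = 0.5
    poisson_noise: bool = True
    support_mean: float = 10.0
    support_poisson: bool = False
    tip_dropout: float = 0.0
    min_tip_spacing: int = 5_000
    region_edge_buffer: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if sum(length for _, length in self.region_layout) != self.chrom_length:
            raise ConfigError("region lengths must sum to chrom_length")
        names = [n for n, _ in self.region_layout]
        if self.n_te_insertions_ydr > 0 and "YDR" not in names:
            raise ConfigError("YDR insertions requested but region layout has no YDR entry")
        for frac in (self.fully_linked_fraction, self.within_diversity, self.missing_rate,
                     self.te_copy_divergence, self.xy_snp_rate, self.tip_dropout):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")
        for count in (self.n_te_insertions_x, self.n_te_insertions_y,
                      self.n_te_insertions_ydr, self.n_te_with_gap):
            if count < 0:
                raise ConfigError("counts must be >= 0")
        for g in self.groups:
            if g.n_females + g.n_males == 0:
                raise ConfigError(f"group {g.name} has zero samples")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,)))


@dataclass
class PlantedTIP:
    """Ground truth for one planted TE insertion polymorphism."""

    tip_id: str
    side: str          # "X" or "Y"
    chrom: str
    start: int         # 0-based half-open, final (post-insertion) coordinates
    end: int
    family: str
    in_slr: bool
    has_gap: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """Everything downstream recovery tests need to know about the truth."""

    region_map_x: RegionMap
    region_map_y: RegionMap
    planted_tips: list
    ydr_interval: tuple | None
    x_length: int
    y_length: int
    gap_intervals_x: list = field(default_factory=list)
    gap_intervals_y: list = field(default_factory=list)
    te_library: list = field(default_factory=list)   # (family, consensus) pairs
    fully_linked_site_ids: dict = field(default_factory=dict)  # group -> set of (chrom, pos)

    def tips_on(self, side: str) -> list:
        return [t for t in self.planted_tips if t.side == side]


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _revcomp(arr: np.ndarray) -> np.ndarray:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return np.array([comp[b] for b in arr[::-1]])


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases at ``rate``, always to a different base."""
    if rate <= 0:
        return arr.copy()
    arr = arr.copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr


def build_reference_pair(config: SimConfig):
    """Build the X and Y haplotype sequences plus ground truth.

    Returns ``(x_seq, y_seq, truth)`` where the sequences are python strings.
    X and Y share the PAR backbone up to ``xy_snp_rate`` substitutions, the
    IV segment is reverse-complemented on Y, the YDR exists only on Y, and
    each planted TE insertion is applied to exactly one haplotype.
    """
    config.validate()
    rng = config.rng(_STAGE_REFERENCE)
    layout = dict(config.region_layout)
    order = [name for name, _ in config.region_layout]

    segments = {name: _random_seq(rng, length) for name, length in config.region_layout}

    # consensus per family, generated once and reused for every insertion
    te_library = [(fam, "".join(_random_seq(rng, length)))
                  for fam, length in config.te_families]

    x_parts, y_parts = [], []
    for name in order:
        seg = segments[name]
        if broad_label(name) == "YDR":
            y_parts.append((name, seg))
            continue
        x_parts.append((name, seg))
        seg_y = _mutate(rng, seg, config.xy_snp_rate)
        if broad_label(name) == "IV":
            seg_y = _revcomp(seg_y)
        y_parts.append((name, seg_y))

    def assemble(parts):
        seqs, regions, pos = [], [], 0
        for name, seg in parts:
            seqs.append(seg)
            regions.append((name, pos, pos + seg.size))
            pos += seg.size
        return np.concatenate(seqs) if seqs else np.array([], dtype="<U1"), regions

    x_seq, x_regions = assemble(x_parts)
    y_seq, y_regions = assemble(y_parts)

    # --- choose insertion sites on the pre-insertion backbones -------------
    def insertable_union(regions, allow_names):
        buf = config.region_edge_buffer
        out = []
        for name, s, e in regions:
            if name in allow_names and e - s > 2 * buf:
                out.append((s + buf, e - buf))
        return out

    syntenic = [n for n in order if broad_label(n) != "YDR"]

    def draw_positions(rng, intervals, n):
        if n == 0:
            return []
        if not intervals:
            raise ConfigError("no region wide enough to host the requested insertions")
        lens = np.array([e - s for s, e in intervals])
        chosen: list[int] = []
        for _ in range(200 * n):
            if len(chosen) == n:
                break
            i = rng.choice(len(intervals), p=lens / lens.sum())
            p = int(rng.integers(intervals[i][0], intervals[i][1]))
            if all(abs(p - q) >= config.min_tip_spacing for q in chosen):
                chosen.append(p)
        if len(chosen) < n:
            raise ConfigError("could not place TE insertions with the requested spacing")
        return sorted(chosen)

    # X and Y insertion points are drawn jointly in X-backbone coordinates so
    # that spacing holds across haplotypes: an X insertion and a Y insertion
    # at nearly the same syntenic spot would cancel in the alignment diagonal
    # and masquerade as a complex substitution instead of two clean TIPs.
    joint = draw_positions(rng, insertable_union(x_regions, syntenic),
                           config.n_te_insertions_x + config.n_te_insertions_y)
    joint = [joint[i] for i in rng.permutation(len(joint))]
    x_pos = sorted(joint[:config.n_te_insertions_x])

    def to_y_coord(p: int) -> int:
        for (xn, xs, xe), (yn, ys, ye) in zip(x_regions, [r for r in y_regions
                                                          if broad_label(r[0]) != "YDR"]):
            if xs <= p < xe:
                return ys + (xe - p) if broad_label(xn) == "IV" else ys + (p - xs)
        raise ConfigError("insertion point outside syntenic regions")

    y_syn_pos = [to_y_coord(p) for p in joint[config.n_te_insertions_x:]]
    y_ydr_pos = draw_positions(rng, insertable_union(
        y_regions, [n for n in order if broad_label(n) == "YDR"]),
        config.n_te_insertions_ydr)
    y_pos = sorted(y_syn_pos + y_ydr_pos)

    planted: list[PlantedTIP] = []
    n_gapped = 0

    def apply_insertions(seq, regions, positions, side, chrom, rng):
        nonlocal n_gapped
        pieces, cursor, offset = [], 0, 0
        tips, gaps = [], []
        label_map = RegionMap([Region(n, chrom, s, e) for n, s, e in regions])
        for j, p in enumerate(positions):
            fam_i = int(rng.integers(0, len(te_library)))
            fam, consensus = te_library[fam_i]
            copy = _mutate(rng, np.array(list(consensus)), config.te_copy_divergence)
            if n_gapped < config.n_te_with_gap:
                g = min(config.gap_run_length, copy.size)
                lo = (copy.size - g) // 2
                copy[lo:lo + g] = "N"
                has_gap = True
                n_gapped += 1
            else:
                has_gap = False
            pieces.append(seq[cursor:p])
            pieces.append(copy)
            start = p + offset
            end = start + copy.size
            region = label_map.broad_label_of(p)
            tips.append(PlantedTIP(
                tip_id=f"{side}-TIP{len(planted) + len(tips) + 1:04d}",
                side=side, chrom=chrom, start=start, end=end, family=fam,
                in_slr=region in ("IV", "YDR"), has_gap=has_gap))
            if has_gap:
                glo = start + (copy.size - min(config.gap_run_length, copy.size)) // 2
                gaps.append((glo, glo + min(config.gap_run_length, copy.size)))
            cursor = p
            offset += copy.size
        pieces.append(seq[cursor:])
        final = np.concatenate(pieces) if pieces else seq
        # shift region boundaries by the insertions that precede them
        shifted = []
        ins = sorted(zip(positions, [t.length for t in tips]))
        for name, s, e in regions:
            ds = sum(length for p, length in ins if p < s)
            de = sum(length for p, length in ins if p < e)
            shifted.append(Region(name, chrom, s + ds, e + de))
        return final, RegionMap(shifted), tips, gaps

    x_final, region_map_x, x_tips, x_gaps = apply_insertions(
        x_seq, x_regions, x_pos, "X", X_CHROM, rng)
    planted.extend(x_tips)
    y_final, region_map_y, y_tips, y_gaps = apply_insertions(
        y_seq, y_regions, y_pos, "Y", Y_CHROM, rng)
    planted.extend(y_tips)

    ydr = None
    if "YDR" in region_map_y:
        r = region_map_y.get("YDR")
        ydr = (r.start, r.end)

    truth = TruthSet(
        region_map_x=region_map_x, region_map_y=region_map_y,
        planted_tips=planted, ydr_interval=ydr,
        x_length=int(x_final.size), y_length=int(y_final.size),
        gap_intervals_x=x_gaps, gap_intervals_y=y_gaps,
        te_library=te_library,
    )
    return "".join(x_final), "".join(y_final), truth


def make_sample_sheet(config: SimConfig) -> pd.DataFrame:
    """Deterministic sample sheet: per group, females then males."""
    rows = []
    for g in config.groups:
        tag = g.name[:3]
        for i in range(g.n_females):
            rows.append((f"{tag}_F{i + 1:02d}", "F", g.name))
        for i in range(g.n_males):
            rows.append((f"{tag}_M{i + 1:02d}", "M", g.name))
    return pd.DataFrame(rows, columns=["sample_id", "sex", "group"])


def simulate_genotypes(truth: TruthSet, config: SimConfig) -> GenotypeMatrix:
    """Simulate a biallelic SNP genotype matrix on the Y reference.

    Each group carries a consensus allele per site that differs from the
    ancestral reference with probability ``divergence`` (scaled by
    ``slr_divergence_scale`` inside IV+YDR); with probability
    ``within_diversity`` a site is polymorphic within the group and
    individual genotypes are binomial draws. A ``fully_linked_fraction`` of
    SLR sites is then forced fully sex-linked (males het, females hom-alt)
    in every SLR-sharing group, and those site ids are recorded in
    ``truth.fully_linked_site_ids`` per group. Missing genotypes are
    injected at ``missing_rate``.
    """
    config.validate()
    rng = config.rng(_STAGE_GENOTYPES)
    samples = make_sample_sheet(config)

    n_sites = int(round(config.snp_density * truth.y_length))
    pos = np.sort(rng.choice(np.arange(1, truth.y_length + 1), size=n_sites,
                             replace=False))
    ref_i = rng.integers(0, 4, size=n_sites)
    alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4
    labels = np.array([truth.region_map_y.broad_label_of(p - 1) or "NA" for p in pos])
    in_slr = np.isin(labels, ["IV", "YDR"])

    slr_idx = np.flatnonzero(in_slr)
    n_linked = int(round(config.fully_linked_fraction * slr_idx.size))
    linked_idx = np.sort(rng.choice(slr_idx, size=n_linked, replace=False)) \
        if n_linked else np.array([], dtype=int)
    linked_mask = np.zeros(n_sites, dtype=bool)
    linked_mask[linked_idx] = True

    geno = np.empty((n_sites, len(samples)), dtype=np.int8)
    col = 0
    for g in config.groups:
        n = g.n_females + g.n_males
        div = np.where(in_slr, g.divergence * config.slr_divergence_scale, g.divergence)
        flipped = rng.random(n_sites) < div
        poly = rng.random(n_sites) < config.within_diversity
        minor = rng.uniform(0.1, 0.5, size=n_sites)
        p_alt = np.where(flipped, 1.0 - minor * poly, minor * poly)
        block = rng.binomial(2, p_alt[:, None], size=(n_sites, n)).astype(np.int8)
        if g.shares_slr and linked_idx.size:
            in_group = samples["group"].eq(g.name).to_numpy()
            is_f = (samples.loc[in_group, "sex"] == "F").to_numpy()
            block[np.ix_(linked_idx, is_f)] = HOM_ALT
            block[np.ix_(linked_idx, ~is_f)] = HET
        geno[:, col:col + n] = block
        col += n

    if config.missing_rate > 0:
        geno[rng.random(geno.shape) < config.missing_rate] = MISSING

    qual = np.round(rng.uniform(40, 100, size=n_sites), 1)
    sites = pd.DataFrame({
        "chrom": Y_CHROM, "pos": pos.astype(int),
        "ref": _BASES[ref_i], "alt": _BASES[alt_i],
        "qual": qual, "region_label": labels,
    })
    ids = list(zip(sites["chrom"], sites["pos"].astype(int)))
    linked_ids = {ids[i] for i in linked_idx}
    truth.fully_linked_site_ids = {
        g.name: (set(linked_ids) if g.shares_slr else set()) for g in config.groups
    }
    return GenotypeMatrix(sites, samples, geno)


def simulate_coverage_tracks(truth: TruthSet, config: SimConfig):
    """Per-sample binned read-depth tracks on the Y reference.

    Returns ``(bins, depths, samples)``: ``bins`` is a DataFrame with
    ``chrom/start/end``, ``depths`` maps sample_id to a per-bin mean-depth
    array. Female depth is ``female_ydr_dose * depth_mean`` over the YDR and
    ``depth_mean`` elsewhere; males carry ``male_ydr_dose`` (haploid dose by
    default) over the YDR. With ``poisson_noise``, per-bin read counts are
    Poisson draws.
    """
    config.validate()
    if config.depth_mean <= 0:
        raise ConfigError("depth_mean must be > 0")
    bin_size = config.coverage_bin_size
    if bin_size > truth.y_length:
        raise ConfigError("bin size exceeds chromosome length")
    rng = config.rng(_STAGE_COVERAGE)
    samples = make_sample_sheet(config)

    starts = np.arange(0, truth.y_length, bin_size)
    ends = np.minimum(starts + bin_size, truth.y_length)
    bin_len = ends - starts

    ydr_frac = np.zeros(starts.size)
    if truth.ydr_interval is not None:
        ys, ye = truth.ydr_interval
        ov = np.minimum(ends, ye) - np.maximum(starts, ys)
        ydr_frac = np.clip(ov, 0, None) / bin_len

    depths = {}
    for _, row in samples.iterrows():
        dose = config.female_ydr_dose if row["sex"] == "F" else config.male_ydr_dose
        mean = config.depth_mean * ((1 - ydr_frac) + dose * ydr_frac)
        if config.poisson_noise:
            depth = rng.poisson(mean * bin_len) / bin_len
        else:
            depth = mean.astype(float)
        depths[row["sample_id"]] = depth

    bins = pd.DataFrame({"chrom": Y_CHROM, "start": starts, "end": ends})
    return bins, depths, samples


@dataclass
class TIPSupportTable:
    """Simulated junction support plus the underlying true genotypes."""

    support: pd.DataFrame        # tip_id, sample_id, presence_reads, absence_reads
    true_genotypes: pd.DataFrame  # tips x samples codes (0/1/2, -1 never planted)


def simulate_tip_support(truth: TruthSet, config: SimConfig) -> TIPSupportTable:
    """Simulate per-sample junction support counts for every planted TIP.

    True genotypes follow the sex-linkage logic for SLR TIPs in SLR-sharing
    groups (X-TIPs: females presence/presence, males presence/absence;
    Y-TIPs: males presence/absence, females absence/absence) and
    Hardy-Weinberg draws at presence frequency 0.5 for PAR TIPs and for the
    diverged group, where Y-SLR TIPs are absent and X-SLR TIPs fixed present
    (the insertion predates the split of the SLR-sharing groups only).
    Support per presence/absence allele is ``support_mean`` split across the
    two haplotypes (Poisson-distributed when ``support_poisson``); a cell
    drops out entirely with probability ``tip_dropout``.
    """
    if not truth.planted_tips:
        raise ConfigError("no planted TIPs in TruthSet")
    config.validate()
    rng = config.rng(_STAGE_SUPPORT)
    samples = make_sample_sheet(config)
    shares = {g.name: g.shares_slr for g in config.groups}

    codes = np.empty((len(truth.planted_tips), len(samples)), dtype=np.int8)
    for i, tip in enumerate(truth.planted_tips):
        for j, row in samples.iterrows():
            if tip.in_slr and shares[row["group"]]:
                if tip.side == "X":
                    codes[i, j] = 2 if row["sex"] == "F" else 1
                else:
                    codes[i, j] = 1 if row["sex"] == "M" else 0
            else:
                # PAR TIPs everywhere, and all TIPs in the diverged group,
                # segregate without sex linkage (HWE, presence freq 0.5)
                codes[i, j] = rng.binomial(2, 0.5)

    half = config.support_mean / 2.0

    def allele_reads(n_copies: int) -> float:
        mean = half * n_copies
        if mean == 0:
            return 0
        return int(rng.poisson(mean)) if config.support_poisson else int(round(mean))

    rows = []
    for i, tip in enumerate(truth.planted_tips):
        for j, row in samples.iterrows():
            if rng.random() < config.tip_dropout:
                p = a = 0
            else:
                c = codes[i, j]
                p = allele_reads(int(c))
                a = allele_reads(2 - int(c))
            rows.append((tip.tip_id, row["sample_id"], p, a))
    support = pd.DataFrame(
        rows, columns=["tip_id", "sample_id", "presence_reads", "absence_reads"])
    true_geno = pd.DataFrame(codes, index=[t.tip_id for t in truth.planted_tips],
                             columns=samples["sample_id"])
    return TIPSupportTable(support=support, true_genotypes=true_geno)


# ---------------------------------------------------------------------------
# file output

def write_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Run every stage and write FASTA/VCF/TSV/bedGraph/BED outputs.

    Returns a dict of written paths. Outputs are byte-identical across runs
    with the same config (including seed).
    """
    from . import io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x_seq, y_seq, truth = build_reference_pair(config)
    m = simulate_genotypes(truth, config)
    bins, depths, samples = simulate_coverage_tracks(truth, config)
    support = simulate_tip_support(truth, config) if truth.planted_tips else None

    paths = {}
    paths["x_fasta"] = sio.write_fasta({X_CHROM: x_seq}, outdir / "chrX_sim.fa")
    paths["y_fasta"] = sio.write_fasta({Y_CHROM: y_seq}, outdir / "chrY_sim.fa")
    paths["te_library"] = sio.write_te_library(truth.te_library, outdir / "te_library.fa")
    paths["vcf"] = sio.write_vcf(m, outdir / "genotypes.vcf")
    paths["samples"] = sio.write_sample_sheet(m.samples, outdir / "samples.tsv")
    covdir = outdir / "coverage"
    covdir.mkdir(exist_ok=True)
    for sid, depth in depths.items():
        sio.write_bedgraph(bins, depth, covdir / f"{sid}.bedgraph")
    paths["coverage_dir"] = covdir
    paths["regions_x"] = sio.write_bed(truth.region_map_x.to_frame(), outdir / "regions_x.bed")
    paths["regions_y"] = sio.write_bed(truth.region_map_y.to_frame(), outdir / "regions_y.bed")
    truth_df = pd.DataFrame(
        [(t.tip_id, t.side, t.chrom, t.start, t.end, t.family, t.in_slr, t.has_gap)
         for t in truth.planted_tips],
        columns=["tip_id", "side", "chrom", "start", "end", "family", "in_slr", "has_gap"])
    paths["truth_tips"] = sio.write_tsv(truth_df, outdir / "truth_tips.tsv")
    if support is not None:
        paths["tip_support"] = sio.write_tsv(support.support, outdir / "tip_support.tsv")
    return paths
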