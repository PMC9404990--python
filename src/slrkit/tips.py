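"""TE insertion polymorphism (TIP) detection between X and Y haplotypes.

The detection chain mirrors a whole-genome-alignment indel workflow:

1. :func:`align_pair` - exact unique-k-mer anchoring and same-diagonal
   chaining into alignment blocks (a toy aligner for synthetic data and
   tests; precomputed block files read via :func:`slrkit.io.read_blocks`
   are the production path),
2. :func:`one_to_one` - identity filtering plus a non-overlapping
   one-to-one block subset,
3. :func:`call_indels` - indels >= 50 bp between adjacent collinear blocks,
   with non-collinear blocks flagged as BRK,
4. :func:`filter_candidates` - exclusion of BRK features and candidates
   overlapping assembly N-gaps,
5. :func:`classify_te` - local alignment against a TE consensus library
   with the >= 80% identity / >= 80% coverage acceptance rule.

An insertion hosted by the X chromosome is an X-TIP; hosted by Y, a Y-TIP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq
from scipy import stats

from .regions import RegionMap, any_overlap
from .utils import percentage_table

# slack (bp) allowed on the "empty" side of a clean insertion gap
COLLINEAR_SLOP = 20


@dataclass(frozen=True)
class AlignmentBlock:
    """One gapless-diagonal alignment block (0-based half-open on both axes)."""

    ref_chrom: str
    qry_chrom: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    strand: str
    identity: float  # percent, 0-100

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end or self.qry_start >= self.qry_end:
            raise ValueError("block needs start < end on both axes")
        if not 0 <= self.identity <= 100:
            raise ValueError("identity must be a percentage in [0, 100]")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def weight(self) -> float:
        return self.ref_span * self.identity


@dataclass
class IndelCandidate:
    """A candidate insertion on one host chromosome, or a BRK discontinuity."""

    host: str        # "X" or "Y"
    chrom: str
    start: int
    end: int
    sequence: str
    feature: str     # "GAP" or "BRK"
    gap_overlap: bool = False
    syntenic: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TIPRecord:
    """An accepted TE insertion polymorphism."""

    tip_id: str
    side: str      # "X-TIP" or "Y-TIP"
    chrom: str
    start: int
    end: int
    family: str
    identity: float   # fraction, >= 0.8
    coverage: float   # fraction, >= 0.8

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# anchoring aligner

_LUT = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _LUT[b] = i
for i, b in enumerate(b"acgt"):
    _LUT[b] = i


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed k-mer codes and a validity mask (windows without N)."""
    arr = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = arr.size
    if n < k:
        raise ValueError(f"anchor k = {k} exceeds sequence length {n}")
    bad = np.concatenate([[0], np.cumsum(arr == 255)])
    valid = (bad[k:] - bad[:-k]) == 0
    vals = np.where(arr == 255, 0, arr).astype(np.uint64)
    codes = np.zeros(n - k + 1, dtype=np.uint64)
    for i in range(k):
        codes = (codes << np.uint64(2)) | vals[i: i + n - k + 1]
    return codes, valid


def _unique_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(sorted codes, positions) of k-mers occurring exactly once."""
    codes, valid = _kmer_codes(seq, k)
    pos = np.flatnonzero(valid)
    sub = codes[pos]
    order = np.argsort(sub, kind="stable")
    s, p = sub[order], pos[order]
    uniq = np.ones(s.size, dtype=bool)
    uniq[1:] &= s[1:] != s[:-1]
    uniq[:-1] &= s[:-1] != s[1:]
    return s[uniq], p[uniq]


def _chain_anchors(pa: np.ndarray, pb: np.ndarray, k: int, max_gap: int,
                   min_cluster: int, min_match: int):
    """Chain shared-diagonal anchors into (ref_start, ref_end, qry_start) blocks."""
    if pa.size == 0:
        return []
    diag = pb.astype(np.int64) - pa.astype(np.int64)
    order = np.lexsort((pa, diag))
    pa, pb, diag = pa[order], pb[order], diag[order]
    blocks = []
    i = 0
    n = pa.size
    while i < n:
        j = i
        while (j + 1 < n and diag[j + 1] == diag[i]
               and pa[j + 1] - (pa[j] + k) <= max_gap):
            j += 1
        span = pa[j] + k - pa[i]
        anchor_cov = int(np.minimum(np.diff(pa[i:j + 1]), k).sum() + k) if j > i else k
        if span >= min_cluster and anchor_cov >= min_match:
            blocks.append((int(pa[i]), int(pa[j] + k), int(pb[i])))
        i = j + 1
    return blocks


def align_pair(ref_seq: str, qry_seq: str, anchor_k: int = 21, max_gap: int = 1000,
               min_cluster: int = 90, min_match: int = 40,
               ref_name: str = "ref", qry_name: str = "qry") -> list[AlignmentBlock]:
    """Anchor-based toy alignment of two chromosome sequences.

    Blocks are maximal chains of k-mers that are unique in both sequences
    and share one diagonal, with inter-anchor gaps <= ``max_gap``; chains
    must span >= ``min_cluster`` bp and carry >= ``min_match`` anchor bp.
    Both orientations are searched; block identity is the percent base match
    over the block span. Not a general-purpose aligner: it exists for
    synthetic data and tests.
    """
    if not ref_seq or not qry_seq:
        raise ValueError("sequences must be non-empty")
    if anchor_k > len(ref_seq) or anchor_k > len(qry_seq):
        raise ValueError("anchor k larger than a sequence")

    codes_r, pos_r = _unique_kmers(ref_seq, anchor_k)
    blocks: list[AlignmentBlock] = []

    for strand, qseq in (("+", qry_seq),
                         ("-", str(Seq(qry_seq).reverse_complement()))):
        codes_q, pos_q = _unique_kmers(qseq, anchor_k)
        common, ir, iq = np.intersect1d(codes_r, codes_q,
                                        assume_unique=True, return_indices=True)
        pa, pb = pos_r[ir], pos_q[iq]
        for rs, re, qs in _chain_anchors(pa, pb, anchor_k, max_gap,
                                         min_cluster, min_match):
            qe = qs + (re - rs)
            a = ref_seq[rs:re]
            b = qseq[qs:qe]
            ident = 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
            if strand == "-":
                qs, qe = len(qry_seq) - qe, len(qry_seq) - qs
            blocks.append(AlignmentBlock(ref_name, qry_name, rs, re, qs, qe,
                                         strand, round(ident, 3)))
    blocks.sort(key=lambda b: (b.ref_start, b.qry_start))
    return blocks


# ---------------------------------------------------------------------------
# one-to-one filtering

def _overlaps_1d(s1: int, e1: int, s2: int, e2: int) -> bool:
    return min(e1, e2) - max(s1, s2) > 0


def one_to_one(blocks: Sequence[AlignmentBlock], min_identity: float = 90.0,
               max_trim: int = 50) -> list[AlignmentBlock]:
    """Identity-filtered, non-overlapping one-to-one block subset.

    Blocks under ``min_identity`` percent are dropped; remaining blocks are
    admitted greedily by weight (aligned length x identity, deterministic
    coordinate tie-break) subject to zero overlap with already-kept blocks
    on either axis. A candidate conflicting with kept blocks by up to
    ``max_trim`` bp in total is trimmed at its ends instead of dropped
    (anchors may legitimately cross an indel junction by a few bases, giving
    adjacent blocks a 1-2 bp overlap). The result is ordered by reference
    coordinate.
    """
    kept: list[AlignmentBlock] = []
    candidates = [b for b in blocks if b.identity >= min_identity]
    for b in sorted(candidates, key=lambda b: (-b.weight, b.ref_start, b.qry_start)):
        rs, re, qs, qe = b.ref_start, b.ref_end, b.qry_start, b.qry_end
        trimmed, ok, changed = 0, True, True
        while ok and changed:
            changed = False
            for o in kept:
                if b.ref_chrom == o.ref_chrom and rs < re and \
                        _overlaps_1d(rs, re, o.ref_start, o.ref_end):
                    if o.ref_start <= rs:
                        d = o.ref_end - rs
                        rs += d
                        if b.strand == "+":
                            qs += d
                        else:
                            qe -= d
                    elif o.ref_end >= re:
                        d = re - o.ref_start
                        re -= d
                        if b.strand == "+":
                            qe -= d
                        else:
                            qs += d
                    else:  # a kept block sits strictly inside the candidate
                        ok = False
                        break
                    trimmed += d
                    changed = True
                if b.qry_chrom == o.qry_chrom and qs < qe and \
                        _overlaps_1d(qs, qe, o.qry_start, o.qry_end):
                    if o.qry_start <= qs:
                        d = o.qry_end - qs
                        qs += d
                        if b.strand == "+":
                            rs += d
                        else:
                            re -= d
                    elif o.qry_end >= qe:
                        d = qe - o.qry_start
                        qe -= d
                        if b.strand == "+":
                            re -= d
                        else:
                            rs += d
                    else:
                        ok = False
                        break
                    trimmed += d
                    changed = True
            if trimmed > max_trim:
                ok = False
        if ok and rs < re and qs < qe:
            kept.append(AlignmentBlock(b.ref_chrom, b.qry_chrom, rs, re, qs, qe,
                                       b.strand, b.identity))
    kept.sort(key=lambda b: (b.ref_chrom, b.ref_start, b.qry_start))
    return kept


# ---------------------------------------------------------------------------
# indel calling

def _collinear_backbone(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Maximum-weight collinear chain per strand (weighted LIS on block order)."""
    backbone: list[AlignmentBlock] = []
    for strand in "+-":
        sub = [b for b in blocks if b.strand == strand]
        n = len(sub)
        if n == 0:
            continue
        best = [b.weight for b in sub]
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                if sub[j].ref_end <= sub[i].ref_start and (
                        sub[j].qry_end <= sub[i].qry_start if strand == "+"
                        else sub[i].qry_end <= sub[j].qry_start):
                    cand = best[j] + sub[i].weight
                    if cand > best[i]:
                        best[i], prev[i] = cand, j
        i = int(np.argmax(best))
        chain = []
        while i != -1:
            chain.append(sub[i])
            i = prev[i]
        backbone.extend(reversed(chain))
    backbone.sort(key=lambda b: b.ref_start)
    return backbone


def call_indels(blocks: Sequence[AlignmentBlock], ref_seq: str | None = None,
                qry_seq: str | None = None, min_len: int = 50,
                ref_host: str = "Y", qry_host: str = "X") -> list[IndelCandidate]:
    """Call insertion candidates >= ``min_len`` bp between adjacent collinear
    blocks of a one-to-one alignment.

    For each adjacent pair along the maximum-weight collinear backbone, a
    query gap exceeding the reference gap by >= ``min_len`` (with the
    reference gap ~0) is an insertion on the query chromosome, and
    symmetrically for the reference. One-to-one blocks off the backbone, and
    adjacent pairs violating collinearity or orientation, yield ``BRK``
    candidates, which downstream filtering removes. ``ref_host``/``qry_host``
    name the host chromosome ("Y"/"X" by convention: the query is the X
    haplotype aligned onto the Y reference).

    Input blocks must be sorted by reference coordinate and non-overlapping
    (the contract of :func:`one_to_one`); unsorted input raises.
    """
    blocks = list(blocks)
    for a, b in zip(blocks, blocks[1:]):
        if (a.ref_chrom, a.ref_start) > (b.ref_chrom, b.ref_start):
            raise ValueError("blocks must be sorted by reference coordinate")

    backbone = _collinear_backbone(blocks)
    off = [b for b in blocks if b not in backbone]
    out: list[IndelCandidate] = []
    for b in off:
        out.append(IndelCandidate(host=ref_host, chrom=b.ref_chrom,
                                  start=b.ref_start, end=b.ref_end,
                                  sequence="", feature="BRK"))

    def seq_slice(seq, s, e):
        return "" if seq is None else seq[s:e]

    for b1, b2 in zip(backbone, backbone[1:]):
        if b1.strand != b2.strand:
            continue  # inversion boundary: no simple gap to interpret
        g_ref = b2.ref_start - b1.ref_end
        if b1.strand == "+":
            g_qry = b2.qry_start - b1.qry_end
            qlo, qhi = b1.qry_end, b2.qry_start
        else:
            g_qry = b1.qry_start - b2.qry_end
            qlo, qhi = b2.qry_end, b1.qry_start
        if g_ref < 0 or g_qry < 0:
            out.append(IndelCandidate(host=ref_host, chrom=b1.ref_chrom,
                                      start=b1.ref_end, end=max(b2.ref_start, b1.ref_end + 1),
                                      sequence="", feature="BRK"))
            continue
        diff = g_qry - g_ref
        if diff >= min_len and g_ref <= COLLINEAR_SLOP:
            out.append(IndelCandidate(
                host=qry_host, chrom=b1.qry_chrom, start=qlo, end=qhi,
                sequence=seq_slice(qry_seq, qlo, qhi), feature="GAP"))
        elif -diff >= min_len and g_qry <= COLLINEAR_SLOP:
            out.append(IndelCandidate(
                host=ref_host, chrom=b1.ref_chrom, start=b1.ref_end, end=b2.ref_start,
                sequence=seq_slice(ref_seq, b1.ref_end, b2.ref_start), feature="GAP"))
        elif abs(diff) >= min_len:
            # both sides carry substantial unaligned sequence: not a clean indel
            out.append(IndelCandidate(host=ref_host, chrom=b1.ref_chrom,
                                      start=b1.ref_end, end=b2.ref_start,
                                      sequence="", feature="BRK"))
    return [c for c in out if c.feature == "BRK" or c.length >= min_len]


def filter_candidates(cands: Iterable[IndelCandidate],
                      gap_mask_x: Sequence[tuple[int, int]] = (),
                      gap_mask_y: Sequence[tuple[int, int]] = ()) -> list[IndelCandidate]:
    """Drop BRK features and candidates overlapping an assembly N-gap.

    Gap overlap uses any-overlap (>= 1 bp) semantics against the host
    chromosome's gap mask. Retained candidates are flagged syntenic (they
    arise between adjacent collinear one-to-one blocks by construction).
    """
    masks = {"X": list(gap_mask_x), "Y": list(gap_mask_y)}
    out = []
    for c in cands:
        if c.feature == "BRK":
            continue
        if any_overlap(c.start, c.end, masks.get(c.host, [])):
            continue
        out.append(replace_candidate(c, syntenic=True))
    return out


def replace_candidate(c: IndelCandidate, **kw) -> IndelCandidate:
    d = dict(host=c.host, chrom=c.chrom, start=c.start, end=c.end,
             sequence=c.sequence, feature=c.feature,
             gap_overlap=c.gap_overlap, syntenic=c.syntenic)
    d.update(kw)
    return IndelCandidate(**d)


# ---------------------------------------------------------------------------
# TE classification

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _local_identity_coverage(cand: str, consensus: str, aligner) -> tuple[float, float, float]:
    """(score, identity fraction, candidate coverage fraction) of the best
    local alignment of a candidate against one consensus."""
    aln = aligner.align(cand, consensus)
    if len(aln) == 0:
        return -np.inf, 0.0, 0.0
    best = aln[0]
    seg_t, seg_q = best.aligned
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(seg_t, seg_q):
        matches += sum(a == b for a, b in zip(cand[ts:te], consensus[qs:qe]))
        aligned_cols += te - ts
    # columns include internal gaps on both sequences
    span_t = seg_t[-1][1] - seg_t[0][0]
    span_q = seg_q[-1][1] - seg_q[0][0]
    columns = aligned_cols + (span_t - aligned_cols) + (span_q - aligned_cols)
    identity = matches / columns if columns else 0.0
    coverage = span_t / len(cand)
    return best.score, identity, coverage


def classify_te(cand: IndelCandidate, lib: Sequence[tuple[str, str]],
                min_identity: float = 0.8, min_coverage: float = 0.8,
                tip_id: str | None = None) -> TIPRecord | None:
    """Classify a candidate insertion against a TE consensus library.

    Each library consensus (both orientations) is locally aligned to the
    candidate; the best hit by score wins, with ties broken by higher
    identity then library order. A TIPRecord is returned iff identity >=
    ``min_identity`` and candidate coverage >= ``min_coverage`` (both
    inclusive, fractions); otherwise None. Consensi too short to possibly
    reach the coverage floor are skipped without alignment.
    """
    if not lib:
        raise ValueError("empty TE library")
    if not cand.sequence:
        raise ValueError("candidate has no sequence")
    aligner = _make_aligner()
    cand_seq = cand.sequence.upper()
    best = None  # (score, identity, coverage, order, family)
    for order, (family, consensus) in enumerate(lib):
        if len(consensus) < min_coverage * len(cand_seq):
            continue
        for cseq in (consensus.upper(), str(Seq(consensus.upper()).reverse_complement())):
            score, ident, cov = _local_identity_coverage(cand_seq, cseq, aligner)
            key = (score, ident, -order)
            if best is None or key > (best[0], best[1], -best[3]):
                best = (score, ident, cov, order, family)
    if best is None:
        return None
    score, ident, cov, _, family = best
    if ident >= min_identity and cov >= min_coverage:
        side = f"{cand.host}-TIP"
        return TIPRecord(tip_id=tip_id or f"{cand.host}-TIP@{cand.chrom}:{cand.start}",
                         side=side, chrom=cand.chrom, start=cand.start, end=cand.end,
                         family=family, identity=round(ident, 4), coverage=round(cov, 4))
    return None


def detect_tips(ref_seq: str, qry_seq: str, lib: Sequence[tuple[str, str]],
                gap_mask_ref: Sequence[tuple[int, int]] = (),
                gap_mask_qry: Sequence[tuple[int, int]] = (),
                blocks: Sequence[AlignmentBlock] | None = None,
                min_len: int = 50, min_identity: float = 0.8,
                min_coverage: float = 0.8, ref_host: str = "Y",
                qry_host: str = "X", **align_kw) -> list[TIPRecord]:
    """Full detection chain: align -> one-to-one -> indels -> filter -> classify.

    ``blocks`` may carry precomputed one-to-one alignment blocks (the
    production path); otherwise the built-in anchor aligner runs on the two
    sequences. The reference is the Y haplotype by convention.
    """
    if blocks is None:
        blocks = align_pair(ref_seq, qry_seq, ref_name=ref_host, qry_name=qry_host,
                            **align_kw)
    blocks = one_to_one(blocks)
    cands = call_indels(blocks, ref_seq=ref_seq, qry_seq=qry_seq, min_len=min_len,
                        ref_host=ref_host, qry_host=qry_host)
    masks = {ref_host: gap_mask_ref, qry_host: gap_mask_qry}
    cands = filter_candidates(cands, gap_mask_x=masks.get("X", ()),
                              gap_mask_y=masks.get("Y", ()))
    tips = []
    for i, c in enumerate(cands):
        rec = classify_te(c, lib, min_identity=min_identity, min_coverage=min_coverage,
                          tip_id=f"{c.host}-TIP{i + 1:04d}")
        if rec is not None:
            tips.append(rec)
    return tips


# ---------------------------------------------------------------------------
# summaries

@dataclass
class TIPSummary:
    density: pd.DataFrame          # per-bin TIP counts per side with region label
    families: pd.DataFrame         # per-family counts and percentages
    lengths: pd.DataFrame          # median/quartile lengths per side
    density_contrast: tuple | None  # (t, p) SLR vs PAR per-bin densities
    length_contrast: tuple | None   # (t, p) X-TIP vs Y-TIP lengths


def tip_summary(tips: Sequence[TIPRecord], regions: Mapping[str, RegionMap] | RegionMap,
                bin_size: int = 1_000_000) -> TIPSummary:
    """Density, family and length summaries plus Student's t contrasts.

    ``regions`` maps host side ("X"/"Y") to that chromosome's RegionMap (a
    single map is applied to both sides). Density bins are labelled by the
    broad region (PAR/IV/YDR) at their midpoint; the density contrast is a
    pooled-variance two-sample t of per-bin TIP counts, SLR bins vs PAR
    bins, and the length contrast compares X-TIP vs Y-TIP lengths.
    """
    if not isinstance(regions, Mapping):
        regions = {"X": regions, "Y": regions}

    dens_rows = []
    for side in ("X", "Y"):
        rmap = regions.get(side)
        if rmap is None or len(rmap) == 0:
            continue
        chrom_len = max(r.end for r in rmap)
        starts = np.arange(0, chrom_len, bin_size)
        side_tips = [t for t in tips if t.side.startswith(side)]
        pos = np.array([t.start for t in side_tips], dtype=int)
        for s in starts:
            e = min(s + bin_size, chrom_len)
            label = rmap.broad_label_of((s + e) // 2)
            count = int(((pos >= s) & (pos < e)).sum()) if pos.size else 0
            dens_rows.append((side, int(s), int(e), count, label))
    density = pd.DataFrame(dens_rows,
                           columns=["side", "start", "end", "count", "region"])

    fam_counts: dict[str, int] = {}
    for t in tips:
        fam_counts[t.family] = fam_counts.get(t.family, 0) + 1
    families = percentage_table(fam_counts) if fam_counts else \
        pd.DataFrame(columns=["count", "percent"])

    len_rows = []
    for side in ("X-TIP", "Y-TIP"):
        lens = np.array([t.length for t in tips if t.side == side])
        if lens.size:
            len_rows.append((side, lens.size, float(np.median(lens)),
                             float(np.percentile(lens, 25)),
                             float(np.percentile(lens, 75))))
    lengths = pd.DataFrame(len_rows, columns=["side", "n", "median", "q1", "q3"])

    slr = density.loc[density["region"].isin(["IV", "YDR"]), "count"].to_numpy()
    par = density.loc[density["region"] == "PAR", "count"].to_numpy()
    density_contrast = None
    if slr.size >= 2 and par.size >= 2:
        t, p = stats.ttest_ind(slr, par, equal_var=True)
        density_contrast = (float(t), float(p))

    x_len = np.array([t.length for t in tips if t.side == "X-TIP"])
    y_len = np.array([t.length for t in tips if t.side == "Y-TIP"])
    length_contrast = None
    if x_len.size >= 2 and y_len.size >= 2:
        t, p = stats.ttest_ind(x_len, y_len, equal_var=True)
        length_contrast = (float(t), float(p))

    return TIPSummary(density, families, lengths, density_contrast, length_contrast)
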