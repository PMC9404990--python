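"""Binned depth normalization, the log2(F/M) coverage-ratio statistic,
male-specific (YDR-like) region detection, and per-region contrasts.

The log2(F/M) statistic per bin is::

    log2((mean normalized female depth + eps) / (mean normalized male depth + eps))

Female-depleted male-specific sequence (a Y-duplication region) shows up as
a run of strongly negative bins; :func:`detect_male_specific_region` turns
such runs into intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import RegionMap


@dataclass
class CoverageRatioTrack:
    """Per-bin mean normalized depths by sex and their log2 ratio."""

    chrom: str
    bin_size: int
    starts: np.ndarray
    female_mean: np.ndarray
    male_mean: np.ndarray
    log2_fm: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.starts.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "start": self.starts,
            "end": self.starts + self.bin_size,
            "female_mean": self.female_mean, "male_mean": self.male_mean,
            "log2_fm": self.log2_fm,
        })


def bin_depth(track, chrom_length: int | None = None, bin_size: int = 20_000,
              norm: str = "genome_mean") -> np.ndarray:
    """Per-bin mean depth of one sample, optionally genome-mean normalized.

    ``track`` is either a per-base depth array or a bedGraph-like DataFrame
    with ``start/end/value`` interval columns (half-open). With
    ``norm="genome_mean"`` the binned track is divided by the sample's
    genome-wide mean depth, making samples of different sequencing depth
    comparable; ``norm="none"`` returns raw per-bin means.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if isinstance(track, pd.DataFrame):
        if chrom_length is None:
            chrom_length = int(track["end"].max())
        per_base_sum = np.zeros(int(np.ceil(chrom_length / bin_size)))
        counts = np.zeros_like(per_base_sum)
        for row in track.itertuples(index=False):
            s, e, v = int(row.start), int(row.end), float(row.value)
            if float(v) < 0:
                raise ValueError("depth values must be >= 0")
            b0, b1 = s // bin_size, (e - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo, hi = max(s, b * bin_size), min(e, (b + 1) * bin_size)
                per_base_sum[b] += v * (hi - lo)
                counts[b] += hi - lo
        bin_starts = np.arange(len(per_base_sum)) * bin_size
        bin_len = np.minimum(bin_starts + bin_size, chrom_length) - bin_starts
        binned = per_base_sum / bin_len
        genome_mean = per_base_sum.sum() / chrom_length
    else:
        depth = np.asarray(track, dtype=float)
        if (depth < 0).any():
            raise ValueError("depth values must be >= 0")
        if chrom_length is None:
            chrom_length = depth.size
        n_bins = int(np.ceil(chrom_length / bin_size))
        binned = np.array([depth[i * bin_size: min((i + 1) * bin_size, chrom_length)].mean()
                           for i in range(n_bins)])
        genome_mean = depth[:chrom_length].mean()
    if norm == "genome_mean":
        if genome_mean <= 0:
            raise ValueError("cannot normalize a zero-coverage sample")
        return binned / genome_mean
    if norm == "none":
        return binned
    raise ValueError(f"unknown norm {norm!r}")


def normalize_binned(binned) -> np.ndarray:
    """Genome-mean normalization of an already-binned uniform-grid track."""
    binned = np.asarray(binned, dtype=float)
    mean = binned.mean()
    if mean <= 0:
        raise ValueError("cannot normalize a zero-coverage sample")
    return binned / mean


def log2_fm_ratio(female_tracks: Sequence[np.ndarray], male_tracks: Sequence[np.ndarray],
                  eps: float = 0.05, chrom: str = "chrY", bin_size: int = 20_000,
                  starts: np.ndarray | None = None) -> CoverageRatioTrack:
    """The per-bin log2(F/M) coverage-ratio statistic.

    ``female_tracks`` and ``male_tracks`` are binned (normalized) depth
    arrays on an identical grid. The pseudocount ``eps`` (normalized-depth
    units) keeps the ratio finite over female-depleted bins and must be
    positive.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0 (log2 ratio undefined at zero depth)")
    female = [np.asarray(t, dtype=float) for t in female_tracks]
    male = [np.asarray(t, dtype=float) for t in male_tracks]
    if not female or not male:
        raise ValueError("need at least one female and one male track")
    n = female[0].size
    if any(t.size != n for t in female + male):
        raise ValueError("mismatched bin grids between samples")
    fmean = np.mean(female, axis=0)
    mmean = np.mean(male, axis=0)
    ratio = np.log2((fmean + eps) / (mmean + eps))
    if starts is None:
        starts = np.arange(n) * bin_size
    return CoverageRatioTrack(chrom, bin_size, np.asarray(starts),
                              fmean, mmean, ratio)


def detect_male_specific_region(track: CoverageRatioTrack, threshold: float = -2.0,
                                min_run_bins: int = 5) -> list[tuple[int, int]]:
    """Intervals of sustained female depletion in a log2(F/M) track.

    Maximal runs of bins with ``log2_fm <= threshold`` are merged across
    single-bin interruptions; runs of at least ``min_run_bins`` (counting
    only below-threshold bins) are reported as half-open bp intervals.
    """
    below = track.log2_fm <= threshold
    intervals = []
    i = 0
    n = below.size
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n:
            if below[j + 1]:
                j += 1
            elif j + 2 < n and below[j + 2]:  # bridge a single interrupting bin
                j += 2
            else:
                break
        if int(below[i:j + 1].sum()) >= min_run_bins:
            start = int(track.starts[i])
            end = int(track.starts[j]) + track.bin_size
            intervals.append((start, end))
        i = j + 1
    return intervals


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test, normal approximation with tie
    correction. Returns (rank-sum statistic of the first sample, p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / ((n) * (n - 1)) if n > 1 else 0.0
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w == 0:
        return w, 1.0
    z = (w - mean_w) / np.sqrt(var_w)
    p = 2 * stats.norm.sf(abs(z))
    return w, float(min(p, 1.0))


def region_contrast(values_by_region: Mapping[str, Sequence[float]],
                    regions: RegionMap | None = None,
                    test: str = "student_t") -> pd.DataFrame:
    """Two-sample contrasts of a statistic between named regions.

    ``values_by_region`` maps a region label to its per-bin/window values;
    every pair of labels is contrasted with a pooled-variance Student's t
    (``test="student_t"``) or the rank-sum Wilcoxon with normal
    approximation and tie correction (``test="wilcoxon"``). Each region
    needs at least two values. ``regions`` optionally restricts/orders the
    labels. Returns a DataFrame of (region_a, region_b, statistic, p_value).
    """
    if test not in ("student_t", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}")
    labels = [r.name for r in regions if r.name in values_by_region] if regions \
        else list(values_by_region)
    for lab in labels:
        if len(values_by_region[lab]) < 2:
            raise ValueError(f"region {lab!r} has fewer than 2 values")
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            va = np.asarray(values_by_region[a], dtype=float)
            vb = np.asarray(values_by_region[b], dtype=float)
            if test == "student_t":
                res = stats.ttest_ind(va, vb, equal_var=True)
                statistic, p = float(res.statistic), float(res.pvalue)
                if np.isnan(statistic):  # zero pooled variance: identical multisets
                    statistic, p = 0.0, 1.0
            else:
                statistic, p = wilcoxon_rank_sum(va, vb)
            rows.append((a, b, statistic, p))
    return pd.DataFrame(rows, columns=["region_a", "region_b", "statistic", "p_value"])
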