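"""Population analyses on genotype matrices: p-distance and neighbor-joining,
PCA of standardized dosages, and windowed Weir-Cockerham FST.

The FST estimator is Weir & Cockerham (1984): per biallelic site, variance
components ``a`` (among populations), ``b`` (among individuals within
populations) and ``c`` (within individuals) are computed from sample sizes,
allele frequencies and observed heterozygosities of the two populations;
a window's estimate is the weighted (ratio-of-sums) form
``sum(a) / sum(a + b + c)`` over its sites. Negative per-window estimates
are reported, not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import wilcoxon_rank_sum
from .regions import RegionMap, broad_label
from .variants import HET, HOM_ALT, MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distance matrix over samples."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def p_distance(m: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise p-distance from diploid dosages.

    For samples i, j: the mean of ``|dosage_i - dosage_j| / 2`` over sites
    where both are called, dosage in {0, 1, 2}. A pair sharing zero called
    sites is an error naming the pair.
    """
    if m.n_samples < 2:
        raise ValueError("need >= 2 samples")
    d = m.dosage()
    ids = list(m.samples["sample_id"])
    n = len(ids)
    out = np.zeros((n, n))
    called = ~np.isnan(d)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            if not both.any():
                raise ValueError(f"samples {ids[i]} and {ids[j]} share no called sites")
            out[i, j] = out[j, i] = np.abs(d[both, i] - d[both, j]).mean() / 2.0
    return DistanceMatrix(ids, out)


# ---------------------------------------------------------------------------
# neighbor joining

class Tree:
    """An unrooted tree as a Newick string plus convenience accessors."""

    def __init__(self, newick: str, leaves: list[str]):
        self.newick = newick
        self.leaves = list(leaves)

    def __str__(self) -> str:
        return self.newick


def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Standard agglomerative neighbor joining.

    Joins minimize the Q criterion with deterministic tie-breaking by the
    smallest index pair; branch lengths follow the usual join formulas, with
    negative branch lengths clamped to zero and the deficit transferred to
    the sibling branch. The final three clusters join at an unrooted
    trifurcation.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 samples")
    dist = d.values.astype(float).copy()
    nodes = [f"{name}" for name in d.ids]
    active = list(range(n))

    def join_lengths(i, j, li, lj):
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        r = len(active)
        totals = {i: sum(dist[i, k] for k in active if k != i) for i in active}
        best, best_q = None, np.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * dist[i, j] - totals[i] - totals[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * dist[i, j] + (totals[i] - totals[j]) / (2 * (r - 2))
        lj = dist[i, j] - li
        li, lj = join_lengths(i, j, li, lj)
        new = dist.shape[0]
        grown = np.zeros((new + 1, new + 1))
        grown[:new, :new] = dist
        for k in active:
            if k in (i, j):
                continue
            grown[new, k] = grown[k, new] = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
        dist = grown
        nodes.append(f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})")
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    li = 0.5 * (dist[i, j] + dist[i, k] - dist[j, k])
    lj = 0.5 * (dist[i, j] + dist[j, k] - dist[i, k])
    lk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
    li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    newick = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g},{nodes[k]}:{lk:.10g});"
    return Tree(newick, list(d.ids))


# ---------------------------------------------------------------------------
# PCA

def pca(m: GenotypeMatrix, n_components: int = 10):
    """PCA of mean-centered, variance-standardized genotype dosages.

    Sites are centered at twice the alt-allele frequency and scaled by
    ``sqrt(2 p (1 - p))`` with ``p`` from called alleles; fixed sites are
    dropped and missing dosages imputed to the site mean. Returns
    ``(coordinates, variance_fractions)``; coordinate signs are fixed so the
    largest-magnitude entry of each component is positive.
    """
    if m.n_samples < 2:
        raise ValueError("need >= 2 samples")
    d = m.dosage()
    p = np.nanmean(d, axis=1) / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.any():
        raise ValueError("no polymorphic sites")
    d = d[poly]
    p = p[poly]
    z = (d - 2 * p[:, None]) / np.sqrt(2 * p * (1 - p))[:, None]
    z = np.where(np.isnan(z), 0.0, z)  # mean imputation after centering

    # eigendecomposition of the sample-by-sample covariance
    cov = z.T @ z / z.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0, None)
    k = min(n_components, len(evals))
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for c in range(k):
        idx = np.argmax(np.abs(coords[:, c]))
        if coords[idx, c] < 0:
            coords[:, c] = -coords[:, c]
    total = evals.sum()
    frac = evals[:k] / total if total > 0 else np.zeros(k)
    return coords, frac


# ---------------------------------------------------------------------------
# Weir-Cockerham FST

def wc_fst_components(m: GenotypeMatrix, pop_a: str, pop_b: str) -> pd.DataFrame:
    """Per-site Weir-Cockerham (1984) variance components for two populations.

    Sites where either population has fewer than two called samples are
    dropped. Returns a DataFrame with chrom, pos and components a, b, c.
    """
    groups = set(m.samples["group"])
    for pop in (pop_a, pop_b):
        if pop not in groups:
            raise ValueError(f"population {pop!r} absent from the sample sheet")
    masks = [(m.samples["group"] == pop).to_numpy() for pop in (pop_a, pop_b)]
    g = m.genotypes
    r = 2

    n_i, p_i, h_i = [], [], []
    for mask in masks:
        sub = g[:, mask]
        called = (sub != MISSING).sum(axis=1).astype(float)
        alt = np.where(sub == HET, 1, 0).sum(axis=1) + 2 * (sub == HOM_ALT).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called > 0, alt / (2 * called), np.nan)
            h = np.where(called > 0, (sub == HET).sum(axis=1) / called, np.nan)
        n_i.append(called)
        p_i.append(p)
        h_i.append(h)
    n_i = np.stack(n_i)   # (2, sites)
    p_i = np.stack(p_i)
    h_i = np.stack(h_i)

    ok = (n_i >= 2).all(axis=0)
    n_i, p_i, h_i = n_i[:, ok], p_i[:, ok], h_i[:, ok]

    n_bar = n_i.mean(axis=0)
    n_c = (r * n_bar - (n_i ** 2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar)
                                    - s2 * (r - 1) / r - h_bar / 4.0))
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r
        - h_bar * (2 * n_bar - 1) / (4 * n_bar))
    c = h_bar / 2.0

    sites = m.sites.loc[ok, ["chrom", "pos"]].reset_index(drop=True)
    return sites.assign(a=a, b=b, c=c)


@dataclass(frozen=True)
class FstWindow:
    chrom: str
    start: int
    end: int
    fst: float
    n_sites: int


def wc_fst_windows(m: GenotypeMatrix, pop_a: str, pop_b: str,
                   window: int = 1_000_000, step: int = 200_000,
                   chrom_length: int | None = None) -> list[FstWindow]:
    """Windowed weighted Weir-Cockerham FST between two populations.

    Windows of ``window`` bp advance by ``step`` bp over half-open
    coordinates; each window's estimate is ``sum(a) / sum(a+b+c)`` over the
    sites it contains. Windows without sites (or with a zero denominator)
    are omitted.
    """
    comp = wc_fst_components(m, pop_a, pop_b)
    out: list[FstWindow] = []
    for chrom, grp in comp.groupby("chrom", sort=False):
        pos0 = grp["pos"].to_numpy() - 1  # half-open 0-based bins
        end = chrom_length if chrom_length is not None else int(pos0.max()) + 1
        a, b, c = (grp[k].to_numpy() for k in "abc")
        start = 0
        while start < end:
            stop = min(start + window, end)
            in_win = (pos0 >= start) & (pos0 < stop)
            denom = (a[in_win] + b[in_win] + c[in_win]).sum()
            if in_win.any() and denom > 0:
                out.append(FstWindow(chrom, start, stop,
                                     float(a[in_win].sum() / denom),
                                     int(in_win.sum())))
            if stop >= end:
                break
            start += step
    return out


def region_fst_summary(windows: list[FstWindow], regions: RegionMap) -> tuple[pd.DataFrame, float]:
    """Mean window FST per broad region plus a PAR-vs-SLR Wilcoxon contrast.

    Windows are assigned to the broad region (PAR / IV / YDR) covering their
    midpoint; the SLR is IV plus YDR. Returns ``(per-region table,
    two-sided Wilcoxon rank-sum p for PAR vs SLR window sets)``. Regions
    without windows, or a contrast with fewer than two windows on a side,
    raise.
    """
    by_region: dict[str, list[float]] = {}
    for w in windows:
        label = regions.broad_label_of((w.start + w.end) // 2)
        if label is not None:
            by_region.setdefault(label, []).append(w.fst)
    wanted = {broad_label(r.name) for r in regions}
    missing = wanted - set(by_region)
    if missing:
        raise ValueError(f"regions without windows: {sorted(missing)}")
    table = pd.DataFrame(
        [(lab, len(v), float(np.mean(v))) for lab, v in sorted(by_region.items())],
        columns=["region", "n_windows", "mean_fst"])
    par = by_region.get("PAR", [])
    slr = by_region.get("IV", []) + by_region.get("YDR", [])
    if len(par) < 2 or len(slr) < 2:
        raise ValueError("PAR-vs-SLR contrast needs >= 2 windows per side")
    _, p = wilcoxon_rank_sum(par, slr)
    return table, p
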