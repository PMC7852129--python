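"""Enrichment and randomisation statistics for coverage-region analyses.

Implements the log likelihood ratio (log10 odds ratio of a 2x2 table) with
Haldane correction for zero cells, Fisher/BH gene-set enrichment, windowed
density correlations, label-reshuffle and matched-random-placement z-scores,
and two-sample distribution comparisons.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .intervals import intersect_length, merge


@dataclass
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


@dataclass
class StatResult:
    observed: float
    null_mean: float = np.nan
    null_sd: float = np.nan
    z: float = np.nan
    n_perm: int = 0
    p_value: float = np.nan
    q_value: float = np.nan
    rho: float = np.nan
    pearson_r: float = np.nan
    flags: list[str] = field(default_factory=list)


def llr(table: ContingencyTable) -> tuple[float, bool]:
    """log10((a/b)/(c/d)); Haldane +0.5 on every cell if any cell is 0.

    Returns (value, corrected) where ``corrected`` flags the adjustment.
    Antisymmetric under swapping (a,b) with (c,d).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    # summed per-cell logs keep llr(a,b,c,d) == -llr(c,d,a,b) bit-exact
    la, lb, lc, ld = (np.log10(x) for x in (a, b, c, d))
    return float((la - lb) - (lc - ld)), corrected


def enrichment_test(
    term_genes: dict[str, set[str]],
    target_genes: set[str],
    universe: set[str],
) -> pd.DataFrame:
    """Per-term Fisher p, BH q and LLR for enrichment of terms in a gene set.

    For each term G: a = genes with G in the target set, b = target genes
    without G, c = genes with G outside the target, d = the rest of the
    universe. BH is applied within this family of terms.
    """
    if not universe:
        raise ValueError("empty gene universe")
    target = target_genes & universe
    rows = []
    for term, genes in sorted(term_genes.items()):
        g = genes & universe
        a = len(g & target)
        b = len(target - g)
        c = len(g - target)
        d = len(universe - g - target)
        p = float(sps.fisher_exact([[a, b], [c, d]])[1])
        val, corr = llr(ContingencyTable(a, b, c, d))
        rows.append((term, a, b, c, d, p, val, corr))
    df = pd.DataFrame(
        rows, columns=["term", "a", "b", "c", "d", "p_value", "llr", "haldane"]
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["q_value"] = []
    return df.sort_values("llr", ascending=False).reset_index(drop=True)


def _window_density(
    intervals: dict[str, np.ndarray], chrom_lengths: dict[str, int], window: int
) -> np.ndarray:
    dens = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        iv = intervals.get(chrom, np.empty((0, 2), int))
        for s in range(0, L, window):
            e = min(s + window, L)
            dens.append(intersect_length(iv, np.array([[s, e]])) / (e - s))
    return np.asarray(dens)


def _by_chrom(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {c: merge(g[["start", "end"]].to_numpy()) for c, g in df.groupby("chrom")}


def density_correlation(
    regions: pd.DataFrame,
    track: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 500_000,
) -> StatResult:
    """Spearman/Pearson correlation of two interval densities in genome windows."""
    n_windows = sum(-(-L // window) for L in chrom_lengths.values())
    if n_windows < 3:
        raise ValueError("fewer than 3 windows: shrink the window size")
    da = _window_density(_by_chrom(regions), chrom_lengths, window)
    db = _window_density(_by_chrom(track), chrom_lengths, window)
    rho, p = sps.spearmanr(da, db)
    r, _ = sps.pearsonr(da, db)
    return StatResult(observed=float(rho), p_value=float(p), rho=float(rho), pearson_r=float(r))


def reshuffle_zscore(
    regions: pd.DataFrame,
    cls: str,
    track: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 500_000,
    n: int = 1000,
    seed: int = 0,
    class_column: str = "coverage_class",
) -> StatResult:
    """z-score of the class/track density correlation against a label-shuffle null.

    The null relabels the region class assignments at random (class counts
    preserved; coordinates fixed) and recomputes Spearman's rho each time.
    """
    if class_column not in regions:
        raise ValueError("regions must carry class labels")
    rng = np.random.default_rng(seed)
    db = _window_density(_by_chrom(track), chrom_lengths, window)

    # per-region overlap with each genome window, computed once; a permuted
    # labelling's density profile is then a row-subset sum
    win_bounds = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        for s in range(0, L, window):
            win_bounds.append((chrom, s, min(s + window, L)))
    M = np.zeros((len(regions), len(win_bounds)))
    for i, r in enumerate(regions.itertuples()):
        for j, (wc, ws, we) in enumerate(win_bounds):
            if wc == r.chrom:
                ov = min(we, r.end) - max(ws, r.start)
                if ov > 0:
                    M[i, j] = ov / (we - ws)
    db_rank = sps.rankdata(db)

    def rho_for(labels) -> float:
        da = M[labels == cls].sum(axis=0)
        if np.ptp(da) == 0:
            return 0.0
        v = sps.pearsonr(sps.rankdata(da), db_rank)[0]
        return float(v) if np.isfinite(v) else 0.0

    labels = regions[class_column].to_numpy()
    obs = rho_for(labels)
    null = np.array([rho_for(rng.permutation(labels)) for _ in range(n)])
    sd = null.std()
    res = StatResult(
        observed=obs,
        null_mean=float(null.mean()),
        null_sd=float(sd),
        n_perm=n,
        rho=obs,
    )
    if sd > 0:
        res.z = float((obs - null.mean()) / sd)
    else:
        res.flags.append("zero null SD: z undefined")
    res.p_value = float((1 + np.sum(np.abs(null - null.mean()) >= abs(obs - null.mean()))) / (n + 1))
    return res


def place_matched_intervals(
    lengths,
    bg_space: pd.DataFrame,
    rng: np.random.Generator,
    max_retries: int = 10_000,
) -> pd.DataFrame:
    """One null draw: non-overlapping intervals with the given length multiset
    placed uniformly inside the background space (rejection sampling)."""
    bg_iv = _by_chrom(bg_space)
    seg_list = [(c, int(s), int(e)) for c in sorted(bg_iv) for s, e in bg_iv[c]]
    seg_lens = np.array([e - s for _, s, e in seg_list], float)
    lengths = np.asarray(lengths, int)
    if seg_lens.sum() < lengths.sum():
        raise ValueError("background space smaller than the interval length total")
    p_seg = seg_lens / seg_lens.sum()
    occupied: dict[int, list[tuple[int, int]]] = {}
    rows = []
    for L in sorted(lengths, reverse=True):
        for _ in range(max_retries):
            si = int(rng.choice(len(seg_list), p=p_seg))
            c, s0, e0 = seg_list[si]
            if e0 - s0 < L:
                continue
            s = int(rng.integers(s0, e0 - L + 1))
            if any(s < oe and s + L > os for os, oe in occupied.get(si, ())):
                continue
            occupied.setdefault(si, []).append((s, s + L))
            rows.append((c, s, s + int(L)))
            break
        else:
            raise RuntimeError("matched random placement failed after bounded retries")
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def matched_random_regions_zscore(
    hc_regions: pd.DataFrame,
    bg_space: pd.DataFrame,
    features_by_type: dict[str, pd.DataFrame],
    chrom_lengths: dict[str, int],
    n: int = 10_000,
    seed: int = 0,
    max_retries: int = 10_000,
) -> pd.DataFrame:
    """z-score of feature counts in HC regions vs length-matched random draws.

    Each null draw places ``len(hc_regions)`` non-overlapping intervals with
    the HC length multiset inside the background space (rejection sampling,
    bounded retries), and counts overlapping features per type.
    """
    lengths = (hc_regions["end"] - hc_regions["start"]).to_numpy()
    feat_iv = {t: _by_chrom(df) for t, df in features_by_type.items()}

    def count_overlaps(placed: dict[str, list[tuple[int, int]]], t: str) -> int:
        total = 0
        for c, ivs in placed.items():
            fi = feat_iv[t].get(c)
            if fi is None:
                continue
            arr = np.asarray(ivs)
            for s, e in fi:
                if np.any((arr[:, 0] < e) & (arr[:, 1] > s)):
                    total += 1
        return total

    obs_placed = {
        c: list(map(tuple, g[["start", "end"]].to_numpy()))
        for c, g in hc_regions.groupby("chrom")
    }
    types = sorted(features_by_type)
    observed = {t: count_overlaps(obs_placed, t) for t in types}

    rng = np.random.default_rng(seed)
    null_counts = {t: np.empty(n) for t in types}
    for it in range(n):
        draw = place_matched_intervals(lengths, bg_space, rng, max_retries)
        placed = {
            c: list(map(tuple, g[["start", "end"]].to_numpy()))
            for c, g in draw.groupby("chrom")
        }
        for t in types:
            null_counts[t][it] = count_overlaps(placed, t)

    rows = []
    for t in types:
        nc = null_counts[t]
        sd = nc.std()
        z = (observed[t] - nc.mean()) / sd if sd > 0 else np.nan
        p = float((1 + np.sum(np.abs(nc - nc.mean()) >= abs(observed[t] - nc.mean()))) / (n + 1))
        rows.append((t, observed[t], float(nc.mean()), float(sd), float(z) if sd > 0 else np.nan, p))
    return pd.DataFrame(
        rows, columns=["feature_type", "observed", "null_mean", "null_sd", "z", "p_value"]
    )


def compare_distributions(x, y, test: str = "wilcoxon-ranksum") -> StatResult:
    """Two-sided two-sample comparison: rank-sum, KS, variance F, or Kruskal."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    if test == "wilcoxon-ranksum":
        stat, p = sps.ranksums(x, y)
    elif test == "ks":
        stat, p = sps.ks_2samp(x, y)
    elif test == "f-variance":
        f = x.var(ddof=1) / y.var(ddof=1)
        dfx, dfy = len(x) - 1, len(y) - 1
        p = 2 * min(sps.f.cdf(f, dfx, dfy), sps.f.sf(f, dfx, dfy))
        stat = f
    elif test == "kruskal":
        stat, p = sps.kruskal(x, y)
    else:
        raise ValueError(f"unknown test {test!r}")
    return StatResult(observed=float(stat), p_value=float(p))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for one family."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]
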