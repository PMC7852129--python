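"""Per-region genomic features: densities, GC, k-mers, SSRs, tandem genes.

Density of a feature track in a region is the fraction of the region's
length covered by the union of the track's intervals, so overlapping track
entries can never push a density above 1. Flanking windows come in seven
sizes (0.5-32 kb), upstream and downstream combined, clipped at chromosome
ends.
"""
from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import clip, intersect_length, merge

FLANK_SIZES = (500, 1000, 2000, 4000, 8000, 16000, 32000)
BASE_TRACKS = ("genes", "tandem_genes", "non_tandem_genes", "pseudogenes", "tes", "ssrs")


def track_density(track: np.ndarray, region: tuple[int, int]) -> float:
    """union(track ∩ region) / region length."""
    s, e = region
    if e <= s:
        raise ValueError("zero-length region")
    iv = np.asarray(track, dtype=np.int64).reshape(-1, 2)
    return intersect_length(iv, np.array([[s, e]])) / (e - s)


def flanking_windows(
    region: tuple[int, int], size: int, chrom_length: int
) -> np.ndarray:
    """Upstream [start-s, start) and downstream [end, end+s) windows, clipped."""
    s, e = region
    win = np.array([[s - size, s], [e, e + size]], dtype=np.int64)
    return clip(win, chrom_length)


def gc_fraction(seq: str) -> float:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    nonn = ~np.isin(arr, np.frombuffer(b"Nn", np.uint8))
    if not nonn.any():
        return np.nan
    return float(np.isin(arr[nonn], np.frombuffer(b"GCgc", np.uint8)).mean())


def kmer_density(seq: str, k: int) -> dict[str, float]:
    """Overlapping k-mer counts / number of N-free windows, single strand.

    Windows containing N are excluded from both numerator and denominator;
    no reverse-complement canonicalisation (AT and TA are distinct motifs).
    """
    if not 1 <= k <= 6:
        raise ValueError("k must be in 1..6")
    if k > len(seq):
        warnings.warn("k exceeds sequence length: all densities 0")
        return {}
    counts: dict[str, int] = {}
    valid = 0
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        valid += 1
        counts[w] = counts.get(w, 0) + 1
    if valid == 0:
        return {}
    return {m: c / valid for m, c in counts.items()}


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def find_ssrs(
    seq: str, min_unit: int = 2, max_unit: int = 64, min_copies: int = 2
) -> pd.DataFrame:
    """Exact adjacent repeats of a 2-64 bp unit, >= 2 copies, maximal spans.

    The smallest-period motif is reported; a tract whose period is a multiple
    of an already reported period and whose span is contained in that
    reported tract is suppressed.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(s)
    reported: list[tuple[int, int, int]] = []  # (start, end, period)
    rows = []
    for p in range(min_unit, min(max_unit, n // min_copies) + 1):
        eq = (s[:-p] == s[p:]) & (s[:-p] != ord("N"))
        if not eq.any():
            continue
        padded = np.concatenate([[False], eq, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for a, b in zip(starts, ends):
            run = b - a  # matched offsets; tract length = run + p
            if run < p * (min_copies - 1):
                continue
            ts, te = int(a), int(b + p)
            if any(p % q == 0 and qs <= ts and te <= qe for qs, qe, q in reported):
                continue
            reported.append((ts, te, p))
            rows.append((ts, te, seq[ts : ts + p], p, (te - ts) / p))
    out = pd.DataFrame(rows, columns=["start", "end", "motif", "unit_length", "copies"])
    return out.sort_values(["start", "unit_length"]).reset_index(drop=True)


def classify_tandem(
    paralog_pairs: list[tuple[str, str]],
    gene_order: dict[str, list[str]],
    max_intervening: int = 10,
) -> dict[str, bool]:
    """Tandem-duplicate flags: paralogs adjacent or separated by <= 10
    non-homologous genes form a cluster; transitive closure merges chains."""
    pos: dict[str, tuple[str, int]] = {}
    for chrom, order in gene_order.items():
        for i, g in enumerate(order):
            pos[g] = (chrom, i)
    paralogs: dict[str, set[str]] = {}
    for a, b in paralog_pairs:
        for g in (a, b):
            if g not in pos:
                raise KeyError(f"gene {g!r} absent from gene order")
        paralogs.setdefault(a, set()).add(b)
        paralogs.setdefault(b, set()).add(a)
    parent: dict[str, str] = {g: g for g in pos}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tandem = {g: False for g in pos}
    for a, b in paralog_pairs:
        ca, ia = pos[a]
        cb, ib = pos[b]
        if ca != cb:
            continue
        lo, hi = sorted((ia, ib))
        between = gene_order[ca][lo + 1 : hi]
        hom = paralogs.get(a, set()) | paralogs.get(b, set()) | {a, b}
        n_nonhom = sum(1 for g in between if g not in hom)
        if n_nonhom <= max_intervening:
            parent[find(a)] = find(b)
            tandem[a] = tandem[b] = True
    # propagate through clusters (a chain A-B, B-C makes all three tandem)
    roots = {g: find(g) for g in pos}
    tandem_roots = {roots[g] for g, t in tandem.items() if t}
    return {g: roots[g] in tandem_roots for g in pos}


def functional_presence(
    regions: pd.DataFrame, genes: pd.DataFrame, gene_terms: dict[str, set[str]]
) -> pd.DataFrame:
    """Presence flag per (region, term): any overlapping gene carries the term."""
    terms = sorted(set().union(*gene_terms.values())) if gene_terms else []
    mat = np.zeros((len(regions), len(terms)), dtype=int)
    tidx = {t: j for j, t in enumerate(terms)}
    for i, r in enumerate(regions.itertuples()):
        hit = genes[
            (genes.chrom == r.chrom) & (genes.start < r.end) & (genes.end > r.start)
        ]
        for g in hit.itertuples():
            for t in gene_terms.get(g.gene_id, ()):  # noqa: B905
                mat[i, tidx[t]] = 1
    return pd.DataFrame(mat, index=regions.index, columns=terms)


def screen_features(
    X: pd.DataFrame, labels, alpha: float = 0.05
) -> tuple[list[str], pd.Series]:
    """Kruskal-Wallis screen: keep features with p < alpha across classes."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    kept, pvals = [], {}
    for col in X.columns:
        v = X[col].to_numpy(float)
        if np.nanstd(v) == 0:
            warnings.warn(f"feature {col!r} is constant: dropped")
            pvals[col] = np.nan
            continue
        groups = [v[labels == c] for c in classes]
        try:
            p = float(sps.kruskal(*groups).pvalue)
        except ValueError:
            warnings.warn(f"feature {col!r} degenerate under Kruskal-Wallis: dropped")
            pvals[col] = np.nan
            continue
        pvals[col] = p
        if p < alpha:
            kept.append(col)
    return kept, pd.Series(pvals, name="kruskal_p")


def _density_features(
    region: tuple[str, int, int],
    tracks: dict[str, dict[str, np.ndarray]],
    windows: np.ndarray,
    prefix: str,
) -> dict[str, float]:
    chrom = region[0]
    total = int((windows[:, 1] - windows[:, 0]).sum())
    feats = {}
    for name, by_chrom in tracks.items():
        iv = by_chrom.get(chrom, np.empty((0, 2), int))
        ov = sum(intersect_length(iv, w.reshape(1, 2)) for w in windows)
        feats[f"{prefix}{name}_density"] = ov / total if total else 0.0
    return feats


def build_feature_matrix(
    regions: pd.DataFrame,
    seqs: dict[str, str],
    tracks: dict[str, pd.DataFrame],
    flank_sizes: tuple[int, ...] = FLANK_SIZES,
    kmax: int = 0,
    include_ssr_motifs: bool = False,
) -> pd.DataFrame:
    """Regions x features matrix: GC + base-track densities, the same for
    each flanking window size, and optional per-motif k-mer densities.

    ``tracks`` maps track name -> BED-like DataFrame. k-mer features are the
    union of motifs observed across regions (k = 1..kmax); per-motif SSR
    densities come from exact SSR calls inside each region.
    """
    track_iv = {
        name: {c: merge(g[["start", "end"]].to_numpy()) for c, g in df.groupby("chrom")}
        for name, df in tracks.items()
        if len(df)
    }
    for name in tracks:
        track_iv.setdefault(name, {})
    rows = []
    for r in regions.itertuples():
        L = len(seqs[r.chrom])
        span = np.array([[r.start, r.end]])
        feats: dict[str, float] = {"gc": gc_fraction(seqs[r.chrom][r.start : r.end])}
        feats.update(_density_features((r.chrom, r.start, r.end), track_iv, span, ""))
        for size in flank_sizes:
            win = flanking_windows((r.start, r.end), size, L)
            if len(win) == 0:
                win = span  # fully clipped: fall back to the region itself
            seq_parts = "".join(seqs[r.chrom][a:b] for a, b in win)
            feats[f"flank{size}_gc"] = gc_fraction(seq_parts)
            feats.update(
                _density_features((r.chrom, r.start, r.end), track_iv, win, f"flank{size}_")
            )
        if kmax:
            seq = seqs[r.chrom][r.start : r.end]
            for k in range(1, kmax + 1):
                for m, d in kmer_density(seq, k).items():
                    feats[f"kmer_{m}"] = d
        if include_ssr_motifs:
            seq = seqs[r.chrom][r.start : r.end]
            calls = find_ssrs(seq)
            for c in calls.itertuples():
                key = f"ssr_{c.motif}"
                feats[key] = feats.get(key, 0.0) + (c.end - c.start) / len(seq)
        rows.append(feats)
    X = pd.DataFrame(rows, index=regions.index).fillna(0.0)
    return X.reindex(sorted(X.columns), axis=1)
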