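"""Per-bin read depth: counting, GC-bias correction, normalisation.

A read is assigned to the single bin that holds >= 50% of its length, with
exact 50/50 ties going to the earlier bin; each read counts in at most one
bin. Counts are corrected for GC bias by per-stratum scaling (1 GC percentage
point strata, 30-bin minimum) and normalised so the genome-wide median read
depth (RD) of non-N bins is 1.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

PLACEMENT_COLUMNS = ["read_id", "chrom", "start", "length", "multimap"]


def make_bins(seqs: dict[str, str], bin_size: int) -> pd.DataFrame:
    """Tile each chromosome with fixed-width bins and record GC / N content.

    ``gc`` is the G+C fraction of non-N bases (NaN for all-N bins);
    ``n_frac`` is the N fraction of the bin.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    frames = []
    for chrom in sorted(seqs):
        arr = np.frombuffer(seqs[chrom].encode(), dtype=np.uint8)
        L = len(arr)
        n_bins = -(-L // bin_size)
        pad = n_bins * bin_size - L
        isgc = np.isin(arr, np.frombuffer(b"GCgc", np.uint8)).astype(np.float64)
        isn = np.isin(arr, np.frombuffer(b"Nn", np.uint8)).astype(np.float64)
        if pad:
            isgc = np.concatenate([isgc, np.zeros(pad)])
            isn = np.concatenate([isn, np.ones(pad)])
        gc_sum = isgc.reshape(n_bins, bin_size).sum(axis=1)
        n_sum = isn.reshape(n_bins, bin_size).sum(axis=1)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, L)
        valid = (ends - starts) - n_sum[: n_bins]
        with np.errstate(invalid="ignore", divide="ignore"):
            gc = np.where(valid > 0, gc_sum / np.maximum(valid, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "gc": gc,
                    "n_frac": n_sum / (ends - starts),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def count_reads_per_bin(
    placements: pd.DataFrame, bins: pd.DataFrame, bin_size: int
) -> pd.DataFrame:
    """Attach raw (and multi-mapping) read counts to bins.

    A read counts in the bin containing >= 50% of its length; a read longer
    than two bins (no bin reaches 50%) is not counted anywhere.
    """
    bins = bins.copy()
    bins["raw_count"] = 0
    bins["multimap_count"] = 0
    chrom_len = bins.groupby("chrom")["end"].max()
    offsets = {}
    off = 0
    for chrom, grp in bins.groupby("chrom", sort=False):
        offsets[chrom] = (off, len(grp))
        off += len(grp)
    raw = np.zeros(len(bins), dtype=np.int64)
    mm = np.zeros(len(bins), dtype=np.int64)
    for chrom, grp in placements.groupby("chrom", sort=False):
        if chrom not in offsets:
            raise ValueError(f"placement on unknown chromosome {chrom!r}")
        L = int(chrom_len[chrom])
        s = grp["start"].to_numpy(np.int64)
        ln = grp["length"].to_numpy(np.int64)
        bad = (s < 0) | (s + ln > L)
        if bad.any():
            rid = grp.loc[grp.index[np.flatnonzero(bad)[0]], "read_id"]
            raise ValueError(f"read {rid!r} outside chromosome {chrom!r} bounds")
        # bin of the centre base, biased to the earlier bin on an exact tie
        b = (s + (ln - 1) // 2) // bin_size
        ov = np.minimum((b + 1) * bin_size, s + ln) - np.maximum(b * bin_size, s)
        keep = 2 * ov >= ln
        o, n = offsets[chrom]
        raw[o : o + n] += np.bincount(b[keep], minlength=n)[:n]
        mmk = keep & (grp["multimap"].to_numpy() > 0)
        mm[o : o + n] += np.bincount(b[mmk], minlength=n)[:n]
    bins["raw_count"] = raw
    bins["multimap_count"] = mm
    return bins


def gc_correct(bins: pd.DataFrame, min_stratum: int = 30) -> pd.DataFrame:
    """Scale counts per 1-percentage-point GC stratum to remove GC bias.

    corrected = raw * (mean over bins in qualifying strata) / (stratum mean);
    strata with fewer than ``min_stratum`` bins, zero-mean strata and
    majority-N bins are left uncorrected (factor 1), so the global total is
    conserved exactly and the operation is idempotent.
    """
    bins = bins.copy()
    eligible = (bins["n_frac"] <= 0.5) & bins["gc"].notna()
    if not eligible.any():
        raise ValueError("no bins with defined GC content")
    strat = np.full(len(bins), -1, dtype=int)
    strat[eligible.to_numpy()] = np.clip(
        np.floor(bins.loc[eligible, "gc"].to_numpy() * 100).astype(int), 0, 100
    )
    raw = bins["raw_count"].to_numpy(float)
    factor = np.ones(len(bins))
    counts_by = {}
    for s in np.unique(strat[strat >= 0]):
        idx = strat == s
        if idx.sum() >= min_stratum:
            m = raw[idx].mean()
            if m > 0:
                counts_by[s] = (idx, m)
    if counts_by:
        big_mask = np.zeros(len(bins), dtype=bool)
        for idx, _ in counts_by.values():
            big_mask |= idx
        gm = raw[big_mask].mean()
        for s, (idx, m) in counts_by.items():
            factor[idx] = gm / m
    bins["corrected_count"] = raw * factor
    return bins


def normalize_rd(bins: pd.DataFrame) -> pd.DataFrame:
    """RD = corrected count / genome-wide median corrected count of non-N bins."""
    bins = bins.copy()
    if "corrected_count" not in bins:
        raise ValueError("run gc_correct (or set corrected_count) first")
    nonn = bins["n_frac"] <= 0.5
    med = float(bins.loc[nonn, "corrected_count"].median())
    if med == 0:
        raise ValueError("median corrected count is 0: coverage too low")
    bins["rd"] = bins["corrected_count"] / med
    return bins


def compute_rd(
    placements: pd.DataFrame,
    seqs: dict[str, str],
    bin_size: int = 100,
    gc_correction: bool = True,
) -> pd.DataFrame:
    """Convenience pipeline: bins -> counts -> GC correction -> RD."""
    bins = count_reads_per_bin(placements, make_bins(seqs, bin_size), bin_size)
    if gc_correction:
        bins = gc_correct(bins)
    else:
        bins = bins.assign(corrected_count=bins["raw_count"].astype(float))
    return normalize_rd(bins)


def choose_bin_size(
    placements: pd.DataFrame,
    chrom_lengths: dict[str, int],
    candidates: list[int],
    target_range: tuple[float, float] = (4.0, 5.0),
) -> tuple[int, pd.DataFrame]:
    """Pick the smallest bin size whose count mean/SD ratio falls in [4, 5].

    If no candidate lands in the range the one with ratio closest to the
    range midpoint (4.5) is returned. Also returns the full ratio table.
    """
    if len(placements) == 0:
        raise ValueError("no placements")
    if len(candidates) == 1:
        warnings.warn("single candidate bin size: returned without evaluation")
    rows = []
    for size in sorted(candidates):
        counts = []
        for chrom, grp in placements.groupby("chrom"):
            L = chrom_lengths[chrom]
            n_bins = -(-L // size)
            s = grp["start"].to_numpy(np.int64)
            ln = grp["length"].to_numpy(np.int64)
            b = (s + (ln - 1) // 2) // size
            ov = np.minimum((b + 1) * size, s + ln) - np.maximum(b * size, s)
            keep = 2 * ov >= ln
            counts.append(np.bincount(b[keep], minlength=n_bins)[:n_bins])
        c = np.concatenate(counts)
        sd = c.std()
        rows.append((size, c.mean(), sd, c.mean() / sd if sd > 0 else np.inf))
    table = pd.DataFrame(rows, columns=["bin_size", "mean", "sd", "ratio"])
    lo, hi = target_range
    ok = table[(table.ratio >= lo) & (table.ratio <= hi)]
    if len(ok):
        best = int(ok.bin_size.iloc[0])
    else:
        mid = (lo + hi) / 2
        best = int(table.bin_size.iloc[(table.ratio - mid).abs().argmin()])
    return best, table


def subsample_placements(
    placements: pd.DataFrame, target_fold: float, source_fold: float, seed: int = 0
) -> pd.DataFrame:
    """Uniform read subsampling without replacement to a lower fold coverage."""
    if target_fold > source_fold:
        raise ValueError("target fold exceeds source fold")
    n = int(round(len(placements) * target_fold / source_fold))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(placements), size=n, replace=False))
    return placements.iloc[idx].reset_index(drop=True)


def rd_correlation(rd_a, rd_b) -> tuple[float, float]:
    """Pearson and Spearman correlation between two per-bin RD vectors."""
    a = np.asarray(rd_a, float)
    b = np.asarray(rd_b, float)
    if a.shape != b.shape:
        raise ValueError("RD vectors must align bin-for-bin")
    return float(sps.pearsonr(a, b)[0]), float(sps.spearmanr(a, b)[0])
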