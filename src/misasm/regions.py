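"""Coverage-region calling: segmentation, q-value filtering, dual thresholds.

Candidate high/low regions are maximal runs of bins whose RD sits above/below
background, bridging at most one neutral bin between concordant neighbours;
the rest of each chromosome forms background candidates. Each candidate gets
a two-sided one-sample t-test p-value (its bins' RD against the genome-wide
non-N mean), Benjamini-Hochberg adjusted over all candidates, and q0 (the
fraction of multi-mapping reads). High/low candidates survive only with
q < 0.08 and q0 < 0.5, and the final HC / LC / BG classes come from the dual
RD thresholds (defaults 0.72 / 1.76); candidates failing their own class's
threshold become "other".
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .intervals import intersect_length, merge

DEFAULT_LOW = 0.72
DEFAULT_HIGH = 1.76
DEFAULT_QMAX = 0.08
DEFAULT_Q0MAX = 0.5

REGION_COLUMNS = [
    "chrom", "start", "end", "candidate", "mean_rd", "p_value", "q_value", "q0", "n_bins",
]


def _runs(idx: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Group sorted indices into runs allowing gaps of <= max_gap indices."""
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    return [(int(idx[a]), int(idx[b]) + 1) for a, b in zip(starts, ends)]


def segment_bins(
    bins: pd.DataFrame,
    bin_high: float = 1.5,
    bin_low: float = 0.5,
    max_gap_bins: int = 1,
    min_bins: int = 2,
) -> pd.DataFrame:
    """Segment normalised bins into candidate high / low / background regions.

    A bin is high-state if rd > ``bin_high`` and low-state if rd < ``bin_low``.
    Runs of a concordant state may bridge up to ``max_gap_bins`` *neutral*
    bins; a bin of the opposite state always terminates a run, so high and
    low candidates can never overlap and the candidates tile the genome.
    Runs with fewer than ``min_bins`` concordant bins stay background
    (single-bin Poisson outliers carry no multi-bin support).
    """
    if len(bins) == 0:
        raise ValueError("no bins to segment")
    if "rd" not in bins:
        raise ValueError("normalised rd required (run normalize_rd)")
    nonn = bins["n_frac"] <= 0.5
    popmean = float(bins.loc[nonn, "rd"].mean())
    rows = []
    for chrom, grp in bins.groupby("chrom", sort=True):
        grp = grp.sort_values("start").reset_index(drop=True)
        rd = grp["rd"].to_numpy()
        state = np.zeros(len(grp), dtype=int)
        state[rd > bin_high] = 1
        state[rd < bin_low] = -1
        claimed = np.zeros(len(grp), dtype=bool)
        for sgn in (1, -1):
            idx = np.flatnonzero(state == sgn)
            for a, b in _runs(idx, max_gap_bins):
                # never bridge across an opposite-state bin
                segs = []
                cur = a
                for i in range(a, b):
                    if state[i] == -sgn:
                        if i > cur:
                            segs.append((cur, i))
                        cur = i + 1
                if b > cur:
                    segs.append((cur, b))
                for s, e in segs:
                    # trim neutral edges left by the split
                    while s < e and state[s] != sgn:
                        s += 1
                    while e > s and state[e - 1] != sgn:
                        e -= 1
                    if e > s and int((state[s:e] == sgn).sum()) >= min_bins:
                        rows.append((chrom, s, e, "high" if sgn == 1 else "low", grp))
                        claimed[s:e] = True
        for a, b in _runs(np.flatnonzero(~claimed), 0):
            rows.append((chrom, a, b, "bg", grp))

    out = []
    for chrom, s, e, cand, grp in rows:
        sub = grp.iloc[s:e]
        rd = sub["rd"].to_numpy()
        if len(rd) >= 2 and rd.std() > 0:
            p = float(sps.ttest_1samp(rd, popmean).pvalue)
        else:
            p = 1.0 if np.allclose(rd.mean(), popmean) else 0.0
        tot = int(sub["raw_count"].sum())
        q0 = float(sub["multimap_count"].sum() / tot) if tot > 0 else 0.0
        out.append(
            (
                chrom,
                int(sub["start"].iloc[0]),
                int(sub["end"].iloc[-1]),
                cand,
                float(rd.mean()),
                p,
                np.nan,
                q0,
                len(sub),
            )
        )
    regions = pd.DataFrame(out, columns=REGION_COLUMNS)
    regions = regions.sort_values(["chrom", "start"]).reset_index(drop=True)
    regions["q_value"] = multipletests(regions["p_value"], method="fdr_bh")[1]
    return regions


def filter_candidates(
    regions: pd.DataFrame,
    q_max: float = DEFAULT_QMAX,
    q0_max: float = DEFAULT_Q0MAX,
) -> pd.DataFrame:
    """Keep high/low candidates with q < q_max and q0 < q0_max; BG unfiltered."""
    hl = regions["candidate"].isin(["high", "low"])
    keep = ~hl | ((regions["q_value"] < q_max) & (regions["q0"] < q0_max))
    return regions[keep].reset_index(drop=True)


def apply_thresholds(
    regions: pd.DataFrame,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> pd.DataFrame:
    """Assign HC/LC/BG/other from candidate class and mean RD (strict cuts).

    HC requires a high candidate with mean RD > ``high``; LC a low candidate
    with mean RD < ``low``; BG candidates must have mean RD inside
    [``low``, ``high``]; anything failing its candidate's cut is "other".
    """
    if low >= high:
        raise ValueError("low threshold must be below high threshold")
    regions = regions.copy()
    cls = np.full(len(regions), "other", dtype=object)
    cand = regions["candidate"].to_numpy()
    rd = regions["mean_rd"].to_numpy()
    cls[(cand == "high") & (rd > high)] = "HC"
    cls[(cand == "low") & (rd < low)] = "LC"
    cls[(cand == "bg") & (rd >= low) & (rd <= high)] = "BG"
    regions["coverage_class"] = cls
    return regions


def select_thresholds(samples_by_class: dict[str, np.ndarray], step: float = 0.01) -> tuple[float, float]:
    """Grid-search the LC/BG and BG/HC cuts that minimise class overlap.

    For each adjacent class pair, the objective at a cut c is
    (fraction of the lower class above c) + (fraction of the upper class
    below c); ties are broken toward the midpoint of the tying interval.
    """
    for key in ("LC", "BG", "HC"):
        if key in samples_by_class and len(samples_by_class[key]) < 10:
            raise ValueError(f"need >= 10 samples for class {key}")

    def best_cut(lower: np.ndarray, upper: np.ndarray) -> float:
        lower = np.asarray(lower, float)
        upper = np.asarray(upper, float)
        if np.array_equal(np.sort(lower), np.sort(upper)):
            raise ValueError("degenerate (identical) class distributions")
        lo = np.floor(min(lower.min(), upper.min()) / step) * step
        hi = np.ceil(max(lower.max(), upper.max()) / step) * step
        grid = np.round(np.arange(lo, hi + step / 2, step), 10)
        obj = np.array(
            [ (lower > c).mean() + (upper < c).mean() for c in grid ]
        )
        ties = np.flatnonzero(np.isclose(obj, obj.min()))
        # midpoint of the contiguous tying stretch containing the argmin
        first = ties[0]
        runs = np.split(ties, np.flatnonzero(np.diff(ties) > 1) + 1)
        run = runs[0] if first in runs[0] else runs[int(np.argmax([first in r for r in runs]))]
        return float((grid[run[0]] + grid[run[-1]]) / 2)

    low = best_cut(samples_by_class["LC"], samples_by_class["BG"])
    high = best_cut(samples_by_class["BG"], samples_by_class["HC"])
    return low, high


@dataclass
class RegionCallScore:
    tp: float
    fp: float
    fn: float

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


def _class_intervals(df: pd.DataFrame, cls: str, col: str) -> dict[str, np.ndarray]:
    sub = df[df[col] == cls]
    return {
        chrom: grp[["start", "end"]].to_numpy()
        for chrom, grp in sub.groupby("chrom")
    }


def score_region_calls(
    called: pd.DataFrame,
    truth: pd.DataFrame,
    classes: tuple[str, ...] = ("HC", "LC", "BG"),
    level: str = "nucleotide",
) -> pd.DataFrame:
    """Precision/recall/F1 of called vs truth class intervals.

    nucleotide level counts overlapping bases; region level counts regions
    with >= 1 bp overlap of matching class.
    """
    ccol = "coverage_class"
    if set(called["chrom"]) - set(truth["chrom"]) and set(truth["chrom"]) - set(called["chrom"]):
        raise ValueError("mismatched chromosome sets between called and truth")
    rows = []
    for cls in classes:
        ca = _class_intervals(called, cls, ccol)
        tr = _class_intervals(truth, cls, ccol)
        if level == "nucleotide":
            tp = fp = fn = 0
            for chrom in set(ca) | set(tr):
                a = ca.get(chrom, np.empty((0, 2), int))
                b = tr.get(chrom, np.empty((0, 2), int))
                ov = intersect_length(a, b)
                la = int((merge(a)[:, 1] - merge(a)[:, 0]).sum()) if len(a) else 0
                lb = int((merge(b)[:, 1] - merge(b)[:, 0]).sum()) if len(b) else 0
                tp += ov
                fp += la - ov
                fn += lb - ov
        elif level == "region":
            tp = fp = fn = 0
            for chrom in set(ca) | set(tr):
                a = ca.get(chrom, np.empty((0, 2), int))
                b = tr.get(chrom, np.empty((0, 2), int))
                hit_a = [intersect_length(row.reshape(1, 2), b) > 0 for row in a]
                hit_b = [intersect_length(row.reshape(1, 2), a) > 0 for row in b]
                tp += sum(hit_a)
                fp += len(a) - sum(hit_a)
                fn += len(b) - sum(hit_b)
        else:
            raise ValueError("level must be 'nucleotide' or 'region'")
        sc = RegionCallScore(tp, fp, fn)
        rows.append((cls, tp, fp, fn, sc.precision, sc.recall, sc.f1))
    return pd.DataFrame(
        rows, columns=["coverage_class", "TP", "FP", "FN", "precision", "recall", "f1"]
    )


def f1_by_q_threshold(
    candidates: pd.DataFrame,
    truth: pd.DataFrame,
    q_grid,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
    q0_max: float = DEFAULT_Q0MAX,
    level: str = "nucleotide",
) -> pd.DataFrame:
    """F1 per class as a function of the q-value cutoff."""
    rows = []
    for q in q_grid:
        called = apply_thresholds(filter_candidates(candidates, q, q0_max), low, high)
        sc = score_region_calls(called, truth, level=level)
        for r in sc.itertuples():
            rows.append((float(q), r.coverage_class, r.f1))
    return pd.DataFrame(rows, columns=["q_max", "coverage_class", "f1"])


def region_n_fraction(regions: pd.DataFrame, seqs: dict[str, str]) -> pd.Series:
    """Fraction of N bases per region."""
    vals = []
    for r in regions.itertuples():
        seq = seqs.get(r.chrom)
        if seq is None or r.end > len(seq):
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} outside assembly")
        sub = seq[r.start : r.end]
        vals.append(sub.count("N") / len(sub) if sub else 0.0)
    return pd.Series(vals, index=regions.index, name="n_fraction")
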