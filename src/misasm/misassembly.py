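"""Six-way assembly-category classification from whole-genome alignment blocks.

Query regions of a short-read-style assembly are classified against a truth
(long-read-style) assembly from show-coords-style alignment blocks:

* C1/M1 — single-copy in the subject; M1 when the single subject hit is off
  the expected location (off the monotonic anchor chain, or on a different
  subject chromosome than the chromosome's dominant one).
* C2/M2 — duplicated locally (all subject hits on one subject chromosome).
* C3/M3 — duplicated non-locally (subject hits on several chromosomes).

A duplicated query region is misassembled (M2/M3) iff it is >= 100 bp, the
overlap among its duplicated subject regions is < 50% of the query length,
and those subject regions align to no other query region (i.e. the assembly
holds one copy of something the truth genome holds several of).
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import intersect_length, merge, reciprocal_clusters, union_length

COORDS_COLUMNS = ["S1", "E1", "S2", "E2", "LEN1", "LEN2", "IDY", "QCHR", "SCHR"]
BLOCK_COLUMNS = ["qchrom", "qstart", "qend", "schrom", "sstart", "send", "identity", "orient"]

MISASSEMBLY_MIN_LENGTH = 100
MISASSEMBLY_MAX_SUBJECT_OVERLAP = 0.5


def parse_coords(source) -> pd.DataFrame:
    """Read a show-coords-style table into 0-based half-open blocks.

    Accepts a path, file-like object or DataFrame with columns
    S1 E1 S2 E2 LEN1 LEN2 IDY QCHR SCHR (1-based inclusive coordinates;
    S2 > E2 marks a reverse-orientation subject interval).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
        else:
            text = source.read()
        df = pd.read_csv(_io.StringIO(text), sep="\t")
    missing = [c for c in COORDS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"coords table missing columns {missing}")
    for i, row in enumerate(df.itertuples(), start=2):
        if row.S1 > row.E1 or min(row.S1, row.E1, min(row.S2, row.E2)) < 1:
            raise ValueError(f"malformed coords row at line {i}")
    rev = df["S2"] > df["E2"]
    sstart = np.where(rev, df["E2"], df["S2"]) - 1
    send = np.where(rev, df["S2"], df["E2"])
    return pd.DataFrame(
        {
            "qchrom": df["QCHR"],
            "qstart": df["S1"] - 1,
            "qend": df["E1"],
            "schrom": df["SCHR"],
            "sstart": sstart.astype(np.int64),
            "send": send.astype(np.int64),
            "identity": df["IDY"].astype(float),
            "orient": np.where(rev, "-", "+"),
        }
    )


def write_coords(blocks: pd.DataFrame, path) -> None:
    """Inverse of :func:`parse_coords` (1-based inclusive on disk)."""
    rev = blocks["orient"] == "-"
    out = pd.DataFrame(
        {
            "S1": blocks["qstart"] + 1,
            "E1": blocks["qend"],
            "S2": np.where(rev, blocks["send"], blocks["sstart"] + 1),
            "E2": np.where(rev, blocks["sstart"] + 1, blocks["send"]),
            "LEN1": blocks["qend"] - blocks["qstart"],
            "LEN2": blocks["send"] - blocks["sstart"],
            "IDY": blocks["identity"],
            "QCHR": blocks["qchrom"],
            "SCHR": blocks["schrom"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def filter_identity(blocks: pd.DataFrame, min_identity: float = 95.0) -> pd.DataFrame:
    """Drop blocks below the identity cutoff (default >= 95%)."""
    return blocks[blocks["identity"] >= min_identity].reset_index(drop=True)


def group_subjects(blocks: pd.DataFrame, reciprocal: float = 0.5):
    """Cluster query intervals into query regions and deduplicate subjects.

    Query intervals overlapping >= 50% reciprocally are one query region.
    Subject intervals are clustered the same way genome-wide; a query region
    is "duplicated" iff >= 2 distinct merged subject regions remain,
    regardless of subject chromosome.

    Returns (query_regions, block_assignments) where query_regions has one
    row per region (qid, chrom, start, end, subject ids, duplicated flag)
    and block_assignments maps each block to (qid, sid).
    """
    blocks = blocks.reset_index(drop=True)
    qid = np.full(len(blocks), -1, dtype=int)
    next_q = 0
    for chrom in sorted(blocks["qchrom"].unique()):
        idx = blocks.index[blocks["qchrom"] == chrom].to_numpy()
        labels = reciprocal_clusters(blocks.loc[idx, ["qstart", "qend"]].to_numpy(), reciprocal)
        qid[idx] = labels + next_q
        next_q += labels.max() + 1 if len(labels) else 0
    sid = np.full(len(blocks), -1, dtype=int)
    next_s = 0
    for chrom in sorted(blocks["schrom"].unique()):
        idx = blocks.index[blocks["schrom"] == chrom].to_numpy()
        labels = reciprocal_clusters(blocks.loc[idx, ["sstart", "send"]].to_numpy(), reciprocal)
        sid[idx] = labels + next_s
        next_s += labels.max() + 1 if len(labels) else 0
    assign = pd.DataFrame({"qid": qid, "sid": sid}, index=blocks.index)
    rows = []
    for q in np.unique(qid):
        members = blocks[qid == q]
        sids = sorted(set(sid[qid == q]))
        rows.append(
            (
                q,
                members["qchrom"].iloc[0],
                int(members["qstart"].min()),
                int(members["qend"].max()),
                sids,
                len(sids) >= 2,
            )
        )
    query_regions = pd.DataFrame(
        rows, columns=["qid", "chrom", "start", "end", "sids", "duplicated"]
    )
    return query_regions, assign


def _lis_chain(order_positions: list[tuple[int, int, int]]) -> set[int]:
    """Length-weighted longest increasing subsequence over (qpos, spos, weight).

    Returns the set of member indices on the chain.
    """
    items = sorted(range(len(order_positions)), key=lambda i: order_positions[i][0])
    best = [0.0] * len(items)
    prev = [-1] * len(items)
    for a, i in enumerate(items):
        _, s_i, w_i = order_positions[i]
        best[a] = w_i
        for b in range(a):
            j = items[b]
            if order_positions[j][1] <= s_i and best[b] + w_i > best[a]:
                best[a] = best[b] + w_i
                prev[a] = b
    if not items:
        return set()
    a = int(np.argmax(best))
    chain = set()
    while a != -1:
        chain.add(items[a])
        a = prev[a]
    return chain


def classify_query_regions(
    blocks: pd.DataFrame,
    min_length: int = MISASSEMBLY_MIN_LENGTH,
    max_subject_overlap: float = MISASSEMBLY_MAX_SUBJECT_OVERLAP,
    reciprocal: float = 0.5,
) -> pd.DataFrame:
    """Assign a C1/C2/C3/M1/M2/M3 category to every query region.

    See module docstring for the decision rules. Query regions whose
    subjects are shared with other query regions and outnumber them are
    labelled ``complex`` (multiple query copies with even more subject
    copies) and excluded from the six-way scheme.
    """
    query_regions, assign = group_subjects(blocks, reciprocal)
    blocks = blocks.reset_index(drop=True)
    sid_to_qids: dict[int, set[int]] = {}
    for r in assign.itertuples():
        sid_to_qids.setdefault(r.sid, set()).add(r.qid)

    cats = []
    for qr in query_regions.itertuples():
        members = blocks[assign["qid"] == qr.qid]
        qlen = qr.end - qr.start
        if not qr.duplicated:
            cats.append(None)  # decided below via the anchor chain
            continue
        schroms = set(members["schrom"])
        local = len(schroms) == 1
        private = all(sid_to_qids[s] == {qr.qid} for s in qr.sids)
        # union of pairwise intersections among merged subject regions
        sub_iv = {}
        for s in qr.sids:
            m = members[assign.loc[members.index, "sid"] == s]
            sub_iv[s] = (
                m["schrom"].iloc[0],
                merge(m[["sstart", "send"]].to_numpy()),
            )
        ov = 0
        sids = list(sub_iv)
        for i in range(len(sids)):
            for j in range(i + 1, len(sids)):
                ca, ia = sub_iv[sids[i]]
                cb, ib = sub_iv[sids[j]]
                if ca == cb:
                    ov += intersect_length(ia, ib)
        mis = (
            qlen >= min_length
            and ov < max_subject_overlap * qlen
            and private
        )
        if not private:
            n_subject_copies = len(qr.sids)
            sharing_qids = set().union(*(sid_to_qids[s] for s in qr.sids))
            if n_subject_copies > len(sharing_qids) and len(sharing_qids) >= 2:
                cats.append("complex")
                continue
        if mis:
            cats.append("M2" if local else "M3")
        else:
            cats.append("C2" if local else "C3")

    # C1 vs M1 for the non-duplicated regions, per query chromosome
    query_regions = query_regions.assign(category=cats)
    for chrom, grp in query_regions[~query_regions["duplicated"]].groupby("chrom"):
        if grp.empty:
            continue
        idxs = grp.index.to_list()
        # dominant subject chromosome by aligned query length
        weights: dict[str, int] = {}
        schrom_of = {}
        anchors = []
        for i in idxs:
            qr = query_regions.loc[i]
            members = blocks[assign["qid"] == qr.qid]
            sch = members["schrom"].mode().iloc[0]
            schrom_of[i] = sch
            weights[sch] = weights.get(sch, 0) + (qr.end - qr.start)
        dominant = max(weights, key=weights.get)
        on_dom = [i for i in idxs if schrom_of[i] == dominant]
        chain_items = []
        for i in on_dom:
            qr = query_regions.loc[i]
            members = blocks[assign["qid"] == qr.qid]
            chain_items.append((qr.start, int(members["sstart"].min()), qr.end - qr.start))
        chain = _lis_chain(chain_items)
        for pos, i in enumerate(on_dom):
            query_regions.loc[i, "category"] = "C1" if pos in chain else "M1"
        for i in idxs:
            if schrom_of[i] != dominant:
                query_regions.loc[i, "category"] = "M1"
    return query_regions[["qid", "chrom", "start", "end", "duplicated", "category"]]


def add_unaligned(categories: pd.DataFrame, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Append 'unaligned' rows covering query spans with no category."""
    rows = []
    for chrom, L in sorted(chrom_lengths.items()):
        iv = categories[categories.chrom == chrom][["start", "end"]].to_numpy()
        m = merge(iv) if len(iv) else np.empty((0, 2), int)
        prev = 0
        for s, e in m:
            if s > prev:
                rows.append((-1, chrom, prev, s, False, "unaligned"))
            prev = max(prev, e)
        if prev < L:
            rows.append((-1, chrom, prev, L, False, "unaligned"))
    extra = pd.DataFrame(rows, columns=["qid", "chrom", "start", "end", "duplicated", "category"])
    return (
        pd.concat([categories, extra], ignore_index=True)
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )


def intersect_with_coverage(
    categories: pd.DataFrame, regions: pd.DataFrame, majority: float = 0.5
):
    """Cross coverage classes with assembly categories.

    Returns a tuple:
    * class_fractions — per coverage class, the fraction of its length in
      each category;
    * category_fractions — per category, the fraction of its classed length
      overlapped by HC/BG/LC/other (rows sum to 1);
    * labelled regions — the regions table with an ``assembly_label`` column
      ("M2/M3" or "C2/C3") where a strict majority (> 50% of region length)
      of one pair exists.
    """
    cat_iv = {
        cat: {c: g[["start", "end"]].to_numpy() for c, g in grp.groupby("chrom")}
        for cat, grp in categories.groupby("category")
    }
    cls_iv = {
        cls: {c: g[["start", "end"]].to_numpy() for c, g in grp.groupby("chrom")}
        for cls, grp in regions.groupby("coverage_class")
    }

    def overlap(a_by_chrom, b_by_chrom):
        return sum(
            intersect_length(a_by_chrom[c], b_by_chrom[c])
            for c in set(a_by_chrom) & set(b_by_chrom)
        )

    classes = ["HC", "BG", "LC", "other"]
    class_fractions = {}
    for cls in classes:
        if cls not in cls_iv:
            continue
        total = sum(union_length(iv) for iv in cls_iv[cls].values())
        class_fractions[cls] = {
            cat: overlap(cls_iv[cls], cat_iv[cat]) / total if total else 0.0
            for cat in cat_iv
        }
    category_fractions = {}
    for cat in cat_iv:
        ovs = {
            cls: overlap(cat_iv[cat], cls_iv.get(cls, {})) for cls in classes
        }
        tot = sum(ovs.values())
        category_fractions[cat] = {
            cls: (ovs[cls] / tot if tot else 0.0) for cls in classes
        }

    labels = []
    mis_iv = {c: merge(np.vstack([
        cat_iv.get("M2", {}).get(c, np.empty((0, 2), int)),
        cat_iv.get("M3", {}).get(c, np.empty((0, 2), int)),
    ])) for c in set(regions["chrom"])}
    cor_iv = {c: merge(np.vstack([
        cat_iv.get("C2", {}).get(c, np.empty((0, 2), int)),
        cat_iv.get("C3", {}).get(c, np.empty((0, 2), int)),
    ])) for c in set(regions["chrom"])}
    for r in regions.itertuples():
        span = np.array([[r.start, r.end]])
        L = r.end - r.start
        f_m = intersect_length(span, mis_iv[r.chrom]) / L if L else 0.0
        f_c = intersect_length(span, cor_iv[r.chrom]) / L if L else 0.0
        if f_m > majority:
            labels.append("M2/M3")
        elif f_c > majority:
            labels.append("C2/C3")
        else:
            labels.append(None)
    labelled = regions.assign(assembly_label=labels)
    return class_fractions, category_fractions, labelled


def cross_assembly_class_map(
    regions_on_query: pd.DataFrame,
    blocks: pd.DataFrame,
    regions_on_subject: pd.DataFrame,
) -> pd.Series:
    """Project each query region through the alignment and report the subject
    coverage class covering the plurality of its projected bases."""
    sub_cls = {
        (r.chrom, r.start, r.end): r.coverage_class for r in regions_on_subject.itertuples()
    }
    sub_by_chrom = {
        c: g[["start", "end"]].to_numpy() for c, g in regions_on_subject.groupby("chrom")
    }
    out = []
    for r in regions_on_query.itertuples():
        votes: dict[str, int] = {}
        hits = blocks[
            (blocks.qchrom == r.chrom) & (blocks.qstart < r.end) & (blocks.qend > r.start)
        ]
        for b in hits.itertuples():
            a = max(r.start, b.qstart)
            z = min(r.end, b.qend)
            if b.orient == "+":
                ps, pe = b.sstart + (a - b.qstart), b.sstart + (z - b.qstart)
            else:
                ps, pe = b.send - (z - b.qstart), b.send - (a - b.qstart)
            proj = np.array([[ps, pe]])
            for sr in regions_on_subject[regions_on_subject.chrom == b.schrom].itertuples():
                ov = intersect_length(proj, np.array([[sr.start, sr.end]]))
                if ov:
                    votes[sr.coverage_class] = votes.get(sr.coverage_class, 0) + ov
        out.append(max(votes, key=votes.get) if votes else "unaligned")
    return pd.Series(out, index=regions_on_query.index, name="subject_class")
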