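"""Synthetic genome / misassembly test bench.

Builds a "truth" genome with planted duplications and annotation tracks,
derives a short-read-style assembly in which chosen duplicate clusters are
collapsed to a single copy (the canonical collapsed-duplication misassembly)
and chosen intervals are replaced by N gaps, simulates read placements at a
target fold coverage, and emits the truth labels every downstream stage is
scored against:

* per-base expected read depth (k over a collapsed k-copy cluster, 0 over
  gaps, 1 elsewhere),
* the six-way assembly category (C1/C2/C3/M1/M2/M3),
* truth alignment blocks between the collapsed and truth assemblies.

No aligner is run: multi-mapping is emulated by flagging reads that originate
inside a duplicated tract that is retained (both copies present) in the
assembly, and alignment blocks are emitted directly from the construction.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import merge

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N = ord("N")


class GenomeSpecError(ValueError):
    """Raised when a genome spec is internally inconsistent."""


@dataclass
class TandemCluster:
    """n_copies adjacent near-identical units of unit_length bp."""

    name: str
    chrom: str
    start: int
    unit_length: int
    n_copies: int = 2

    @property
    def end(self) -> int:
        return self.start + self.unit_length * self.n_copies

    def copy_interval(self, i: int) -> tuple[int, int]:
        s = self.start + i * self.unit_length
        return s, s + self.unit_length


@dataclass
class InterchromPair:
    """A near-identical duplicate pair on two different chromosomes."""

    name: str
    chrom_a: str
    start_a: int
    chrom_b: str
    start_b: int
    length: int


@dataclass
class SSRTract:
    chrom: str
    start: int
    unit_length: int
    n_copies: int

    @property
    def end(self) -> int:
        return self.start + self.unit_length * self.n_copies


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    n_exons: int = 3
    exon_length: int = 300
    intron_length: int = 150

    @property
    def end(self) -> int:
        n_int = max(self.n_exons - 1, 0)
        return self.start + self.n_exons * self.exon_length + n_int * self.intron_length

    @property
    def n_introns(self) -> int:
        return max(self.n_exons - 1, 0)


@dataclass
class FeatureInterval:
    chrom: str
    start: int
    end: int


@dataclass
class GenomeSpec:
    """Declarative description of a synthetic truth genome and its derived assembly.

    Coordinates are 0-based half-open on the truth genome. ``collapse_events``
    name tandem clusters / interchromosomal pairs (by their ``name``) that are
    merged into one copy in the derived assembly; ``gap_events`` are truth
    intervals replaced by N there.
    """

    chrom_lengths: dict[str, int]
    gc: float = 0.36
    gc_segments: list[tuple[str, int, int, float]] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    paralog_pairs: list[tuple[str, str]] = field(default_factory=list)
    tandem_clusters: list[TandemCluster] = field(default_factory=list)
    interchrom_pairs: list[InterchromPair] = field(default_factory=list)
    tes: list[FeatureInterval] = field(default_factory=list)
    pseudogenes: list[FeatureInterval] = field(default_factory=list)
    ncrnas: list[FeatureInterval] = field(default_factory=list)
    ssr_tracts: list[SSRTract] = field(default_factory=list)
    collapse_events: list[str] = field(default_factory=list)
    gap_events: list[tuple[str, int, int]] = field(default_factory=list)
    coverage: float = 46.0
    read_length: int = 100
    gc_bias: float = 0.0
    multimap_fraction: float = 0.9
    mutation_rate: float = 0.01
    seed: int = 0

    def duplicate_names(self) -> set[str]:
        return {c.name for c in self.tandem_clusters} | {
            p.name for p in self.interchrom_pairs
        }

    def validate(self) -> None:
        if self.coverage <= 0:
            raise GenomeSpecError("coverage must be > 0")
        if self.read_length < 1:
            raise GenomeSpecError("read length must be >= 1")
        if not 0 <= self.mutation_rate <= 0.05:
            raise GenomeSpecError("mutation rate must be in [0, 0.05]")
        for chrom, s, e in [
            *((c.chrom, c.start, c.end) for c in self.tandem_clusters),
            *((p.chrom_a, p.start_a, p.start_a + p.length) for p in self.interchrom_pairs),
            *((p.chrom_b, p.start_b, p.start_b + p.length) for p in self.interchrom_pairs),
            *((t.chrom, t.start, t.end) for t in self.ssr_tracts),
            *((g.chrom, g.start, g.end) for g in self.genes),
            *((f.chrom, f.start, f.end) for f in self.tes + self.pseudogenes + self.ncrnas),
            *self.gap_events,
        ]:
            if chrom not in self.chrom_lengths:
                raise GenomeSpecError(f"unknown chromosome {chrom!r}")
            if not (0 <= s < e <= self.chrom_lengths[chrom]):
                raise GenomeSpecError(
                    f"interval {chrom}:{s}-{e} outside chromosome bounds"
                )
        dup = self.duplicate_names()
        for ev in self.collapse_events:
            if ev not in dup:
                raise GenomeSpecError(f"collapse event {ev!r} references no planted cluster")
        # sequence-writing features must not collide
        writers: list[tuple[str, str, int, int]] = []
        for c in self.tandem_clusters:
            writers.append((c.name, c.chrom, c.start, c.end))
        for p in self.interchrom_pairs:
            writers.append((p.name + ":target", p.chrom_b, p.start_b, p.start_b + p.length))
        for i, t in enumerate(self.ssr_tracts):
            writers.append((f"ssr{i}", t.chrom, t.start, t.end))
        by_chrom: dict[str, list] = {}
        for w in writers:
            by_chrom.setdefault(w[1], []).append(w)
        for chrom, ws in by_chrom.items():
            ws.sort(key=lambda w: w[2])
            for a, b in zip(ws, ws[1:]):
                if b[2] < a[3]:
                    raise GenomeSpecError(
                        f"planted features {a[0]!r} and {b[0]!r} overlap on {chrom}"
                    )


@dataclass
class TruthGenome:
    seqs: dict[str, str]
    tracks: dict[str, pd.DataFrame]
    duplicates: pd.DataFrame  # name, kind, chrom, start, end, copy
    spec: GenomeSpec


@dataclass
class TruthLabels:
    """Per-base truth on the collapsed assembly, as a tiling segment table."""

    segments: pd.DataFrame  # chrom, start, end, expected_rd, category, name
    blocks: pd.DataFrame  # qchrom..send, identity, orient

    def expected_rd_per_bin(self, chrom: str, length: int, bin_size: int) -> np.ndarray:
        base = np.ones(length)
        for row in self.segments[self.segments.chrom == chrom].itertuples():
            base[row.start : row.end] = row.expected_rd
        n_bins = -(-length // bin_size)
        pad = n_bins * bin_size - length
        if pad:
            base = np.concatenate([base, np.zeros(pad)])
        return base.reshape(n_bins, bin_size).mean(axis=1)

    def class_intervals(self) -> pd.DataFrame:
        """Expected coverage class (HC/LC/BG) intervals on the collapsed assembly."""
        seg = self.segments
        cls = np.where(seg.expected_rd >= 2, "HC", np.where(seg.expected_rd == 0, "LC", "BG"))
        return pd.DataFrame(
            {"chrom": seg.chrom, "start": seg.start, "end": seg.end, "coverage_class": cls}
        )


@dataclass
class CollapsedAssembly:
    seqs: dict[str, str]
    labels: TruthLabels
    truth: TruthGenome


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def build_truth_genome(spec: GenomeSpec) -> TruthGenome:
    """Materialise a spec: random chromosomes plus planted feature tracks.

    Deterministic for a fixed ``spec.seed``. Duplicate copies are created by
    copy-then-point-mutate at ``spec.mutation_rate`` (default 1%), so copies
    share >= 95% identity by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    seqs: dict[str, np.ndarray] = {}
    for chrom in sorted(spec.chrom_lengths):
        seqs[chrom] = _random_seq(rng, spec.chrom_lengths[chrom], spec.gc)
    for chrom, s, e, gc in spec.gc_segments:
        seqs[chrom][s:e] = _random_seq(rng, e - s, gc)

    # SSR tracts: a random unit repeated exactly
    ssr_rows = []
    for t in spec.ssr_tracts:
        unit = _random_seq(rng, t.unit_length, spec.gc)
        tract = np.tile(unit, t.n_copies)
        seqs[t.chrom][t.start : t.end] = tract
        ssr_rows.append((t.chrom, t.start, t.end, unit.tobytes().decode()))

    dup_rows = []
    for c in spec.tandem_clusters:
        unit = seqs[c.chrom][c.start : c.start + c.unit_length].copy()
        for i in range(c.n_copies):
            s, e = c.copy_interval(i)
            if i > 0:
                seqs[c.chrom][s:e] = _mutate(rng, unit, spec.mutation_rate)
            dup_rows.append((c.name, "tandem", c.chrom, s, e, i))
    for p in spec.interchrom_pairs:
        src = seqs[p.chrom_a][p.start_a : p.start_a + p.length].copy()
        seqs[p.chrom_b][p.start_b : p.start_b + p.length] = _mutate(
            rng, src, spec.mutation_rate
        )
        dup_rows.append((p.name, "interchrom", p.chrom_a, p.start_a, p.start_a + p.length, 0))
        dup_rows.append((p.name, "interchrom", p.chrom_b, p.start_b, p.start_b + p.length, 1))

    def _bed(rows, cols=("chrom", "start", "end")):
        return pd.DataFrame(rows, columns=list(cols))

    gene_rows = [
        (g.chrom, g.start, g.end, g.gene_id, g.n_introns) for g in spec.genes
    ]
    tracks = {
        "genes": _bed(gene_rows, ("chrom", "start", "end", "gene_id", "n_introns")),
        "tes": _bed([(f.chrom, f.start, f.end) for f in spec.tes]),
        "pseudogenes": _bed([(f.chrom, f.start, f.end) for f in spec.pseudogenes]),
        "ncrnas": _bed([(f.chrom, f.start, f.end) for f in spec.ncrnas]),
        "ssrs": _bed(ssr_rows, ("chrom", "start", "end", "motif")),
    }
    duplicates = pd.DataFrame(
        dup_rows, columns=["name", "kind", "chrom", "start", "end", "copy"]
    )
    return TruthGenome(
        seqs={c: a.tobytes().decode() for c, a in seqs.items()},
        tracks=tracks,
        duplicates=duplicates,
        spec=spec,
    )


def derive_collapsed_assembly(
    truth: TruthGenome,
    collapse_events: list[str] | None = None,
    gap_events: list[tuple[str, int, int]] | None = None,
) -> CollapsedAssembly:
    """Merge the named duplicate clusters to single copies and insert N gaps.

    For a collapsed k-copy cluster the retained copy gets expected RD = k and
    category M2 (copies were on one truth chromosome) or M3 (different
    chromosomes); uncollapsed duplicates keep RD 1 with category C2/C3; gaps
    get RD 0; all remaining unique sequence is C1 with RD 1.
    """
    spec = truth.spec
    if collapse_events is None:
        collapse_events = spec.collapse_events
    if gap_events is None:
        gap_events = spec.gap_events
    known = spec.duplicate_names()
    for ev in collapse_events:
        if ev not in known:
            raise GenomeSpecError(f"collapse of unknown cluster {ev!r}")

    dups = truth.duplicates
    removals: dict[str, list[tuple[int, int]]] = {c: [] for c in spec.chrom_lengths}
    # special truth intervals: (chrom, s, e, expected_rd, category, name)
    specials: list[tuple[str, int, int, float, str, str]] = []
    for name in sorted(known):
        rows = dups[dups.name == name].sort_values("copy")
        kind = rows.kind.iloc[0]
        k = len(rows)
        first = rows.iloc[0]
        if name in collapse_events:
            for r in rows.iloc[1:].itertuples():
                removals[r.chrom].append((r.start, r.end))
            cat = "M2" if kind == "tandem" else "M3"
            specials.append((first.chrom, first.start, first.end, float(k), cat, name))
        else:
            cat = "C2" if kind == "tandem" else "C3"
            for r in rows.itertuples():
                specials.append((r.chrom, r.start, r.end, 1.0, cat, name))
    for i, (chrom, s, e) in enumerate(gap_events):
        specials.append((chrom, s, e, 0.0, "gap", f"gap{i}"))

    seg_rows = []
    seqs: dict[str, str] = {}
    offsets: dict[str, list[tuple[int, int, int]]] = {}
    for chrom in sorted(spec.chrom_lengths):
        L = spec.chrom_lengths[chrom]
        rem = merge(np.array(removals[chrom]).reshape(-1, 2)) if removals[chrom] else np.empty((0, 2), int)
        # kept truth segments
        kept = []
        prev = 0
        for s, e in rem:
            if s > prev:
                kept.append((prev, s))
            prev = e
        if prev < L:
            kept.append((prev, L))
        chrom_specials = sorted(
            [sp for sp in specials if sp[0] == chrom], key=lambda sp: sp[1]
        )
        pieces = []
        off = 0
        offsets[chrom] = []
        for ks, ke in kept:
            offsets[chrom].append((off, off + (ke - ks), ks))
            cuts = {ks, ke}
            for _, s, e, _, _, _ in chrom_specials:
                if ks < e and s < ke:
                    cuts.add(max(s, ks))
                    cuts.add(min(e, ke))
            bounds = sorted(cuts)
            for a, b in zip(bounds, bounds[1:]):
                rd, cat, name = 1.0, "C1", ""
                for _, s, e, srd, scat, sname in chrom_specials:
                    if s <= a and b <= e:
                        rd, cat, name = srd, scat, sname
                        break
                seg = truth.seqs[chrom][a:b]
                if cat == "gap":
                    seg = "N" * (b - a)
                pieces.append(seg)
                seg_rows.append((chrom, off, off + (b - a), rd, cat, name, a, b))
                off += b - a
        seqs[chrom] = "".join(pieces)

    segments = pd.DataFrame(
        seg_rows,
        columns=["chrom", "start", "end", "expected_rd", "category", "name", "truth_start", "truth_end"],
    )
    blocks = _truth_blocks(truth, segments)
    labels = TruthLabels(segments=segments, blocks=blocks)
    return CollapsedAssembly(seqs=seqs, labels=labels, truth=truth)


def _identity(a: str, b: str) -> float:
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    n = min(len(x), len(y))
    if n == 0:
        return 100.0
    return 100.0 * float((x[:n] == y[:n]).mean())


def _truth_blocks(truth: TruthGenome, segments: pd.DataFrame) -> pd.DataFrame:
    """One alignment block per (collapsed interval, truth copy) pair."""
    dups = truth.duplicates
    rows = []
    # merge runs of contiguous C1 segments into single full blocks
    for chrom, seg in segments.groupby("chrom", sort=True):
        run = None
        for r in seg.sort_values("start").itertuples():
            if r.category == "C1":
                if (
                    run is not None
                    and run[1] == r.start
                    and run[3] == r.truth_start
                ):
                    run = (run[0], r.end, run[2], r.truth_end)
                else:
                    if run is not None:
                        rows.append((chrom, run[0], run[1], chrom, run[2], run[3], 100.0, "+"))
                    run = (r.start, r.end, r.truth_start, r.truth_end)
            else:
                if run is not None:
                    rows.append((chrom, run[0], run[1], chrom, run[2], run[3], 100.0, "+"))
                    run = None
                if r.category == "gap":
                    continue
                copies = dups[dups.name == r.name]
                for c in copies.itertuples():
                    ident = _identity(
                        truth.seqs[chrom][r.truth_start : r.truth_end],
                        truth.seqs[c.chrom][c.start : c.end],
                    )
                    rows.append(
                        (chrom, r.start, r.end, c.chrom, c.start, c.end, round(ident, 2), "+")
                    )
        if run is not None:
            rows.append((chrom, run[0], run[1], chrom, run[2], run[3], 100.0, "+"))
    return pd.DataFrame(
        rows,
        columns=["qchrom", "qstart", "qend", "schrom", "sstart", "send", "identity", "orient"],
    )


def simulate_reads(
    seqs: dict[str, str],
    segments: pd.DataFrame,
    coverage: float,
    read_length: int,
    gc_bias: float = 0.0,
    multimap_fraction: float = 1.0,
    seed: int = 0,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Poisson read-start sampling per bin, scaled by expected read depth.

    ``segments`` is a (chrom, start, end, expected_rd[, category]) table; the
    expected number of read starts in a bin is
    ``expected_rd * coverage * bin_size / read_length`` before GC bias, which
    multiplies the rate by the logistic factor ``2 / (1 + exp(b*(gc - gc0)))``
    centred on the genome-mean GC. Reads whose origin lies inside a retained
    duplicated tract (category C2/C3) are flagged multi-mapping with
    probability ``multimap_fraction``. Reads never start on an N base.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    has_cat = "category" in segments.columns
    frames = []
    gc0 = None
    if gc_bias != 0.0:
        tot_gc, tot = 0, 0
        for s in seqs.values():
            arr = np.frombuffer(s.encode(), dtype=np.uint8)
            tot_gc += int(np.isin(arr, np.frombuffer(b"GC", np.uint8)).sum())
            tot += int((arr != _N).sum())
        gc0 = tot_gc / max(tot, 1)
    read_no = 0
    for chrom in sorted(seqs):
        L = len(seqs[chrom])
        if read_length > L:
            raise ValueError(f"read length {read_length} exceeds chromosome {chrom} length")
        arr = np.frombuffer(seqs[chrom].encode(), dtype=np.uint8)
        rd = np.ones(L)
        mm = np.zeros(L, dtype=bool)
        for row in segments[segments.chrom == chrom].itertuples():
            rd[row.start : row.end] = row.expected_rd
            if has_cat and row.category in ("C2", "C3"):
                mm[row.start : row.end] = True
        n_bins = -(-L // bin_size)
        pad = n_bins * bin_size - L
        rdp = np.concatenate([rd, np.zeros(pad)]) if pad else rd
        bin_rd = rdp.reshape(n_bins, bin_size).mean(axis=1)
        lam = bin_rd * coverage * bin_size / read_length
        if gc_bias != 0.0:
            isgc = np.isin(arr, np.frombuffer(b"GC", np.uint8)).astype(float)
            isn = (arr == _N)
            if pad:
                isgc = np.concatenate([isgc, np.zeros(pad)])
                isn = np.concatenate([isn, np.ones(pad, bool)])
            nn = (~isn).reshape(n_bins, bin_size).sum(axis=1)
            gcb = np.where(
                nn > 0, isgc.reshape(n_bins, bin_size).sum(axis=1) / np.maximum(nn, 1), gc0
            )
            lam = lam * 2.0 / (1.0 + np.exp(gc_bias * (gcb - gc0)))
        counts = rng.poisson(lam)
        starts = np.repeat(np.arange(n_bins) * bin_size, counts) + rng.integers(
            0, bin_size, counts.sum()
        )
        starts = np.minimum(starts, L - read_length)
        starts = starts[arr[starts] != _N]
        starts.sort(kind="stable")
        flagged = mm[starts] & (rng.random(len(starts)) < multimap_fraction)
        frames.append(
            pd.DataFrame(
                {
                    "read_id": [f"r{read_no + i:08d}" for i in range(len(starts))],
                    "chrom": chrom,
                    "start": starts.astype(np.int64),
                    "length": read_length,
                    "multimap": flagged.astype(np.int64),
                }
            )
        )
        read_no += len(starts)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["read_id", "chrom", "start", "length", "multimap"]
    )


def emit_alignment_coords(collapsed: CollapsedAssembly) -> pd.DataFrame:
    """Truth alignment blocks in show-coords layout (1-based inclusive).

    Columns: S1 E1 S2 E2 LEN1 LEN2 IDY QCHR SCHR where S1/E1 are query
    (collapsed assembly) and S2/E2 subject (truth assembly) coordinates.
    Round-trips through :func:`misasm.misassembly.parse_coords`.
    """
    b = collapsed.labels.blocks
    return pd.DataFrame(
        {
            "S1": b.qstart + 1,
            "E1": b.qend,
            "S2": np.where(b.orient == "+", b.sstart + 1, b.send),
            "E2": np.where(b.orient == "+", b.send, b.sstart + 1),
            "LEN1": b.qend - b.qstart,
            "LEN2": b.send - b.sstart,
            "IDY": b.identity,
            "QCHR": b.qchrom,
            "SCHR": b.schrom,
        }
    )


def demo_spec(
    seed: int = 0,
    n_chroms: int = 2,
    chrom_length: int = 400_000,
    coverage: float = 46.0,
) -> GenomeSpec:
    """A randomised but reproducible spec with all feature kinds planted.

    The layout emulates the real use case at desk scale: a few kilobase-scale
    tandem clusters (half of them collapsed in the derived assembly), one
    collapsed and one retained interchromosomal pair, N gaps, TEs, SSR
    tracts, genes with tandem paralogs, pseudogenes and ncRNAs; 46-fold
    coverage of 100 bp reads, 1% duplicate-copy divergence.
    """
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    spec = GenomeSpec(chrom_lengths={c: chrom_length for c in chroms}, seed=seed, coverage=coverage)
    slot = 20_000  # feature slots keep planted writers disjoint
    for ci, chrom in enumerate(chroms):
        pos = 10_000
        k = 0
        while pos + 12_000 < chrom_length - 10_000:
            r = rng.random()
            if r < 0.25:
                unit = int(rng.integers(2000, 4000))
                copies = int(rng.integers(2, 4))
                name = f"td_{chrom}_{k}"
                spec.tandem_clusters.append(
                    TandemCluster(name, chrom, pos, unit, copies)
                )
                if rng.random() < 0.5:
                    spec.collapse_events.append(name)
            elif r < 0.40:
                spec.gap_events.append((chrom, pos, pos + int(rng.integers(1500, 4000))))
            elif r < 0.55:
                spec.ssr_tracts.append(
                    SSRTract(chrom, pos, int(rng.integers(2, 7)), int(rng.integers(20, 80)))
                )
            elif r < 0.75:
                spec.tes.append(FeatureInterval(chrom, pos, pos + int(rng.integers(500, 3000))))
            else:
                g = GeneModel(f"g_{chrom}_{k}", chrom, pos, n_exons=int(rng.integers(1, 6)))
                spec.genes.append(g)
                if rng.random() < 0.3:
                    g2 = GeneModel(f"g_{chrom}_{k}t", chrom, g.end + 200, n_exons=g.n_exons)
                    if g2.end < chrom_length - 10_000:
                        spec.genes.append(g2)
                        spec.paralog_pairs.append((g.gene_id, g2.gene_id))
                if rng.random() < 0.3:
                    spec.pseudogenes.append(
                        FeatureInterval(chrom, pos + 7000, pos + 7000 + int(rng.integers(200, 800)))
                    )
                if rng.random() < 0.2:
                    spec.ncrnas.append(
                        FeatureInterval(chrom, pos + 9000, pos + 9000 + int(rng.integers(100, 400)))
                    )
            pos += slot
            k += 1
    if n_chroms >= 2:
        L = chrom_length
        spec.interchrom_pairs.append(
            InterchromPair("ic_0", chroms[0], L - 9_000, chroms[1], L - 9_000, 3_000)
        )
        spec.interchrom_pairs.append(
            InterchromPair("ic_1", chroms[0], L - 5_000, chroms[1], L - 5_000, 3_000)
        )
        spec.collapse_events.append("ic_0")
    return spec
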