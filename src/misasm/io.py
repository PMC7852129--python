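"""Readers and writers for the formats the pipeline exchanges.

Every 1-based format (GFF3, coords tables) is converted to the package's
internal 0-based half-open convention at this boundary; internal code never
sees 1-based coordinates.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .depth import PLACEMENT_COLUMNS
from .misassembly import parse_coords, write_coords  # noqa: F401  (re-exported)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sorted(seqs.items())]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_placements(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PLACEMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"placements table missing columns {missing}")
    return df[PLACEMENT_COLUMNS]


def write_placements(df: pd.DataFrame, path) -> None:
    df[PLACEMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_bedgraph(bins: pd.DataFrame, path, value_col: str = "rd") -> None:
    bins[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gff3_genes(path) -> pd.DataFrame:
    """Minimal GFF3 reader: gene records with exon counts, 0-based half-open."""
    rows = []
    exon_counts: dict[str, int] = {}
    genes: dict[str, tuple] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 record at line {lineno}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", f"gene{lineno}")
                genes[gid] = (chrom, int(start) - 1, int(end), strand)
            elif ftype == "exon":
                parent = attr.get("Parent", "")
                exon_counts[parent] = exon_counts.get(parent, 0) + 1
    for gid, (chrom, s, e, strand) in genes.items():
        n_ex = exon_counts.get(gid, 1)
        rows.append((chrom, s, e, gid, max(n_ex - 1, 0), strand))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "n_introns", "strand"]
    )


def write_gff3_genes(genes: pd.DataFrame, path) -> None:
    """Inverse of :func:`read_gff3_genes`: gene + exon records (1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            strand = getattr(g, "strand", "+")
            fh.write(
                f"{g.chrom}\tmisasm\tgene\t{g.start + 1}\t{g.end}\t.\t{strand}\t.\tID={g.gene_id}\n"
            )
            n_exons = int(getattr(g, "n_introns", 0)) + 1
            length = g.end - g.start
            # evenly spaced exons reproducing the intron count
            exon_len = max(length // (2 * n_exons - 1), 1)
            pos = g.start
            for i in range(n_exons):
                e_end = min(pos + exon_len, g.end) if i < n_exons - 1 else g.end
                fh.write(
                    f"{g.chrom}\tmisasm\texon\t{pos + 1}\t{e_end}\t.\t{strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )
                pos = min(pos + 2 * exon_len, g.end)


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "coverage_class", "mean_rd", "q_value", "q0"]
    present = [c for c in cols if c in regions.columns]
    regions[present].to_csv(path, sep="\t", header=True, index=False)


def read_regions_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_exists(path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p
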