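"""End-to-end pipeline driver over the synthetic test bench.

simulate -> depth -> call-regions -> classify -> features -> train ->
enrich / permutation tests, emitting one JSON report with the numeric
analogues of the study's figures (RD distributions, model F1, density
correlations and z-scores, enrichment LLR lists, class-by-category
fractions). Every stage logs its seed and parameters into the report.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import depth, features, misassembly, models, regions, stats, synthetic
from .io import write_fasta, write_placements, write_regions_bed


@dataclass
class PipelineConfig:
    out_dir: str = "misasm_out"
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 400_000
    coverage: float = 46.0
    read_length: int = 100
    bin_size: int = 100
    low: float = regions.DEFAULT_LOW
    high: float = regions.DEFAULT_HIGH
    q_max: float = regions.DEFAULT_QMAX
    q0_max: float = regions.DEFAULT_Q0MAX
    min_identity: float = 95.0
    flank_sizes: tuple[int, ...] = (500, 1000, 2000)
    n_balanced: int = 10
    n_perm: int = 200
    model: str = "1"
    window: int = 50_000
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        cfg = cls(**kwargs)
        cfg.extra = {k: v for k, v in data.items() if k not in known}
        if "flank_sizes" in data:
            cfg.flank_sizes = tuple(data["flank_sizes"])
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a generated dataset; returns (and writes) the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in dataclasses.asdict(config).items()}}

    # --- simulate -----------------------------------------------------------
    spec = synthetic.demo_spec(
        seed=config.seed,
        n_chroms=config.n_chroms,
        chrom_length=config.chrom_length,
        coverage=config.coverage,
    )
    truth = synthetic.build_truth_genome(spec)
    collapsed = synthetic.derive_collapsed_assembly(truth)
    placements = synthetic.simulate_reads(
        collapsed.seqs,
        collapsed.labels.segments,
        coverage=config.coverage,
        read_length=config.read_length,
        multimap_fraction=spec.multimap_fraction,
        seed=config.seed,
        bin_size=config.bin_size,
    )
    write_fasta(collapsed.seqs, out / "assembly.fa")
    write_placements(placements, out / "placements.tsv")
    coords = synthetic.emit_alignment_coords(collapsed)
    coords.to_csv(out / "coords.tsv", sep="\t", index=False)
    report["simulate"] = {"seed": config.seed, "n_reads": int(len(placements))}

    # --- depth --------------------------------------------------------------
    bins = depth.compute_rd(placements, collapsed.seqs, bin_size=config.bin_size)
    report["depth"] = {
        "median_rd": float(bins.loc[bins.n_frac <= 0.5, "rd"].median()),
        "n_bins": int(len(bins)),
    }

    # --- call regions -------------------------------------------------------
    cand = regions.segment_bins(bins)
    called = regions.apply_thresholds(
        regions.filter_candidates(cand, config.q_max, config.q0_max),
        config.low,
        config.high,
    )
    called["n_fraction"] = regions.region_n_fraction(called, collapsed.seqs)
    write_regions_bed(called, out / "regions.bed")
    counts = called["coverage_class"].value_counts().to_dict()
    by_class_rd = {
        cls: called.loc[called.coverage_class == cls, "mean_rd"].describe().to_dict()
        for cls in ("HC", "LC", "BG")
        if (called.coverage_class == cls).any()
    }
    report["regions"] = {"counts": counts, "mean_rd": by_class_rd}

    # --- classify -----------------------------------------------------------
    blocks = misassembly.filter_identity(
        misassembly.parse_coords(coords), config.min_identity
    )
    cats = misassembly.classify_query_regions(blocks)
    chrom_lengths = {c: len(s) for c, s in collapsed.seqs.items()}
    cats_full = misassembly.add_unaligned(cats, chrom_lengths)
    cls_frac, cat_frac, labelled = misassembly.intersect_with_coverage(cats_full, called)
    report["misassembly"] = {
        "class_fractions": cls_frac,
        "category_fractions": cat_frac,
        "category_lengths": {
            cat: int((g.end - g.start).sum()) for cat, g in cats_full.groupby("category")
        },
    }

    # --- features + model ---------------------------------------------------
    tandem = features.classify_tandem(
        spec.paralog_pairs,
        {
            c: list(g.sort_values("start").gene_id)
            for c, g in truth.tracks["genes"].groupby("chrom")
        },
    )
    genes = truth.tracks["genes"]
    tracks = {
        "genes": genes,
        "tandem_genes": genes[genes.gene_id.map(tandem).fillna(False)],
        "non_tandem_genes": genes[~genes.gene_id.map(tandem).fillna(False)],
        "pseudogenes": truth.tracks["pseudogenes"],
        "tes": truth.tracks["tes"],
        "ssrs": truth.tracks["ssrs"],
    }
    usable = labelled[labelled.coverage_class.isin(["HC", "LC", "BG"])].reset_index(drop=True)
    X = features.build_feature_matrix(
        usable, collapsed.seqs, tracks, flank_sizes=config.flank_sizes
    )
    y = usable["coverage_class"].to_numpy()
    have = {c: int((y == c).sum()) for c in ("HC", "LC", "BG")}
    report["features"] = {"n_regions": int(len(usable)), "class_counts": have}
    if min(have.values()) >= 5:
        train, test = models.split_holdout(y, seed=config.seed)
        datasets = [
            train[d] for d in models.make_balanced_datasets(
                y[train], n_datasets=config.n_balanced, seed=config.seed
            )
        ]
        rep = models.evaluate(
            X, y, datasets, {"n_estimators": 100, "max_depth": None},
            test_idx=test, folds=min(5, min(have.values())), seed=config.seed,
        )
        report["model"] = rep.summary()

    # --- stats --------------------------------------------------------------
    te_corr = stats.density_correlation(
        called[called.coverage_class == "LC"], truth.tracks["tes"],
        chrom_lengths, window=config.window,
    )
    z = stats.reshuffle_zscore(
        called[called.coverage_class.isin(["HC", "LC", "BG"])].reset_index(drop=True),
        "LC", truth.tracks["tes"], chrom_lengths,
        window=config.window, n=config.n_perm, seed=config.seed,
    )
    report["stats"] = {
        "lc_te_spearman": te_corr.rho,
        "lc_te_reshuffle_z": z.z,
        "n_perm": config.n_perm,
        "seed": config.seed,
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
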