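"""Shared fixtures: one synthetic dataset reused across test modules."""
from dataclasses import dataclass

import pandas as pd
import pytest

from misasm import depth, regions, synthetic as syn


@dataclass
class Dataset:
    spec: syn.GenomeSpec
    truth: syn.TruthGenome
    collapsed: syn.CollapsedAssembly
    placements: pd.DataFrame
    bins: pd.DataFrame
    candidates: pd.DataFrame
    called: pd.DataFrame


@pytest.fixture(scope="session")
def demo() -> Dataset:
    """46x synthetic dataset with collapsed clusters, gaps and annotations."""
    spec = syn.demo_spec(seed=3, n_chroms=2, chrom_length=300_000)
    truth = syn.build_truth_genome(spec)
    collapsed = syn.derive_collapsed_assembly(truth)
    placements = syn.simulate_reads(
        collapsed.seqs,
        collapsed.labels.segments,
        coverage=spec.coverage,
        read_length=spec.read_length,
        multimap_fraction=spec.multimap_fraction,
        seed=3,
    )
    bins = depth.compute_rd(placements, collapsed.seqs, bin_size=100)
    candidates = regions.segment_bins(bins)
    called = regions.apply_thresholds(regions.filter_candidates(candidates))
    return Dataset(spec, truth, collapsed, placements, bins, candidates, called)


@pytest.fixture(scope="session")
def uniform_null():
    """Featureless genome with uniformly sampled reads (the no-signal control)."""
    spec = syn.GenomeSpec(chrom_lengths={"chr1": 1_000_000}, seed=7)
    truth = syn.build_truth_genome(spec)
    seg = pd.DataFrame(
        {"chrom": ["chr1"], "start": [0], "end": [1_000_000], "expected_rd": [1.0]}
    )
    placements = syn.simulate_reads(truth.seqs, seg, 46, 100, seed=7)
    bins = depth.compute_rd(placements, truth.seqs, 100)
    return truth, placements, bins
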