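"""Shared fixtures: simulated experiments reused across test modules.

Session-scoped pipelines keep the suite fast; every run is seed-pinned so
results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from edu_xrseq.damage_profiles import damage_signature_filter
from edu_xrseq.models import AlignedFragment, SimulationConfig
from edu_xrseq.pipeline import build_fixture, preprocess_bundle
from edu_xrseq.preprocess import GenomeIndex, PreprocessResult
from edu_xrseq.repair_landscape import select_analysis_genes
from edu_xrseq.synthetic_data import FixtureBundle


def truth_fragments(truth) -> list[AlignedFragment]:
    """Ground-truth records viewed as perfectly aligned fragments."""
    return [
        AlignedFragment(t.chrom, t.start, t.end, t.strand, t.read_id) for t in truth
    ]


@dataclass
class SimRun:
    bundle: FixtureBundle
    result: PreprocessResult

    @property
    def fragments(self):
        return self.result.fragments

    @property
    def total_mapped(self) -> int:
        return self.result.ledger.n_aligned

    def filtered(self):
        kept, _ = damage_signature_filter(self.fragments, self.bundle.genome)
        return kept

    def analysis_genes(self, expressed_only: bool = True):
        genes = self.bundle.genes
        if expressed_only:
            genes = [g for g in genes if g.expressed]
        return select_analysis_genes(genes)


@pytest.fixture(scope="session")
def default_run() -> SimRun:
    """Full pipeline under the default study conditions: 2-Mb genome,
    40 genes, 50k reads with default excision geometry."""
    bundle = build_fixture(seed=101, config=SimulationConfig(n_reads=50_000))
    return SimRun(bundle=bundle, result=preprocess_bundle(bundle))


@pytest.fixture(scope="session")
def tcr_runs() -> dict[float, SimRun]:
    """100k-read runs with transcribed-strand enhancement 2.5 and 1.2
    (uniform chromatin multipliers), sharing one genome and aligner index."""
    runs: dict[float, SimRun] = {}
    index: GenomeIndex | None = None
    for alpha in (2.5, 1.2):
        cfg = SimulationConfig(n_reads=100_000, tcr_factor=alpha, state_multipliers={})
        bundle = build_fixture(seed=11, config=cfg)
        if index is None:
            index = GenomeIndex(bundle.genome)
        runs[alpha] = SimRun(bundle=bundle, result=preprocess_bundle(bundle, index=index))
    return runs


CHROMATIN_MULTIPLIERS = {
    "Active_Promoter": 2.0,
    "Strong_Enhancer": 1.5,
    "Heterochrom_LowSignal": 0.5,
}


@pytest.fixture(scope="session")
def chromatin_run() -> SimRun:
    """100k-read run with distinctive chromatin-state multipliers and no
    transcription-coupled enhancement."""
    cfg = SimulationConfig(
        n_reads=100_000, tcr_factor=1.0, state_multipliers=dict(CHROMATIN_MULTIPLIERS)
    )
    bundle = build_fixture(seed=5, config=cfg)
    return SimRun(bundle=bundle, result=preprocess_bundle(bundle))
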