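"""Gene selection, strand assignment, RPKM, unit-gene metaprofiles and
TS:NTS ratios."""

from __future__ import annotations

import math

import numpy as np
import pytest

from edu_xrseq.models import AlignedFragment, GeneModel, SimulationConfig
from edu_xrseq.repair_landscape import (
    assign_ts_nts,
    export_strand_tracks,
    gene_repair_summaries,
    rpkm,
    select_analysis_genes,
    timecourse,
    ts_nts_ratio,
    unit_gene_metaprofile,
)
from edu_xrseq.synthetic_data import simulate_excision_reads

from conftest import truth_fragments


def _gene(id, start, end, strand="+", chrom="chr1", expressed=True):
    return GeneModel(id=id, chrom=chrom, start=start, end=end, strand=strand, expressed=expressed)


def _frag(start, end, strand="+", chrom="chr1", rid="r"):
    return AlignedFragment(chrom, start, end, strand, rid)


class TestSelectAnalysisGenes:
    def test_exact_5kb_gene_removed(self):
        genes = [_gene("a", 0, 5_000), _gene("b", 20_000, 25_001)]
        kept = select_analysis_genes(genes)
        assert [g.id for g in kept] == ["b"]

    def test_close_pair_both_removed(self):
        genes = [_gene("a", 0, 6_000), _gene("b", 10_999, 17_000)]  # gap 4999
        assert select_analysis_genes(genes) == []

    def test_random_set_vs_quadratic_oracle(self):
        rng = np.random.default_rng(12)
        genes = []
        for i in range(50):
            chrom = f"chr{1 + i % 2}"
            start = int(rng.integers(0, 500_000))
            length = int(rng.integers(2_000, 12_000))
            genes.append(_gene(f"g{i}", start, start + length, chrom=chrom))
        kept = select_analysis_genes(genes)
        oracle = []
        for g in genes:
            if g.length <= 5_000:
                continue
            ok = True
            for h in genes:
                if h is g or h.chrom != g.chrom:
                    continue
                if max(h.start - g.end, g.start - h.end) < 5_000:
                    ok = False
                    break
            if ok:
                oracle.append(g.id)
        assert sorted(g.id for g in kept) == sorted(oracle)


class TestAssignTsNts:
    gene_plus = _gene("g", 1_000, 7_000, "+")

    def test_opposite_strand_is_ts(self):
        assert assign_ts_nts(_frag(3_000, 3_026, "-"), self.gene_plus) == "TS"

    def test_same_strand_is_nts(self):
        assert assign_ts_nts(_frag(3_000, 3_026, "+"), self.gene_plus) == "NTS"

    def test_midpoint_boundaries(self):
        # midpoint one bp left of start -> outside; at start -> inside
        f_out = _frag(986, 1_012)   # midpoint 999
        f_in = _frag(988, 1_012)    # midpoint 1000
        assert assign_ts_nts(f_out, self.gene_plus) == "outside"
        assert assign_ts_nts(f_in, self.gene_plus) == "NTS"
        f_end = _frag(6_988, 7_014)  # midpoint 7001 >= end
        assert assign_ts_nts(f_end, self.gene_plus) == "outside"

    def test_minus_gene_swaps_classes(self):
        gene_minus = _gene("g", 1_000, 7_000, "-")
        assert assign_ts_nts(_frag(3_000, 3_026, "+"), gene_minus) == "TS"
        assert assign_ts_nts(_frag(3_000, 3_026, "-"), gene_minus) == "NTS"


class TestRpkm:
    def test_direct_arithmetic(self):
        assert rpkm(10, 2_000, 1_000_000, 1e6) == 5.0
        assert rpkm(0, 2_000, 1_000_000) == 0.0

    def test_per_ten_million_scales_by_ten(self):
        assert rpkm(7, 1_500, 3_000_000, 1e7) == pytest.approx(
            10 * rpkm(7, 1_500, 3_000_000, 1e6)
        )

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)


class TestUnitGeneMetaprofile:
    def test_bin_count_default_configuration(self, default_run):
        genes = default_run.analysis_genes()
        prof = unit_gene_metaprofile(default_run.filtered(), genes,
                                     total_mapped=default_run.total_mapped)
        assert prof.n_bins == 20 + 60 + 20
        assert prof.n_upstream == prof.n_downstream == 20

    def test_empty_gene_set_rejected(self, default_run):
        with pytest.raises(ValueError):
            unit_gene_metaprofile(default_run.fragments, [])

    def test_flat_and_equal_under_symmetry(self, default_run):
        """With alpha = 1 and uniform chromatin, TS and NTS body signals are
        statistically flat and equal."""
        b = default_run.bundle
        cfg = SimulationConfig(n_reads=50_000, tcr_factor=1.0, state_multipliers={}, seed=19)
        _, truth = simulate_excision_reads(b.genome, b.genes, b.segmentation, cfg)
        frags = truth_fragments(truth)
        genes = default_run.analysis_genes()
        prof = unit_gene_metaprofile(frags, genes, total_mapped=len(frags))
        ts = prof.ts_counts[prof.body_slice].sum()
        nts = prof.nts_counts[prof.body_slice].sum()
        ratio = ts / nts
        assert abs(ratio - 1.0) <= 3 * math.sqrt(1 / ts + 1 / nts) + 0.02
        # flatness: no body bin deviates grossly from the mean (the fixed
        # lesion-site realization adds a few percent on top of Poisson noise)
        body = (prof.ts_counts + prof.nts_counts)[prof.body_slice]
        mean = body.mean()
        assert np.all(np.abs(body - mean) <= 5 * math.sqrt(mean) + 0.05 * mean)

    def test_minus_strand_gene_orientation(self):
        """A fragment just inside the TSS of a minus-strand gene lands in the
        first body bin, not the last."""
        gene = _gene("g", 1_000, 7_000, "-")
        frag = _frag(6_940, 6_966, "+")  # midpoint 6953, 46 bp from the TSS at 6999
        prof = unit_gene_metaprofile([frag], [gene], total_mapped=1)
        assert prof.ts_counts[prof.n_upstream] == 1  # first body bin, TS class
        assert prof.ts_counts[prof.n_upstream + prof.n_body - 1] == 0

    def test_upstream_fragment_of_minus_gene(self):
        gene = _gene("g", 1_000, 7_000, "-")
        frag = _frag(7_030, 7_056, "-")  # midpoint 7043: 44 bp upstream of TSS
        prof = unit_gene_metaprofile([frag], [gene], total_mapped=1)
        assert prof.nts_counts[prof.n_upstream - 1] == 1  # flank bin closest to TSS

    def test_reversal_symmetry(self, default_run):
        """Flipping every gene strand swaps TS and NTS exactly: per-gene
        counts swap, flank bins mirror, and body totals swap."""
        genes = default_run.analysis_genes()
        flipped = [
            GeneModel(
                id=g.id, chrom=g.chrom, start=g.start, end=g.end,
                strand="-" if g.strand == "+" else "+", expressed=g.expressed,
            )
            for g in genes
        ]
        frags = default_run.filtered()
        total = default_run.total_mapped
        for s_a, s_b in zip(
            gene_repair_summaries(frags, genes, total_mapped=total),
            gene_repair_summaries(frags, flipped, total_mapped=total),
        ):
            assert (s_a.ts_count, s_a.nts_count) == (s_b.nts_count, s_b.ts_count)
        a = unit_gene_metaprofile(frags, genes, total_mapped=total)
        b = unit_gene_metaprofile(frags, flipped, total_mapped=total)
        # flipping reverses the 5'->3' bin axis; flank bins mirror exactly
        rev = b.nts_counts[::-1]
        n_f = a.n_upstream
        assert np.array_equal(rev[:n_f], a.ts_counts[:n_f])
        assert np.array_equal(rev[-n_f:], a.ts_counts[-n_f:])
        assert rev[n_f:-n_f].sum() == a.ts_counts[n_f:-n_f].sum()

    def test_counts_match_naive_overlap_scan(self, default_run):
        genes = default_run.analysis_genes()
        frags = default_run.filtered()[:3_000]
        summaries = gene_repair_summaries(frags, genes, total_mapped=len(frags))
        for g, s in zip(genes, summaries):
            ts = nts = 0
            for f in frags:
                cls = assign_ts_nts(f, g)
                if cls == "TS":
                    ts += 1
                elif cls == "NTS":
                    nts += 1
            assert (s.ts_count, s.nts_count) == (ts, nts)


class TestTsNtsRatio:
    def test_equal_counts_give_one(self):
        gene = _gene("g", 0, 10_000)
        frags = [_frag(100 + 30 * i, 126 + 30 * i, s) for i in range(20) for s in "+-"]
        summaries = gene_repair_summaries(frags, [gene], total_mapped=len(frags))
        assert ts_nts_ratio(summaries) == 1.0

    def test_zero_nts_flagged(self):
        gene = _gene("g", 0, 10_000)
        frags = [_frag(100, 126, "-")]
        summaries = gene_repair_summaries(frags, [gene], total_mapped=1)
        assert math.isnan(ts_nts_ratio(summaries))
        assert not summaries[0].ratio_defined

    def test_five_prime_weighted_decay_gradient(self, default_run):
        """With a 5'-weighted TCR decay, promoter-proximal body bins show
        higher TS:NTS than distal bins."""
        b = default_run.bundle
        cfg = SimulationConfig(
            n_reads=60_000, tcr_factor=4.0, tcr_five_prime_decay=3.0,
            state_multipliers={}, seed=23,
        )
        _, truth = simulate_excision_reads(b.genome, b.genes, b.segmentation, cfg)
        genes = default_run.analysis_genes()
        prof = unit_gene_metaprofile(truth_fragments(truth), genes, total_mapped=len(truth))
        per_bin = ts_nts_ratio(prof, scope="per-bin")
        body = per_bin[prof.body_slice]
        proximal = np.nanmean(body[:10])
        distal = np.nanmean(body[-10:])
        assert proximal > distal


def test_antisense_promoter_strand_switch():
    """With antisense promoter units enabled, preferential repair switches
    strand upstream of the TSS: TS dominates gene bodies while the
    gene-strand class (NTS) dominates the antisense window."""
    from edu_xrseq.pipeline import build_fixture

    cfg = SimulationConfig(
        n_reads=30_000, tcr_factor=4.0, state_multipliers={}, duplication_rate=0.0
    )
    bundle = build_fixture(
        seed=44, n_chrom=1, chrom_bp=500_000, n_genes=8,
        expressed_fraction=1.0, antisense_promoter_fraction=1.0, config=cfg,
    )
    frags = truth_fragments(bundle.truth)
    genes = select_analysis_genes(bundle.genes)
    prof = unit_gene_metaprofile(frags, genes, total_mapped=len(frags))
    assert prof.ts_counts[prof.body_slice].sum() > 2 * prof.nts_counts[prof.body_slice].sum()
    antisense_window = slice(8, 18)  # upstream flank bins covering -1200..-200
    assert (
        prof.nts_counts[antisense_window].sum()
        > 2 * prof.ts_counts[antisense_window].sum()
    )


class TestTimecourse:
    def test_single_sample_matches_ratio(self, default_run):
        genes = default_run.analysis_genes()
        frags = default_run.filtered()
        table = timecourse({"6h": frags}, genes,
                           total_mapped={"6h": default_run.total_mapped})
        assert len(table) == 1
        summaries = gene_repair_summaries(frags, genes, total_mapped=default_run.total_mapped)
        expected = ts_nts_ratio(summaries)
        assert table.loc[0, "ratio"] == pytest.approx(expected)

    def test_empty_sample_isolated(self, default_run):
        genes = default_run.analysis_genes()
        frags = default_run.filtered()
        table = timecourse({"6h": frags, "48h": []}, genes)
        row6 = table[table.timepoint == "6h"].iloc[0]
        row48 = table[table.timepoint == "48h"].iloc[0]
        assert not row6.flagged_empty and row6.ratio > 0
        assert row48.flagged_empty and math.isnan(row48.ratio)


class TestStrandTracks:
    def test_empty_input(self):
        tracks = export_strand_tracks([], {"chr1": 1_000})
        assert tracks["+"] == [] and tracks["-"] == []

    def test_single_fragment_value(self):
        frags = [_frag(100, 126, "+")]
        tracks = export_strand_tracks(frags, {"chr1": 10_000}, bin_bp=50, total_mapped=1)
        assert len(tracks["+"]) == 1 and tracks["-"] == []
        chrom, start, end, value = tracks["+"][0].split("\t")
        assert (chrom, start, end) == ("chr1", "100", "150")
        assert float(value) == pytest.approx(rpkm(1, 50, 1, 1e7))

    def test_conservation_identity(self, default_run):
        """Sum over bins of value * bin_kb * (total / 1e7) recovers the
        fragment count per strand."""
        frags = default_run.fragments[:2_000]
        lengths = default_run.bundle.genome.lengths
        total = len(frags)
        tracks = export_strand_tracks(frags, lengths, bin_bp=50, total_mapped=total)
        for strand in "+-":
            recovered = 0.0
            for line in tracks[strand]:
                _, s, e, v = line.split("\t")
                recovered += float(v) * (int(e) - int(s)) / 1_000.0 * (total / 1e7)
            expected = sum(1 for f in frags if f.strand == strand)
            assert recovered == pytest.approx(expected, rel=1e-4)
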