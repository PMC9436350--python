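"""Synthetic genome, annotation, chromatin tracks and excision-read simulator.

The simulator emulates the data-generating process of an EdU XR-seq
experiment: EdU replaces a fraction of thymidines on both strands during
replication; the excision nuclease removes lesion-containing oligomers by
dual incision, leaving the lesion ``d`` nucleotides from the 5' end (d in
19-21, peak 20) with a ``k``-nucleotide 3' tail (product length L = d + k,
22-30 nt, nominal 26-mer); excision is enhanced by a factor alpha on the
transcribed strand of expressed genes (transcription-coupled repair) and
modulated by chromatin state; the library then acquires a 3' adapter
read-through and PCR duplicates.

Every read carries an :class:`~edu_xrseq.models.ExcisionTruthRecord` so that
downstream estimates (geometry, TS:NTS ratio, state enrichment) can be
checked against the simulated ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import io as _io
from .models import (
    CapacityError,
    ChromatinSegmentation,
    DNasePeak,
    DNasePeakSet,
    ExcisionTruthRecord,
    GeneModel,
    NoEligibleSitesError,
    RawRead,
    SimulationConfig,
    SyntheticGenome,
    reverse_complement,
)

# A 15-label vocabulary in the style of the ChromHMM core model.
CHROMATIN_STATES: tuple[str, ...] = (
    "Active_Promoter",
    "Weak_Promoter",
    "Poised_Promoter",
    "Strong_Enhancer",
    "Strong_Enhancer_2",
    "Weak_Enhancer",
    "Weak_Enhancer_2",
    "Insulator",
    "Txn_Transition",
    "Txn_Elongation",
    "Weak_Txn",
    "Repressed",
    "Heterochrom_LowSignal",
    "Repetitive_CNV",
    "Repetitive_CNV_2",
)

_BASES = b"ACGT"

# products never extend past chromosome ends; margin covers max d + max k
_EDGE_MARGIN = 40


def generate_genome(
    n_chrom: int, length_bp: int, gc_fraction: float, seed: int
) -> SyntheticGenome:
    """Generate i.i.d. random chromosomes with the requested GC content.

    P(G) = P(C) = gc_fraction / 2 and P(A) = P(T) = (1 - gc_fraction) / 2.
    Deterministic given ``seed``.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if length_bp < 10_000:
        raise ValueError("length_bp must be >= 10000")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    p = np.array([at, gc, gc, at])
    lut = np.frombuffer(_BASES, dtype=np.uint8)
    chroms = {}
    for i in range(n_chrom):
        codes = rng.choice(4, size=length_bp, p=p)
        chroms[f"chr{i + 1}"] = lut[codes].tobytes().decode("ascii")
    return SyntheticGenome(chroms)


def _apportion(total: int, weights: Sequence[int]) -> list[int]:
    """Largest-remainder apportionment of ``total`` items by weight."""
    w = np.asarray(weights, dtype=float)
    exact = total * w / w.sum()
    counts = np.floor(exact).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    return counts.tolist()


def generate_annotation(
    genome: SyntheticGenome,
    n_genes: int,
    min_len: int = 5_001,
    min_gap: int = 5_000,
    expressed_fraction: float = 0.7,
    seed: int = 0,
    max_len: Optional[int] = None,
    antisense_promoter_fraction: float = 0.0,
) -> list[GeneModel]:
    """Place non-overlapping genes with pairwise gaps >= ``min_gap``.

    Defaults (min_len=5001, min_gap=5000) make every generated gene pass the
    downstream analysis-gene filter (length > 5 kb, inter-gene distance
    >= 5 kb).  Genes are apportioned to chromosomes by length; strands and
    expression status are random.  Raises :class:`CapacityError` naming the
    achievable count when the packing is infeasible.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if n_genes == 0:
        return []
    if max_len is None:
        max_len = 2 * min_len
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")

    rng = np.random.default_rng(seed)
    names = list(genome.chromosomes)
    lengths = [len(genome.chromosomes[c]) for c in names]
    unit = min_len + min_gap
    # gaps are only needed *between* genes, so each chromosome of length L
    # holds floor((L + min_gap) / unit) genes at minimum size
    capacity = sum((L + min_gap) // unit for L in lengths)
    if n_genes > capacity:
        raise CapacityError(
            f"cannot place {n_genes} genes of >= {min_len} bp with {min_gap} bp gaps; "
            f"achievable count is {capacity}"
        )

    per_chrom = _apportion(n_genes, lengths)
    # rebalance any chromosome past its own capacity
    for _ in range(len(names)):
        for i, c in enumerate(names):
            cap_i = (lengths[i] + min_gap) // unit
            if per_chrom[i] > cap_i:
                excess = per_chrom[i] - cap_i
                per_chrom[i] = cap_i
                for j in range(len(names)):
                    cap_j = (lengths[j] + min_gap) // unit
                    take = min(excess, cap_j - per_chrom[j])
                    per_chrom[j] += take
                    excess -= take
                    if excess == 0:
                        break

    genes: list[GeneModel] = []
    idx = 0
    for chrom, chrom_len, m in zip(names, lengths, per_chrom):
        if m == 0:
            continue
        # cap per-gene extra length so the packing always fits
        budget = chrom_len - m * min_len - (m - 1) * min_gap
        head = min(max_len - min_len, budget // m)
        gene_lens = min_len + rng.integers(0, head + 1, size=m)
        slack = chrom_len - int(gene_lens.sum()) - (m - 1) * min_gap
        extra_gaps = rng.multinomial(slack, [1.0 / (m + 1)] * (m + 1))
        pos = int(extra_gaps[0])
        for j in range(m):
            start = pos
            end = start + int(gene_lens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            expressed = bool(rng.random() < expressed_fraction)
            ap: Optional[tuple[int, int]] = None
            if expressed and rng.random() < antisense_promoter_fraction:
                if strand == "+" and start - 1_200 >= 0:
                    ap = (start - 1_200, start - 200)
                elif strand == "-" and end + 1_200 <= chrom_len:
                    ap = (end + 200, end + 1_200)
            idx += 1
            genes.append(
                GeneModel(
                    id=f"gene_{idx:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    expressed=expressed,
                    antisense_promoter=ap,
                )
            )
            pos = end + min_gap + int(extra_gaps[j + 1])
    return genes


def generate_chromatin_tracks(
    genome: SyntheticGenome,
    genes: Sequence[GeneModel],
    seed: int = 0,
    mean_tile_bp: int = 2_000,
    promoter_peak_halfwidth: int = 150,
    n_intergenic_peaks: Optional[int] = None,
) -> tuple[ChromatinSegmentation, DNasePeakSet]:
    """Tile the genome with 15 chromatin states and place DNase peaks.

    The segmentation partitions each chromosome exactly once.  Tiles
    containing the TSS of an expressed gene are relabeled
    ``Active_Promoter``; tiles fully inside expressed gene bodies get
    transcription-associated labels.  DNase peaks are placed at expressed
    promoters (genic) and at random gene-free positions (intergenic).
    """
    for g in genes:
        if g.chrom not in genome.chromosomes or g.end > len(genome.chromosomes[g.chrom]):
            raise ValueError(f"gene {g.id} does not fit the supplied genome")

    rng = np.random.default_rng(seed)
    tile_units = max(1, mean_tile_bp // 200)
    intervals: list[tuple[str, int, int, str]] = []
    for chrom, seq in genome.chromosomes.items():
        L = len(seq)
        pos = 0
        while pos < L:
            tile = 200 * int(rng.integers(1, 2 * tile_units + 1))
            end = min(pos + tile, L)
            label = CHROMATIN_STATES[int(rng.integers(len(CHROMATIN_STATES)))]
            intervals.append((chrom, pos, end, label))
            pos = end

    # relabel promoter / transcribed tiles for expressed genes
    by_chrom: dict[str, list[int]] = {}
    for i, (chrom, start, end, _) in enumerate(intervals):
        by_chrom.setdefault(chrom, []).append(i)
    txn_labels = ("Txn_Transition", "Txn_Elongation", "Weak_Txn")
    for g in genes:
        if not g.expressed:
            continue
        for i in by_chrom.get(g.chrom, []):
            chrom, start, end, label = intervals[i]
            if start <= g.tss < end:
                intervals[i] = (chrom, start, end, "Active_Promoter")
            elif g.start <= start and end <= g.end:
                new = txn_labels[int(rng.integers(len(txn_labels)))]
                intervals[i] = (chrom, start, end, new)

    segmentation = ChromatinSegmentation(intervals=intervals, states=CHROMATIN_STATES)

    peaks: list[DNasePeak] = []
    for g in genes:
        if not g.expressed:
            continue
        chrom_len = len(genome.chromosomes[g.chrom])
        start = max(0, g.tss - promoter_peak_halfwidth)
        end = min(chrom_len, g.tss + promoter_peak_halfwidth)
        if end > start:
            peaks.append(DNasePeak(g.chrom, start, end, g.tss - start))

    if n_intergenic_peaks is None:
        n_intergenic_peaks = max(len(peaks), 8)
    names = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in names], dtype=float)
    gene_ivs: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        gene_ivs.setdefault(g.chrom, []).append((g.start, g.end))
    width = 300
    placed = 0
    attempts = 0
    while placed < n_intergenic_peaks and attempts < 50 * n_intergenic_peaks:
        attempts += 1
        ci = int(rng.choice(len(names), p=lengths / lengths.sum()))
        chrom = names[ci]
        L = int(lengths[ci])
        if L <= width:
            continue
        start = int(rng.integers(0, L - width))
        end = start + width
        if any(start < ge and gs < end for gs, ge in gene_ivs.get(chrom, [])):
            continue
        peaks.append(DNasePeak(chrom, start, end, width // 2))
        placed += 1
    return segmentation, DNasePeakSet(peaks)


def _pmf_arrays(pmf) -> tuple[np.ndarray, np.ndarray]:
    keys = np.array(sorted(pmf), dtype=np.int64)
    probs = np.array([pmf[int(k)] for k in keys], dtype=float)
    return keys, probs / probs.sum()


def simulate_excision_reads(
    genome: SyntheticGenome,
    genes: Sequence[GeneModel],
    segmentation: Optional[ChromatinSegmentation],
    config: SimulationConfig,
    timepoint_label: str = "t0",
) -> tuple[list[str], list[ExcisionTruthRecord]]:
    """Draw excision products from the EdU lesion landscape.

    Each thymidine (T on the plus strand, A on the plus strand for the minus
    strand) is flagged as EdU with probability ``p_edu``.  Flagged sites are
    sampled with weight alpha (transcribed strand of an expressed gene body)
    times the chromatin-state multiplier; sites are drawn with replacement
    because the sequenced pool aggregates lesions over a large cell
    population, so a genomic coordinate can yield many independent excision
    events.  For each read a 5'-offset ``d`` and 3'-tail ``k`` are drawn and
    the excised-strand sequence of length d + k is emitted with the lesion
    (a T) at 1-based position d.

    Returns the read sequences (index-aligned with their truth records).
    """
    config.validate()
    if config.p_edu == 0:
        raise NoEligibleSitesError("p_edu is 0: no eligible lesion sites")

    rng = np.random.default_rng(config.seed)
    alpha = config.tcr_factor
    decay = config.tcr_five_prime_decay

    chrom_names: list[str] = []
    site_chrom: list[np.ndarray] = []
    site_pos: list[np.ndarray] = []
    site_strand: list[np.ndarray] = []
    site_weight: list[np.ndarray] = []

    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    for ci, (chrom, seq) in enumerate(genome.chromosomes.items()):
        chrom_names.append(chrom)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        L = len(arr)
        mult = np.ones(L, dtype=float)
        if segmentation is not None:
            for c, s, e, label in segmentation.intervals:
                if c != chrom:
                    continue
                m = config.state_multipliers.get(label, 1.0)
                if m != 1.0:
                    mult[s:e] = m
        for strand, base in (("+", ord("T")), ("-", ord("A"))):
            pos = np.nonzero(arr == base)[0]
            pos = pos[(pos >= _EDGE_MARGIN) & (pos < L - _EDGE_MARGIN)]
            keep = rng.random(pos.size) < config.p_edu
            pos = pos[keep]
            if pos.size == 0:
                continue
            w = mult[pos].copy()
            for g in genes_by_chrom.get(chrom, []):
                if not g.expressed:
                    continue
                if strand == g.transcribed_strand:
                    m = (pos >= g.start) & (pos < g.end)
                    if m.any():
                        if decay > 0:
                            if g.strand == "+":
                                frac = (pos[m] - g.start) / g.length
                            else:
                                frac = (g.end - 1 - pos[m]) / g.length
                            w[m] *= 1.0 + (alpha - 1.0) * np.exp(-decay * frac)
                        else:
                            w[m] *= alpha
                if g.antisense_promoter is not None and strand == g.strand:
                    s, e = g.antisense_promoter
                    m = (pos >= s) & (pos < e)
                    w[m] *= alpha
            site_chrom.append(np.full(pos.size, ci, dtype=np.int32))
            site_pos.append(pos.astype(np.int64))
            site_strand.append(np.full(pos.size, 0 if strand == "+" else 1, dtype=np.int8))
            site_weight.append(w)

    if not site_pos or sum(p.size for p in site_pos) == 0:
        raise NoEligibleSitesError("no eligible lesion sites in the genome")

    all_chrom = np.concatenate(site_chrom)
    all_pos = np.concatenate(site_pos)
    all_strand = np.concatenate(site_strand)
    all_weight = np.concatenate(site_weight)
    prob = all_weight / all_weight.sum()

    n = config.n_reads
    picks = rng.choice(all_pos.size, size=n, replace=True, p=prob)
    d_keys, d_probs = _pmf_arrays(config.five_prime_offset_pmf)
    k_keys, k_probs = _pmf_arrays(config.three_prime_tail_pmf)
    ds = d_keys[rng.choice(d_keys.size, size=n, p=d_probs)]
    ks = k_keys[rng.choice(k_keys.size, size=n, p=k_probs)]

    reads: list[str] = []
    truth: list[ExcisionTruthRecord] = []
    for i in range(n):
        j = int(picks[i])
        chrom = chrom_names[int(all_chrom[j])]
        g = int(all_pos[j])
        d = int(ds[i])
        k = int(ks[i])
        if all_strand[j] == 0:
            strand = "+"
            start, end = g - d + 1, g + k + 1
            seq = genome.chromosomes[chrom][start:end]
        else:
            strand = "-"
            start, end = g - k, g + d
            seq = reverse_complement(genome.chromosomes[chrom][start:end])
        rid = f"r{i:06d}"
        reads.append(seq)
        truth.append(
            ExcisionTruthRecord(
                read_id=rid,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                lesion_pos=g,
                offset=d,
            )
        )
    return reads, truth


def add_library_artifacts(
    reads: Sequence[str],
    config: SimulationConfig,
    read_ids: Optional[Sequence[str]] = None,
    min_overlap: int = 3,
) -> list[RawRead]:
    """Apply library construction: 3' adapter read-through, PCR duplication.

    The 5' adapter is consumed by the sequencing primer and never appears in
    the read; the full 3' adapter is appended (short inserts are read
    through).  Each read is duplicated with probability ``duplication_rate``
    (duplicate ids get a ``_dupN`` suffix); output order is shuffled
    deterministically under the configuration seed.
    """
    if len(reads) == 0:
        raise ValueError("reads must be non-empty")
    if len(config.adapter3) < min_overlap:
        warnings.warn(
            f"3' adapter ({len(config.adapter3)} nt) is shorter than the trimming "
            f"min_overlap ({min_overlap}); trimming will not recognize it",
            stacklevel=2,
        )
    if read_ids is None:
        read_ids = [f"r{i:06d}" for i in range(len(reads))]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x11B]))
    out: list[RawRead] = []
    for rid, seq in zip(read_ids, reads):
        full = seq + config.adapter3
        qual = "I" * len(full)
        out.append(RawRead(rid, full, qual))
        if rng.random() < config.duplication_rate:
            out.append(RawRead(f"{rid}_dup1", full, qual))
    order = rng.permutation(len(out))
    return [out[i] for i in order]


@dataclass
class FixtureBundle:
    """All components of one simulated experiment."""

    genome: SyntheticGenome
    genes: list[GeneModel]
    segmentation: ChromatinSegmentation
    peaks: DNasePeakSet
    reads: list[RawRead]
    truth: list[ExcisionTruthRecord]
    config: SimulationConfig
    timepoint: str = "t0"


def write_fixture_bundle(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write genome FASTA (+ .fai), genes BED6, states BED4, peaks BED,
    reads FASTQ, truth TSV and a run manifest.  Re-running with the same
    seed reproduces byte-identical files (no timestamps are written)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": _io.write_fasta(bundle.genome, outdir / "genome.fa"),
        "genes": _io.write_genes_bed(bundle.genes, outdir / "genes.bed"),
        "states": _io.write_states_bed(bundle.segmentation, outdir / "states.bed"),
        "peaks": _io.write_peaks_bed(bundle.peaks, outdir / "peaks.bed"),
        "reads": _io.write_fastq(bundle.reads, outdir / "reads.fastq"),
        "truth": _io.write_truth_tsv(bundle.truth, outdir / "truth.tsv"),
    }
    cfg = bundle.config
    manifest = {
        "seed": cfg.seed,
        "timepoint": bundle.timepoint,
        "n_reads": cfg.n_reads,
        "p_edu": cfg.p_edu,
        "tcr_factor": cfg.tcr_factor,
        "tcr_five_prime_decay": cfg.tcr_five_prime_decay,
        "duplication_rate": cfg.duplication_rate,
        "adapter3": cfg.adapter3,
        "adapter5": cfg.adapter5,
        "five_prime_offset_pmf": {int(k): float(v) for k, v in cfg.five_prime_offset_pmf.items()},
        "three_prime_tail_pmf": {int(k): float(v) for k, v in cfg.three_prime_tail_pmf.items()},
        "state_multipliers": {k: float(v) for k, v in cfg.state_multipliers.items()},
    }
    manifest_path = outdir / "run_manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    paths["manifest"] = manifest_path
    return paths
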