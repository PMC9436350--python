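"""Raw reads to uniquely aligned, strand-aware excision fragments.

Stages mirror a standard XR-seq preprocessing chain: 3'-adapter trimming,
exact-sequence deduplication (before alignment), then unique alignment of
each read against both strands of the reference.  The built-in aligner is a
k-mer seeded exact matcher (0 mismatches by default) adequate for synthetic
genomes; externally produced BED6 can be consumed instead via
:func:`edu_xrseq.io.read_fragments_bed`.

Every stage reports counts into a :class:`PreprocessLedger`, and the ledger
balances exactly: input = kept + each discard reason at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .models import AlignedFragment, RawRead, SyntheticGenome, reverse_complement

MIN_FRAGMENT_LEN = 10
MAX_FRAGMENT_LEN = 50

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def trim_adapters(
    read: RawRead,
    adapter3: str,
    min_overlap: int = 3,
    max_mismatch_rate: float = 0.1,
) -> Optional[RawRead]:
    """Remove a 3'-adapter suffix; return None if the insert is too short.

    The longest suffix of the read matching a prefix of ``adapter3`` with at
    least ``min_overlap`` bases and a mismatch rate <= ``max_mismatch_rate``
    is removed.  Reads whose remaining insert is shorter than
    ``MIN_FRAGMENT_LEN`` are discarded (returned as None).
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq = read.sequence
    best_n = 0
    for n in range(min(len(seq), len(adapter3)), min_overlap - 1, -1):
        allowed = int(max_mismatch_rate * n)
        mism = 0
        tail = seq[len(seq) - n :]
        for a, b in zip(tail, adapter3):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            best_n = n
            break
    if best_n == 0:
        trimmed = read
    else:
        keep = len(seq) - best_n
        trimmed = RawRead(read.id, seq[:keep], read.quality[:keep])
    if len(trimmed) < MIN_FRAGMENT_LEN:
        return None
    return trimmed


def deduplicate(reads: Sequence[RawRead]) -> tuple[list[RawRead], int]:
    """Keep the first occurrence of each exact sequence (order preserved)."""
    seen: set[str] = set()
    unique: list[RawRead] = []
    dups = 0
    for r in reads:
        if r.sequence in seen:
            dups += 1
        else:
            seen.add(r.sequence)
            unique.append(r)
    return unique, dups


class GenomeIndex:
    """Sorted k-mer index over the plus strand of every chromosome.

    Queries search both the read and its reverse complement, so minus-strand
    hits are reported in plus coordinates with strand "-".
    """

    def __init__(self, genome: SyntheticGenome, k: int = 12):
        if k < 4 or k > 30:
            raise ValueError("k must lie in [4, 30]")
        self.genome = genome
        self.k = k
        self._chrom_names = list(genome.chromosomes)
        codes_parts = []
        chrom_parts = []
        pos_parts = []
        for ci, name in enumerate(self._chrom_names):
            seq = genome.chromosomes[name]
            v = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            n = len(seq) - k + 1
            if n <= 0:
                continue
            codes = np.zeros(n, dtype=np.int64)
            for i in range(k):
                codes = codes * 4 + v[i : i + n]
            codes_parts.append(codes)
            chrom_parts.append(np.full(n, ci, dtype=np.int32))
            pos_parts.append(np.arange(n, dtype=np.int64))
        codes = np.concatenate(codes_parts)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._chrom = np.concatenate(chrom_parts)[order]
        self._pos = np.concatenate(pos_parts)[order]

    def _encode(self, kmer: str) -> int:
        code = 0
        for c in kmer:
            v = _CODE[ord(c)]
            if v < 0:
                return -1
            code = code * 4 + int(v)
        return code

    def _seed_candidates(self, kmer: str):
        code = self._encode(kmer)
        if code < 0:
            return
        lo = int(np.searchsorted(self._codes, code, side="left"))
        hi = int(np.searchsorted(self._codes, code, side="right"))
        for i in range(lo, hi):
            yield self._chrom_names[int(self._chrom[i])], int(self._pos[i])

    def find_all(self, seq: str, max_mismatches: int = 0) -> list[tuple[str, int, str]]:
        """All genomic loci (chrom, start, strand) matching the read."""
        k = self.k
        hits: set[tuple[str, int, str]] = set()
        for strand in ("+", "-"):
            q = seq if strand == "+" else reverse_complement(seq)
            if len(q) < k:
                continue
            offsets = [0]
            if max_mismatches > 0:
                offsets = [j * k for j in range(max_mismatches + 1) if j * k + k <= len(q)]
            for off in offsets:
                for chrom, pos in self._seed_candidates(q[off : off + k]):
                    start = pos - off
                    ref = self.genome.chromosomes[chrom]
                    if start < 0 or start + len(q) > len(ref):
                        continue
                    window = ref[start : start + len(q)]
                    if max_mismatches == 0:
                        if window == q:
                            hits.add((chrom, start, strand))
                    else:
                        mism = sum(a != b for a, b in zip(window, q))
                        if mism <= max_mismatches:
                            hits.add((chrom, start, strand))
        return sorted(hits)


@dataclass
class AlignmentOutcome:
    status: str  # "unique" | "unmapped" | "multimapped" | "too-short"
    fragment: Optional[AlignedFragment] = None
    n_hits: int = 0


def align_unique(
    read: RawRead, index: GenomeIndex, max_mismatches: int = 0
) -> AlignmentOutcome:
    """Align a read; only a single genomic locus yields a fragment.

    Zero loci -> "unmapped"; two or more -> "multimapped" (excluded from all
    downstream counting); reads shorter than the seed length -> "too-short".
    """
    if len(read) < index.k:
        return AlignmentOutcome(status="too-short")
    hits = index.find_all(read.sequence, max_mismatches=max_mismatches)
    if len(hits) == 0:
        return AlignmentOutcome(status="unmapped")
    if len(hits) > 1:
        return AlignmentOutcome(status="multimapped", n_hits=len(hits))
    chrom, start, strand = hits[0]
    frag = AlignedFragment(
        chrom=chrom,
        start=start,
        end=start + len(read),
        strand=strand,
        read_id=read.id,
    )
    return AlignmentOutcome(status="unique", fragment=frag, n_hits=1)


def fragments_to_bed(fragments: Sequence[AlignedFragment]) -> list[str]:
    """BED6 lines (chrom, start, end, read_id, score=0, strand), sorted."""
    ordered = sorted(fragments, key=lambda f: (f.chrom, f.start, f.end, f.strand))
    return [
        f"{f.chrom}\t{f.start}\t{f.end}\t{f.read_id}\t0\t{f.strand}" for f in ordered
    ]


@dataclass
class PreprocessLedger:
    """Exact read accounting across the pipeline stages."""

    n_input: int = 0
    n_trimmed_kept: int = 0
    n_trim_discarded_short: int = 0
    n_trim_discarded_long: int = 0
    n_dedup_unique: int = 0
    n_duplicates: int = 0
    n_aligned: int = 0
    n_unmapped: int = 0
    n_multimapped: int = 0
    n_too_short: int = 0

    def check(self) -> None:
        assert self.n_input == (
            self.n_trimmed_kept + self.n_trim_discarded_short + self.n_trim_discarded_long
        ), "trim stage does not balance"
        assert self.n_trimmed_kept == self.n_dedup_unique + self.n_duplicates, (
            "dedup stage does not balance"
        )
        assert self.n_dedup_unique == (
            self.n_aligned + self.n_unmapped + self.n_multimapped + self.n_too_short
        ), "alignment stage does not balance"

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


@dataclass
class PreprocessResult:
    fragments: list[AlignedFragment]
    ledger: PreprocessLedger = field(default_factory=PreprocessLedger)


def run_preprocess(
    reads: Sequence[RawRead],
    genome: SyntheticGenome,
    adapter3: str,
    min_overlap: int = 3,
    max_mismatch_rate: float = 0.1,
    max_mismatches: int = 0,
    k: int = 12,
    index: Optional[GenomeIndex] = None,
) -> PreprocessResult:
    """Trim, deduplicate and align; returns fragments plus a balanced ledger."""
    ledger = PreprocessLedger(n_input=len(reads))
    trimmed: list[RawRead] = []
    for r in reads:
        t = trim_adapters(r, adapter3, min_overlap=min_overlap, max_mismatch_rate=max_mismatch_rate)
        if t is None:
            ledger.n_trim_discarded_short += 1
        elif len(t) > MAX_FRAGMENT_LEN:
            ledger.n_trim_discarded_long += 1
        else:
            trimmed.append(t)
    ledger.n_trimmed_kept = len(trimmed)

    unique, dups = deduplicate(trimmed)
    ledger.n_dedup_unique = len(unique)
    ledger.n_duplicates = dups

    if index is None:
        index = GenomeIndex(genome, k=k)
    fragments: list[AlignedFragment] = []
    for r in unique:
        out = align_unique(r, index, max_mismatches=max_mismatches)
        if out.status == "unique":
            fragments.append(out.fragment)
            ledger.n_aligned += 1
        elif out.status == "unmapped":
            ledger.n_unmapped += 1
        elif out.status == "multimapped":
            ledger.n_multimapped += 1
        else:
            ledger.n_too_short += 1
    ledger.check()
    return PreprocessResult(fragments=fragments, ledger=ledger)
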