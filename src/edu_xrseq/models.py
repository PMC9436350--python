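"""Core data structures shared across the EdU XR-seq pipeline.

All genomic intervals are 0-based half-open (BED convention) on the plus
(reference) strand; strand is "+" or "-".  Lesion offsets along an excised
oligomer are 1-based from the product's 5' end, so "T at 19" means the 19th
base of the read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class CapacityError(ValueError):
    """Requested placement does not fit in the genome."""


class NoEligibleSitesError(RuntimeError):
    """No lesion sites are available under the simulation configuration."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticGenome:
    """An in-memory reference genome: ordered chromosome name -> sequence."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            if not set(seq) <= VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise ValueError(f"chromosome {name!r} contains non-ACGT characters {bad}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Strand-aware slice: the 5'->3' sequence of the requested strand."""
        seq = self.chromosomes[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(f"interval {chrom}:{start}-{end} out of bounds")
        s = seq[start:end]
        return s if strand == "+" else reverse_complement(s)


@dataclass(frozen=True)
class GeneModel:
    """A transcription unit on the synthetic genome.

    The transcribed strand (TS) is the strand *opposite* ``strand`` (the
    template read by RNA polymerase II); the annotated strand is the
    nontranscribed strand (NTS).
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    expressed: bool = True
    antisense_promoter: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.start}-{self.end}")
        ap = self.antisense_promoter
        if ap is not None:
            s, e = ap
            if not s < e:
                raise ValueError("antisense promoter interval is empty")
            # must lie strictly upstream of the TSS
            if self.strand == "+" and e > self.start:
                raise ValueError("antisense promoter must end before the TSS")
            if self.strand == "-" and s < self.end:
                raise ValueError("antisense promoter must start after the TSS")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Coordinate of the transcription start site (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def transcribed_strand(self) -> str:
        return "-" if self.strand == "+" else "+"


@dataclass
class ChromatinSegmentation:
    """Non-overlapping labeled intervals covering (parts of) the genome."""

    intervals: list[tuple[str, int, int, str]]
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        vocab = set(self.states)
        prev: dict[str, int] = {}
        for chrom, start, end, label in self.intervals:
            if label not in vocab:
                raise ValueError(f"state label {label!r} not in vocabulary")
            if not start < end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            if chrom in prev and start < prev[chrom]:
                raise ValueError(
                    f"segmentation intervals overlap or are unsorted at {chrom}:{start}"
                )
            prev[chrom] = end
        self._index: dict[str, tuple[list[int], list[int], list[str]]] = {}
        for chrom, start, end, label in self.intervals:
            starts, ends, labels = self._index.setdefault(chrom, ([], [], []))
            starts.append(start)
            ends.append(end)
            labels.append(label)

    def state_at(self, chrom: str, pos: int) -> Optional[str]:
        entry = self._index.get(chrom)
        if entry is None:
            return None
        starts, ends, labels = entry
        import bisect

        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return labels[i]
        return None

    def total_bp_by_state(self) -> dict[str, int]:
        out = {s: 0 for s in self.states}
        for _, start, end, label in self.intervals:
            out[label] += end - start
        return out

    def covered_bp(self) -> int:
        return sum(e - s for _, s, e, _ in self.intervals)


@dataclass(frozen=True)
class DNasePeak:
    chrom: str
    start: int
    end: int
    summit_offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.summit_offset < self.end - self.start):
            raise ValueError("summit offset outside peak interval")

    @property
    def summit(self) -> int:
        return self.start + self.summit_offset


@dataclass
class DNasePeakSet:
    peaks: list[DNasePeak] = field(default_factory=list)

    def __iter__(self) -> Iterator[DNasePeak]:
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


# Excision geometry defaults.  The 5' incision places the lesion d nucleotides
# from the product's 5' end (1-based); the 3' incision leaves a k-nucleotide
# tail after the lesion, so the product length is L = d + k.  The defaults put
# the lesion at positions 19-21 (peak 20) and span lengths 22-30 (mode 26).
DEFAULT_FIVE_PRIME_OFFSET_PMF: dict[int, float] = {19: 0.25, 20: 0.50, 21: 0.25}
DEFAULT_THREE_PRIME_TAIL_PMF: dict[int, float] = {
    3: 0.04,
    4: 0.08,
    5: 0.17,
    6: 0.25,
    7: 0.20,
    8: 0.14,
    9: 0.12,
}

# TruSeq small-RNA-style adapters: the 5' adapter is consumed by the
# sequencing primer and never appears in the read; the 3' adapter is read
# through and must be trimmed.
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

# Rate multipliers emulating higher repair over accessible chromatin.
DEFAULT_STATE_MULTIPLIERS: dict[str, float] = {
    "Active_Promoter": 3.0,
    "Weak_Promoter": 2.0,
    "Strong_Enhancer": 2.0,
    "Txn_Transition": 1.5,
    "Heterochrom_LowSignal": 0.5,
}


@dataclass
class SimulationConfig:
    """Parameters of the excision-read simulator.

    p_edu
        Per-thymidine probability that EdU was incorporated in place of T
        (both strands, independently).
    five_prime_offset_pmf
        Distribution of the lesion's 1-based offset d from the product 5' end.
    three_prime_tail_pmf
        Distribution of the tail length k after the lesion; L = d + k.
    tcr_factor
        Multiplicative excision-rate excess alpha for lesions on the
        transcribed strand inside expressed gene bodies (per time point).
    tcr_five_prime_decay
        Optional exponential decay of the TCR excess along the gene body
        (0 = uniform); effective alpha at fractional position x from the TSS
        is 1 + (alpha - 1) * exp(-decay * x).
    state_multipliers
        Chromatin-state label -> excision-rate multiplier (missing labels
        default to 1.0).
    """

    p_edu: float = 0.2
    five_prime_offset_pmf: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_FIVE_PRIME_OFFSET_PMF)
    )
    three_prime_tail_pmf: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_THREE_PRIME_TAIL_PMF)
    )
    tcr_factor: float = 2.5
    tcr_five_prime_decay: float = 0.0
    state_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_MULTIPLIERS)
    )
    n_reads: int = 50_000
    duplication_rate: float = 0.1
    adapter5: str = DEFAULT_ADAPTER5
    adapter3: str = DEFAULT_ADAPTER3
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_edu <= 1.0:
            raise ValueError("p_edu must lie in [0, 1]")
        for name, pmf in (
            ("five_prime_offset_pmf", self.five_prime_offset_pmf),
            ("three_prime_tail_pmf", self.three_prime_tail_pmf),
        ):
            if not pmf:
                raise ValueError(f"{name} is empty")
            total = sum(pmf.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} sums to {total}, not 1")
            if any(p < 0 for p in pmf.values()):
                raise ValueError(f"{name} has negative mass")
        lengths = {
            d + k
            for d, pd in self.five_prime_offset_pmf.items()
            if pd > 0
            for k, pk in self.three_prime_tail_pmf.items()
            if pk > 0
        }
        if lengths and not (20 <= min(lengths) and max(lengths) <= 35):
            raise ValueError(f"product length support {sorted(lengths)} outside [20, 35]")
        if self.tcr_factor <= 0:
            raise ValueError("tcr_factor must be positive")
        if any(m <= 0 for m in self.state_multipliers.values()):
            raise ValueError("state multipliers must be positive")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if not 0.0 <= self.duplication_rate <= 1.0:
            raise ValueError("duplication_rate must lie in [0, 1]")

    def length_support(self) -> list[int]:
        """Achievable product lengths L = d + k with positive mass."""
        return sorted(
            {
                d + k
                for d, pd in self.five_prime_offset_pmf.items()
                if pd > 0
                for k, pk in self.three_prime_tail_pmf.items()
                if pk > 0
            }
        )

    def length_pmf(self) -> dict[int, float]:
        """Convolution of the (d, k) distributions: P(L)."""
        out: dict[int, float] = {}
        for d, pd in self.five_prime_offset_pmf.items():
            for k, pk in self.three_prime_tail_pmf.items():
                out[d + k] = out.get(d + k, 0.0) + pd * pk
        return out


@dataclass(frozen=True)
class ExcisionTruthRecord:
    """Ground-truth origin of one simulated excision product."""

    read_id: str
    chrom: str
    strand: str
    start: int
    end: int
    lesion_pos: int
    offset: int  # 1-based position of the lesion from the product 5' end

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError("empty product interval")
        if not self.start <= self.lesion_pos < self.end:
            raise ValueError("lesion outside product interval")


@dataclass(frozen=True)
class RawRead:
    """One FASTQ record (Phred-33 qualities)."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedFragment:
    """A uniquely mapped excision product in reference (+) coordinates.

    ``strand`` is the strand whose 5'->3' sequence equals the read.
    """

    chrom: str
    start: int
    end: int
    strand: str
    read_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError("empty fragment interval")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sequence(self, genome: SyntheticGenome) -> str:
        """The excised-strand sequence 5'->3' (the read, for exact alignments)."""
        return genome.fetch(self.chrom, self.start, self.end, self.strand)
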