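"""Excision-product length and base-composition profiles.

The diagnostic fingerprint of excision products is a narrow length
distribution (mode 26 nt) together with a thymine enrichment around
position 20 from the 5' end — thymidines being the potential sites of EdU
substitution.  The signature read filter keeps only 26-mers with T at
position 19 and 27-mers with T at position 20.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .models import AlignedFragment, SyntheticGenome

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: length -> required 1-based T position (the lesion signature)
DEFAULT_SIGNATURE_RULES: dict[int, int] = {26: 19, 27: 20}


@dataclass
class LengthHistogram:
    counts: dict[int, int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("histogram counts do not sum to total")


@dataclass
class BaseCompositionMatrix:
    """Per-position base frequencies of fixed-length excised-strand reads.

    ``freqs[p - 1, _BASE_INDEX[b]]`` is the frequency of base ``b`` at
    1-based position ``p``.  ``empty`` flags the no-fragment case.
    """

    length: int
    freqs: np.ndarray
    n_fragments: int

    @property
    def empty(self) -> bool:
        return self.n_fragments == 0

    def frequency(self, position: int, base: str) -> float:
        """Frequency of ``base`` at 1-based ``position``."""
        return float(self.freqs[position - 1, _BASE_INDEX[base]])

    def argmax_position(self, base: str) -> int:
        """1-based position where ``base`` is most frequent."""
        if self.empty:
            raise ValueError("composition matrix is empty")
        return int(np.argmax(self.freqs[:, _BASE_INDEX[base]])) + 1


def length_histogram(
    fragments: Sequence[AlignedFragment],
    length_range: tuple[int, int] | None = None,
) -> LengthHistogram:
    """Count fragments by length; empty-support lengths only if a range is given."""
    counts: Counter[int] = Counter(f.length for f in fragments)
    if length_range is not None:
        lo, hi = length_range
        for L in range(lo, hi + 1):
            counts.setdefault(L, 0)
    return LengthHistogram(counts=dict(counts), total=len(fragments))


def positional_base_composition(
    fragments: Sequence[AlignedFragment], genome: SyntheticGenome, length: int
) -> BaseCompositionMatrix:
    """Tally bases per 1-based position of length-``length`` fragments.

    Sequences are taken 5'->3' along the excised strand (reverse complement
    of the plus-strand slice for minus-strand fragments).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    counts = np.zeros((length, 4), dtype=np.int64)
    n = 0
    for f in fragments:
        if f.length != length:
            continue
        seq = f.sequence(genome)
        for p, b in enumerate(seq):
            counts[p, _BASE_INDEX[b]] += 1
        n += 1
    freqs = counts / n if n else np.zeros((length, 4))
    return BaseCompositionMatrix(length=length, freqs=freqs, n_fragments=n)


@dataclass
class FilterStats:
    kept: int = 0
    removed_wrong_length: int = 0
    removed_no_signature_t: int = 0
    rules: Mapping[int, int] = field(default_factory=dict)


def damage_signature_filter(
    fragments: Sequence[AlignedFragment],
    genome: SyntheticGenome,
    rules: Mapping[int, int] | None = None,
) -> tuple[list[AlignedFragment], FilterStats]:
    """Keep fragments carrying the lesion signature.

    Default rule: length 26 with T at 1-based position 19, or length 27 with
    T at position 20; everything else is removed with a counted reason.
    Idempotent: filtering twice equals filtering once.
    """
    if rules is None:
        rules = DEFAULT_SIGNATURE_RULES
    stats = FilterStats(rules=dict(rules))
    kept: list[AlignedFragment] = []
    for f in fragments:
        pos = rules.get(f.length)
        if pos is None:
            stats.removed_wrong_length += 1
            continue
        seq = f.sequence(genome)
        if seq[pos - 1] == "T":
            kept.append(f)
            stats.kept += 1
        else:
            stats.removed_no_signature_t += 1
    return kept, stats


def modal_length(hist: LengthHistogram) -> int:
    """Length with the maximal count; ties break toward the smaller length."""
    if hist.total == 0:
        raise ValueError("modal_length of an empty histogram is undefined")
    return min(
        (L for L, c in hist.counts.items() if c == max(hist.counts.values())),
    )
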