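"""Repair in chromatin context: state enrichment and DNase-peak profiles.

Fragment counts over a (non-overlapping) chromatin-state segmentation are
normalized per million mapped reads and per kilobase of interval length,
so densities are comparable across states of different total extent and
across libraries of different depth.  Aggregate profiles around DNase
hypersensitivity peak summits are computed separately for genic and
intergenic peaks (a peak is genic when its summit lies inside a gene).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import (
    AlignedFragment,
    ChromatinSegmentation,
    DNasePeak,
    DNasePeakSet,
    GeneModel,
)


@dataclass
class StateEnrichmentTable:
    """Per-state read counts, interval bp and normalized density."""

    table: pd.DataFrame  # index: state; columns: count, interval_bp, density
    n_assigned: int
    n_outside: int
    total_mapped: int

    def density(self, state: str) -> float:
        return float(self.table.loc[state, "density"])

    def count(self, state: str) -> int:
        return int(self.table.loc[state, "count"])


def state_enrichment(
    fragments: Sequence[AlignedFragment],
    segmentation: ChromatinSegmentation,
    total_mapped: Optional[int] = None,
) -> StateEnrichmentTable:
    """Assign fragments (midpoint rule) to states and normalize densities.

    density = count / (total_mapped / 1e6) / (state_bp / 1000).  Fragments
    whose midpoint is not covered by the segmentation are excluded and
    counted in ``n_outside``.  The segmentation type itself rejects
    overlapping intervals, so counting is well defined.
    """
    if total_mapped is None:
        total_mapped = len(fragments)
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    counts = {s: 0 for s in segmentation.states}
    outside = 0
    for f in fragments:
        state = segmentation.state_at(f.chrom, f.midpoint)
        if state is None:
            outside += 1
        else:
            counts[state] += 1
    bp = segmentation.total_bp_by_state()
    rows = []
    for state in segmentation.states:
        c = counts[state]
        b = bp[state]
        dens = c / (total_mapped / 1e6) / (b / 1_000.0) if b > 0 else np.nan
        rows.append({"state": state, "count": c, "interval_bp": b, "density": dens})
    table = pd.DataFrame(rows).set_index("state")
    return StateEnrichmentTable(
        table=table,
        n_assigned=int(table["count"].sum()),
        n_outside=outside,
        total_mapped=total_mapped,
    )


def split_peaks_genic_intergenic(
    peaks: Union[DNasePeakSet, Sequence[DNasePeak]],
    genes: Sequence[GeneModel],
) -> tuple[list[DNasePeak], list[DNasePeak]]:
    """Partition peaks: genic iff the summit lies within any gene interval
    (half-open, so a summit at gene.start is genic and at gene.end is not)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for ivs in by_chrom.values():
        ivs.sort()
    genic: list[DNasePeak] = []
    intergenic: list[DNasePeak] = []
    for p in peaks:
        ivs = by_chrom.get(p.chrom, [])
        starts = [s for s, _ in ivs]
        i = bisect.bisect_right(starts, p.summit) - 1
        if i >= 0 and p.summit < ivs[i][1]:
            genic.append(p)
        else:
            intergenic.append(p)
    return genic, intergenic


@dataclass
class PeakProfile:
    """Mean normalized repair density around peak summits."""

    half_width: int
    n_bins: int
    density: np.ndarray
    counts: np.ndarray
    n_peaks: int
    total_mapped: int
    peak_class: Optional[str] = None

    @property
    def bin_width(self) -> float:
        return 2.0 * self.half_width / self.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        """Signed distance (bp) of each bin center from the summit."""
        edges = np.linspace(-self.half_width, self.half_width, self.n_bins + 1)
        return (edges[:-1] + edges[1:]) / 2.0

    @property
    def center_bin(self) -> int:
        return self.n_bins // 2


def peak_metaprofile(
    fragments: Sequence[AlignedFragment],
    peaks: Union[DNasePeakSet, Sequence[DNasePeak]],
    total_mapped: Optional[int] = None,
    half_width: int = 2_000,
    n_bins: int = 81,
    peak_class: Optional[str] = None,
) -> PeakProfile:
    """Bin fragments by signed midpoint-to-summit distance, averaged over peaks.

    ``n_bins`` must be odd so the center bin sits on the summit.  Densities
    use the state-enrichment normalization with each bin's total bp summed
    over peaks.
    """
    peak_list = list(peaks)
    if not peak_list:
        raise ValueError("peaks must be non-empty")
    if n_bins % 2 == 0:
        raise ValueError("n_bins must be odd (center bin on the summit)")
    if total_mapped is None:
        total_mapped = len(fragments)
    width = 2.0 * half_width / n_bins

    mids: dict[str, np.ndarray] = {}
    for f in fragments:
        mids.setdefault(f.chrom, []).append(f.midpoint)  # type: ignore[arg-type]
    mids = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in mids.items()}

    counts = np.zeros(n_bins, dtype=np.int64)
    for p in peak_list:
        arr = mids.get(p.chrom)
        if arr is None:
            continue
        lo = int(np.searchsorted(arr, p.summit - half_width, side="left"))
        hi = int(np.searchsorted(arr, p.summit + half_width, side="right"))
        for m in arr[lo:hi]:
            dist = int(m) - p.summit
            b = int((dist + half_width) // width)
            if 0 <= b < n_bins:
                counts[b] += 1
    bin_bp = width * len(peak_list)
    if total_mapped > 0:
        density = counts / (total_mapped / 1e6) / (bin_bp / 1_000.0)
    else:
        density = np.zeros(n_bins)
    return PeakProfile(
        half_width=half_width,
        n_bins=n_bins,
        density=density,
        counts=counts,
        n_peaks=len(peak_list),
        total_mapped=total_mapped,
        peak_class=peak_class,
    )
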