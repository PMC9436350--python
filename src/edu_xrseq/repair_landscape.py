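"""Transcription-coupled repair quantification.

Excision fragments are assigned to the transcribed (TS) or nontranscribed
(NTS) strand of analysis genes: the TS is the template strand, i.e. the
strand opposite the gene's annotated strand, and a fragment belongs to a
gene when its midpoint falls inside the gene body.  Per-gene read densities
are expressed as RPKM (reads per kilobase of feature per million mapped
reads); browser-style strand tracks use a per-10-million variant.  Average
repair across genes is summarized on a "unit gene": bodies rescaled to a
common number of bins plus fixed 2-kb flanks in 100-bp bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import AlignedFragment, GeneModel


def select_analysis_genes(
    genes: Sequence[GeneModel], min_len: int = 5_000, min_gap: int = 5_000
) -> list[GeneModel]:
    """Keep genes longer than ``min_len`` bp that overlap no other gene and
    whose nearest neighbor on each side is at least ``min_gap`` bp away
    (chromosome ends satisfy the distance requirement)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    kept: list[GeneModel] = []
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.start, g.end))
        for i, g in enumerate(chrom_genes):
            if g.length <= min_len:
                continue
            ok = True
            for j, other in enumerate(chrom_genes):
                if i == j:
                    continue
                gap = max(other.start - g.end, g.start - other.end)
                if gap < min_gap:  # negative gap = overlap
                    ok = False
                    break
            if ok:
                kept.append(g)
    kept.sort(key=lambda g: (g.chrom, g.start))
    return kept


def assign_ts_nts(fragment: AlignedFragment, gene: GeneModel) -> str:
    """Classify a fragment as "TS", "NTS" or "outside" for one gene.

    Midpoint rule: the fragment belongs to the gene body when its midpoint
    lies in [start, end).  TS means the fragment strand differs from the
    gene's annotated strand (it maps to the template strand).
    """
    mid = fragment.midpoint
    if fragment.chrom != gene.chrom or not (gene.start <= mid < gene.end):
        return "outside"
    return "TS" if fragment.strand != gene.strand else "NTS"


def rpkm(count: int, feature_bp: int, total_mapped: int, per: float = 1e6) -> float:
    """Reads per kilobase of feature per ``per`` mapped reads."""
    if feature_bp <= 0:
        raise ValueError("feature_bp must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count / (feature_bp / 1_000.0) / (total_mapped / per)


@dataclass
class GeneRepairSummary:
    gene_id: str
    ts_count: int
    nts_count: int
    ts_rpkm: float
    nts_rpkm: float

    @property
    def ratio(self) -> float:
        """TS:NTS RPKM ratio; NaN when the NTS signal is zero."""
        if self.nts_rpkm == 0:
            return math.nan
        return self.ts_rpkm / self.nts_rpkm

    @property
    def ratio_defined(self) -> bool:
        return self.nts_rpkm > 0


def _midpoints_by_chrom(
    fragments: Sequence[AlignedFragment],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sorted midpoint and strand-code arrays per chromosome (0='+', 1='-')."""
    acc: dict[str, tuple[list[int], list[int]]] = {}
    for f in fragments:
        mids, strands = acc.setdefault(f.chrom, ([], []))
        mids.append(f.midpoint)
        strands.append(0 if f.strand == "+" else 1)
    out = {}
    for chrom, (mids, strands) in acc.items():
        m = np.asarray(mids, dtype=np.int64)
        s = np.asarray(strands, dtype=np.int8)
        order = np.argsort(m, kind="stable")
        out[chrom] = (m[order], s[order])
    return out


def gene_repair_summaries(
    fragments: Sequence[AlignedFragment],
    genes: Sequence[GeneModel],
    total_mapped: Optional[int] = None,
    per: float = 1e6,
) -> list[GeneRepairSummary]:
    """TS/NTS counts and RPKM per gene (midpoint assignment)."""
    if total_mapped is None:
        total_mapped = len(fragments)
    index = _midpoints_by_chrom(fragments)
    out = []
    for g in genes:
        ts = nts = 0
        entry = index.get(g.chrom)
        if entry is not None:
            mids, strands = entry
            lo = int(np.searchsorted(mids, g.start, side="left"))
            hi = int(np.searchsorted(mids, g.end, side="left"))
            gene_code = 0 if g.strand == "+" else 1
            in_body = strands[lo:hi]
            nts = int(np.sum(in_body == gene_code))
            ts = int(hi - lo) - nts
        out.append(
            GeneRepairSummary(
                gene_id=g.id,
                ts_count=ts,
                nts_count=nts,
                ts_rpkm=rpkm(ts, g.length, total_mapped, per) if total_mapped else 0.0,
                nts_rpkm=rpkm(nts, g.length, total_mapped, per) if total_mapped else 0.0,
            )
        )
    return out


@dataclass
class MetaProfile:
    """Unit-gene repair profile: upstream flank, scaled body, downstream flank.

    ``ts`` / ``nts`` are RPKM-normalized signals per bin; ``ts_counts`` /
    ``nts_counts`` the raw pooled counts; ``bin_bp`` the summed genomic width
    of each bin across genes (identical for the two strand classes).
    """

    ts: np.ndarray
    nts: np.ndarray
    ts_counts: np.ndarray
    nts_counts: np.ndarray
    bin_bp: np.ndarray
    n_upstream: int
    n_body: int
    n_downstream: int
    n_genes: int
    flank_bp: int
    flank_bin_bp: int
    total_mapped: int

    @property
    def n_bins(self) -> int:
        return self.n_upstream + self.n_body + self.n_downstream

    @property
    def body_slice(self) -> slice:
        return slice(self.n_upstream, self.n_upstream + self.n_body)

    def to_frame(self) -> pd.DataFrame:
        region = (
            ["upstream"] * self.n_upstream
            + ["body"] * self.n_body
            + ["downstream"] * self.n_downstream
        )
        return pd.DataFrame(
            {
                "bin": np.arange(self.n_bins),
                "region": region,
                "ts_rpkm": self.ts,
                "nts_rpkm": self.nts,
                "ts_count": self.ts_counts,
                "nts_count": self.nts_counts,
                "bin_bp": self.bin_bp,
            }
        )


def unit_gene_metaprofile(
    fragments: Sequence[AlignedFragment],
    genes: Sequence[GeneModel],
    flank_bp: int = 2_000,
    n_body_bins: int = 60,
    flank_bin_bp: int = 100,
    total_mapped: Optional[int] = None,
) -> MetaProfile:
    """Average strand-resolved repair over genes rescaled to a unit gene.

    Coordinates are oriented 5'->3' along each gene; the body is divided
    into ``n_body_bins`` equal fractions and each flank into fixed
    ``flank_bin_bp`` bins.  Fragments increment the bin containing their
    midpoint for their strand class (TS/NTS relative to the gene), and bins
    are normalized to RPKM using the bin's summed bp across genes.
    """
    if not genes:
        raise ValueError("empty gene set")
    if flank_bp % flank_bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of flank_bin_bp")
    if total_mapped is None:
        total_mapped = len(fragments)
    n_flank = flank_bp // flank_bin_bp
    n_bins = 2 * n_flank + n_body_bins
    ts_counts = np.zeros(n_bins, dtype=np.int64)
    nts_counts = np.zeros(n_bins, dtype=np.int64)
    bin_bp = np.zeros(n_bins, dtype=float)
    index = _midpoints_by_chrom(fragments)

    for g in genes:
        bin_bp[:n_flank] += flank_bin_bp
        bin_bp[n_flank : n_flank + n_body_bins] += g.length / n_body_bins
        bin_bp[n_flank + n_body_bins :] += flank_bin_bp
        entry = index.get(g.chrom)
        if entry is None:
            continue
        mids, strands = entry
        lo = int(np.searchsorted(mids, g.start - flank_bp, side="left"))
        hi = int(np.searchsorted(mids, g.end + flank_bp, side="left"))
        gene_code = 0 if g.strand == "+" else 1
        for m, s in zip(mids[lo:hi], strands[lo:hi]):
            rel = int(m) - g.start if g.strand == "+" else (g.end - 1) - int(m)
            if rel < -flank_bp or rel >= g.length + flank_bp:
                continue
            if rel < 0:
                b = (rel + flank_bp) // flank_bin_bp
            elif rel < g.length:
                b = n_flank + int(rel * n_body_bins / g.length)
            else:
                b = n_flank + n_body_bins + (rel - g.length) // flank_bin_bp
            if s == gene_code:
                nts_counts[b] += 1
            else:
                ts_counts[b] += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = (bin_bp / 1_000.0) * (total_mapped / 1e6) if total_mapped else None
    if total_mapped:
        ts = np.where(bin_bp > 0, ts_counts / denom, 0.0)
        nts = np.where(bin_bp > 0, nts_counts / denom, 0.0)
    else:
        ts = np.zeros(n_bins)
        nts = np.zeros(n_bins)
    return MetaProfile(
        ts=ts,
        nts=nts,
        ts_counts=ts_counts,
        nts_counts=nts_counts,
        bin_bp=bin_bp,
        n_upstream=n_flank,
        n_body=n_body_bins,
        n_downstream=n_flank,
        n_genes=len(genes),
        flank_bp=flank_bp,
        flank_bin_bp=flank_bin_bp,
        total_mapped=total_mapped,
    )


def ts_nts_ratio(
    obj: Union[MetaProfile, Sequence[GeneRepairSummary]],
    scope: str = "genome-wide",
) -> Union[float, np.ndarray, dict[str, float]]:
    """TS:NTS repair ratio.

    genome-wide: summed TS RPKM over gene-body bins (or pooled gene counts)
    divided by the NTS equivalent — flanks are excluded.  per-bin: ratio per
    metaprofile bin.  per-gene: gene id -> ratio.  Zero NTS signal yields
    NaN (the undefined-ratio flag).
    """
    if isinstance(obj, MetaProfile):
        if scope == "genome-wide":
            ts = float(obj.ts[obj.body_slice].sum())
            nts = float(obj.nts[obj.body_slice].sum())
            return ts / nts if nts > 0 else math.nan
        if scope == "per-bin":
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(obj.nts > 0, obj.ts / obj.nts, np.nan)
        raise ValueError(f"unknown scope {scope!r} for a MetaProfile")
    summaries = list(obj)
    if scope == "genome-wide":
        ts = sum(s.ts_count for s in summaries)
        nts = sum(s.nts_count for s in summaries)
        return ts / nts if nts > 0 else math.nan
    if scope == "per-gene":
        return {s.gene_id: s.ratio for s in summaries}
    raise ValueError(f"unknown scope {scope!r} for gene summaries")


def timecourse(
    samples: Mapping[str, Sequence[AlignedFragment]],
    genes: Sequence[GeneModel],
    total_mapped: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Genome-wide TS/NTS table, one row per time point.

    No monotonicity is assumed; empty samples are flagged with NaN ratios
    without affecting other rows.
    """
    if not samples:
        raise ValueError("at least one sample is required")
    body_bp = sum(g.length for g in genes)
    rows = []
    for label, frags in samples.items():
        n_total = (
            total_mapped[label] if total_mapped is not None else len(frags)
        )
        summaries = gene_repair_summaries(frags, genes, total_mapped=max(n_total, 1))
        ts = sum(s.ts_count for s in summaries)
        nts = sum(s.nts_count for s in summaries)
        if n_total > 0 and body_bp > 0:
            ts_r = rpkm(ts, body_bp, n_total)
            nts_r = rpkm(nts, body_bp, n_total)
        else:
            ts_r = nts_r = math.nan
        rows.append(
            {
                "timepoint": label,
                "total_mapped": n_total,
                "ts_rpkm": ts_r,
                "nts_rpkm": nts_r,
                "ratio": ts_r / nts_r if nts_r and nts_r > 0 else math.nan,
                "flagged_empty": n_total == 0,
            }
        )
    return pd.DataFrame(rows)


def export_strand_tracks(
    fragments: Sequence[AlignedFragment],
    chrom_lengths: Mapping[str, int],
    bin_bp: int = 50,
    total_mapped: Optional[int] = None,
    per: float = 1e7,
) -> dict[str, list[str]]:
    """Fixed-width per-strand coverage tracks in bedGraph syntax.

    Values are reads per kilobase per ``per`` (default 10 million) mapped
    reads; only nonzero bins are emitted.
    """
    if total_mapped is None:
        total_mapped = len(fragments)
    counts: dict[str, dict[tuple[str, int], int]] = {"+": {}, "-": {}}
    for f in fragments:
        b = f.midpoint // bin_bp
        key = (f.chrom, b)
        counts[f.strand][key] = counts[f.strand].get(key, 0) + 1
    tracks: dict[str, list[str]] = {}
    for strand in ("+", "-"):
        lines = []
        for (chrom, b), c in sorted(counts[strand].items()):
            start = b * bin_bp
            end = min(start + bin_bp, chrom_lengths[chrom])
            value = rpkm(c, end - start, total_mapped, per) if total_mapped else 0.0
            lines.append(f"{chrom}\t{start}\t{end}\t{value:.6g}")
        tracks[strand] = lines
    return tracks
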