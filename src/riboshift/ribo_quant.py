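"""Frameshifting efficiency from ribosome-profiling footprint densities.

A ribosome-protected fragment (RPF) marks the position of a translating
ribosome; after P-site assignment each footprint contributes one count at a
single transcript nucleotide.  For a dual-ORF frameshift gene the fraction of
ribosomes that shift into the +1 frame can be read off the footprint
densities: the number of RPFs in each region is normalised by the number of
codons in that region, and the +1-ORF density is divided by the 0-frame
density and multiplied by 100, giving a percentage frameshifting efficiency.

Two counting modes are provided.  ``region`` (default) sums every count
inside each region; ``frame`` restricts to counts falling on the region's own
reading frame, the stricter reading of "RPFs on each frame".  The two agree
exactly when footprints are perfectly frame-resolved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heptamer_scan import DualOrfGeneModel

logger = logging.getLogger(__name__)

#: Community-standard P-site offsets (5' read end -> P-site) by read length.
DEFAULT_PSITE_OFFSETS: dict[int, int] = {28: 12, 29: 12, 30: 12}


@dataclass
class RiboProfile:
    """Per-nucleotide P-site footprint counts over one transcript."""

    seq_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if np.any(self.counts < 0):
            raise ValueError("footprint counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class FsEstimate:
    """A density-ratio frameshifting-efficiency estimate.

    ``efficiency_pct = 100 * (rpf1/codons1) / (rpf0/codons0)``.  When the
    0-frame region holds no counts the ratio is undefined (``defined`` False,
    ``efficiency_pct`` NaN) — no signal is distinguished from no
    frameshifting.
    """

    seq_id: str
    efficiency_pct: float
    rpf0: float
    rpf1: float
    codons0: int
    codons1: int
    region0: tuple[int, int]
    region1: tuple[int, int]
    defined: bool = True


@dataclass
class AggregateSummary:
    """Boxplot-style summary of efficiencies across datasets.

    Quartiles use linear interpolation; whiskers extend to the most extreme
    values within 1.5 x IQR of the 25th/75th percentiles.
    """

    n_datasets: int
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    values: list[float]


def frame_composition(
    profile: RiboProfile, region: tuple[int, int], anchor: int
) -> tuple[float, float, float]:
    """Fractions of region counts supporting frames 0/1/2 relative to ``anchor``.

    An all-zero region returns (NaN, NaN, NaN).
    """
    lo, hi = region
    if not (0 <= lo <= hi <= len(profile)):
        raise ValueError(f"region {region} outside profile of length {len(profile)}")
    counts = profile.counts[lo:hi]
    phases = (np.arange(lo, hi) - anchor) % 3
    totals = np.array([counts[phases == f].sum() for f in range(3)], dtype=float)
    grand = totals.sum()
    if grand == 0:
        return (math.nan, math.nan, math.nan)
    return tuple(totals / grand)  # type: ignore[return-value]


def fs_regions(
    model: DualOrfGeneModel, trim_codons: int = 1, region0_end: str = "psite"
) -> tuple[tuple[int, int], tuple[int, int]]:
    """The two half-open nucleotide regions entering the density ratio.

    Region 0 covers the 0-frame ORF from the start codon to the heptamer
    P-site codon (``region0_end="stop"`` extends it to the 0-frame stop, for
    genes with long overlaps); region 1 covers the +1 ORF from the first +1
    codon clear of the 0-frame ORF to the +1 stop.  Both regions are shrunk by
    ``trim_codons`` codons at each end to keep initiation/termination peaks
    out of the densities.
    """
    if trim_codons < 0:
        raise ValueError("trim_codons must be >= 0")
    s = model.site.start
    t = 3 * trim_codons

    end0 = s + 3 if region0_end == "psite" else model.orf0_end
    if region0_end not in ("psite", "stop"):
        raise ValueError("region0_end must be 'psite' or 'stop'")
    r0 = (model.orf0_start + t, end0 - t)

    # first +1-frame codon at/after the end of the 0-frame ORF
    k = max(0, math.ceil((model.orf0_end - (s + 4)) / 3))
    r1 = (s + 4 + 3 * k + t, model.orf1_end - t)

    for name, (lo, hi) in (("region0", r0), ("region1", r1)):
        if hi - lo < 3:
            raise ValueError(f"{name} shorter than 1 codon after trimming: {lo, hi}")
    return r0, r1


def fs_efficiency(
    profile: RiboProfile,
    model: DualOrfGeneModel,
    trim_codons: int = 1,
    mode: str = "region",
    region0_end: str = "psite",
) -> FsEstimate:
    """Density-ratio frameshifting efficiency (percent) from a footprint profile."""
    if mode not in ("region", "frame"):
        raise ValueError("mode must be 'region' or 'frame'")
    if len(profile) < model.orf1_end:
        raise ValueError("profile does not cover the gene model")
    r0, r1 = fs_regions(model, trim_codons, region0_end)
    frame_anchor0 = model.orf0_start
    frame_anchor1 = model.site.start + 4
    rpf0 = _region_counts(profile, r0, frame_anchor0, mode)
    rpf1 = _region_counts(profile, r1, frame_anchor1, mode)
    codons0 = (r0[1] - r0[0]) // 3
    codons1 = (r1[1] - r1[0]) // 3
    if rpf0 == 0:
        logger.warning("%s: zero 0-frame counts; efficiency undefined", profile.seq_id)
        return FsEstimate(
            profile.seq_id, math.nan, rpf0, rpf1, codons0, codons1, r0, r1, defined=False
        )
    eff = 100.0 * (rpf1 / codons1) / (rpf0 / codons0)
    return FsEstimate(profile.seq_id, eff, rpf0, rpf1, codons0, codons1, r0, r1)


def _region_counts(
    profile: RiboProfile, region: tuple[int, int], anchor: int, mode: str
) -> float:
    lo, hi = region
    counts = profile.counts[lo:hi]
    if mode == "region":
        return float(counts.sum())
    phases = (np.arange(lo, hi) - anchor) % 3
    return float(counts[phases == 0].sum())


def aggregate(estimates: list[FsEstimate]) -> AggregateSummary:
    """Summarise efficiencies across datasets as boxplot statistics.

    Undefined estimates are dropped (with a logged count); at least one
    defined estimate is required.
    """
    values = [e.efficiency_pct for e in estimates if e.defined]
    dropped = len(estimates) - len(values)
    if dropped:
        logger.info("aggregate: dropped %d undefined estimate(s)", dropped)
    if not values:
        raise ValueError("no defined frameshifting estimates to aggregate")
    arr = np.asarray(values, dtype=float)
    q25, med, q75 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    iqr = q75 - q25
    in_low = arr[arr >= q25 - 1.5 * iqr]
    in_high = arr[arr <= q75 + 1.5 * iqr]
    return AggregateSummary(
        n_datasets=len(values),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(in_low.min()),
        whisker_high=float(in_high.max()),
        values=values,
    )


def assign_psite(
    reads: list[tuple[int, int]],
    transcript_length: int,
    offsets: dict[int, int] | None = None,
    seq_id: str = "seq",
) -> tuple[RiboProfile, int]:
    """Collapse (5'-end position, read length) pairs into a P-site profile.

    Each read contributes one count at ``position + offset[length]``.  Reads
    whose length has no offset, or whose shifted position falls outside the
    transcript, are dropped; the dropped count is returned alongside the
    profile.
    """
    if offsets is None:
        offsets = DEFAULT_PSITE_OFFSETS
    counts = np.zeros(transcript_length, dtype=np.int64)
    dropped = 0
    for pos, length in reads:
        off = offsets.get(length)
        if off is None:
            dropped += 1
            continue
        p = pos + off
        if 0 <= p < transcript_length:
            counts[p] += 1
        else:
            dropped += 1
    if dropped:
        logger.info("assign_psite: dropped %d read(s)", dropped)
    return RiboProfile(seq_id, counts), dropped


# ---------------------------------------------------------------------------
# I/O: bedGraph / TSV count tracks and result tables
# ---------------------------------------------------------------------------

def read_bedgraph(path, seq_id: str, transcript_length: int) -> RiboProfile:
    """Read per-nt counts from bedGraph (chrom, start, end, value; 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
    )
    df = df[df["chrom"] == seq_id]
    counts = np.zeros(transcript_length, dtype=np.int64)
    for start, end, value in df[["start", "end", "value"]].itertuples(index=False):
        counts[int(start) : int(end)] += int(value)
    return RiboProfile(seq_id, counts)


def read_counts_tsv(path, seq_id: str | None = None, transcript_length: int | None = None) -> RiboProfile:
    """Read per-nt counts from TSV (seq_id, pos, count; positions 1-based)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["seq_id", "pos", "count"])
    if seq_id is None:
        seq_id = str(df["seq_id"].iloc[0])
    df = df[df["seq_id"] == seq_id]
    length = transcript_length if transcript_length is not None else int(df["pos"].max())
    counts = np.zeros(length, dtype=np.int64)
    counts[df["pos"].to_numpy(dtype=int) - 1] = df["count"].to_numpy(dtype=int)
    return RiboProfile(seq_id, counts)


def write_estimates_tsv(estimates: list[FsEstimate], path) -> None:
    rows = [
        {
            "seq_id": e.seq_id,
            "efficiency_pct": e.efficiency_pct,
            "rpf0": e.rpf0,
            "rpf1": e.rpf1,
            "codons0": e.codons0,
            "codons1": e.codons1,
            "region0_start": e.region0[0], "region0_end": e.region0[1],
            "region1_start": e.region1[0], "region1_end": e.region1[1],
            "defined": e.defined,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary_tsv(summary: AggregateSummary, path) -> None:
    pd.DataFrame(
        [
            {
                "n_datasets": summary.n_datasets,
                "median": summary.median,
                "q25": summary.q25,
                "q75": summary.q75,
                "whisker_low": summary.whisker_low,
                "whisker_high": summary.whisker_high,
            }
        ]
    ).to_csv(path, sep="\t", index=False)
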