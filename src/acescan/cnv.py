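"""Depth-of-coverage (DOC) ratio scanning for gene duplications.

A tandem duplication doubles the read depth over the duplicated span in a
resistant sample relative to a single-copy sensitive sample, while a
deletion halves it.  The scan works on per-base depth tables
(samtools-depth dialect: contig, 1-based position, depth), averages depth
in fixed windows, normalizes each sample by its genome-wide median
per-base depth to remove library-size differences, and calls a
duplication when the mean windowed resistant/sensitive ratio over the
locus clears a threshold while a single-copy control locus (here the
voltage-gated sodium channel gene, vgsc, on a separate contig) stays near
one.

Coordinates are 1-based inclusive in files (depth TSV windows included)
and 0-based half-open internally (`Span`), matching BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Span",
    "CoverageProfile",
    "RatioTrack",
    "DuplicationCall",
    "CnvParams",
    "read_depth_tsv",
    "read_bed_spans",
    "depth_array",
    "profile_from_depth",
    "doc_ratio",
    "call_duplication",
    "write_bedgraph",
]


class Span(NamedTuple):
    """0-based half-open genomic interval."""

    contig: str
    start: int
    end: int


@dataclass(frozen=True)
class CoverageProfile:
    """Windowed mean depth along one contig.

    ``starts``/``ends`` are 1-based inclusive window bounds; ``normalizer``
    is the sample's genome-wide median per-base depth over every contig in
    the source table (used for cross-sample normalization).
    """

    contig: str
    window_size: int
    window_step: int
    starts: np.ndarray
    ends: np.ndarray
    mean_depth: np.ndarray
    normalizer: float


@dataclass(frozen=True)
class RatioTrack:
    """Per-window resistant/sensitive normalized DOC ratio; NaN = masked."""

    contig: str
    starts: np.ndarray
    ends: np.ndarray
    ratio: np.ndarray

    @property
    def masked_fraction(self) -> float:
        return float(np.isnan(self.ratio).mean()) if self.ratio.size else 0.0


@dataclass(frozen=True)
class DuplicationCall:
    locus_name: str
    span: Span
    mean_ratio: float
    copy_estimate: float  #: mean_ratio × 1 copy per haploid genome
    is_duplicated: bool
    control_mean_ratio: float
    control_ok: bool


@dataclass(frozen=True)
class CnvParams:
    """Calling thresholds: a locus is duplicated when its mean ratio is at
    least ``dup_threshold`` (midway between the 1- and 2-copy expectations)
    and the control locus ratio lies inside ``control_band``."""

    dup_threshold: float = 1.5
    control_band: tuple[float, float] = (0.75, 1.25)


def read_depth_tsv(path: str | Path) -> pd.DataFrame:
    """Read a samtools-depth-style TSV (contig, 1-based pos, depth; no
    header).  Zero-depth positions may be omitted."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "pos", "depth"])
    if (df["depth"] < 0).any() or (df["pos"] < 1).any():
        raise ValueError("positions must be >=1 and depths nonnegative")
    return df


def read_bed_spans(path: str | Path) -> dict[str, Span]:
    """Read named spans from a BED file (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "name"],
        usecols=[0, 1, 2, 3],
    )
    return {str(r.name): Span(str(r.contig), int(r.start), int(r.end)) for r in df.itertuples()}


def depth_array(
    depth: pd.DataFrame, contig: str, contig_length: int | None = None
) -> np.ndarray:
    """Dense per-base depth for one contig, implicit zeros filled in.

    Length defaults to the largest position listed for the contig.
    """
    sub = depth[depth["contig"] == contig]
    if sub.empty:
        raise ValueError(f"contig {contig!r} absent from depth table")
    length = contig_length if contig_length is not None else int(sub["pos"].max())
    arr = np.zeros(length, dtype=float)
    pos = sub["pos"].to_numpy(dtype=int)
    if (pos > length).any():
        raise ValueError("position beyond stated contig length")
    arr[pos - 1] = sub["depth"].to_numpy(dtype=float)
    return arr


def profile_from_depth(
    depth: pd.DataFrame,
    contig: str,
    window_size: int = 100,
    window_step: int = 100,
    contig_lengths: Mapping[str, int] | None = None,
) -> CoverageProfile:
    """Windowed mean depth over one contig of a per-base depth table.

    Windows cover exactly ``window_size`` bases starting at position 1 and
    advancing by ``window_step``; a final partial window is dropped.
    Missing positions count as depth 0.  The normalizer is the median
    per-base depth pooled over every contig present in ``depth`` (with
    implicit zeros), so profiles from libraries of different size become
    comparable after division.
    """
    if window_size <= 0 or window_step <= 0:
        raise ValueError("window size and step must be positive")
    lengths = dict(contig_lengths or {})
    arr = depth_array(depth, contig, lengths.get(contig))
    starts0 = np.arange(0, len(arr) - window_size + 1, window_step)
    means = np.array([arr[s : s + window_size].mean() for s in starts0])
    per_base_all = np.concatenate(
        [depth_array(depth, c, lengths.get(c)) for c in depth["contig"].unique()]
    )
    return CoverageProfile(
        contig=contig,
        window_size=window_size,
        window_step=window_step,
        starts=starts0 + 1,
        ends=starts0 + window_size,
        mean_depth=means,
        normalizer=float(np.median(per_base_all)),
    )


def doc_ratio(resistant: CoverageProfile, sensitive: CoverageProfile) -> RatioTrack:
    """Per-window ratio of median-normalized depths, resistant over
    sensitive.  Windows where the sensitive normalized depth is zero are
    masked (NaN)."""
    if resistant.contig != sensitive.contig:
        raise ValueError("profiles are for different contigs")
    if (
        resistant.window_size != sensitive.window_size
        or resistant.window_step != sensitive.window_step
        or len(resistant.starts) != len(sensitive.starts)
    ):
        raise ValueError("windowing mismatch between profiles")
    if resistant.normalizer <= 0 or sensitive.normalizer <= 0:
        raise ValueError("profiles with zero median depth cannot be normalized")
    num = resistant.mean_depth / resistant.normalizer
    den = sensitive.mean_depth / sensitive.normalizer
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / den, np.nan)
    return RatioTrack(
        contig=resistant.contig,
        starts=resistant.starts.copy(),
        ends=resistant.ends.copy(),
        ratio=ratio,
    )


def _span_mean(track: RatioTrack, span: Span) -> float:
    if span.contig != track.contig:
        raise ValueError(f"span contig {span.contig!r} != track contig {track.contig!r}")
    # window [start, end] 1-based inclusive overlaps half-open [span.start, span.end)
    sel = (track.starts - 1 < span.end) & (track.ends > span.start)
    vals = track.ratio[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no unmasked windows overlap the span")
    return float(vals.mean())


def call_duplication(
    track: RatioTrack,
    locus_span: Span,
    control_track: RatioTrack,
    control_span: Span,
    params: CnvParams = CnvParams(),
    locus_name: str = "locus",
) -> DuplicationCall:
    """Call a duplication at a locus, gated on the single-copy control.

    ``mean_ratio`` averages the unmasked window ratios overlapping the
    locus span; the call is positive only when the control locus mean sits
    inside the control band (otherwise normalization is suspect and no
    duplication is claimed regardless of the locus signal).  The copy
    estimate is the mean ratio itself, in units of copies per haploid
    genome of the sensitive sample.
    """
    mean_ratio = _span_mean(track, locus_span)
    control_mean = _span_mean(control_track, control_span)
    lo, hi = params.control_band
    control_ok = lo <= control_mean <= hi
    return DuplicationCall(
        locus_name=locus_name,
        span=locus_span,
        mean_ratio=mean_ratio,
        copy_estimate=mean_ratio,
        is_duplicated=bool(control_ok and mean_ratio >= params.dup_threshold),
        control_mean_ratio=control_mean,
        control_ok=control_ok,
    )


def write_bedgraph(track: RatioTrack, path: str | Path, name: str = "doc_ratio") -> None:
    """Write the ratio track as bedGraph (0-based half-open); masked
    windows are skipped."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for s, e, r in zip(track.starts, track.ends, track.ratio):
            if not np.isnan(r):
                fh.write(f"{track.contig}\t{s - 1}\t{e}\t{r:.6g}\n")
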