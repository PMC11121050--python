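"""Windowed mutation-frequency tracks, HF-region calling, colocalization.

Bins are 0-based half-open; a mutation at 1-based position p falls in bin
floor((p-1)/window_size).  Region coordinates in output follow BED
conventions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

#: terminal windows shorter than this fraction of window_size are excluded
#: from HF calling (their per-bp denominator blows up)
MIN_TERMINAL_FRACTION = 0.1


@dataclass
class WindowTrack:
    """Per-window mutation counts along one chromosome."""

    chrom: str
    window_size: int
    counts: np.ndarray
    chrom_length: int
    mclass_filter: str = "all"

    @property
    def n_windows(self) -> int:
        return len(self.counts)

    def window_length(self, i: int) -> int:
        if i < self.n_windows - 1:
            return self.window_size
        rem = self.chrom_length - (self.n_windows - 1) * self.window_size
        return rem

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def mean_frequency(self) -> float:
        """Chromosome-mean per-bp frequency (hotspot windows included)."""
        return self.total / self.chrom_length


@dataclass(frozen=True)
class HFRegion:
    """Merged run of flagged high-frequency windows (0-based half-open)."""

    chrom: str
    start: int
    end: int
    mclass: str
    fold: float
    fraction_of_total: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty region")


def window_counts(
    mutations,
    chrom: str,
    chrom_length: int,
    window_size: int,
    mclass_filter: str = "all",
) -> WindowTrack:
    """Bin mutations of one chromosome into fixed windows.

    ``mclass_filter``: "all", "SBS", or "InDel" (INS+DEL).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    n_windows = -(-chrom_length // window_size)  # ceil
    counts = np.zeros(n_windows, dtype=np.int64)
    for m in mutations:
        if m.chrom != chrom:
            continue
        if mclass_filter == "SBS" and m.mclass != "SBS":
            continue
        if mclass_filter == "InDel" and m.mclass not in ("INS", "DEL"):
            continue
        if not (1 <= m.pos <= chrom_length):
            raise ValueError(f"position {m.pos} beyond chromosome {chrom} ({chrom_length} bp)")
        counts[(m.pos - 1) // window_size] += 1
    return WindowTrack(chrom, window_size, counts, chrom_length, mclass_filter)


def frequency(track: WindowTrack) -> np.ndarray:
    """Per-window per-bp frequencies; the short terminal window uses its
    true length as denominator."""
    lengths = np.full(track.n_windows, track.window_size, dtype=float)
    if track.n_windows:
        lengths[-1] = track.window_length(track.n_windows - 1)
    return track.counts / lengths


def flagged_windows(track: WindowTrack, fold_threshold: float = 20.0) -> np.ndarray:
    """Indices of windows whose frequency is >= fold_threshold x chromosome
    mean; empty when the chromosome mean is zero."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    mean = track.mean_frequency
    if mean == 0:
        return np.array([], dtype=int)
    freqs = frequency(track)
    flags = freqs >= fold_threshold * mean
    if track.n_windows and track.window_length(track.n_windows - 1) < MIN_TERMINAL_FRACTION * track.window_size:
        flags[-1] = False
    return np.nonzero(flags)[0]


def call_hf_regions(
    track: WindowTrack,
    fold_threshold: float = 20.0,
    pond_total: int | None = None,
) -> list[HFRegion]:
    """Merge adjacent flagged windows into HF regions.

    ``pond_total`` (defaults to the track total) is the denominator for each
    region's fraction_of_total.
    """
    idx = flagged_windows(track, fold_threshold)
    if pond_total is None:
        pond_total = track.total
    mean = track.mean_frequency
    regions: list[HFRegion] = []
    if len(idx) == 0:
        return regions
    runs: list[list[int]] = [[idx[0], idx[0]]]
    for i in idx[1:]:
        if i == runs[-1][1] + 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    for first, last in runs:
        start = first * track.window_size
        end = min((last + 1) * track.window_size, track.chrom_length)
        count = int(track.counts[first : last + 1].sum())
        region_freq = count / (end - start)
        regions.append(
            HFRegion(
                chrom=track.chrom,
                start=start,
                end=end,
                mclass=track.mclass_filter,
                fold=region_freq / mean,
                fraction_of_total=count / pond_total if pond_total else 0.0,
            )
        )
    return regions


@dataclass(frozen=True)
class ColocalizationReport:
    chrom: str
    window_size: int
    n_windows: int
    n_flagged_a: int
    n_flagged_b: int
    shared_windows: int
    jaccard: float
    p_hypergeom: float


def _region_windows(regions: list[HFRegion], window_size: int) -> set[int]:
    out: set[int] = set()
    for r in regions:
        out.update(range(r.start // window_size, -(-r.end // window_size)))
    return out


def colocalization(
    hf_a: list[HFRegion],
    hf_b: list[HFRegion],
    chrom: str,
    chrom_length: int,
    window_size: int,
) -> ColocalizationReport:
    """Overlap of two HF-region sets on the same chromosome geometry.

    Reports shared flagged windows, the Jaccard index of the flagged-window
    sets, and the hypergeometric tail probability of >= that many shared
    windows given the two set sizes and the total window count.
    """
    for r in hf_a + hf_b:
        if r.chrom != chrom or r.end > chrom_length:
            raise ValueError("region geometry does not match the given chromosome")
    n_windows = -(-chrom_length // window_size)
    wa = _region_windows(hf_a, window_size)
    wb = _region_windows(hf_b, window_size)
    if max(wa, default=-1) >= n_windows or max(wb, default=-1) >= n_windows:
        raise ValueError("flagged windows beyond chromosome geometry")
    shared = len(wa & wb)
    union = len(wa | wb)
    jaccard = shared / union if union else 0.0
    # P(X >= shared) for X ~ Hypergeom(N=n_windows, K=|A|, n=|B|)
    p = float(hypergeom.sf(shared - 1, n_windows, len(wa), len(wb)))
    return ColocalizationReport(
        chrom=chrom,
        window_size=window_size,
        n_windows=n_windows,
        n_flagged_a=len(wa),
        n_flagged_b=len(wb),
        shared_windows=shared,
        jaccard=jaccard,
        p_hypergeom=p,
    )


def write_track_tsv(path: str | os.PathLike, tracks: list[WindowTrack]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcount\tfrequency\n")
        for track in tracks:
            freqs = frequency(track)
            for i in range(track.n_windows):
                start = i * track.window_size
                end = min(start + track.window_size, track.chrom_length)
                fh.write(f"{track.chrom}\t{start}\t{end}\t{track.counts[i]}\t{freqs[i]:.6g}\n")


def write_hf_bed(path: str | os.PathLike, regions: list[HFRegion]) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.mclass)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.mclass}\t{round(r.fold)}\n")


def write_colocalization_tsv(path: str | os.PathLike, reports: list[ColocalizationReport]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\twindow_size\tn_windows\tflagged_sbs\tflagged_indel\tshared\tjaccard\tp_hypergeom\n")
        for r in reports:
            fh.write(
                f"{r.chrom}\t{r.window_size}\t{r.n_windows}\t{r.n_flagged_a}\t{r.n_flagged_b}\t"
                f"{r.shared_windows}\t{r.jaccard:.4f}\t{r.p_hypergeom:.4g}\n"
            )
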