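"""Windowed copy-number profiling.

The copy-number ratio of a window is its read count divided by the
genome-wide median count (zero-count windows excluded from the median),
multiplied by the sample's assumed ploidy, so that unaltered regions sit at
the ploidy value. Tracks are segmented by recursive binary segmentation with
a mean-difference z-score stopping rule, and segments are called gain /
neutral / loss against the normalisation ploidy with a half-copy margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import WindowCountTable

__all__ = [
    "CopyNumberTrack",
    "Segment",
    "count_to_ratio",
    "gc_correct",
    "segment_track",
    "call_states",
    "gene_copy_number",
]


@dataclass
class CopyNumberTrack:
    windows: pd.DataFrame  # chrom, start, end, count, ratio
    ploidy: int

    @property
    def ratios(self) -> np.ndarray:
        return self.windows["ratio"].to_numpy()


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    mean_ratio: float  # median of member-window ratios
    n_windows: int
    state: str = "neutral"
    estimated_cn: int | None = None


def count_to_ratio(counts: WindowCountTable, ploidy: int) -> CopyNumberTrack:
    """ratio_i = count_i / median(nonzero counts) * ploidy."""
    df = counts.data.copy()
    nonzero = df.loc[df["count"] > 0, "count"].to_numpy(dtype=float)
    if nonzero.size == 0:
        raise ValueError("all window counts are zero; cannot normalise")
    med = float(np.median(nonzero))
    df["ratio"] = df["count"].to_numpy(dtype=float) / med * ploidy
    return CopyNumberTrack(df, ploidy)


def gc_correct(counts: WindowCountTable, n_bins: int = 20) -> WindowCountTable:
    """Rescale counts by per-GC-bin medians.

    Windows are binned by GC content into ``n_bins`` equal-width bins; counts
    in each bin are multiplied by global_median / bin_median. Bins holding
    fewer than 20 windows are left unscaled (their medians are too noisy to
    act on).
    """
    if not counts.has_gc:
        raise ValueError(
            "window table has no gc column; skip GC correction or add one"
        )
    df = counts.data.copy()
    gc = df["gc"].to_numpy(dtype=float)
    cnt = df["count"].to_numpy(dtype=float)
    nonzero = cnt > 0
    global_med = float(np.median(cnt[nonzero]))
    edges = np.linspace(gc.min(), gc.max() + 1e-12, n_bins + 1)
    bin_idx = np.clip(np.digitize(gc, edges) - 1, 0, n_bins - 1)
    scaled = cnt.copy()
    for b in range(n_bins):
        mask = bin_idx == b
        if mask.sum() < 20:
            continue
        bin_med = float(np.median(cnt[mask & nonzero])) if (mask & nonzero).any() else 0.0
        if bin_med > 0:
            scaled[mask] = cnt[mask] * global_med / bin_med
    df["count"] = np.rint(scaled).astype(int)
    return WindowCountTable(df)


def _noise_sigma(x: np.ndarray) -> float:
    """Robust per-window noise SD from first differences.

    The MAD of lag-1 differences is insensitive to the level shifts the
    segmentation is trying to find; for Gaussian noise,
    sd = median|diff| / (0.6745 * sqrt(2)).
    """
    if len(x) < 2:
        return 0.0
    mad = float(np.median(np.abs(np.diff(x))))
    return mad / 0.9539392014169523


def _best_split(x: np.ndarray, min_windows: int, sigma: float) -> tuple[int, float]:
    """Best breakpoint of x by two-sample mean-difference z-score.

    Returns (index, z) where index is the left-segment length; z is 0 when
    no admissible split exists. The denominator uses the robust global noise
    SD rather than within-side SDs, which a true copy-number step would
    inflate (masking the very shift being tested).
    """
    n = len(x)
    if n < 2 * min_windows:
        return 0, 0.0
    csum = np.cumsum(x)
    k = np.arange(min_windows, n - min_windows + 1)
    left_sum = csum[k - 1]
    mean_l = left_sum / k
    mean_r = (csum[-1] - left_sum) / (n - k)
    se = max(sigma, 1e-9) * np.sqrt(1.0 / k + 1.0 / (n - k))
    z = np.abs(mean_l - mean_r) / se
    j = int(np.argmax(z))
    return int(k[j]), float(z[j])


def _segment_chrom(
    x: np.ndarray, min_windows: int, z_threshold: float
) -> list[tuple[int, int]]:
    sigma = _noise_sigma(x)
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        split, z = _best_split(x[lo:hi], min_windows, sigma)
        if split == 0 or z <= z_threshold:
            out.append((lo, hi))
            return
        recurse(lo, lo + split)
        recurse(lo + split, hi)

    recurse(0, len(x))
    out = sorted(out)
    # merge pass: recursion can strand a short stub next to an off-by-a-few
    # breakpoint; adjacent segments whose mean difference does not itself
    # clear the z threshold are coalesced
    merged = True
    while merged and len(out) > 1:
        merged = False
        for i in range(len(out) - 1):
            lo_a, hi_a = out[i]
            lo_b, hi_b = out[i + 1]
            n_a, n_b = hi_a - lo_a, hi_b - lo_b
            diff = abs(float(np.mean(x[lo_a:hi_a])) - float(np.mean(x[lo_b:hi_b])))
            z = diff / (max(sigma, 1e-9) * np.sqrt(1.0 / n_a + 1.0 / n_b))
            if z <= z_threshold:
                out[i : i + 2] = [(lo_a, hi_b)]
                merged = True
                break
    return out


def segment_track(
    track: CopyNumberTrack, min_windows: int = 5, z_threshold: float = 5.0
) -> list[Segment]:
    """Recursive binary segmentation of the ratio track, per chromosome.

    A candidate breakpoint is accepted when the two-sided mean-difference
    z-score exceeds ``z_threshold`` and both sides retain at least
    ``min_windows`` windows. The procedure is deterministic: identical input
    yields identical breakpoints. Per-segment ``mean_ratio`` is the median of
    member windows (robust to focal outliers within a segment).
    """
    if min_windows < 1:
        raise ValueError("min_windows must be >= 1")
    if track.windows.empty:
        raise ValueError("empty copy-number track")
    segments: list[Segment] = []
    for chrom, grp in track.windows.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        ratios = g["ratio"].to_numpy(dtype=float)
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        for lo, hi in _segment_chrom(ratios, min_windows, z_threshold):
            segments.append(
                Segment(
                    chrom=str(chrom),
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                    mean_ratio=float(np.median(ratios[lo:hi])),
                    n_windows=hi - lo,
                )
            )
    return segments


def call_states(
    segments: list[Segment], ploidy: int, margin: float = 0.5
) -> list[Segment]:
    """Call gain/neutral/loss against the normalisation ploidy.

    gain when mean_ratio > ploidy + margin, loss when < ploidy - margin;
    estimated integer copy number is the rounded mean_ratio clipped at 0.
    Contiguous segments landing on the same state and integer copy number
    are one event and are reported as a single merged segment.
    """
    for seg in segments:
        if seg.mean_ratio > ploidy + margin:
            seg.state = "gain"
        elif seg.mean_ratio < ploidy - margin:
            seg.state = "loss"
        else:
            seg.state = "neutral"
        seg.estimated_cn = int(max(0, round(seg.mean_ratio)))

    merged: list[Segment] = []
    for seg in sorted(segments, key=lambda s: (s.chrom, s.start)):
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.chrom == seg.chrom
            and prev.end == seg.start
            and prev.state == seg.state
            and prev.estimated_cn == seg.estimated_cn
        ):
            total = prev.n_windows + seg.n_windows
            prev.mean_ratio = (
                prev.mean_ratio * prev.n_windows + seg.mean_ratio * seg.n_windows
            ) / total
            prev.end = seg.end
            prev.n_windows = total
        else:
            merged.append(seg)
    return merged


def gene_copy_number(
    counts_fine: WindowCountTable,
    gene_interval: tuple[str, int, int],
    ploidy: int,
) -> float:
    """Gene-level copy number from fine (e.g. 5 kbp / 1 kbp) windows.

    Median ratio of the fine windows overlapping the interval, after median
    normalisation of the whole fine-window table at the given ploidy.
    """
    chrom, start, end = gene_interval
    track = count_to_ratio(counts_fine, ploidy)
    df = track.windows
    mask = (df["chrom"] == chrom) & (df["end"] > start) & (df["start"] < end)
    if not mask.any():
        raise ValueError(f"no fine windows overlap {chrom}:{start}-{end}")
    return float(np.median(df.loc[mask, "ratio"]))


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "mean_ratio": s.mean_ratio,
                "n_windows": s.n_windows,
                "state": s.state,
                "estimated_cn": s.estimated_cn,
            }
            for s in segments
        ]
    )
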