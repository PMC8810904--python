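"""Windowed read-depth CNV screen.

Mirrors a coarse whole-genome coverage check: mean depth in 50 kb tiling
windows, median normalization to copy ratios, and run-length calling of
windows beyond loss/gain thresholds. Intended to exclude large-scale
copy-number changes, not to fine-map breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 50_000


@dataclass
class CoverageProfile:
    """Per-window mean depth over one sequence (half-open tiling windows)."""

    label: str
    window: int
    depths: np.ndarray
    trailing_length: int = 0      # length of the excluded partial window
    trailing_depth: float = float("nan")

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        if (self.depths < 0).any():
            raise ValueError("depths must be >= 0")

    @property
    def starts(self) -> np.ndarray:
        return np.arange(len(self.depths)) * self.window

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.label,
            "start": self.starts,
            "end": self.starts + self.window,
            "depth": self.depths,
        })


@dataclass(frozen=True)
class CnvSegment:
    """A called copy-number segment (window-aligned, half-open)."""

    label: str
    start: int
    end: int
    mean_ratio: float
    n_windows: int
    call: str  # loss | gain


def bin_depth(positions_depth: pd.DataFrame | np.ndarray, sequence_length: int,
              window: int = DEFAULT_WINDOW, label: str = "seq") -> CoverageProfile:
    """Bin per-base depth into tiling windows.

    Accepts a per-base depth vector, or a DataFrame with columns
    ``start``, ``end``, ``depth`` (half-open intervals of constant depth).
    The trailing partial window is reported but excluded from calling.
    """
    if sequence_length < window:
        raise ValueError("sequence length must be >= window")
    if isinstance(positions_depth, pd.DataFrame):
        if positions_depth.empty:
            raise ValueError("empty depth input")
        per_base = np.zeros(sequence_length)
        for s, e, d in positions_depth[["start", "end", "depth"]].itertuples(index=False):
            per_base[int(s):int(e)] += d
    else:
        per_base = np.asarray(positions_depth, dtype=float)
        if per_base.size == 0:
            raise ValueError("empty depth input")
        if per_base.size != sequence_length:
            raise ValueError("per-base depth length mismatch")
    n_win = sequence_length // window
    means = per_base[:n_win * window].reshape(n_win, window).mean(axis=1)
    trailing = sequence_length - n_win * window
    t_depth = per_base[n_win * window:].mean() if trailing else float("nan")
    return CoverageProfile(label, window, means, trailing, float(t_depth))


def normalize_profile(profile: CoverageProfile) -> CoverageProfile:
    """Divide each window by the profile-wide median depth (copy ratios)."""
    med = float(np.median(profile.depths))
    if med <= 0:
        raise ValueError("median depth must be > 0 for normalization")
    return CoverageProfile(profile.label, profile.window,
                           profile.depths / med,
                           profile.trailing_length,
                           profile.trailing_depth / med)


def call_cnv(ratio_profile: CoverageProfile, loss_threshold: float = 0.75,
             gain_threshold: float = 1.25, min_windows: int = 3) -> list[CnvSegment]:
    """Maximal runs of >= min_windows consecutive out-of-band windows."""
    r = ratio_profile.depths
    state = np.where(r < loss_threshold, -1, np.where(r > gain_threshold, 1, 0))
    segments: list[CnvSegment] = []
    i = 0
    while i < len(state):
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j < len(state) and state[j] == state[i]:
            j += 1
        if j - i >= min_windows:
            w = ratio_profile.window
            segments.append(CnvSegment(
                ratio_profile.label, i * w, j * w,
                float(r[i:j].mean()), j - i,
                "loss" if state[i] < 0 else "gain"))
        i = j
    return segments


def segments_to_bed(segments: list[CnvSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.label, s.start, s.end, s.call, f"{s.mean_ratio:.4f}", ".")
         for s in segments],
        columns=["chrom", "start", "end", "name", "score", "strand"])
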