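"""Peak calling on composite profiles and nucleosome array features.

A barrier-aligned composite of dyad coverage shows a train of peaks on each
side of the alignment point; each peak maximum approximates a nucleosome
dyad. Two features summarize the array geometry:

* distance to barrier — from the barrier center to the proximal *flank* of
  the first nucleosome: ``|first peak offset| - 73`` (half of the 147 bp
  core footprint);
* linker_i — free DNA between consecutive footprints:
  ``|peak_{i+1} - peak_i| - 147``.

Peaks are called by an outward-seeded windowed argmax: the profile is
smoothed with a centered moving average, the first downstream peak is the
maximum over ``[min_first_offset, min_first_offset + search_max_repeat]``,
and each subsequent peak is the maximum over
``[previous + search_min_repeat, previous + search_max_repeat]``, stopping
when the window leaves the profile or the candidate falls below a fraction
of the first peak's height. The upstream side is treated symmetrically.
Features are computed per side and then averaged over the sides present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

HALF_FOOTPRINT = 73
FOOTPRINT = 147

FEATURE_NAMES = ("distance_to_barrier", "linker_1", "linker_2", "linker_3")


@dataclass(frozen=True)
class PeakCallParams:
    smooth_window: int = 15
    min_first_offset: int = 30
    search_min_repeat: int = 100
    search_max_repeat: int = 250
    min_prominence_fraction: float = 0.1
    max_peaks_per_side: int = 8

    def __post_init__(self) -> None:
        if self.smooth_window % 2 != 1 or self.smooth_window < 1:
            raise ValueError("smooth_window must be odd and positive")
        if self.search_min_repeat >= self.search_max_repeat:
            raise ValueError("search_min_repeat must be < search_max_repeat")


@dataclass
class PeakSet:
    """Called peak offsets (bp relative to barrier) and their heights."""

    downstream: list[int] = field(default_factory=list)
    upstream: list[int] = field(default_factory=list)  # negative offsets
    downstream_heights: list[float] = field(default_factory=list)
    upstream_heights: list[float] = field(default_factory=list)
    diagnostic: str = ""

    @property
    def is_empty(self) -> bool:
        return not self.downstream and not self.upstream


@dataclass
class ArrayFeatures:
    """Distance to barrier and linker lengths, per side and averaged.

    ``per_side[side][feature]`` holds the raw per-side values for side in
    {"down", "up"}; ``averaged[feature]`` is the mean over the sides where
    the feature could be computed. A feature needing peaks i and i+1 is
    absent from a side with fewer peaks.
    """

    per_side: dict[str, dict[str, float]]
    averaged: dict[str, float]
    peak_heights: dict[str, list[float]]
    barrier_kind: str = ""
    n_sites: int = 0
    replicate_id: str = ""
    replicate_values: dict[str, list[float]] | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (side, feature, value)."""
        rows = []
        for side, feats in self.per_side.items():
            for name, value in feats.items():
                rows.append((self.replicate_id, self.barrier_kind, side, name, value))
        for name, value in self.averaged.items():
            rows.append((self.replicate_id, self.barrier_kind, "avg", name, value))
        return pd.DataFrame(
            rows, columns=["replicate", "barrier_kind", "side", "feature", "value"]
        )


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    return uniform_filter1d(values.astype(float), size=window, mode="nearest")


def _argmax_smallest_abs(segment: np.ndarray, offsets: np.ndarray) -> int:
    """Index of the maximum with a two-stage tie rule.

    A contiguous run of tied maxima is a plateau (e.g. the boxcar composite
    of perfectly positioned dyads) and resolves to its center, rounding away
    from the alignment point so the 1 bp asymmetry of the even fragment
    window cancels between the two sides. Disconnected tied maxima resolve
    toward the smallest |offset|.
    """
    top = segment.max()
    tol = 1e-9 * max(abs(float(top)), 1e-300)
    tied = np.flatnonzero(segment >= top - tol)
    runs = np.split(tied, np.flatnonzero(np.diff(tied) > 1) + 1)
    if len(runs) == 1:
        run = runs[0]
        mid2 = int(run[0]) + int(run[-1])
        if mid2 % 2 == 0:
            return mid2 // 2
        k1, k2 = mid2 // 2, mid2 // 2 + 1
        return k1 if abs(offsets[k1]) > abs(offsets[k2]) else k2
    return int(tied[np.argmin(np.abs(offsets[tied]))])

def _call_one_side(
    values: np.ndarray,
    raw: np.ndarray,
    offsets: np.ndarray,
    params: PeakCallParams,
    sign: int,
) -> tuple[list[int], list[float]]:
    """Outward-seeded windowed argmax along one side (sign=+1 down, -1 up)."""
    first = int(offsets[0])

    def seg(lo: int, hi: int):  # inclusive offset range -> (slice, offsets)
        lo_i = max(lo - first, 0)
        hi_i = min(hi - first, len(values) - 1)
        if lo_i > hi_i:
            return None
        idx = np.arange(lo_i, hi_i + 1)
        return idx, offsets[idx]

    lo = params.min_first_offset
    hi = params.min_first_offset + params.search_max_repeat
    window = seg(*sorted((sign * lo, sign * hi)))
    if window is None:
        return [], []
    idx, offs = window
    # flatness is judged on the unsmoothed profile: a constant (or all-zero)
    # stretch has no local structure, whatever the smoother does to it
    if np.ptp(raw[idx]) <= 1e-12 * max(abs(float(raw[idx].max())), 1e-300):
        return [], []
    vals = values[idx]
    k = _argmax_smallest_abs(vals, offs)
    peaks = [int(offs[k])]
    heights = [float(vals[k])]
    ref_height = heights[0]
    while len(peaks) < params.max_peaks_per_side:
        prev = peaks[-1]
        lo = prev + sign * params.search_min_repeat
        hi = prev + sign * params.search_max_repeat
        window = seg(*sorted((lo, hi)))
        if window is None or len(window[0]) < (params.search_max_repeat
                                               - params.search_min_repeat + 1):
            break  # window left the profile
        idx, offs = window
        vals = values[idx]
        k = _argmax_smallest_abs(vals, offs)
        if vals[k] < params.min_prominence_fraction * ref_height:
            break
        peaks.append(int(offs[k]))
        heights.append(float(vals[k]))
    return peaks, heights


def call_composite_peaks(profile, params: PeakCallParams | None = None) -> PeakSet:
    """Call nucleosome peak maxima on both sides of the alignment point."""
    params = params or PeakCallParams()
    raw = np.asarray(profile.values, dtype=float)
    values = _smooth(raw, params.smooth_window)
    offsets = np.asarray(profile.offsets, dtype=int)
    down, down_h = _call_one_side(values, raw, offsets, params, sign=+1)
    up, up_h = _call_one_side(values, raw, offsets, params, sign=-1)
    diagnostic = "" if (down or up) else "no peaks above prominence threshold"
    return PeakSet(down, up, down_h, up_h, diagnostic=diagnostic)


def quantify_array_features(
    peaks: PeakSet,
    barrier_kind: str = "",
    half_footprint: int = HALF_FOOTPRINT,
    footprint: int | None = None,
    n_sites: int = 0,
    replicate_id: str = "",
) -> ArrayFeatures:
    """Convert called peaks into distance-to-barrier and linker lengths.

    Per side: distance_to_barrier = |first peak| - half_footprint;
    linker_i = |peak_{i+1} - peak_i| - footprint. The averaged value of each
    feature is the mean over the sides where it exists.
    """
    if peaks.is_empty:
        raise ValueError("cannot quantify an empty peak set")
    footprint = footprint if footprint is not None else 2 * half_footprint + 1
    per_side: dict[str, dict[str, float]] = {}
    for side, offs in (("down", peaks.downstream), ("up", peaks.upstream)):
        if not offs:
            continue
        feats = {"distance_to_barrier": float(abs(offs[0]) - half_footprint)}
        for i in range(min(len(offs) - 1, 3)):
            feats[f"linker_{i + 1}"] = float(abs(offs[i + 1] - offs[i]) - footprint)
        per_side[side] = feats
    averaged: dict[str, float] = {}
    for name in FEATURE_NAMES:
        present = [feats[name] for feats in per_side.values() if name in feats]
        if present:
            averaged[name] = float(np.mean(present))
    return ArrayFeatures(
        per_side=per_side,
        averaged=averaged,
        peak_heights={"down": peaks.downstream_heights, "up": peaks.upstream_heights},
        barrier_kind=barrier_kind,
        n_sites=n_sites,
        replicate_id=replicate_id,
    )


def aggregate_replicates(features: list[ArrayFeatures]) -> ArrayFeatures:
    """Mean each feature across replicates, skipping replicates lacking it."""
    if not features:
        raise ValueError("empty replicate list")
    kinds = {f.barrier_kind for f in features}
    if len(kinds) > 1:
        raise ValueError(f"mixed barrier kinds: {sorted(kinds)}")
    averaged: dict[str, float] = {}
    replicate_values: dict[str, list[float]] = {}
    for name in FEATURE_NAMES:
        present = [f.averaged[name] for f in features if name in f.averaged]
        if present:
            averaged[name] = float(np.mean(present))
            replicate_values[name] = present
    per_side: dict[str, dict[str, float]] = {}
    for side in ("down", "up"):
        side_feats: dict[str, float] = {}
        for name in FEATURE_NAMES:
            present = [
                f.per_side[side][name]
                for f in features
                if side in f.per_side and name in f.per_side[side]
            ]
            if present:
                side_feats[name] = float(np.mean(present))
        if side_feats:
            per_side[side] = side_feats
    return ArrayFeatures(
        per_side=per_side,
        averaged=averaged,
        peak_heights={},
        barrier_kind=features[0].barrier_kind,
        n_sites=sum(f.n_sites for f in features),
        replicate_id="mean",
        replicate_values=replicate_values,
    )
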