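"""Behavioral statistics: Attraction Index, Oviposition Preference Index,
occupancy maps and group comparisons.

The Attraction Index over a testing window (5 min in the standard
protocol) is

    AI = (O - C_avg) / (O + C_avg)

where O is the number of tracked positional samples in the odor quadrant
and C_avg the mean sample count per non-odor (control) quadrant.  AI = 1
means every sample fell in the odor quadrant, AI = 0 an even spread over
all four quadrants, AI = -1 no samples in the odor quadrant.  Samples on a
quadrant axis or outside the arena mask are excluded from both O and
C_avg.  All flies' samples are pooled (the per-fly averaged variant is
available behind a flag but is not the default).

The Oviposition Preference Index for the 3-well egg-laying assay is the
same contrast on egg counts:

    OPI = (E_o - E_avg) / (E_o + E_avg)

with E_o the egg count in the odor well and E_avg the mean count of the
two control wells.

When O + C_avg (or E_o + E_avg) is zero the statistic is undefined; this
is reported as an error (or an explicitly flagged NaN in time courses),
never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import (
    ArenaGeometry,
    Quadrant,
    assign_quadrants,
    remap_quadrant,
)
from .tracking import TrackSet

__all__ = [
    "AttractionResult",
    "DegenerateDataError",
    "OccupancyMap",
    "OvipositionResult",
    "UndefinedStatisticError",
    "ai_timecourse",
    "attraction_index",
    "compare_groups",
    "egg_quadrant_counts",
    "occupancy_heatmap",
    "oviposition_preference_index",
    "post_stimulus_analysis",
]


class UndefinedStatisticError(ValueError):
    """The index denominator is zero: no samples/eggs in any counted region."""


class DegenerateDataError(ValueError):
    """Group-comparison input cannot support the test (n < 2, zero variance)."""


@dataclass(frozen=True)
class AttractionResult:
    """Attraction Index over one window.

    ``O`` is the odor-quadrant sample count, ``C_avg`` the mean count per
    control quadrant; ``n_samples_total`` counts every sample in the
    window including excluded (axis / out-of-mask) ones.  ``AI`` is NaN
    only when ``undefined`` is True.
    """

    O: int
    C_avg: float
    AI: float
    window: tuple[float, float]
    n_samples_total: int
    odor_quadrant: Quadrant
    per_quadrant: tuple[int, int, int, int] = (0, 0, 0, 0)

    @property
    def undefined(self) -> bool:
        return bool(np.isnan(self.AI))


@dataclass(frozen=True)
class OvipositionResult:
    """Egg-count preference: per-region counts and the OPI contrast."""

    E_o: int
    E_avg: float
    OPI: float
    per_region_counts: tuple[int, ...]
    total_eggs: int
    odor_region: int


@dataclass(frozen=True)
class OccupancyMap:
    """2-D histogram of in-mask positional samples."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    bin_size_cm: float


def _window_samples(ts: TrackSet, window: tuple[float, float] | None):
    df = ts.to_dataframe()
    if window is None:
        window = (0.0, ts.duration)
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have t_end > t_start")
    sel = df[(df["t_s"] >= t0) & (df["t_s"] < t1)]
    return sel, (float(t0), float(t1))


def _quadrant_counts(x, y, arena: ArenaGeometry) -> np.ndarray:
    labels = assign_quadrants(np.asarray(x, float), np.asarray(y, float), arena)
    return np.array([(labels == k).sum() for k in range(4)], dtype=int)


def attraction_index(
    ts: TrackSet,
    odor_quadrant: Quadrant,
    window: tuple[float, float] | None = None,
    per_fly: bool = False,
) -> AttractionResult:
    """Attraction Index of a track set over a time window [t0, t1).

    Default pools the positional samples of all flies; ``per_fly=True``
    instead computes the AI per track and averages across tracks with at
    least one counted sample.  Raises :class:`UndefinedStatisticError`
    when no sample falls in any quadrant.
    """
    if odor_quadrant is Quadrant.NONE:
        raise ValueError("odor_quadrant must be one of Q1..Q4")
    sel, window = _window_samples(ts, window)
    if per_fly:
        ais = []
        for _, g in sel.groupby("track_id"):
            counts = _quadrant_counts(g["x_cm"], g["y_cm"], ts.arena)
            o = counts[odor_quadrant.index]
            c = (counts.sum() - o) / 3.0
            if o + c > 0:
                ais.append((o - c) / (o + c))
        if not ais:
            raise UndefinedStatisticError("no counted samples in any track")
        counts = _quadrant_counts(sel["x_cm"], sel["y_cm"], ts.arena)
        o = int(counts[odor_quadrant.index])
        c_avg = float((counts.sum() - o) / 3.0)
        ai = float(np.mean(ais))
    else:
        counts = _quadrant_counts(sel["x_cm"], sel["y_cm"], ts.arena)
        o = int(counts[odor_quadrant.index])
        c_avg = float((counts.sum() - o) / 3.0)
        if o + c_avg == 0:
            raise UndefinedStatisticError(
                "AI undefined: no samples in any quadrant in the window"
            )
        ai = (o - c_avg) / (o + c_avg)
    return AttractionResult(
        O=o,
        C_avg=c_avg,
        AI=float(ai),
        window=window,
        n_samples_total=int(len(sel)),
        odor_quadrant=odor_quadrant,
        per_quadrant=tuple(int(c) for c in counts),
    )


def ai_timecourse(
    ts: TrackSet,
    odor_quadrant: Quadrant,
    window_len: float = 300.0,
    stride: float | None = None,
) -> list[AttractionResult]:
    """Sliding-window AI series over the whole recording.

    ``stride`` defaults to ``window_len`` (non-overlapping windows).
    Windows with an undefined AI are kept in the series with ``AI = NaN``
    and ``undefined == True`` rather than dropped.
    """
    if stride is None:
        stride = window_len
    duration = ts.duration
    if window_len > duration:
        raise ValueError("window_len exceeds the recording duration")
    out = []
    t0 = 0.0
    while t0 + window_len <= duration + 1e-9:
        try:
            out.append(
                attraction_index(ts, odor_quadrant, (t0, t0 + window_len))
            )
        except UndefinedStatisticError:
            out.append(
                AttractionResult(
                    O=0,
                    C_avg=0.0,
                    AI=float("nan"),
                    window=(t0, t0 + window_len),
                    n_samples_total=0,
                    odor_quadrant=odor_quadrant,
                )
            )
        t0 += stride
    return out


def post_stimulus_analysis(
    pre_ts: TrackSet,
    post_ts: TrackSet,
    odor_quadrant_at_stimulus: Quadrant,
    rotation_applied: int,
    window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
) -> tuple[AttractionResult, AttractionResult]:
    """AI during stimulation and after the arena rotation.

    The post-stimulus AI is computed against the rotated position of the
    original odor quadrant (its label remapped by the rotation), so that
    attraction to deposits moving with the plate is dissociated from
    any residual signal on the fixed odor-delivery axis.
    """
    if rotation_applied % 90 != 0:
        raise ValueError("rotation_applied must be a multiple of 90")
    expected = (pre_ts.arena.rotation + rotation_applied) % 360
    if post_ts.arena.rotation != expected:
        raise ValueError(
            "inconsistent arena references: post arena rotation "
            f"{post_ts.arena.rotation} != pre rotation + applied ({expected})"
        )
    stim = attraction_index(pre_ts, odor_quadrant_at_stimulus, window)
    remapped = remap_quadrant(odor_quadrant_at_stimulus, rotation_applied)
    post = attraction_index(post_ts, remapped, post_window)
    return stim, post


# ---------------------------------------------------------------------------
# egg statistics
# ---------------------------------------------------------------------------

def _opi_from_counts(counts: np.ndarray, odor_index: int) -> OvipositionResult:
    e_o = int(counts[odor_index])
    others = np.delete(counts, odor_index)
    e_avg = float(others.mean())
    if e_o + e_avg == 0:
        raise UndefinedStatisticError("index undefined: no eggs in any region")
    opi = (e_o - e_avg) / (e_o + e_avg)
    return OvipositionResult(
        E_o=e_o,
        E_avg=e_avg,
        OPI=float(opi),
        per_region_counts=tuple(int(c) for c in counts),
        total_eggs=int(counts.sum()),
        odor_region=odor_index,
    )


def egg_quadrant_counts(
    eggs: pd.DataFrame, arena: ArenaGeometry, odor_quadrant: Quadrant
) -> OvipositionResult:
    """Per-quadrant egg counts of a 4-quadrant egg table, with the odor
    contrast (E_o vs mean of the three control quadrants).

    ``eggs`` needs columns x_cm, y_cm; positions are labelled through the
    arena geometry (axis / out-of-mask eggs excluded from all counts).
    """
    if odor_quadrant is Quadrant.NONE:
        raise ValueError("odor_quadrant must be one of Q1..Q4")
    x = eggs["x_cm"].to_numpy(float)
    y = eggs["y_cm"].to_numpy(float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("egg coordinates must be finite")
    counts = _quadrant_counts(x, y, arena)
    return _opi_from_counts(counts, odor_quadrant.index)


def oviposition_preference_index(
    per_well_counts, odor_well: int
) -> OvipositionResult:
    """OPI of a 3-well assay from its per-well egg counts.

    ``odor_well`` is the 0-based index of the odor well; E_avg is the mean
    of the two control wells.
    """
    counts = np.asarray(per_well_counts, dtype=int)
    if counts.shape != (3,):
        raise ValueError("per_well_counts must be 3 counts")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if not 0 <= odor_well < 3:
        raise ValueError("odor_well must be 0, 1 or 2")
    return _opi_from_counts(counts, odor_well)


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def occupancy_heatmap(ts: TrackSet, bin_size_cm: float = 0.5) -> OccupancyMap:
    """2-D histogram of all in-mask positional samples."""
    if bin_size_cm <= 0:
        raise ValueError("bin_size_cm must be positive")
    from shapely import contains_xy

    df = ts.to_dataframe()
    side = ts.arena.side_length

    def axis_edges(lo: float) -> np.ndarray:
        e = np.arange(lo, lo + side + bin_size_cm * 0.5, bin_size_cm)
        return e if e[-1] >= lo + side else np.append(e, lo + side)

    x = df["x_cm"].to_numpy(float)
    y = df["y_cm"].to_numpy(float)
    inside = contains_xy(ts.arena.mask, x, y)
    counts, xe, ye = np.histogram2d(
        x[inside],
        y[inside],
        bins=[axis_edges(ts.arena.origin[0]), axis_edges(ts.arena.origin[1])],
    )
    return OccupancyMap(
        x_edges=xe, y_edges=ye, counts=counts, bin_size_cm=bin_size_cm
    )


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def compare_groups(values_by_group, welch: bool = False) -> dict:
    """Two-sample t-test (2 groups) or one-way ANOVA (> 2 groups).

    ``values_by_group`` is a mapping name -> values or a sequence of value
    sequences; the sampling unit is the trial (one replicate arena run per
    value).  Student's equal-variance t-test by default; ``welch=True``
    selects Welch's.  p-values are reported raw (no multiplicity
    correction).  Degenerate input (any group with n < 2, or zero pooled
    variance) raises :class:`DegenerateDataError`.
    """
    if isinstance(values_by_group, dict):
        names = list(values_by_group.keys())
        groups = [np.asarray(list(v), dtype=float) for v in values_by_group.values()]
    else:
        groups = [np.asarray(list(v), dtype=float) for v in values_by_group]
        names = [f"group{i + 1}" for i in range(len(groups))]
    if len(groups) < 2:
        raise DegenerateDataError("need at least 2 groups")
    for name, g in zip(names, groups):
        if g.size < 2:
            raise DegenerateDataError(f"group {name!r} has fewer than 2 values")
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        raise DegenerateDataError("all groups constant and equal: test undefined")

    if len(groups) == 2:
        res = sps.ttest_ind(groups[0], groups[1], equal_var=not welch)
        test_name = "welch_t" if welch else "student_t"
    else:
        res = sps.f_oneway(*groups)
        test_name = "one_way_anova"
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "test_name": test_name,
        "n_per_group": [int(g.size) for g in groups],
        "group_names": names,
    }
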