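"""Windowed spike-count and EAG-deflection response measures.

Single-sensillum responses are quantified as a windowed spike-rate change:
spikes are counted in a 1000-ms window beginning 500 ms after the stimulus
trigger, the count in the 1000-ms window immediately before stimulation is
subtracted, and the response evoked by the control solvent -- computed the
same way -- is subtracted in turn:

    corrected = (odor_post - odor_pre) - (solvent_post - solvent_pre)

Because both windows are 1 s long the counts are already rates in
spikes/s.  Windows are half-open [a, b): a spike exactly at the left edge
counts, one exactly at the right edge does not (standard histogram
convention; the boundary behavior is part of the tested contract).

EAG responses are the greatest voltage deflection from the baseline mean,
searched over a configurable response window (default: stimulus onset to
onset + 3 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EAGMeasurement",
    "SSRResponse",
    "SpikeTrain",
    "delta_spikes",
    "dose_response_table",
    "eag_peak",
    "solvent_corrected_response",
]

#: Pre-stimulus window relative to onset, s (half-open).
PRE_WINDOW = (-1.0, 0.0)
#: Response window relative to onset, s: 1000 ms starting 500 ms after trigger.
POST_WINDOW = (0.5, 1.5)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one trial, with stimulus metadata.

    ``label`` distinguishes odor, solvent and unstimulated trials.
    """

    spike_times: np.ndarray
    stim_onset: float
    trial_duration: float
    label: str = "none"

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float).ravel()
        object.__setattr__(self, "spike_times", st)
        if st.size and (np.any(np.diff(st) < 0)):
            raise ValueError("spike_times must be sorted ascending")
        if st.size and (st[0] < 0 or st[-1] > self.trial_duration):
            raise ValueError("spike_times must lie within [0, trial_duration]")
        if self.label not in ("odor", "solvent", "none"):
            raise ValueError(f"unknown label {self.label!r}")

    def shift(self, delta: float) -> "SpikeTrain":
        """Same train translated in time by ``delta`` s."""
        return SpikeTrain(
            spike_times=self.spike_times + delta,
            stim_onset=self.stim_onset + delta,
            trial_duration=self.trial_duration + delta,
            label=self.label,
        )


@dataclass(frozen=True)
class SSRResponse:
    """Windowed spike response: counts, rate change, solvent correction.

    ``delta`` is post_count - pre_count in spikes/s (1-s windows).
    ``solvent_corrected`` is None when no solvent trial was measured --
    a missing control is never assumed to be zero.
    """

    pre_count: int
    post_count: int
    delta: float
    solvent_corrected: float | None = None


def _count_in_window(train: SpikeTrain, a: float, b: float) -> int:
    """Spikes in the half-open window [a, b) (absolute times)."""
    st = train.spike_times
    return int(np.count_nonzero((st >= a) & (st < b)))


def delta_spikes(train: SpikeTrain) -> SSRResponse:
    """Windowed spike-rate change of one trial.

    Requires the pre window to fit before the onset (onset >= 1 s) and the
    post window to fit inside the trial (onset + 1.5 s <= duration).
    """
    onset = train.stim_onset
    if onset + PRE_WINDOW[0] < 0:
        raise ValueError("pre-stimulus window extends before the trial start")
    if onset + POST_WINDOW[1] > train.trial_duration:
        raise ValueError("response window extends past the trial end")
    pre = _count_in_window(train, onset + PRE_WINDOW[0], onset + PRE_WINDOW[1])
    post = _count_in_window(train, onset + POST_WINDOW[0], onset + POST_WINDOW[1])
    return SSRResponse(pre_count=pre, post_count=post, delta=float(post - pre))


def solvent_corrected_response(odor: SpikeTrain, solvent: SpikeTrain) -> SSRResponse:
    """Odor response minus the response to the control solvent.

    Both operands are reduced with :func:`delta_spikes`; the result carries
    the odor trial's window counts with ``solvent_corrected`` filled in.
    """
    od = delta_spikes(odor)
    sv = delta_spikes(solvent)
    return SSRResponse(
        pre_count=od.pre_count,
        post_count=od.post_count,
        delta=od.delta,
        solvent_corrected=od.delta - sv.delta,
    )


@dataclass(frozen=True)
class EAGMeasurement:
    """Greatest-deflection quantification of one EAG trace."""

    peak_deflection_mV: float
    peak_time_s: float
    baseline_mean_mV: float


def eag_peak(
    trace: np.ndarray,
    fs: float,
    baseline_window: tuple[float, float],
    response_window: tuple[float, float],
) -> EAGMeasurement:
    """Greatest absolute deflection from the baseline mean.

    ``trace`` is the sampled voltage (mV) at rate ``fs``; windows are in
    seconds from the trace start, half-open in samples.
    """
    v = np.asarray(trace, dtype=float).ravel()
    if fs <= 0:
        raise ValueError("fs must be positive")

    def to_slice(w: tuple[float, float]) -> slice:
        i0 = int(round(w[0] * fs))
        i1 = int(round(w[1] * fs))
        if not (0 <= i0 < i1 <= v.size):
            raise ValueError(f"window {w} is empty or outside the trace")
        return slice(i0, i1)

    base = float(v[to_slice(baseline_window)].mean())
    rs = to_slice(response_window)
    dev = np.abs(v[rs] - base)
    k = int(np.argmax(dev))
    return EAGMeasurement(
        peak_deflection_mV=float(dev[k]),
        peak_time_s=(rs.start + k) / fs,
        baseline_mean_mV=base,
    )


def dose_response_table(responses_by_dose: dict) -> pd.DataFrame:
    """Per-dose summary of response replicates: mean, SEM, n.

    ``responses_by_dose`` maps a dose/dilution label to a sequence of
    scalar responses.  SEM is null for a single replicate rather than 0.
    """
    rows = []
    for dose, vals in responses_by_dose.items():
        vals = np.asarray(list(vals), dtype=float)
        if vals.size < 1:
            raise ValueError(f"dose {dose!r} has no replicates")
        sem = (
            float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else None
        )
        rows.append(
            {"dose": dose, "mean": float(vals.mean()), "sem": sem, "n": int(vals.size)}
        )
    return pd.DataFrame(rows, columns=["dose", "mean", "sem", "n"])
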