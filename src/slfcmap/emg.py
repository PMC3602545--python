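"""Visceromotor response (VMR) quantification from abdominal EMG.

The VMR to colorectal distension (CRD) is quantified the standard way:
high-pass ("lowcut") filtering at 20 Hz to remove movement interference,
full-wave rectification, then the area under the rectified curve (AUC) over
each 20-s distension epoch normalized by the immediately preceding 20-s
baseline, and finally expressed as a percentage of the day-0 60-mmHg
response.

The filter is a zero-phase 4th-order Butterworth high-pass (forward-backward
application keeps the AUC windows phase-neutral); integration is trapezoidal
on the sample grid.  Normalization defaults to the ratio raw/baseline, with
baseline subtraction available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .errors import SpecificationError, WindowError

#: default CRD series: two repeats of 10/20/40/60 mmHg, 20-s phasic
#: distensions at 4-min interstimulus intervals
CRD_PRESSURES_MMHG = (10, 20, 40, 60)
CRD_EPOCH_S = 20.0
CRD_ISI_S = 240.0


@dataclass(frozen=True)
class Epoch:
    """One distension event: onset (s), duration (s), pressure, day label."""

    onset_s: float
    duration_s: float = CRD_EPOCH_S
    pressure_mmhg: float | None = None
    day: int | None = None

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class EMGTrace:
    """An EMG record with distension-epoch annotations."""

    samples: np.ndarray
    fs: float
    epochs: list[Epoch] = field(default_factory=list)
    rectified: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("EMG trace must be 1D")
        if self.fs <= 40:
            raise SpecificationError(
                "fs must exceed 40 Hz (filter corner below Nyquist)")
        self.epochs = sorted(self.epochs, key=lambda e: e.onset_s)
        dur = len(self.samples) / self.fs
        for e in self.epochs:
            if e.onset_s < 0 or e.end_s > dur + 1e-9:
                raise SpecificationError(f"epoch at {e.onset_s}s outside record")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if a.end_s > b.onset_s + 1e-9:
                raise SpecificationError("epochs overlap")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class EpochAUC:
    """Rectified AUC of one epoch: raw, baseline, and their ratio."""

    epoch: Epoch
    raw_auc: float
    baseline_auc: float
    normalized: float          # NaN when the baseline AUC is zero
    baseline_zero: bool = False


@dataclass(frozen=True)
class VMRResult(EpochAUC):
    """EpochAUC plus the percent-of-control scaling."""

    percent_of_control: float = float("nan")


def default_crd_epochs(day: int = 0, start_s: float = 60.0,
                       pressures: Sequence[float] = CRD_PRESSURES_MMHG,
                       repeats: int = 2) -> list[Epoch]:
    """The default CRD epoch template: ``repeats`` series of phasic
    distensions at each pressure, 20-s long, 4-min apart."""
    epochs, t = [], start_s
    for _ in range(repeats):
        for p in pressures:
            epochs.append(Epoch(onset_s=t, duration_s=CRD_EPOCH_S,
                                pressure_mmhg=p, day=day))
            t += CRD_EPOCH_S + CRD_ISI_S
    return epochs


def highpass_rectify(trace: EMGTrace, corner_hz: float = 20.0) -> EMGTrace:
    """Zero-phase 4th-order Butterworth high-pass, then full-wave rectify."""
    if corner_hz >= trace.fs / 2:
        raise ValueError(
            f"corner {corner_hz} Hz must be below Nyquist ({trace.fs / 2} Hz)")
    if trace.rectified:
        return replace(trace, samples=np.abs(trace.samples))
    sos = butter(4, corner_hz, btype="highpass", fs=trace.fs, output="sos")
    filtered = sosfiltfilt(sos, trace.samples)
    return replace(trace, samples=np.abs(filtered), rectified=True)


def epoch_auc(trace: EMGTrace, epoch: Epoch, baseline_s: float = 20.0,
              mode: str = "ratio") -> EpochAUC:
    """Trapezoidal AUC over the epoch and the preceding baseline window.

    ``mode='ratio'`` (default) normalizes as raw/baseline; ``mode='subtract'``
    as raw − baseline.  Requires ``baseline_s`` of signal before onset.
    """
    if mode not in ("ratio", "subtract"):
        raise ValueError("mode must be 'ratio' or 'subtract'")
    if not trace.rectified:
        raise ValueError("epoch_auc expects a rectified trace")
    fs = trace.fs
    if epoch.onset_s - baseline_s < -1e-9:
        raise WindowError(
            f"epoch at {epoch.onset_s}s lacks {baseline_s}s of baseline")
    i_on = int(round(epoch.onset_s * fs))
    i_off = int(round(epoch.end_s * fs))
    i_base = int(round((epoch.onset_s - baseline_s) * fs))
    if i_off > len(trace.samples):
        raise WindowError(f"epoch at {epoch.onset_s}s runs past the record")
    dx = 1.0 / fs
    raw = float(np.trapezoid(trace.samples[i_on:i_off + 1], dx=dx))
    baseline = float(np.trapezoid(trace.samples[i_base:i_on + 1], dx=dx))
    if mode == "subtract":
        return EpochAUC(epoch, raw, baseline, raw - baseline)
    if baseline == 0.0:
        return EpochAUC(epoch, raw, baseline, float("nan"),
                        baseline_zero=True)
    return EpochAUC(epoch, raw, baseline, raw / baseline)


def percent_of_control(results: Iterable[EpochAUC],
                       reference: EpochAUC | None = None) -> list[VMRResult]:
    """Scale normalized AUCs to percent of the day-0 60-mmHg reference.

    When ``reference`` is omitted it is located among ``results`` (day 0,
    60 mmHg); a missing or undefined reference is a configuration error.
    """
    results = list(results)
    if reference is None:
        candidates = [r for r in results
                      if r.epoch.day == 0 and r.epoch.pressure_mmhg == 60]
        if not candidates:
            raise SpecificationError(
                "no day-0 60-mmHg reference epoch among the results")
        reference = candidates[0]
    if not np.isfinite(reference.normalized) or reference.normalized == 0:
        raise SpecificationError("reference epoch has undefined AUC ratio")
    return [VMRResult(r.epoch, r.raw_auc, r.baseline_auc, r.normalized,
                      r.baseline_zero,
                      percent_of_control=100.0 * r.normalized
                      / reference.normalized)
            for r in results]


def quantify_vmr(trace: EMGTrace, corner_hz: float = 20.0,
                 baseline_s: float = 20.0, mode: str = "ratio",
                 animal_id: str = "") -> pd.DataFrame:
    """Filter + rectify a trace and tabulate per-epoch AUCs.

    Returns a tidy table (animal, day, pressure, raw/baseline/normalized
    AUC, percent of control) with the two repeats per pressure averaged into
    the ``normalized_mean`` column.  Group statistics on these tables are
    left to general-purpose tooling.
    """
    rect = highpass_rectify(trace, corner_hz)
    aucs = [epoch_auc(rect, e, baseline_s=baseline_s, mode=mode)
            for e in rect.epochs]
    scaled = percent_of_control(aucs)
    rows = [{
        "animal": animal_id,
        "day": r.epoch.day,
        "pressure_mmhg": r.epoch.pressure_mmhg,
        "onset_s": r.epoch.onset_s,
        "raw_auc": r.raw_auc,
        "baseline_auc": r.baseline_auc,
        "normalized_auc": r.normalized,
        "percent_of_control": r.percent_of_control,
    } for r in scaled]
    table = pd.DataFrame(rows)
    means = (table.groupby(["animal", "day", "pressure_mmhg"], dropna=False)
             ["normalized_auc"].transform("mean"))
    table["normalized_mean"] = means
    return table
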