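"""Time–activity curve data model and I/O.

This module holds the measurement-side containers of the pipeline:

* :class:`FrameSchedule` — frame start/end times in minutes, possibly with
  gaps (multi-session protocols park the subject between scan blocks);
* :class:`TimeActivityCurve` — decay-corrected regional concentration per
  frame, in kBq/mL;
* :class:`InputFunctionSamples` — discrete arterial samples (total plasma,
  whole blood, parent fraction);
* :class:`RoiMask` and ROI extraction from 4D images;
* :func:`interpolate_input` — a continuous arterial input model built from
  discrete samples, the object every kinetic fit consumes.

Conventions: time is minutes everywhere, concentrations kBq/mL, and decay
correction to injection time is assumed to have been applied upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .errors import ExtrapolationError, FormatError, ScheduleError

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "InputFunctionSamples",
    "RoiMask",
    "ContinuousInput",
    "InterpolatedInput",
    "read_tac_table",
    "write_tac_table",
    "extract_roi_tac",
    "read_image_tacs",
    "interpolate_input",
]

TAC_COLUMNS = ["subject_id", "region", "frame_start_min", "frame_end_min", "kBq_per_mL"]


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, non-overlapping PET frames in minutes. Gaps are allowed."""

    start: np.ndarray
    end: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        end = np.asarray(self.end, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ScheduleError("frame start/end must be equal-length 1-D arrays")
        bad = np.nonzero(end <= start)[0]
        if bad.size:
            raise ScheduleError(f"frame_end <= frame_start at frame index {bad[0]}")
        if np.any(np.diff(start) <= 0):
            raise ScheduleError("frame starts must be strictly ascending")
        overlap = np.nonzero(start[1:] < end[:-1] - 1e-9)[0]
        if overlap.size:
            raise ScheduleError(f"frames {overlap[0]} and {overlap[0] + 1} overlap")

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def mid(self) -> np.ndarray:
        """Frame midpoints, used for plotting and MA1 regression times."""
        return 0.5 * (self.start + self.end)

    @property
    def duration(self) -> np.ndarray:
        return self.end - self.start

    @property
    def total_end(self) -> float:
        return float(self.end[-1])

    def truncate(self, t_end: float) -> "FrameSchedule":
        """Keep frames whose end does not exceed ``t_end`` minutes."""
        keep = self.end <= t_end + 1e-9
        if not np.any(keep):
            raise ScheduleError(f"no frames end at or before {t_end} min")
        return FrameSchedule(self.start[keep], self.end[keep], self.label)

    def frame_mask(self, t_end: float) -> np.ndarray:
        return self.end <= t_end + 1e-9


@dataclass
class TimeActivityCurve:
    """Decay-corrected regional concentration trace, kBq/mL per frame."""

    schedule: FrameSchedule
    concentration: np.ndarray
    region: str
    subject_id: str
    has_noise_model: bool = False

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentration, dtype=float)
        self.concentration = conc
        if conc.shape != (self.schedule.n_frames,):
            raise FormatError(
                f"concentration length {conc.size} != {self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(conc)):
            raise FormatError("concentrations must be finite")
        if not self.has_noise_model and np.any(conc < 0):
            raise FormatError(
                "negative concentrations only permitted with an attached noise model"
            )

    def truncate(self, t_end: float) -> "TimeActivityCurve":
        keep = self.schedule.frame_mask(t_end)
        return TimeActivityCurve(
            self.schedule.truncate(t_end),
            self.concentration[keep],
            self.region,
            self.subject_id,
            self.has_noise_model,
        )


@dataclass
class InputFunctionSamples:
    """Discrete arterial samples: total plasma, whole blood, parent fraction."""

    sample_time: np.ndarray
    total_plasma: np.ndarray
    whole_blood: np.ndarray
    parent_fraction: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_time, dtype=float)
        self.sample_time = t
        for name in ("total_plasma", "whole_blood", "parent_fraction"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != t.shape:
                raise FormatError(f"{name} length differs from sample_time")
        if np.any(np.diff(t) <= 0):
            raise FormatError("sample times must be strictly ascending")
        pf = self.parent_fraction
        if np.any((pf < 0) | (pf > 1)):
            raise FormatError("parent fraction must lie in [0, 1]")

    @property
    def n(self) -> int:
        return int(self.sample_time.size)


@dataclass
class RoiMask:
    """Boolean voxel-inclusion mask for one named region."""

    data: np.ndarray
    region: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise FormatError("RoiMask expects a 3-D voxel grid")
        if not self.data.any():
            raise FormatError(f"mask for region '{self.region}' selects no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@runtime_checkable
class ContinuousInput(Protocol):
    """Continuous-time arterial input model used by all kinetic estimators.

    Implementations must be vectorised over ``t`` (minutes) and return
    concentrations in kBq/mL.  ``t_max`` is the end of the supported domain
    (``inf`` for closed-form models or when tail extrapolation is enabled).
    """

    t_max: float

    def total_plasma(self, t: np.ndarray) -> np.ndarray: ...

    def parent_fraction(self, t: np.ndarray) -> np.ndarray: ...

    def parent_plasma(self, t: np.ndarray) -> np.ndarray: ...

    def whole_blood(self, t: np.ndarray) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# Tabular I/O


def read_tac_table(path: str | Path) -> list[TimeActivityCurve]:
    """Read a TAC CSV into one curve per (subject, region).

    The CSV must contain the columns ``subject_id, region, frame_start_min,
    frame_end_min, kBq_per_mL``.  Schedule invariants are validated per curve
    and violations are reported with the offending CSV row number (1-based,
    excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"TAC table {path} is missing columns: {missing}")
    out: list[TimeActivityCurve] = []
    for (subject, region), grp in df.groupby(["subject_id", "region"], sort=True):
        grp = grp.sort_values("frame_start_min")
        start = grp["frame_start_min"].to_numpy(float)
        end = grp["frame_end_min"].to_numpy(float)
        bad = np.nonzero(end <= start)[0]
        if bad.size:
            row = int(grp.index[bad[0]]) + 1
            raise ScheduleError(
                f"frame_end <= frame_start at table row {row} "
                f"(subject {subject}, region {region})"
            )
        schedule = FrameSchedule(start, end, label=str(region))
        conc = grp["kBq_per_mL"].to_numpy(float)
        out.append(
            TimeActivityCurve(
                schedule, conc, str(region), str(subject), has_noise_model=True
            )
        )
    return out


def write_tac_table(tacs: Sequence[TimeActivityCurve], path: str | Path) -> None:
    """Write curves to CSV (inverse of :func:`read_tac_table`)."""
    rows = []
    for tac in tacs:
        for s, e, c in zip(tac.schedule.start, tac.schedule.end, tac.concentration):
            rows.append((tac.subject_id, tac.region, s, e, c))
    pd.DataFrame(rows, columns=TAC_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Image-side extraction


def extract_roi_tac(
    image4d: np.ndarray, mask: RoiMask, schedule: FrameSchedule, subject_id: str = ""
) -> TimeActivityCurve:
    """Unweighted mean over included voxels, per frame.

    ``image4d`` is (x, y, z, frame).  Partial-volume weighting is out of
    scope; every included voxel counts equally.
    """
    img = np.asarray(image4d, dtype=float)
    if img.ndim != 4:
        raise FormatError("image must be 4-D (x, y, z, frame)")
    if img.shape[:3] != mask.data.shape:
        raise FormatError(
            f"mask grid {mask.data.shape} does not match image grid {img.shape[:3]}"
        )
    if img.shape[3] != schedule.n_frames:
        raise FormatError(
            f"image has {img.shape[3]} frames but schedule has {schedule.n_frames}"
        )
    conc = img[mask.data, :].mean(axis=0)
    return TimeActivityCurve(
        schedule, conc, mask.region, subject_id, has_noise_model=True
    )


def read_image_tacs(
    image_path: str | Path,
    sidecar_path: str | Path,
    masks: Sequence[tuple[str | Path, str]] | Sequence[RoiMask],
    subject_id: str = "",
) -> list[TimeActivityCurve]:
    """Extract regional TACs from a 4-D NIfTI plus a frame-timing sidecar.

    ``sidecar_path`` is a JSON file with keys ``frame_start_min`` and
    ``frame_end_min``.  ``masks`` is either a list of ``(nifti_path, region)``
    pairs (nonzero voxels included) or prepared :class:`RoiMask` objects.
    """
    import nibabel as nib

    img = np.asarray(nib.load(str(image_path)).get_fdata(), dtype=float)
    with open(sidecar_path) as fh:
        timing = json.load(fh)
    try:
        schedule = FrameSchedule(
            np.asarray(timing["frame_start_min"], float),
            np.asarray(timing["frame_end_min"], float),
        )
    except KeyError as exc:
        raise FormatError(f"sidecar missing key {exc}") from exc
    out = []
    for entry in masks:
        if isinstance(entry, RoiMask):
            mask = entry
        else:
            mask_path, region = entry
            mdata = np.asarray(nib.load(str(mask_path)).get_fdata()) != 0
            mask = RoiMask(mdata, str(region))
        out.append(extract_roi_tac(img, mask, schedule, subject_id))
    return out


# ---------------------------------------------------------------------------
# Continuous input model from discrete samples


def _hill_parent_fraction(t: np.ndarray, floor: float, t50: float, slope: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(t > 0, t / t50, 0.0)
    return floor + (1.0 - floor) / (1.0 + ratio**slope)


class _PeakedCurve:
    """Piecewise-linear before the sampled peak, log-linear (exponential
    between samples) after it; avoids negative overshoot on washout."""

    def __init__(self, t: np.ndarray, y: np.ndarray):
        self.t = t
        self.y = y
        self.i_peak = int(np.argmax(y))
        # log-linear interpolation only valid on strictly positive samples
        post = y[self.i_peak:]
        self.log_ok = bool(np.all(post > 0))
        self.log_y = np.log(np.maximum(y, 1e-300))

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lin = np.interp(t, self.t, self.y)
        if not self.log_ok:
            return lin
        geo = np.exp(np.interp(t, self.t, self.log_y))
        return np.where(t <= self.t[self.i_peak], lin, geo)


class InterpolatedInput:
    """Continuous input model constructed from :class:`InputFunctionSamples`.

    Total plasma and whole blood are interpolated piecewise-linearly up to
    their sampled peak and exponentially (linear in log) between samples
    afterwards; the parent fraction is a fitted 3-parameter Hill function of
    time (monotone non-increasing, bounded in [floor, 1]).  Queries outside
    the sampled range raise :class:`ExtrapolationError` unless a
    mono-exponential tail was enabled at construction.
    """

    def __init__(
        self, samples: InputFunctionSamples, allow_tail_extrapolation: bool = False
    ):
        if samples.n < 4:
            raise FormatError("need at least 4 input samples")
        self.samples = samples
        self._plasma = _PeakedCurve(samples.sample_time, samples.total_plasma)
        self._blood = _PeakedCurve(samples.sample_time, samples.whole_blood)
        self._t0 = float(samples.sample_time[0])
        self._t_end = float(samples.sample_time[-1])
        self.allow_tail = bool(allow_tail_extrapolation)
        self.t_max = np.inf if self.allow_tail else self._t_end
        self._fit_parent_fraction()
        self._fit_tail()

    def _fit_parent_fraction(self) -> None:
        from scipy.optimize import curve_fit

        t = self.samples.sample_time
        pf = self.samples.parent_fraction
        if np.allclose(pf, pf[0]):
            c = float(pf[0])
            self._pf_params = None
            self._pf_const = c
            return
        self._pf_const = None
        p0 = (max(float(pf.min()), 1e-3), max(np.median(t), 1.0), 1.5)
        bounds = ([0.0, 1e-3, 0.3], [1.0, 1e4, 10.0])
        popt, _ = curve_fit(
            _hill_parent_fraction, t, pf, p0=p0, bounds=bounds, maxfev=20000
        )
        self._pf_params = tuple(float(v) for v in popt)

    def _fit_tail(self) -> None:
        # mono-exponential through the last two samples of each curve
        def tail(curve: _PeakedCurve) -> tuple[float, float]:
            t1, t2 = curve.t[-2], curve.t[-1]
            y1, y2 = curve.y[-2], curve.y[-1]
            if y1 > 0 and y2 > 0 and y2 < y1:
                lam = np.log(y1 / y2) / (t2 - t1)
            else:
                lam = 0.0
            return float(y2), float(lam)

        self._plasma_tail = tail(self._plasma)
        self._blood_tail = tail(self._blood)

    def _check_domain(self, t: np.ndarray) -> None:
        t = np.asarray(t, dtype=float)
        if np.any(t < self._t0 - 1e-9):
            raise ExtrapolationError(
                f"query before first sample at {self._t0} min"
            )
        if not self.allow_tail and np.any(t > self._t_end + 1e-9):
            raise ExtrapolationError(
                f"query beyond last sample at {self._t_end} min; "
                "enable tail extrapolation to allow this"
            )

    def _eval(self, curve: _PeakedCurve, tail: tuple[float, float], t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        self._check_domain(t)
        out = curve(np.clip(t, self._t0, self._t_end))
        if self.allow_tail:
            y_end, lam = tail
            beyond = t > self._t_end
            if np.any(beyond):
                out = np.where(
                    beyond, y_end * np.exp(-lam * (t - self._t_end)), out
                )
        return out

    def total_plasma(self, t) -> np.ndarray:
        return self._eval(self._plasma, self._plasma_tail, t)

    def whole_blood(self, t) -> np.ndarray:
        return self._eval(self._blood, self._blood_tail, t)

    def parent_fraction(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self._pf_const is not None:
            return np.full(t.shape, self._pf_const)
        return _hill_parent_fraction(t, *self._pf_params)

    def parent_plasma(self, t) -> np.ndarray:
        return self.total_plasma(t) * self.parent_fraction(t)


def interpolate_input(
    samples: InputFunctionSamples, allow_tail_extrapolation: bool = False
) -> InterpolatedInput:
    """Build a continuous arterial input model from discrete samples."""
    return InterpolatedInput(samples, allow_tail_extrapolation)


def read_input_samples(path: str | Path) -> InputFunctionSamples:
    """Read arterial samples from CSV with columns
    ``sample_time_min, total_plasma_kBq_per_mL, whole_blood_kBq_per_mL,
    parent_fraction``."""
    df = pd.read_csv(path)
    cols = [
        "sample_time_min",
        "total_plasma_kBq_per_mL",
        "whole_blood_kBq_per_mL",
        "parent_fraction",
    ]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"input table {path} missing columns: {missing}")
    return InputFunctionSamples(
        df[cols[0]].to_numpy(float),
        df[cols[1]].to_numpy(float),
        df[cols[2]].to_numpy(float),
        df[cols[3]].to_numpy(float),
    )


def write_input_samples(samples: InputFunctionSamples, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_time_min": samples.sample_time,
            "total_plasma_kBq_per_mL": samples.total_plasma,
            "whole_blood_kBq_per_mL": samples.whole_blood,
            "parent_fraction": samples.parent_fraction,
        }
    ).to_csv(path, index=False)
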