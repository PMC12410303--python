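"""Windowed semi-quantitative PET metrics and reliability measures.

SUV, SUVR (against metabolite-corrected plasma or terminal plasma), their
"−1" variants (which subtract the free-tracer contribution so that zero means
no specific signal), DVR from V_T ratios, test–retest variability, and the
mouse ex vivo biodistribution SUVR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .errors import WindowError
from .kinetics import KineticFit
from .tac_io import ContinuousInput, TimeActivityCurve

__all__ = [
    "StaticMetric",
    "TrtResult",
    "BiodistSample",
    "suv",
    "suvr_parent_plasma",
    "suvr_vt_agreement",
    "dvr",
    "test_retest",
    "cohort_test_retest",
    "biodist_suvr",
    "organ_weight_ratio",
]

DEFAULT_WINDOW = (255.0, 285.0)  # minutes; the selected late cardiac window


@dataclass(frozen=True)
class StaticMetric:
    """One windowed metric value with its provenance."""

    kind: str  # SUV | SUVR | SUVR_minus_1 | DVR | DVR_minus_1
    value: float
    window_start: float
    window_end: float
    reference: str  # parent plasma | terminal plasma | region name
    subject_id: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        if self.window_end <= self.window_start:
            raise WindowError(
                f"window ({self.window_start}, {self.window_end}) is malformed"
            )


@dataclass
class TrtResult:
    """Cohort test–retest summary for one region."""

    region: str
    trv_per_subject: np.ndarray  # percent
    mean: float
    sd: float


@dataclass(frozen=True)
class BiodistSample:
    """One ex vivo gamma-count measurement."""

    tissue: str
    tissue_concentration: float  # activity per gram
    terminal_plasma: float  # activity per gram
    injected_dose: float
    body_weight: float

    def __post_init__(self) -> None:
        if self.tissue_concentration < 0:
            raise ValueError("tissue concentration must be >= 0")
        if self.terminal_plasma <= 0:
            raise ValueError("terminal plasma concentration must be > 0 for SUVR")


def suv(concentration, injected_dose, body_weight):
    """SUV = concentration / (injected dose / body weight).

    Uses the g/mL ≈ 1 convention; pass unit-consistent arguments
    (e.g. kBq/mL, kBq, g — or any common rescaling).  Vectorised.
    """
    concentration = np.asarray(concentration, float)
    injected_dose = np.asarray(injected_dose, float)
    body_weight = np.asarray(body_weight, float)
    if np.any(injected_dose <= 0) or np.any(body_weight <= 0):
        raise ValueError("injected dose and body weight must be > 0")
    out = concentration / (injected_dose / body_weight)
    return float(out) if out.ndim == 0 else out


def _window_frames(tac: TimeActivityCurve, window: tuple[float, float]) -> np.ndarray:
    """Frames fully inside the closed-open window [start, end)."""
    w0, w1 = window
    if w1 <= w0:
        raise WindowError(f"window ({w0}, {w1}) is malformed")
    sched = tac.schedule
    inside = (sched.start >= w0 - 1e-9) & (sched.end <= w1 + 1e-9)
    if not inside.any():
        raise WindowError(
            f"no frames fully inside window ({w0}, {w1}); "
            f"TAC covers {sched.start[0]}–{sched.total_end} min"
        )
    return inside


def suvr_parent_plasma(
    tac: TimeActivityCurve,
    input_model: ContinuousInput,
    window: tuple[float, float] = DEFAULT_WINDOW,
    plasma_mode: str = "window_average",
) -> tuple[StaticMetric, StaticMetric]:
    """SUVR of tissue against metabolite-corrected (parent) plasma.

    Tissue is the frame-duration-weighted mean concentration over the
    window; the plasma reference is the time-average of the modelled parent
    plasma over the same window (``plasma_mode='window_average'``) or its
    value at the window midpoint (``'single_sample'``).  Returns the SUVR
    and SUVR−1 metrics (SUVR−1 is exactly SUVR − 1).
    """
    w0, w1 = float(window[0]), float(window[1])
    inside = _window_frames(tac, (w0, w1))
    if getattr(input_model, "t_max", np.inf) < w1 - 1e-9:
        raise WindowError("window extends beyond input-function support")
    dur = tac.schedule.duration[inside]
    tissue = float(np.sum(tac.concentration[inside] * dur) / np.sum(dur))
    if plasma_mode == "window_average":
        grid = np.linspace(w0, w1, max(int(round((w1 - w0) / 0.1)) + 1, 11))
        cp = np.asarray(input_model.parent_plasma(grid), float)
        plasma = float(integrate.trapezoid(cp, grid) / (w1 - w0))
    elif plasma_mode == "single_sample":
        plasma = float(np.asarray(input_model.parent_plasma(0.5 * (w0 + w1)))[0])
    else:
        raise ValueError("plasma_mode must be 'window_average' or 'single_sample'")
    if plasma <= 0:
        raise WindowError("plasma reference is non-positive over the window")
    ratio = tissue / plasma
    mk = lambda kind, value: StaticMetric(
        kind, value, w0, w1, "parent plasma", tac.subject_id, tac.region
    )
    return mk("SUVR", ratio), mk("SUVR_minus_1", ratio - 1.0)


def suvr_vt_agreement(
    metrics: Sequence[StaticMetric], fits: Sequence[KineticFit | object]
) -> pd.DataFrame:
    """Pearson correlation of SUVR against model V_T, per window.

    Pairs are matched on (subject_id, region); fits may be compartmental or
    MA1 results (anything with .subject_id, .region, .vt).  Windows with a
    constant SUVR are flagged with an undefined correlation rather than a
    spurious number.
    """
    vt_map = {(f.subject_id, f.region): f.vt for f in fits}
    rows = []
    by_window: dict[tuple[float, float], list[tuple[float, float]]] = {}
    for m in metrics:
        if m.kind not in ("SUVR", "SUVR_minus_1"):
            continue
        key = (m.subject_id, m.region)
        if key in vt_map and np.isfinite(vt_map[key]):
            by_window.setdefault((m.window_start, m.window_end), []).append(
                (m.value, vt_map[key])
            )
    if not by_window:
        raise WindowError("no matching (subject, region) pairs")
    for window, pairs in sorted(by_window.items()):
        if len(pairs) < 3:
            raise WindowError(
                f"window {window} has {len(pairs)} pairs; need at least 3"
            )
        x, y = np.array(pairs).T
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((*window, np.nan, np.nan, len(pairs), True))
        else:
            r, p = stats.pearsonr(x, y)
            rows.append((*window, r, p, len(pairs), False))
    return pd.DataFrame(
        rows,
        columns=["window_start", "window_end", "pearson_r", "p_value", "n", "flagged"],
    )


def dvr(vt_target: float, vt_reference: float) -> tuple[float, float]:
    """Distribution volume ratio and DVR−1.

    DVR = V_T(target)/V_T(reference); the plasma free fraction cancels, so
    DVR is invariant to any common scaling of the two V_T values.
    """
    if vt_reference <= 0:
        raise ValueError("reference V_T must be > 0")
    if vt_target <= 0:
        raise ValueError("target V_T must be > 0")
    ratio = vt_target / vt_reference
    return ratio, ratio - 1.0


def test_retest(test: float, retest: float) -> float:
    """Test–retest variability, percent: TRV = 200·|test − retest|/(test + retest).

    Symmetric in its arguments and bounded by 200%.  Returns NaN when the
    two measurements sum to zero or below (undefined).
    """
    if not (np.isfinite(test) and np.isfinite(retest)):
        raise ValueError("test and retest must both be finite")
    denom = test + retest
    if denom <= 0:
        return float("nan")
    return min(200.0 * abs(test - retest) / denom, 200.0)


def cohort_test_retest(
    pairs: Iterable[tuple[float, float]], region: str = ""
) -> TrtResult:
    """Mean ± SD of per-subject TRV over a cohort (NaN pairs flagged out)."""
    trv = np.array([test_retest(a, b) for a, b in pairs])
    valid = trv[np.isfinite(trv)]
    if valid.size == 0:
        raise ValueError("no defined test-retest pairs")
    return TrtResult(
        region=region,
        trv_per_subject=trv,
        mean=float(valid.mean()),
        sd=float(valid.std(ddof=1)) if valid.size > 1 else 0.0,
    )


def biodist_suvr(samples: Sequence[BiodistSample] | pd.DataFrame) -> pd.DataFrame:
    """Per-tissue SUVR relative to terminal plasma.

    Dose/weight normalisation cancels in the ratio; the plain ratio of
    activity concentrations is returned.  Accepts prepared
    :class:`BiodistSample` objects or the generator's biodistribution table.
    """
    if isinstance(samples, pd.DataFrame):
        df = samples
        if np.any(df["terminal_plasma_kBq_per_g"] <= 0):
            raise ValueError("terminal plasma must be > 0")
        if np.any(df["tissue_kBq_per_g"] < 0):
            raise ValueError("tissue concentrations must be >= 0")
        out = df.copy()
        out["suvr"] = out["tissue_kBq_per_g"] / out["terminal_plasma_kBq_per_g"]
        return out
    rows = [
        {"tissue": s.tissue, "suvr": s.tissue_concentration / s.terminal_plasma}
        for s in samples
    ]
    return pd.DataFrame(rows)


def organ_weight_ratio(organ_weight, body_weight):
    """Organ-to-body weight ratio (same mass unit for both). Vectorised."""
    organ_weight = np.asarray(organ_weight, float)
    body_weight = np.asarray(body_weight, float)
    if np.any(organ_weight <= 0) or np.any(body_weight <= 0):
        raise ValueError("weights must be > 0")
    out = organ_weight / body_weight
    return float(out) if out.ndim == 0 else out
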