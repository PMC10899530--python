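"""Single-cell responder analysis of KTR activity traces.

Implements the floor normalization (each cell's trace referenced to its
MEK-inhibited ERK activity), the per-cell paired t-test for a significant
pre- versus post-treatment change at alpha = 0.005, the maximum response
amplitude within 1 h of ligand addition, the 12-h area under the curve as a
surrogate for response duration, the population responder fraction with a
Wilson confidence interval, a logistic dose-response fit of the fraction,
and ensemble response-class assignment (transient / waning / sustained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .schedule import AcquisitionSchedule, AnalysisWindows
from .traces import TraceSet

__all__ = ["ResponderCall", "DoseResponseFit", "normalize_traces",
           "call_responder", "call_responders", "max_amplitude", "auc_12h",
           "responder_fraction", "wilson_interval", "fit_dose_response",
           "classify_response_class"]


# ---------------------------------------------------------------------------
# normalization


def normalize_traces(traces: TraceSet, mode: str = "divide") -> TraceSet:
    """Reference each cell's trace to its MEK-inhibited activity floor.

    Per cell, let ``m`` be the mean activity over the MEKi floor window.
    ``divide`` (default) rescales by ``1/m`` so the floor maps to exactly 1;
    ``subtract`` shifts by ``-m`` so the floor maps to exactly 0.  Cells
    with ``m <= 0`` in divide mode are dropped (a warning reports how many).
    """
    if mode not in ("divide", "subtract"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    schedule = traces.schedule
    win = schedule.meki_window_frames()
    if len(win) == 0:
        raise ValueError("schedule has no MEKi floor window")

    cell_ids, act, valid = traces.to_matrix()
    win_act = np.where(valid[:, win], act[:, win], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(win_act, axis=1)

    keep = np.isfinite(m)
    if mode == "divide":
        keep &= m > 0
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(
            f"normalize_traces: dropped {dropped} cell(s) with unusable "
            "MEKi floor", stacklevel=2)
    act, valid, m = act[keep], valid[keep], m[keep]
    cell_ids = cell_ids[keep]
    if mode == "divide":
        act = act / m[:, None]
    else:
        act = act - m[:, None]
    return TraceSet.from_matrix(act, schedule, valid=valid,
                                cell_ids=cell_ids,
                                condition=traces.condition,
                                dose_ng_ml=traces.dose_ng_ml)


# ---------------------------------------------------------------------------
# per-cell responder call

@dataclass
class ResponderCall:
    """Per-cell test decision plus response features.

    ``amplitude`` and ``auc`` are populated only for responders (cells with
    a significant response are the ones analyzed further).
    """

    cell_id: int
    p_value: float
    is_responder: bool
    direction: Literal["increase", "decrease", "none"] = "none"
    amplitude: float | None = None
    auc: float | None = None
    indeterminate: bool = False
    auc_low_confidence: bool = False


def _window_frames(times: np.ndarray, lo: float, hi: float,
                   closed: str) -> np.ndarray:
    if closed == "left":
        sel = (times >= lo) & (times < hi)
    elif closed == "right":
        sel = (times > lo) & (times <= hi)
    elif closed == "both":
        sel = (times >= lo) & (times <= hi)
    else:
        raise ValueError(closed)
    return np.nonzero(sel)[0]


def _cell_vectors(trace: pd.DataFrame) -> tuple[np.ndarray, np.ndarray,
                                                np.ndarray]:
    trace = trace.sort_values("frame")
    return (trace["time_min"].to_numpy(dtype=float),
            trace["activity"].to_numpy(dtype=float),
            trace["valid"].to_numpy(dtype=bool))


def call_responder(trace: pd.DataFrame, schedule: AcquisitionSchedule,
                   windows: AnalysisWindows | None = None,
                   policy: str = "increase_only") -> ResponderCall:
    """Paired pre/post t-test responder decision for one cell.

    The last ``k`` valid frames ending at the treatment time are paired,
    in order, with the first ``k`` valid frames after it
    (``k`` = the smaller window frame count); a two-sided paired t-test is
    applied to the differences.  Under the default ``increase_only`` policy
    a cell is a responder iff p < alpha and the post mean exceeds the pre
    mean; ``any`` accepts either direction.  Zero-variance differences give
    p = 1 (non-responder); fewer than 3 valid frames in either window
    flags the call indeterminate.
    """
    if policy not in ("increase_only", "any"):
        raise ValueError(f"unknown policy {policy!r}")
    windows = windows or AnalysisWindows()
    t, act, valid = _cell_vectors(trace)
    cid = int(trace["cell_id"].iloc[0])
    tx = schedule.treatment_time

    pre_idx = _window_frames(t, tx - windows.pre_window, tx, closed="right")
    post_idx = _window_frames(t, tx, tx + windows.post_window, closed="right")
    pre_idx = pre_idx[valid[pre_idx]]
    post_idx = post_idx[valid[post_idx]]
    if len(pre_idx) < 3 or len(post_idx) < 3:
        return ResponderCall(cell_id=cid, p_value=float("nan"),
                             is_responder=False, indeterminate=True)

    k = min(len(pre_idx), len(post_idx))
    pre = act[pre_idx[-k:]]
    post = act[post_idx[:k]]
    diff = post - pre
    if np.allclose(diff.std(ddof=1), 0.0):
        p = 1.0
        tstat = 0.0
    else:
        tstat, p = stats.ttest_rel(post, pre)
        p = float(p)

    increased = post.mean() > pre.mean()
    significant = p < windows.alpha
    if policy == "increase_only":
        is_resp = significant and increased
    else:
        is_resp = significant
    direction = "none"
    if significant:
        direction = "increase" if increased else "decrease"
    return ResponderCall(cell_id=cid, p_value=p, is_responder=is_resp,
                         direction=direction)


def max_amplitude(trace: pd.DataFrame, schedule: AcquisitionSchedule,
                  windows: AnalysisWindows | None = None) -> float | None:
    """Maximum baseline-subtracted activity within 1 h of ligand addition.

    The baseline ``b0`` is the mean activity over the pre-treatment window.
    Returns None when the amplitude window has no valid frames.
    """
    windows = windows or AnalysisWindows()
    t, act, valid = _cell_vectors(trace)
    tx = schedule.treatment_time
    pre = _window_frames(t, tx - windows.pre_window, tx, closed="right")
    pre = pre[valid[pre]]
    amp = _window_frames(t, tx, tx + windows.amplitude_window, closed="both")
    amp = amp[valid[amp]]
    if len(pre) == 0 or len(amp) == 0:
        return None
    b0 = act[pre].mean()
    return float(np.max(act[amp]) - b0)


def auc_12h(trace: pd.DataFrame, schedule: AcquisitionSchedule,
            windows: AnalysisWindows | None = None,
            ) -> tuple[float | None, bool]:
    """Trapezoidal AUC of baseline-subtracted activity over the 12-h window.

    Invalid frames are linearly interpolated; the integrand is not clipped
    at zero.  Returns ``(auc_activity_hours, low_confidence)`` where
    ``low_confidence`` is set when more than 25% of window frames are
    invalid; AUC is None when no valid frames fall in the window.
    """
    windows = windows or AnalysisWindows()
    t, act, valid = _cell_vectors(trace)
    tx = schedule.treatment_time
    pre = _window_frames(t, tx - windows.pre_window, tx, closed="right")
    pre = pre[valid[pre]]
    win = _window_frames(t, tx, tx + windows.auc_window, closed="both")
    if len(win) == 0 or len(pre) == 0:
        return None, False
    win_valid = valid[win]
    if not win_valid.any():
        return None, False
    b0 = act[pre].mean()
    tw = t[win]
    y = act[win].copy()
    if not win_valid.all():
        y[~win_valid] = np.interp(tw[~win_valid], tw[win_valid],
                                  y[win_valid])
    low_conf = (~win_valid).mean() > 0.25
    auc_min = float(np.trapezoid(y - b0, tw))
    return auc_min / 60.0, low_conf


def call_responders(traces: TraceSet,
                    windows: AnalysisWindows | None = None,
                    policy: str = "increase_only") -> list[ResponderCall]:
    """Run the responder analysis for every cell in a TraceSet.

    Responders are further analyzed for amplitude and AUC; non-responders
    carry only the test result.  Ensembles with no invalid frames take a
    vectorized path that is numerically identical to the per-cell one.
    """
    windows = windows or AnalysisWindows()
    cell_ids, act, valid = traces.to_matrix()
    if valid.all() and len(cell_ids):
        return _call_responders_vectorized(
            cell_ids, act, traces.schedule, windows, policy)
    calls = []
    for cid, cell in traces.iter_cells():
        call = call_responder(cell, traces.schedule, windows, policy)
        if call.is_responder:
            call.amplitude = max_amplitude(cell, traces.schedule, windows)
            call.auc, call.auc_low_confidence = auc_12h(
                cell, traces.schedule, windows)
        calls.append(call)
    return calls


def _call_responders_vectorized(cell_ids: np.ndarray, act: np.ndarray,
                                schedule: AcquisitionSchedule,
                                windows: AnalysisWindows,
                                policy: str) -> list[ResponderCall]:
    if policy not in ("increase_only", "any"):
        raise ValueError(f"unknown policy {policy!r}")
    t = schedule.times
    tx = schedule.treatment_time
    pre_idx = _window_frames(t, tx - windows.pre_window, tx, closed="right")
    post_idx = _window_frames(t, tx, tx + windows.post_window,
                              closed="right")
    if min(len(pre_idx), len(post_idx)) < 3:
        return [ResponderCall(cell_id=int(c), p_value=float("nan"),
                              is_responder=False, indeterminate=True)
                for c in cell_ids]
    k = min(len(pre_idx), len(post_idx))
    pre = act[:, pre_idx[-k:]]
    post = act[:, post_idx[:k]]
    d = post - pre
    sd = d.std(axis=1, ddof=1)
    dmean = d.mean(axis=1)
    zero_var = np.isclose(sd, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = dmean / (sd / np.sqrt(k))
    p = 2 * stats.t.sf(np.abs(tstat), df=k - 1)
    p = np.where(zero_var, 1.0, p)
    increased = post.mean(axis=1) > pre.mean(axis=1)
    significant = p < windows.alpha
    is_resp = significant & increased if policy == "increase_only" \
        else significant

    b0 = act[:, pre_idx].mean(axis=1)
    amp_idx = _window_frames(t, tx, tx + windows.amplitude_window,
                             closed="both")
    amplitude = act[:, amp_idx].max(axis=1) - b0
    auc_idx = _window_frames(t, tx, tx + windows.auc_window, closed="both")
    tw = t[auc_idx]
    auc = np.trapezoid(act[:, auc_idx] - b0[:, None], tw, axis=1) / 60.0

    calls = []
    for i, cid in enumerate(cell_ids):
        direction = "none"
        if significant[i]:
            direction = "increase" if increased[i] else "decrease"
        calls.append(ResponderCall(
            cell_id=int(cid), p_value=float(p[i]),
            is_responder=bool(is_resp[i]), direction=direction,
            amplitude=float(amplitude[i]) if is_resp[i] else None,
            auc=float(auc[i]) if is_resp[i] else None))
    return calls


# ---------------------------------------------------------------------------
# population summaries

def wilson_interval(successes: int, total: int,
                    confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if total < 1:
        raise ValueError("total must be >= 1")
    z = stats.norm.ppf(0.5 + confidence / 2)
    phat = successes / total
    denom = 1 + z ** 2 / total
    center = (phat + z ** 2 / (2 * total)) / denom
    half = z * np.sqrt(phat * (1 - phat) / total
                       + z ** 2 / (4 * total ** 2)) / denom
    return max(center - half, 0.0), min(center + half, 1.0)


def responder_fraction(calls: Sequence[ResponderCall],
                       ) -> tuple[float, tuple[float, float]]:
    """Fraction of cells called responders, with a Wilson 95% CI.

    Indeterminate calls are excluded from the denominator.
    """
    usable = [c for c in calls if not c.indeterminate]
    if not usable:
        raise ValueError("no usable responder calls")
    n = len(usable)
    k = sum(c.is_responder for c in usable)
    return k / n, wilson_interval(k, n)


@dataclass
class DoseResponseFit:
    """Logistic (Hill) fit of responder fraction versus dose."""

    pmax: float
    ec50: float
    hill: float
    doses: np.ndarray
    fractions: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    residuals: np.ndarray
    flags: list[str] = field(default_factory=list)

    def predict(self, dose: np.ndarray) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return self.pmax / (1.0 + (self.ec50 / dose) ** self.hill)


def fit_dose_response(doses: Sequence[float],
                      fractions: Sequence[float],
                      counts: Sequence[int] | None = None,
                      ) -> DoseResponseFit:
    """Least-squares Hill fit ``p(dose) = pmax / (1 + (ec50/dose)^hill)``.

    Requires at least 3 positive doses.  Non-monotone or flat data do not
    abort the fit; the result is flagged (``non_monotone``,
    ``ec50_unidentifiable``).
    """
    doses = np.asarray(doses, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if len(doses) < 3:
        raise ValueError("need fractions at >= 3 doses")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    order = np.argsort(doses)
    doses, fractions = doses[order], fractions[order]
    if counts is not None:
        counts = np.asarray(counts)[order]
        ci = np.array([wilson_interval(int(round(f * n)), int(n))
                       for f, n in zip(fractions, counts)])
    else:
        ci = np.column_stack([fractions, fractions])

    flags: list[str] = []
    if np.any(np.diff(fractions) < -1e-12):
        flags.append("non_monotone")
    spread = fractions.max() - fractions.min()

    def model(d, pmax, log_ec50, hill):
        return pmax / (1.0 + (np.exp(log_ec50) / d) ** hill)

    p0 = (min(max(fractions.max(), 0.05), 1.0),
          float(np.log(np.median(doses))), 1.0)
    if spread < 0.02:
        # flat ladder: the plateau is the mean fraction; EC50 is meaningless
        flags.append("ec50_unidentifiable")
        return DoseResponseFit(pmax=float(fractions.mean()),
                               ec50=float(np.exp(p0[1])), hill=1.0,
                               doses=doses, fractions=fractions,
                               ci_low=ci[:, 0], ci_high=ci[:, 1],
                               residuals=fractions - fractions.mean(),
                               flags=flags)
    try:
        with warnings.catch_warnings():
            # only point estimates are used; covariance may be singular
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, doses, fractions, p0=p0,
                bounds=([0.0, np.log(doses.min()) - 5, 0.1],
                        [1.0, np.log(doses.max()) + 5, 10.0]),
                maxfev=10_000)
        pmax, log_ec50, hill = popt
    except RuntimeError:
        pmax, log_ec50, hill = p0
        flags.append("fit_failed")
    fitted = model(doses, pmax, log_ec50, hill)
    return DoseResponseFit(pmax=float(pmax), ec50=float(np.exp(log_ec50)),
                           hill=float(hill), doses=doses,
                           fractions=fractions, ci_low=ci[:, 0],
                           ci_high=ci[:, 1],
                           residuals=fractions - fitted, flags=flags)


# ---------------------------------------------------------------------------
# response-class assignment

def classify_response_class(traces: TraceSet,
                            calls: Sequence[ResponderCall] | None = None,
                            windows: AnalysisWindows | None = None,
                            min_responders: int = 20) -> int:
    """Assign a response class (1 transient / 2 waning / 3 sustained).

    Works on the ensemble-mean, baseline-subtracted responder response
    ``r(t)`` over the AUC window: persistence ``P = r(end) / max r`` and
    normalized duration ``D = AUC / (max r * window)``.  Class 3 when
    ``P >= 0.5`` (sustained), class 1 when ``D <= 0.25`` (transient pulse),
    otherwise class 2.  Raises when the ensemble has too few responders or
    no positive mean response.
    """
    windows = windows or AnalysisWindows()
    schedule = traces.schedule
    if calls is None:
        calls = call_responders(traces, windows)
    resp_ids = {c.cell_id for c in calls if c.is_responder}
    if len(resp_ids) < min_responders:
        raise ValueError(
            f"need >= {min_responders} responder traces, got {len(resp_ids)}")

    cell_ids, act, valid = traces.to_matrix()
    sel = np.isin(cell_ids, list(resp_ids))
    act, valid = act[sel], valid[sel]
    t = schedule.times
    tx = schedule.treatment_time
    pre = _window_frames(t, tx - windows.pre_window, tx, closed="right")
    win = _window_frames(t, tx, tx + windows.auc_window, closed="both")

    masked = np.where(valid, act, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_trace = np.nanmean(masked, axis=0)
        b0 = np.nanmean(mean_trace[pre])
    r = mean_trace[win] - b0
    tw = t[win]
    finite = np.isfinite(r)
    if not finite.any():
        raise ValueError("no valid frames in the AUC window")
    r = np.interp(tw, tw[finite], r[finite])

    rmax = r.max()
    if rmax <= 0:
        raise ValueError("ensemble mean response is non-positive; "
                         "unclassifiable")
    persistence = r[-1] / rmax
    auc = np.trapezoid(r, tw)
    duration = auc / (rmax * (tw[-1] - tw[0]))
    if persistence >= 0.5:
        return 3
    if duration <= 0.25:
        return 1
    return 2
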