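"""Analysis of force-clamp recordings: steps, kinetics, yields, errors.

Mirrors the standard work-up of staircase unfolding data:

1. change-point step detection on the extension signal of each constant
   force pulse, accepting jumps near a multiple of the expected step size;
2. the normalized cumulative unfolding probability P(u) — per-trace
   cumulative step counts rescaled to [0, 1], averaged over traces with at
   least ``min_events`` events, fitted to ``1 - exp(-k_u t)``;
3. refolding yield as the ratio of test-pulse to initial-pulse step counts,
   pooled over recordings after QC (>= 5 initial steps, equal extension at
   the end of the initial and test pulses);
4. nonparametric bootstrap (500 resamples, each recording one data point)
   for the SEM of any such statistic;
5. weighted single-exponential fits of yield-versus-time curves (saturating
   for quench-time sweeps, decaying for extended-time sweeps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .kinetics import FORCE_REGIME_THRESHOLD_PN
from .simulate import RefoldingDataset, Trajectory

__all__ = [
    "StepEvents",
    "UnfoldingCurve",
    "FitResult",
    "FitFailure",
    "QCSettings",
    "detect_steps",
    "unfolding_kinetics",
    "refolding_yield",
    "per_recording_yields",
    "bootstrap_sem",
    "fit_yield_curve",
]


class EmptySelectionError(ValueError):
    """No traces or recordings survive the selection filter."""


@dataclass
class StepEvents:
    """Detected steps for one trace: (time, size, pulse label) triples."""

    times_s: np.ndarray
    sizes_nm: np.ndarray
    pulse_labels: list[str]
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_s) < 0):
            raise ValueError("step times must be ordered")

    def in_pulse(self, label: str) -> np.ndarray:
        mask = np.asarray([p == label for p in self.pulse_labels])
        return self.times_s[mask] if mask.size else np.empty(0)

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class UnfoldingCurve:
    """Normalized cumulative unfolding probability P(u)."""

    time_s: np.ndarray
    p_unfold: np.ndarray
    n_traces: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.p_unfold) < -1e-12):
            raise ValueError("P(u) must be monotone nondecreasing")


@dataclass
class FitResult:
    """Outcome of an exponential fit; ``success=False`` flags a typed failure."""

    form: str
    rate: float | None
    rate_se: float | None
    amplitude: float | None = None
    offset: float | None = None
    amplitude_se: float | None = None
    offset_se: float | None = None
    n_obs: int = 0
    success: bool = True
    message: str = ""


def FitFailure(form: str, message: str, n_obs: int = 0) -> FitResult:
    return FitResult(form=form, rate=None, rate_se=None, n_obs=n_obs,
                     success=False, message=message)


# ---------------------------------------------------------------------------
# change-point step detection


def _best_split(x: np.ndarray, min_left: int, min_right: int):
    """Best single L2 change point of x; returns (index, cost_gain)."""
    n = len(x)
    if n < min_left + min_right:
        return None, 0.0
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    total = c2[-1] - c1[-1] ** 2 / n
    k = np.arange(min_left, n - min_right + 1)
    s1 = c1[k - 1]
    s2 = c2[k - 1]
    left = s2 - s1 ** 2 / k
    nr = n - k
    right = (c2[-1] - s2) - (c1[-1] - s1) ** 2 / nr
    costs = left + right
    i = int(np.argmin(costs))
    return int(k[i]), float(total - costs[i])


def _binary_segmentation(x: np.ndarray, min_size: int, penalty: float,
                         edge_min: int = 2) -> list[int]:
    """Change-point indices (start of each new segment), recursively.

    Internal segments must span at least ``min_size`` samples (the dwell a
    new level must persist); the first and last segments of the region may
    be as short as ``edge_min`` samples, so a step right at a pulse edge is
    still seen.
    """
    out: list[int] = []
    stack = [(0, len(x), edge_min, edge_min)]
    while stack:
        a, b, ml, mr = stack.pop()
        idx, gain = _best_split(x[a:b], ml, mr)
        if idx is None or gain <= penalty:
            continue
        cp = a + idx
        out.append(cp)
        stack.append((a, cp, ml, min_size))
        stack.append((cp, b, min_size, mr))
    return sorted(out)


def detect_steps(trace: Trajectory, expected_step_nm: float = 20.0,
                 min_dwell_s: float = 0.005, *, size_window: float = 0.35,
                 penalty_factor: float = 10.0) -> StepEvents:
    """Detect unfolding steps in the pulse phases of a trace.

    Penalized L2 binary segmentation with a minimum segment length of
    ``min_dwell_s`` is run on each contiguous constant-force pulse region
    (force above the quench threshold).  A positive level change ``d``
    between adjacent segments is accepted as ``m`` simultaneous steps when
    ``|d - m * expected_step_nm| <= size_window * expected_step_nm`` for
    ``m = round(d / expected_step_nm) >= 1`` — unresolvable near-coincident
    unfolding events in a multi-domain polyprotein appear as one jump of
    twice the step size.  Deterministic for fixed input.
    """
    if expected_step_nm <= 0:
        raise ValueError("expected_step_nm must be > 0")
    rate = trace.sampling_rate_hz
    min_size = max(2, int(round(min_dwell_s * rate)))
    if len(trace.time_s) < 2 * min_size:
        raise ValueError("trace shorter than twice the minimum dwell")

    # contiguous pulse regions (constant force above threshold)
    f = trace.force_pn
    pulse = f > FORCE_REGIME_THRESHOLD_PN
    change = np.empty(len(f), dtype=bool)
    change[0] = True
    change[1:] = (np.diff(f) != 0)
    region_id = np.cumsum(change)
    seg_meta = trace.metadata.get("segments")

    times: list[float] = []
    sizes: list[float] = []
    labels: list[str] = []
    pulse_counter = 0
    for rid in np.unique(region_id):
        sel = region_id == rid
        if not pulse[sel][0]:
            continue
        idx0 = int(np.argmax(sel))
        x = trace.extension_nm[sel]
        t = trace.time_s[sel]
        if len(x) < 2 * min_size:
            pulse_counter += 1
            continue
        # robust noise scale from first differences
        dif = np.diff(x)
        sigma = max(np.median(np.abs(dif - np.median(dif))) * 1.4826 / math.sqrt(2),
                    1e-3)
        penalty = penalty_factor * sigma ** 2 * math.log(len(x))
        cps = _binary_segmentation(x, min_size, penalty)
        edges = [0] + cps + [len(x)]
        means = [float(np.mean(x[a:b])) for a, b in zip(edges[:-1], edges[1:])]
        label = _pulse_label(seg_meta, t[0], pulse_counter)

        def accept(cp_idx: int, d: float) -> bool:
            mult = int(round(d / expected_step_nm))
            if mult < 1:
                return False
            if abs(d - mult * expected_step_nm) > size_window * expected_step_nm:
                return False
            for _ in range(mult):
                times.append(float(t[cp_idx]))
                sizes.append(d / mult)
                labels.append(label)
            return True

        for i, cp in enumerate(cps):
            d = means[i + 1] - means[i]
            if d <= 0:
                continue
            if accept(cp, d):
                continue
            if d <= (1.0 + size_window) * expected_step_nm:
                continue
            # jump in the gap between multiplicity windows: two true steps
            # closer than the dwell constraint look like one ramp whose
            # change point splits them unevenly.  Re-segment a local window
            # with a relaxed middle-segment length and re-apply the size
            # rule to the refined jumps.
            lo = max(edges[i], cp - 2 * min_size)
            hi = min(edges[i + 2], cp + 2 * min_size)
            sub = x[lo:hi]
            sub_cps = _binary_segmentation(sub, 2, penalty)
            sub_edges = [0] + sub_cps + [len(sub)]
            sub_means = [float(np.mean(sub[a:b]))
                         for a, b in zip(sub_edges[:-1], sub_edges[1:])]
            for j, scp in enumerate(sub_cps):
                dd = sub_means[j + 1] - sub_means[j]
                if dd > 0:
                    accept(lo + scp, dd)
        pulse_counter += 1
    order = np.argsort(times, kind="stable")
    return StepEvents(np.asarray(times)[order] if times else np.empty(0),
                      np.asarray(sizes)[order] if sizes else np.empty(0),
                      [labels[i] for i in order],
                      settings={"expected_step_nm": expected_step_nm,
                                "min_dwell_s": min_dwell_s,
                                "size_window": size_window,
                                "penalty_factor": penalty_factor})


def _pulse_label(seg_meta, t_start: float, counter: int) -> str:
    if seg_meta:
        for seg in seg_meta:
            if seg["t0"] - 1e-9 <= t_start < seg["t1"]:
                return seg["label"]
    return "initial" if counter == 0 else f"pulse{counter}"


# ---------------------------------------------------------------------------
# unfolding kinetics P(u)


def unfolding_kinetics(step_times, min_events: int = 6,
                       n_grid: int = 200) -> tuple[UnfoldingCurve, FitResult]:
    """P(u) curve and single-exponential unfolding rate.

    ``step_times`` is a sequence of per-trace arrays of unfolding-step
    times (seconds from the pulse start), or of :class:`StepEvents` whose
    first pulse is used.  Traces with fewer than ``min_events`` events are
    discarded.  Each surviving trace's cumulative step count is rescaled to
    [0, 1], the curves are averaged on a common grid, and the average is
    fitted to ``1 - exp(-k_u t)``.
    """
    arrays = []
    for item in step_times:
        if isinstance(item, StepEvents):
            # first pulse of the trace; times are measured from the pulse
            # start, which is t = 0 for unfold-first protocols
            lab = item.pulse_labels[0] if len(item) else "initial"
            ts = item.in_pulse(lab)
        else:
            ts = np.asarray(item, dtype=float)
        if len(ts) >= min_events:
            arrays.append(np.sort(ts))
    if not arrays:
        raise EmptySelectionError(
            f"no traces with >= {min_events} unfolding events")
    t_max = max(a[-1] for a in arrays)
    if t_max <= 0:
        return (UnfoldingCurve(np.asarray([0.0]), np.asarray([1.0]), len(arrays)),
                FitFailure("saturating", "all events at t = 0; rate diverges",
                           n_obs=len(arrays)))
    grid = np.linspace(0.0, t_max, n_grid)
    acc = np.zeros_like(grid)
    for a in arrays:
        acc += np.searchsorted(a, grid, side="right") / len(a)
    p = acc / len(arrays)
    curve = UnfoldingCurve(grid, p, len(arrays))

    def model(t, k):
        return 1.0 - np.exp(-k * t)

    # log-linearized start: -ln(1 - p) ~ k t
    mask = (p > 0) & (p < 1 - 1e-9) & (grid > 0)
    if mask.sum() >= 2:
        k0 = max(np.sum(-np.log1p(-p[mask]) * grid[mask]) /
                 np.sum(grid[mask] ** 2), 1e-6)
    else:
        k0 = 1.0
    try:
        popt, pcov = curve_fit(model, grid, p, p0=[k0], maxfev=10000)
    except RuntimeError as exc:
        return curve, FitFailure("saturating", f"fit did not converge: {exc}",
                                 n_obs=len(arrays))
    k = float(popt[0])
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else None
    if k <= 0 or not np.isfinite(k):
        return curve, FitFailure("saturating", "nonpositive rate", len(arrays))
    return curve, FitResult("saturating", k, se, amplitude=1.0, offset=0.0,
                            n_obs=len(arrays))


# ---------------------------------------------------------------------------
# refolding yield + bootstrap


@dataclass(frozen=True)
class QCSettings:
    """Trace-selection filters for refolding analysis.

    ``min_steps_initial`` keeps recordings with at least that many
    initial-pulse steps; ``extension_tol_frac`` is the allowed relative
    mismatch between the extensions at the end of the initial and test
    pulses (same-molecule check), as a fraction of the total unfolded
    length.
    """

    min_steps_initial: int = 5
    extension_tol_frac: float = 0.10


def _apply_qc(dataset: RefoldingDataset, qc: QCSettings) -> pd.DataFrame:
    r = dataset.records
    total_len = np.maximum(r.ext_end_initial_nm.to_numpy(), 1e-9)
    ok = ((r.steps_initial >= qc.min_steps_initial).to_numpy()
          & (np.abs(r.ext_end_test_nm - r.ext_end_initial_nm).to_numpy()
             <= qc.extension_tol_frac * total_len))
    return r[ok]


def _pooled_yield(df: pd.DataFrame) -> float:
    tot = df.steps_initial.sum()
    return float(df.steps_test.sum() / tot) if tot > 0 else float("nan")


def refolding_yield(dataset: RefoldingDataset, qc: QCSettings = QCSettings(),
                    *, n_boot: int = 500, seed: int = 0) -> tuple[float, float]:
    """Pooled refolding yield and its bootstrap SEM.

    The yield is the ratio of summed test-pulse to summed initial-pulse
    step counts over QC-passing recordings, so every unfolded domain is one
    independent observation.  The SEM resamples whole recordings.
    """
    if len(dataset) == 0:
        raise EmptySelectionError("empty dataset")
    kept = _apply_qc(dataset, qc)
    if len(kept) == 0:
        raise EmptySelectionError("no recording passes QC")
    y = _pooled_yield(kept)
    sub = RefoldingDataset(kept, dataset.step_size_nm, dataset.n_domains_max)
    sem = (bootstrap_sem(sub, _pooled_yield, B=n_boot, seed=seed)
           if len(kept) >= 2 else float("nan"))
    return y, sem


def per_recording_yields(dataset: RefoldingDataset,
                         qc: QCSettings = QCSettings()) -> np.ndarray:
    """Per-recording steps_test/steps_initial ratios after QC (for comparison
    with the pooled estimator)."""
    kept = _apply_qc(dataset, qc)
    return (kept.steps_test / kept.steps_initial).to_numpy()


def bootstrap_sem(dataset: RefoldingDataset, statistic, B: int = 500,
                  seed: int = 0) -> float:
    """SEM of ``statistic(records)`` by resampling recordings with replacement."""
    if B < 2:
        raise ValueError("need B >= 2 bootstrap resamples")
    r = dataset.records
    if len(r) < 2:
        raise ValueError("need >= 2 recordings to bootstrap")
    rng = np.random.default_rng(seed)
    n = len(r)
    vals = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        vals[b] = statistic(r.iloc[idx])
    return float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# yield-curve fitting


def _saturating(t, A, k):
    return A * (1.0 - np.exp(-k * t))


def _decaying(t, y_inf, y0, k):
    return y_inf + (y0 - y_inf) * np.exp(-k * t)


def fit_yield_curve(grid, yields, sems=None, form: str = "saturating") -> FitResult:
    """Weighted exponential fit of a yield curve.

    ``form='saturating'`` fits ``A (1 - exp(-k t))`` (quench-time sweeps);
    ``form='decaying'`` fits ``Y_inf + (Y0 - Y_inf) exp(-k t)``
    (extended-time sweeps).  Weights are 1/sem^2 (absolute); equal or
    missing sems reduce to the unweighted fit.  Starting values come from
    log-linearization.  Flat, non-identifiable data return a failure
    result rather than a NaN rate.
    """
    t = np.asarray(grid, dtype=float)
    y = np.asarray(yields, dtype=float)
    if len(t) < 3:
        raise ValueError("need >= 3 points to fit a yield curve")
    sigma = None
    if sems is not None:
        s = np.asarray(sems, dtype=float)
        if np.any(s < 0):
            raise ValueError("sems must be >= 0")
        if np.any(s > 0):
            s = np.where(s > 0, s, np.median(s[s > 0]))
            sigma = s
    if np.ptp(y) < 1e-12:
        return FitFailure(form, "flat data: rate not identifiable", len(t))
    try:
        if form == "saturating":
            A0 = max(y.max(), 1e-6)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = -np.log1p(-np.clip(y / (A0 * 1.001), None, 1 - 1e-9))
            k0 = max(float(np.sum(z * t) / np.sum(t ** 2)), 1e-6)
            popt, pcov = curve_fit(_saturating, t, y, p0=[A0, k0], sigma=sigma,
                                   absolute_sigma=sigma is not None,
                                   bounds=([0, 1e-9], [1.5, np.inf]),
                                   maxfev=20000)
            A, k = popt
            se = np.sqrt(np.diag(pcov))
            return FitResult(form, float(k), float(se[1]), amplitude=float(A),
                             amplitude_se=float(se[0]), offset=0.0, n_obs=len(t))
        elif form == "decaying":
            y_inf0, y00 = float(y.min()), float(y.max())
            span = max(y00 - y_inf0, 1e-6)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.log(np.clip((y - y_inf0 * 0.95) / span, 1e-9, None))
            k0 = max(float(-np.sum(z * t) / np.sum(t ** 2)), 1e-6)
            popt, pcov = curve_fit(_decaying, t, y, p0=[y_inf0, y00, k0],
                                   sigma=sigma, absolute_sigma=sigma is not None,
                                   bounds=([0, 0, 1e-9], [1.5, 1.5, np.inf]),
                                   maxfev=20000)
            y_inf, y0, k = popt
            se = np.sqrt(np.diag(pcov))
            return FitResult(form, float(k), float(se[2]), amplitude=float(y0),
                             amplitude_se=float(se[1]), offset=float(y_inf),
                             offset_se=float(se[0]), n_obs=len(t))
        raise ValueError(f"unknown form {form!r}")
    except RuntimeError as exc:
        return FitFailure(form, f"fit did not converge: {exc}", len(t))
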