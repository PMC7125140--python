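"""Full-model integration and limit-cycle classification.

Trajectories are integrated window by window (default 500 min windows,
0.1 min output grid, horizon 10,000 min) with an integrator chain — a
stiff-switching method (LSODA), then an implicit multistep method (BDF),
then an explicit Runge-Kutta method (RK45) — falling through on failure.

A window is accepted as a sustained limit cycle when, for every observable
species, at least five *qualifying maxima* (local maxima within 5% of the
window's global maximum) occur in a repeating pattern matching the expected
circular peak order; additionally every species must oscillate with an
amplitude of at least 10% of its window maximum, the window maxima across
species must stay within 100-fold of each other, and the maxima must not be
confined to the beginning of the window (each species needs a qualifying
maximum in the second half — a damped transient fails this).  A window in
which no species moves by more than 1% of its global maximum is a steady
state.  Anything unresolved by the horizon is ``undetermined``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import ode

from .gma import GMAModel, compile_model
from .sampling import ParameterPoint

__all__ = [
    "Trajectory",
    "LimitCycleRecord",
    "integrate_full_model",
    "qualifying_maxima",
    "classify_trajectory",
    "measure_period_and_amplitudes",
    "detect_limit_cycle",
]

VERDICT_LIMIT_CYCLE = "limit_cycle"
VERDICT_STEADY_STATE = "steady_state"
VERDICT_UNDETERMINED = "undetermined"
VERDICT_FAILURE = "integration_failure"

# stiff-switching multistep, implicit multistep, explicit Runge-Kutta
DEFAULT_METHODS = ("lsoda", "bdf", "dopri5")


@dataclass
class Trajectory:
    """Time grid (minutes), per-variable traces and window bookkeeping."""

    t: np.ndarray
    y: np.ndarray                    # (n_vars, n_times)
    var_names: tuple[str, ...]
    windows: list[tuple[int, int]] = field(default_factory=list)
    integrators: list[str] = field(default_factory=list)
    failed: bool = False

    def window_slice(self, k: int = -1) -> tuple[np.ndarray, np.ndarray]:
        i0, i1 = self.windows[k]
        return self.t[i0:i1], self.y[:, i0:i1]

    def trace(self, var: str) -> np.ndarray:
        return self.y[self.var_names.index(var)]


@dataclass
class SpeciesStats:
    global_max: float
    global_min: float
    amplitude_fraction: float


@dataclass
class LimitCycleRecord:
    """Outcome of classifying one (phenotype, parameter point) integration."""

    verdict: str
    period: float | None = None
    species_stats: dict[str, SpeciesStats] = field(default_factory=dict)
    peak_order: tuple[str, ...] | None = None
    case_id: int | None = None
    point: ParameterPoint | None = None
    n_windows: int = 0
    integrators: tuple[str, ...] = ()


class _WorkBudgetExceeded(RuntimeError):
    """Integrator exceeded its per-window work budget (excess-work guard)."""


def integrate_full_model(model: GMAModel, params: Mapping[str, float],
                         initial_state, horizon: float = 10_000.0,
                         window_length: float = 500.0, dt: float = 0.1,
                         methods: Sequence[str] = DEFAULT_METHODS,
                         rtol: float = 1e-6, atol: float = 1e-9,
                         stop_condition: Callable[[Trajectory], bool] | None = None,
                         max_rhs_calls_per_window: int | None = None,
                         max_rhs_calls_total: int | None = None,
                         ) -> Trajectory:
    """Integrate the full GMA model in successive windows.

    Per window the integrator chain is tried in order; if all methods fail
    or the state leaves the finite range the trajectory is marked failed
    (``failed`` flag — never an exception).  ``stop_condition`` is evaluated
    after each window for early termination (e.g. a classifier verdict).

    ``max_rhs_calls_per_window`` is a deterministic excess-work guard (in
    the spirit of lsoda's internal step limit): a method that burns through
    its budget on a pathologically stiff window counts as failed and the
    chain falls through.  Healthy windows use about 1-2 evaluations per
    output point; the default budget allows 10 (with a 50,000 floor), and
    the trajectory-wide default is three window budgets.
    """
    n_out_per_window = max(int(round(window_length / dt)), 1)
    if max_rhs_calls_per_window is None:
        max_rhs_calls_per_window = max(50_000, 10 * n_out_per_window)
    if max_rhs_calls_total is None:
        max_rhs_calls_total = 3 * max_rhs_calls_per_window
    comp = compile_model(model)
    f_raw, jac_raw = comp.rhs_log(params)
    budget = {"left": 0, "used": 0}

    def f(t, x):
        budget["left"] -= 1
        budget["used"] += 1
        if budget["left"] < 0:
            raise _WorkBudgetExceeded
        return f_raw(t, x)

    def jac(t, x):
        return jac_raw(t, x)
    x = comp.state_vector(initial_state)
    names = tuple(comp.dynamic_names)
    traj = Trajectory(np.array([0.0]), x[:, None].copy(), names)
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        traj.failed = True
        return traj
    u = np.log(x)
    ts = [np.array([0.0])]
    ys = [x[:, None].copy()]

    def run_window(method: str, x0: np.ndarray, t0: float,
                   t_eval: np.ndarray) -> np.ndarray | None:
        budget["left"] = max_rhs_calls_per_window
        solver = ode(f, jac)
        if method == "lsoda":
            solver.set_integrator("lsoda", rtol=rtol, atol=atol, nsteps=5000)
        elif method == "bdf":
            solver.set_integrator("vode", method="bdf", rtol=rtol, atol=atol,
                                  nsteps=5000)
        elif method == "dopri5":
            solver.set_integrator("dopri5", rtol=rtol, atol=atol, nsteps=5000)
        else:
            raise ValueError(f"unknown integrator {method!r}")
        solver.set_initial_value(x0, t0)
        out = np.empty((len(x0), len(t_eval)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k, tk in enumerate(t_eval):
                try:
                    with np.errstate(all="ignore"):
                        yk = solver.integrate(tk)
                except (_WorkBudgetExceeded, FloatingPointError, ValueError,
                        OverflowError, ZeroDivisionError):
                    return None
                if not solver.successful() or not np.all(np.isfinite(yk)):
                    return None
                out[:, k] = yk
        return out

    n_win = int(np.ceil(horizon / window_length))
    t0 = 0.0
    for _ in range(n_win):
        t1 = min(t0 + window_length, horizon)
        n_steps = max(int(round((t1 - t0) / dt)), 1)
        t_eval = t0 + dt * np.arange(1, n_steps + 1)
        t_eval[-1] = t1
        sol = None
        used = None
        for method in methods:
            out = run_window(method, u, t0, t_eval)
            if out is not None:
                sol, used = out, method
                break
        if sol is None:
            traj.failed = True
            break
        i0 = sum(len(a) for a in ts)
        ts.append(t_eval)
        ys.append(np.exp(sol))
        traj.t = np.concatenate(ts)
        traj.y = np.concatenate(ys, axis=1)
        traj.windows.append((i0, i0 + len(t_eval)))
        traj.integrators.append(used)
        u = sol[:, -1].copy()
        x = np.exp(u)
        t0 = t1
        if np.any(np.abs(x) > 1e12):
            traj.failed = True
            break
        if stop_condition is not None and stop_condition(traj):
            break
        if budget["used"] > max_rhs_calls_total:
            traj.failed = True
            break
    return traj


def qualifying_maxima(trace: np.ndarray, t: np.ndarray,
                      fraction: float = 0.95) -> np.ndarray:
    """Times of local maxima within 5% of the window's global maximum."""
    trace = np.asarray(trace, float)
    if trace.size < 3:
        return np.empty(0)
    interior = (trace[1:-1] > trace[:-2]) & (trace[1:-1] > trace[2:])
    idx = np.nonzero(interior)[0] + 1
    if idx.size == 0:
        return np.empty(0)
    threshold = fraction * trace.max()
    idx = idx[trace[idx] >= threshold]
    return np.asarray(t)[idx]


def _peak_order_ok(peaks: dict[str, np.ndarray],
                   expected: Sequence[str]) -> tuple[bool, tuple[str, ...]]:
    """Check the merged peak sequence is a rotation of ``expected`` repeated."""
    events = sorted((float(tt), lab) for lab, times in peaks.items()
                    for tt in times)
    labels = [lab for _, lab in events]
    if not labels:
        return False, ()
    k = len(expected)
    try:
        start = list(expected).index(labels[0])
    except ValueError:
        return False, ()
    for i, lab in enumerate(labels):
        if lab != expected[(start + i) % k]:
            return False, ()
    observed = tuple(expected[(start + i) % k] for i in range(k))
    return True, observed


def _classify_window(traj: Trajectory, observables: Mapping[str, str],
                     expected_order: Sequence[str],
                     min_peaks: int = 5, amp_fraction: float = 0.10,
                     max_ratio: float = 100.0,
                     steady_fraction: float = 0.01) -> LimitCycleRecord | None:
    """Classify the last completed window; None means keep integrating."""
    tw, yw = traj.window_slice(-1)
    labels = list(observables)
    traces = {lab: yw[traj.var_names.index(observables[lab])] for lab in labels}
    global_max = {lab: float(traj.trace(observables[lab]).max())
                  for lab in labels}

    # steady state: nothing moved more than 1% of its global maximum
    ranges = {lab: float(tr.max() - tr.min()) for lab, tr in traces.items()}
    if all(ranges[lab] <= steady_fraction * max(global_max[lab], 1e-300)
           for lab in labels):
        return LimitCycleRecord(VERDICT_STEADY_STATE,
                                species_stats=_stats(traces),
                                n_windows=len(traj.windows),
                                integrators=tuple(traj.integrators))

    peaks = {lab: qualifying_maxima(traces[lab], tw) for lab in labels}
    if any(len(p) < min_peaks for p in peaks.values()):
        return None
    wmax = {lab: float(traces[lab].max()) for lab in labels}
    wmin = {lab: float(traces[lab].min()) for lab in labels}
    if any(wmax[lab] - wmin[lab] < amp_fraction * wmax[lab] for lab in labels):
        return None
    if max(wmax.values()) >= max_ratio * min(wmax.values()):
        return None
    half = tw[0] + (tw[-1] - tw[0]) / 2
    if any(p[-1] <= half for p in peaks.values()):
        return None  # maxima only in the beginning: damped transient
    order_ok, observed = _peak_order_ok(peaks, list(expected_order) or labels)
    if not order_ok:
        return None
    ref = expected_order[-1] if expected_order else labels[-1]
    period = float(np.diff(peaks[ref]).mean())
    return LimitCycleRecord(VERDICT_LIMIT_CYCLE, period=period,
                            species_stats=_stats(traces),
                            peak_order=observed,
                            n_windows=len(traj.windows),
                            integrators=tuple(traj.integrators))


def _stats(traces: Mapping[str, np.ndarray]) -> dict[str, SpeciesStats]:
    out = {}
    for lab, tr in traces.items():
        mx, mn = float(tr.max()), float(tr.min())
        out[lab] = SpeciesStats(mx, mn, (mx - mn) / mx if mx > 0 else 0.0)
    return out


def classify_trajectory(traj: Trajectory, observables: Mapping[str, str],
                        expected_order: Sequence[str],
                        at_horizon: bool = True) -> LimitCycleRecord:
    """Final verdict for a (possibly early-stopped) trajectory."""
    if traj.failed or not traj.windows:
        return LimitCycleRecord(VERDICT_FAILURE, n_windows=len(traj.windows),
                                integrators=tuple(traj.integrators))
    rec = _classify_window(traj, observables, expected_order)
    if rec is not None:
        return rec
    verdict = VERDICT_UNDETERMINED if at_horizon else VERDICT_UNDETERMINED
    return LimitCycleRecord(verdict, n_windows=len(traj.windows),
                            integrators=tuple(traj.integrators))


def measure_period_and_amplitudes(record: LimitCycleRecord, traj: Trajectory,
                                  observables: Mapping[str, str],
                                  expected_order: Sequence[str],
                                  ) -> tuple[float, dict[str, SpeciesStats], float]:
    """Period (mean spacing of the last species' qualifying maxima in the
    last window) and per-species amplitude statistics, plus the minimum
    amplitude fraction across species."""
    if record.verdict != VERDICT_LIMIT_CYCLE:
        raise ValueError("period is only defined for a limit-cycle verdict")
    tw, yw = traj.window_slice(-1)
    labels = list(observables)
    traces = {lab: yw[traj.var_names.index(observables[lab])] for lab in labels}
    ref = expected_order[-1] if expected_order else labels[-1]
    peak_t = qualifying_maxima(traces[ref], tw)
    period = float(np.diff(peak_t).mean())
    stats = _stats(traces)
    min_frac = min(s.amplitude_fraction for s in stats.values())
    return period, stats, min_frac


def detect_limit_cycle(model: GMAModel, params: Mapping[str, float],
                       initial_state, horizon: float = 10_000.0,
                       window_length: float = 500.0, dt: float = 0.1,
                       methods: Sequence[str] = DEFAULT_METHODS,
                       **integrator_kwargs,
                       ) -> tuple[LimitCycleRecord, Trajectory]:
    """Integrate with early stopping and classify.

    Integration stops as soon as a window yields a limit-cycle or
    steady-state verdict; otherwise it runs to the horizon and the verdict
    is ``undetermined`` (or ``integration_failure``).
    """
    observables = model.observable_map
    order = model.expected_peak_order
    found: list[LimitCycleRecord] = []

    def stop(traj: Trajectory) -> bool:
        rec = _classify_window(traj, observables, order)
        if rec is not None:
            found.append(rec)
            return True
        return False

    traj = integrate_full_model(model, params, initial_state, horizon,
                                window_length, dt, methods,
                                stop_condition=stop, **integrator_kwargs)
    if traj.failed or not traj.windows:
        return (LimitCycleRecord(VERDICT_FAILURE, n_windows=len(traj.windows),
                                 integrators=tuple(traj.integrators)), traj)
    if found:
        return found[-1], traj
    return (LimitCycleRecord(VERDICT_UNDETERMINED, n_windows=len(traj.windows),
                             integrators=tuple(traj.integrators)), traj)
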