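"""Post-screen analyses of limit-cycle parameter sets.

Everything here is a pure function of screen output (records, models,
parameter points): pairwise Pearson correlations and PCA of log10
parameter values, scaled period sensitivities, 1D bifurcation scans with
phenotype steady-state branches, 2D robustness heatmaps, and phenotype
phase planes.  Correlations and PCA operate on log10 values because the
sampled parameters span many orders of magnitude; PCA standardises each
column to zero mean and unit variance first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator
from sklearn.decomposition import PCA

from .designspace import (DegeneratePhenotypeError, SSystem, build_ssystem,
                          enumerate_signatures, boundary_slacks,
                          ssystem_steady_state, stability_report)
from .gma import GMAModel, substitute_auxiliaries
from .limitcycle import (VERDICT_LIMIT_CYCLE, VERDICT_STEADY_STATE,
                         detect_limit_cycle, measure_period_and_amplitudes)
from .sampling import ParameterPoint

__all__ = [
    "PcaProjection",
    "parameter_correlations",
    "pca_projection",
    "period_parameter_sensitivity",
    "bifurcation_scan_1d",
    "robustness_scan_2d",
    "phenotype_phase_plane",
    "records_to_frame",
]


def records_to_frame(points: Sequence[ParameterPoint | Mapping[str, float]],
                     rename: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Parameter points as a DataFrame of log10 values (one row per point).

    ``rename`` merges design-specific parameter names (e.g. the per-design
    inhibition constants K_zx, K_zs, ... pooled as one 'K' column).
    """
    rows = []
    for pt in points:
        d = pt.as_dict if isinstance(pt, ParameterPoint) else dict(pt)
        if rename:
            d = {rename.get(k, k): v for k, v in d.items()}
        rows.append({k: math.log10(v) for k, v in d.items()})
    return pd.DataFrame(rows)


def parameter_correlations(points, rename=None) -> pd.DataFrame:
    """Pairwise Pearson correlations of log10 parameter values.

    Requires at least 3 points.  Parameters with zero variance yield NaN
    for their pairs (undefined correlation, reported as missing).
    """
    frame = records_to_frame(points, rename)
    if len(frame) < 3:
        raise ValueError("need at least 3 parameter sets for correlations")
    return frame.corr(method="pearson")


@dataclass(frozen=True)
class PcaProjection:
    scores: np.ndarray               # (n_points, 2)
    loadings: np.ndarray             # (n_components, n_params)
    explained_variance_ratio: np.ndarray
    parameter_names: tuple[str, ...]
    mean: np.ndarray                 # of log10 values, per column
    scale: np.ndarray


def pca_projection(points, rename=None) -> PcaProjection:
    """PCA of standardised log10 parameter values; 2D scores for plotting."""
    frame = records_to_frame(points, rename)
    if len(frame) < 3:
        raise ValueError("need at least 3 parameter sets for a PCA")
    X = frame.to_numpy()
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale_safe = np.where(scale > 0, scale, 1.0)
    Z = (X - mean) / scale_safe
    n_comp = min(Z.shape[0], Z.shape[1])
    pca = PCA(n_components=n_comp)
    scores_full = pca.fit_transform(Z)
    return PcaProjection(
        scores=scores_full[:, :2],
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        parameter_names=tuple(frame.columns),
        mean=mean,
        scale=scale_safe,
    )


# ----------------------------------------------------------------------
# period sensitivity
# ----------------------------------------------------------------------

def _period_at(model: GMAModel, params: Mapping[str, float], x0,
               horizon: float, window_length: float, dt: float) -> float | None:
    rec, traj = detect_limit_cycle(model, params, x0, horizon=horizon,
                                   window_length=window_length, dt=dt)
    if rec.verdict != VERDICT_LIMIT_CYCLE:
        return None
    return rec.period


def period_parameter_sensitivity(model: GMAModel, params: Mapping[str, float],
                                 initial_state, rel_step: float = 0.01,
                                 parameters: Iterable[str] | None = None,
                                 horizon: float = 10_000.0,
                                 window_length: float = 500.0,
                                 dt: float = 0.1) -> dict[str, float | None]:
    """Scaled period sensitivities d ln T / d ln p by central differences.

    Each parameter is perturbed by a factor exp(+-rel_step) and the full
    model re-integrated and re-measured.  A parameter whose perturbation
    breaks the limit cycle maps to None ("cycle lost").  By dimensional
    analysis the sensitivities over all rate coefficients sum to -1
    (scaling every coefficient by λ rescales time by 1/λ).
    """
    model = substitute_auxiliaries(model)
    base = _period_at(model, params, initial_state, horizon, window_length, dt)
    if base is None:
        raise ValueError("baseline point is not a verified limit cycle")
    names = list(parameters) if parameters is not None else model.parameter_names
    out: dict[str, float | None] = {}
    for name in names:
        periods = []
        for fac in (math.exp(rel_step), math.exp(-rel_step)):
            p = dict(params)
            p[name] = p[name] * fac
            periods.append(_period_at(model, p, initial_state, horizon,
                                      window_length, dt))
        if None in periods:
            out[name] = None
            continue
        out[name] = (math.log(periods[0]) - math.log(periods[1])) / (2 * rel_step)
    return out


# ----------------------------------------------------------------------
# scans
# ----------------------------------------------------------------------

@dataclass
class BranchPoint:
    """Phenotype steady-state branch value at one scan point."""

    case_id: int
    value: float                  # steady state of the scanned species
    n_positive_eigenvalues: int


@dataclass
class BifurcationScan:
    parameter: str
    species: str
    values: np.ndarray            # scanned parameter values
    env_min: np.ndarray           # full-model oscillation envelope
    env_max: np.ndarray
    verdicts: list[str]
    branches: list[list[BranchPoint]]  # per scan point


def _nondegenerate_ssystems(model: GMAModel) -> list[SSystem]:
    out = []
    for sig in enumerate_signatures(model):
        try:
            out.append(build_ssystem(model, sig))
        except DegeneratePhenotypeError:
            continue
    return out


def _valid_here(ss: SSystem, params: Mapping[str, float],
                tol: float = 1e-9) -> bool:
    slacks = boundary_slacks(ss, params)
    return bool(slacks.size == 0 or slacks.min() >= -tol)


def bifurcation_scan_1d(model: GMAModel, params: Mapping[str, float],
                        parameter: str, log_range: tuple[float, float],
                        n_points: int = 25, species: str | None = None,
                        horizon: float = 10_000.0, window_length: float = 500.0,
                        dt: float = 0.1,
                        ssystems: Sequence[SSystem] | None = None,
                        ) -> BifurcationScan:
    """Oscillation envelope and phenotype branches along one parameter.

    Per scan value the full model is integrated (from each valid
    phenotype's perturbed steady state) and classified; the envelope is the
    min/max of the chosen species in the last window (equal for steady
    states).  The phenotype branches carry the steady state of every
    phenotype valid at that point with its positive-eigenvalue count —
    overlapping branches indicate multi-stability.
    """
    flat = substitute_auxiliaries(model)
    obs = flat.observable_map
    species = species or (list(obs)[1] if len(obs) > 1 else list(obs)[0])
    var = obs.get(species, species)
    if ssystems is None:
        ssystems = _nondegenerate_ssystems(flat)
    values = np.logspace(log_range[0], log_range[1], n_points)
    env_min = np.full(n_points, np.nan)
    env_max = np.full(n_points, np.nan)
    verdicts: list[str] = []
    branches: list[list[BranchPoint]] = []
    for k, val in enumerate(values):
        p = dict(params)
        p[parameter] = float(val)
        pts: list[BranchPoint] = []
        x0 = None
        for ss in ssystems:
            if not _valid_here(ss, p):
                continue
            try:
                rep = stability_report(ss, p)
            except DegeneratePhenotypeError:
                continue
            pts.append(BranchPoint(ss.signature.case_id,
                                   rep.steady_state[var],
                                   int(np.sum(rep.eigenvalues.real > 0))))
            if x0 is None or rep.has_oscillatory_pair:
                x0 = dict(rep.steady_state)
        branches.append(pts)
        if x0 is None:
            verdicts.append("no_valid_phenotype")
            continue
        first = next(iter(x0))
        x0[first] *= 1.01
        rec, traj = detect_limit_cycle(flat, p, x0, horizon=horizon,
                                       window_length=window_length, dt=dt)
        verdicts.append(rec.verdict)
        if rec.verdict in (VERDICT_LIMIT_CYCLE, VERDICT_STEADY_STATE):
            tw, yw = traj.window_slice(-1)
            trace = yw[traj.var_names.index(var)]
            if rec.verdict == VERDICT_STEADY_STATE:
                env_min[k] = env_max[k] = float(trace[-1])
            else:
                env_min[k] = float(trace.min())
                env_max[k] = float(trace.max())
    return BifurcationScan(parameter, species, values, env_min, env_max,
                           verdicts, branches)


@dataclass
class RobustnessScan:
    parameters: tuple[str, str]
    species: str
    samples: np.ndarray           # (n, 2) log10 sampled values
    amplitudes: np.ndarray        # (n,), 0 for steady state / failures
    verdicts: list[str]
    grid_x: np.ndarray
    grid_y: np.ndarray
    grid_amplitude: np.ndarray


def robustness_scan_2d(model: GMAModel, params: Mapping[str, float],
                       parameters: tuple[str, str], n: int = 1000,
                       seed: int = 0, log_bounds=((-2.0, 2.0), (-2.0, 2.0)),
                       species: str | None = None, grid_size: int = 40,
                       horizon: float = 10_000.0, window_length: float = 500.0,
                       dt: float = 0.1, relative: bool = True,
                       ) -> RobustnessScan:
    """Oscillation-amplitude heatmap over random 2D parameter perturbations.

    ``n`` log-uniform samples of the two parameters are drawn (within
    ``log_bounds``, interpreted relative to the base point when
    ``relative``), all other parameters stay fixed; per sample the full
    model is integrated and the amplitude of the chosen species recorded
    (0 for steady states).  A thin-plate-spline radial basis interpolation
    onto a regular grid is provided for rendering; the raw samples are the
    data of record.
    """
    flat = substitute_auxiliaries(model)
    obs = flat.observable_map
    species = species or (list(obs)[1] if len(obs) > 1 else list(obs)[0])
    var = obs.get(species, species)
    rng = np.random.default_rng(seed)
    base = np.array([math.log10(params[parameters[0]]),
                     math.log10(params[parameters[1]])])
    lo = np.array([log_bounds[0][0], log_bounds[1][0]], float)
    hi = np.array([log_bounds[0][1], log_bounds[1][1]], float)
    if relative:
        lo = base + lo
        hi = base + hi
    samples = rng.uniform(lo, hi, size=(n, 2))
    amplitudes = np.zeros(n)
    verdicts: list[str] = []
    ssystems = _nondegenerate_ssystems(flat)
    for k in range(n):
        p = dict(params)
        p[parameters[0]] = 10.0 ** samples[k, 0]
        p[parameters[1]] = 10.0 ** samples[k, 1]
        x0 = None
        for ss in ssystems:
            if not _valid_here(ss, p):
                continue
            try:
                rep = stability_report(ss, p)
            except DegeneratePhenotypeError:
                continue
            x0 = dict(rep.steady_state)
            if rep.has_oscillatory_pair:
                break
        if x0 is None:
            verdicts.append("no_valid_phenotype")
            continue
        first = next(iter(x0))
        x0[first] *= 1.01
        rec, traj = detect_limit_cycle(flat, p, x0, horizon=horizon,
                                       window_length=window_length, dt=dt)
        verdicts.append(rec.verdict)
        if rec.verdict == VERDICT_LIMIT_CYCLE:
            tw, yw = traj.window_slice(-1)
            trace = yw[traj.var_names.index(var)]
            amplitudes[k] = float(trace.max() - trace.min())
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    GX, GY = np.meshgrid(gx, gy)
    pts = np.column_stack([GX.ravel(), GY.ravel()])
    try:
        interp = RBFInterpolator(samples, amplitudes,
                                 kernel="thin_plate_spline")
        grid_amp = interp(pts).reshape(GX.shape)
    except np.linalg.LinAlgError:
        # degenerate sample set: nearest-neighbour fallback
        from scipy.interpolate import NearestNDInterpolator
        interp = NearestNDInterpolator(samples, amplitudes)
        grid_amp = interp(pts).reshape(GX.shape)
    return RobustnessScan(parameters, species, samples, amplitudes, verdicts,
                          gx, gy, grid_amp)


@dataclass
class PhasePlane:
    parameters: tuple[str, str]
    grid_x: np.ndarray            # log10 values
    grid_y: np.ndarray
    # cell -> list of (case_id, n_positive_eigenvalues)
    assignments: list[list[list[tuple[int, int]]]]


def phenotype_phase_plane(model: GMAModel, params: Mapping[str, float],
                          parameters: tuple[str, str],
                          log_range_x: tuple[float, float],
                          log_range_y: tuple[float, float],
                          grid_size: int = 25,
                          ssystems: Sequence[SSystem] | None = None,
                          ) -> PhasePlane:
    """Valid-phenotype sets and eigenvalue counts over a 2D parameter slice.

    Several phenotypes may be valid at the same point (overlapping regions:
    multi-stability); cells with no valid phenotype get an empty list.
    """
    flat = substitute_auxiliaries(model)
    if ssystems is None:
        ssystems = _nondegenerate_ssystems(flat)
    gx = np.linspace(log_range_x[0], log_range_x[1], grid_size)
    gy = np.linspace(log_range_y[0], log_range_y[1], grid_size)
    assignments: list[list[list[tuple[int, int]]]] = []
    for yv in gy:
        row: list[list[tuple[int, int]]] = []
        for xv in gx:
            p = dict(params)
            p[parameters[0]] = 10.0 ** float(xv)
            p[parameters[1]] = 10.0 ** float(yv)
            cell: list[tuple[int, int]] = []
            for ss in ssystems:
                if not _valid_here(ss, p):
                    continue
                try:
                    rep = stability_report(ss, p)
                except DegeneratePhenotypeError:
                    continue
                cell.append((ss.signature.case_id,
                             int(np.sum(rep.eigenvalues.real > 0))))
            row.append(cell)
        assignments.append(row)
    return PhasePlane(parameters, gx, gy, assignments)
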