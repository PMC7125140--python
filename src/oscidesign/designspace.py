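"""Design-space (dominance) decomposition of GMA models.

A *phenotype* fixes, for every equation, which single production and which
single consumption term dominates numerically.  Keeping only the dominant
pair turns each differential equation into a two-term S-system equation,

    a * prod x^g  =  b * prod x^h      at steady state,

which is linear in log-states and log-parameters and therefore solvable in
closed form.  The neglected terms induce one linear *boundary* inequality
each (log dominant >= log neglected); their joint feasibility inside the
global parameter box — a linear program — decides whether the phenotype is
*valid*, i.e. realisable by some parameter set.  Retained algebraic
auxiliaries (rational-regulation denominators) contribute their own
dominance choices and boundaries.

All linear algebra here is in base-10 logarithms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .gma import GMAModel, GMAModelError, PowerLawTerm, compile_model

__all__ = [
    "PhenotypeSignature",
    "SSystem",
    "StabilityReport",
    "DegeneratePhenotypeError",
    "LPSolverError",
    "count_signatures",
    "enumerate_signatures",
    "signature_to_case_id",
    "case_id_to_signature",
    "build_ssystem",
    "ssystem_steady_state",
    "phenotype_validity",
    "parameter_tolerance",
    "stability_report",
]

_EPS = 1e-9


class DegeneratePhenotypeError(ArithmeticError):
    """The phenotype's log-linear steady-state system is singular."""


class LPSolverError(RuntimeError):
    """The LP solver failed for a reason other than infeasibility."""


@dataclass(frozen=True)
class PhenotypeSignature:
    """Per-equation (dominant production index, dominant consumption index).

    Indices are 0-based into the owning equation's term lists.  ``case_id``
    is a 1-based mixed-radix encoding: equations in model order with the
    first equation as the most significant digit, and the production index
    major within each equation's digit.
    """

    choices: tuple[tuple[int, int], ...]
    case_id: int

    def __str__(self) -> str:
        body = ",".join(f"{p}:{c}" for p, c in self.choices)
        return f"<case {self.case_id} [{body}]>"


def _radices(model: GMAModel) -> list[tuple[int, int]]:
    out = []
    for eq in model.equations:
        n_p, n_c = len(eq.production_terms), len(eq.consumption_terms)
        if n_p == 0 or n_c == 0:
            raise GMAModelError(
                f"equation for '{eq.variable}' has an empty term side")
        out.append((n_p, n_c))
    return out


def count_signatures(model: GMAModel) -> int:
    """Total number of dominance phenotypes (product of per-equation choices)."""
    return math.prod(n_p * n_c for n_p, n_c in _radices(model))


def signature_to_case_id(model: GMAModel, choices: Sequence[tuple[int, int]]) -> int:
    case = 0
    for (p, c), (n_p, n_c) in zip(choices, _radices(model)):
        if not (0 <= p < n_p and 0 <= c < n_c):
            raise ValueError("dominance index out of range")
        case = case * (n_p * n_c) + p * n_c + c
    return case + 1


def case_id_to_signature(model: GMAModel, case_id: int) -> PhenotypeSignature:
    radices = _radices(model)
    total = math.prod(n_p * n_c for n_p, n_c in radices)
    if not (1 <= case_id <= total):
        raise ValueError(f"case_id must be in 1..{total}")
    rem = case_id - 1
    digits = []
    for n_p, n_c in reversed(radices):
        rem, d = divmod(rem, n_p * n_c)
        digits.append(divmod(d, n_c))
    return PhenotypeSignature(tuple(reversed(digits)), case_id)


def enumerate_signatures(model: GMAModel) -> Iterator[PhenotypeSignature]:
    """Yield every signature exactly once, lazily, in ascending case_id."""
    per_eq = [
        [(p, c) for p in range(n_p) for c in range(n_c)]
        for n_p, n_c in _radices(model)
    ]
    for case_id, combo in enumerate(itertools.product(*per_eq), start=1):
        yield PhenotypeSignature(tuple(combo), case_id)


# ----------------------------------------------------------------------
# S-system construction
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SSystem:
    """Reduced log-linear system for one phenotype of a flattened model.

    With q = log10(parameters) and u = log10(dynamic steady state):

    * ``u = W @ q + w0``  (closed-form steady state),
    * ``B @ q + b0 >= 0`` (dominance boundaries, log-states eliminated),

    one boundary row per neglected term per equation, including retained
    algebraic auxiliaries.  ``dominant_exponents`` are the (production,
    consumption) exponent matrices of the dominant subsystem over the
    dynamic variables (auxiliaries substituted by their dominant monomial),
    used for stability analysis.
    """

    model: GMAModel
    signature: PhenotypeSignature
    param_names: tuple[str, ...]
    var_names: tuple[str, ...]
    W: np.ndarray
    w0: np.ndarray
    B: np.ndarray
    b0: np.ndarray
    boundary_labels: tuple[str, ...]
    prod_exponents: np.ndarray   # n x n, over dynamic variables
    cons_exponents: np.ndarray
    prod_qrows: np.ndarray       # n x n_params (log10 coefficient rows)
    cons_qrows: np.ndarray
    prod_consts: np.ndarray
    cons_consts: np.ndarray

    @property
    def n_boundaries(self) -> int:
        return len(self.b0)


def _term_row(term: PowerLawTerm, pidx: Mapping[str, int],
              xidx: Mapping[str, int], aidx: Mapping[str, int]):
    """log10(term) = const + qrow.q + xrow.u + arow.u_aux."""
    qrow = np.zeros(len(pidx))
    xrow = np.zeros(len(xidx))
    arow = np.zeros(len(aidx))
    for p, e in term.parameters:
        qrow[pidx[p]] += e
    for v, e in term.variables:
        if v in xidx:
            xrow[xidx[v]] += e
        else:
            arow[aidx[v]] += e
    return math.log10(term.constant), qrow, xrow, arow


def build_ssystem(model: GMAModel, signature: PhenotypeSignature) -> SSystem:
    """Build the S-system and dominance boundaries for ``signature``.

    ``model`` must be flattened (pure power-law auxiliaries substituted);
    retained auxiliaries are replaced by their dominant monomial throughout,
    consistently with the dominance approximation.
    """
    pnames = tuple(model.parameter_names)
    xnames = tuple(model.dynamic_variables)
    anames = tuple(model.auxiliary_variables)
    pidx = {p: i for i, p in enumerate(pnames)}
    xidx = {v: i for i, v in enumerate(xnames)}
    aidx = {v: i for i, v in enumerate(anames)}
    n = len(xnames)

    eqs = list(model.equations)
    if len(signature.choices) != len(eqs):
        raise ValueError("signature does not match model equation count")

    # dominant monomial of each auxiliary, as (const, qrow, xrow); auxiliaries
    # may reference earlier auxiliaries, resolved in order.
    aux_rows: list[tuple[float, np.ndarray, np.ndarray]] = []
    for eq in model.auxiliary_equations:
        j = model.variables.index(eq.variable) - n
        p_choice, _ = signature.choices[model.variables.index(eq.variable)]
        k, qrow, xrow, arow = _term_row(eq.production_terms[p_choice],
                                        pidx, xidx, aidx)
        for jj in range(len(aux_rows)):
            if arow[jj]:
                kk, qq, xx = aux_rows[jj]
                k += arow[jj] * kk
                qrow = qrow + arow[jj] * qq
                xrow = xrow + arow[jj] * xx
        aux_rows.append((k, qrow, xrow))

    def resolved_row(term: PowerLawTerm):
        k, qrow, xrow, arow = _term_row(term, pidx, xidx, aidx)
        for j in range(len(aux_rows)):
            if arow[j]:
                kk, qq, xx = aux_rows[j]
                k += arow[j] * kk
                qrow = qrow + arow[j] * qq
                xrow = xrow + arow[j] * xx
        return k, qrow, xrow

    A_d = np.zeros((n, n))
    Rq = np.zeros((n, len(pnames)))
    r0 = np.zeros(n)
    prod_E = np.zeros((n, n)); cons_E = np.zeros((n, n))
    prod_Q = np.zeros((n, len(pnames))); cons_Q = np.zeros((n, len(pnames)))
    prod_k = np.zeros(n); cons_k = np.zeros(n)
    for i, eq in enumerate(model.dynamic_equations):
        p_choice, c_choice = signature.choices[i]
        kp, qp, xp = resolved_row(eq.production_terms[p_choice])
        kc, qc, xc = resolved_row(eq.consumption_terms[c_choice])
        A_d[i] = xp - xc
        Rq[i] = qc - qp
        r0[i] = kc - kp
        prod_E[i], cons_E[i] = xp, xc
        prod_Q[i], cons_Q[i] = qp, qc
        prod_k[i], cons_k[i] = kp, kc

    # steady state in log space: A_d u = Rq q + r0  ->  u = W q + w0
    if n:
        if np.linalg.matrix_rank(A_d, tol=1e-10 * max(1.0, np.abs(A_d).max())) < n:
            raise DegeneratePhenotypeError(
                f"singular log-linear system for case {signature.case_id}")
        W = np.linalg.solve(A_d, Rq)
        w0 = np.linalg.solve(A_d, r0)
    else:
        W = np.zeros((0, len(pnames)))
        w0 = np.zeros(0)

    # boundaries: log(dominant) - log(neglected) >= 0, states eliminated
    B_rows, b0_rows, labels = [], [], []
    for i, eq in enumerate(eqs):
        p_choice, c_choice = signature.choices[i]
        sides = [("prod", eq.production_terms, p_choice)]
        if not eq.is_algebraic:
            sides.append(("cons", eq.consumption_terms, c_choice))
        for side, terms, choice in sides:
            kd, qd, xd = resolved_row(terms[choice])
            for t_i, term in enumerate(terms):
                if t_i == choice:
                    continue
                kn, qn, xn = resolved_row(term)
                drow = (qd - qn) + (xd - xn) @ W
                dconst = (kd - kn) + (xd - xn) @ w0
                B_rows.append(drow)
                b0_rows.append(dconst)
                labels.append(f"{eq.variable}:{side}:{choice}>{t_i}")

    B = np.array(B_rows) if B_rows else np.zeros((0, len(pnames)))
    b0 = np.array(b0_rows)
    return SSystem(model, signature, pnames, xnames, W, w0, B, b0,
                   tuple(labels), prod_E, cons_E, prod_Q, cons_Q,
                   prod_k, cons_k)


def _log_params(ss: SSystem, params: Mapping[str, float]) -> np.ndarray:
    try:
        p = np.array([params[name] for name in ss.param_names], float)
    except KeyError as err:
        raise KeyError(f"missing parameter {err.args[0]!r}") from None
    if np.any(p <= 0):
        raise ValueError("parameters must be strictly positive")
    return np.log10(p)


def ssystem_steady_state(ss: SSystem, params: Mapping[str, float]) -> dict[str, float]:
    """Closed-form steady state of the dominant subsystem (unique)."""
    q = _log_params(ss, params)
    u = ss.W @ q + ss.w0
    return {v: 10.0 ** ui for v, ui in zip(ss.var_names, u)}


def boundary_slacks(ss: SSystem, params: Mapping[str, float]) -> np.ndarray:
    """log10 dominance margins at a parameter point (>= 0 inside)."""
    q = _log_params(ss, params)
    return ss.B @ q + ss.b0


def _log_bounds(ss: SSystem, bounds) -> tuple[np.ndarray, np.ndarray]:
    if bounds is None:
        reg = ss.model.bounds
        lo = np.array([reg[p][0] for p in ss.param_names])
        hi = np.array([reg[p][1] for p in ss.param_names])
    else:
        lo = np.full(len(ss.param_names), float(bounds[0]))
        hi = np.full(len(ss.param_names), float(bounds[1]))
    return np.log10(lo), np.log10(hi)


def phenotype_validity(ss: SSystem, bounds=None,
                       ) -> tuple[bool, dict[str, float] | None]:
    """LP feasibility of the dominance boundaries inside the parameter box.

    Maximises the minimum normalised boundary slack (Chebyshev-style), so a
    feasible phenotype returns an interior witness at which the dominant
    terms strictly dominate at the solved steady state.
    """
    lo, hi = _log_bounds(ss, bounds)
    n_p = len(ss.param_names)
    if ss.n_boundaries == 0:
        witness = {p: 10.0 ** ((l + h) / 2)
                   for p, l, h in zip(ss.param_names, lo, hi)}
        return True, witness

    norms = np.maximum(np.linalg.norm(ss.B, axis=1), 1e-12)
    # variables [q, t]; maximise t  s.t.  B q + b0 >= t * norms
    A_ub = np.hstack([-ss.B, norms[:, None]])
    b_ub = ss.b0
    c = np.zeros(n_p + 1); c[-1] = -1.0
    var_bounds = [(l, h) for l, h in zip(lo, hi)] + [(-1e6, 1.0)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=var_bounds, method="highs")
    if not res.success:
        if res.status == 2:  # box itself empty – should not happen
            return False, None
        raise LPSolverError(f"linprog failed: {res.message}")
    t = -res.fun
    if t < -_EPS:
        return False, None
    q = res.x[:n_p]
    return True, {p: 10.0 ** qi for p, qi in zip(ss.param_names, q)}


def tolerance_log10(ss: SSystem, q: np.ndarray, j: int,
                    lo_j: float, hi_j: float) -> tuple[float, float]:
    """1D feasible log10-interval for parameter ``j`` with the others fixed."""
    lo, hi = lo_j, hi_j
    if ss.n_boundaries:
        a = ss.B[:, j]
        rest = ss.B @ q - a * q[j] + ss.b0
        for ai, ri in zip(a, rest):
            if ai > _EPS:
                lo = max(lo, -ri / ai)
            elif ai < -_EPS:
                hi = min(hi, -ri / ai)
            elif ri < -1e-7:
                raise ValueError(
                    "parameter point violates a boundary not involving "
                    "the scanned parameter")
    return lo, hi


def parameter_tolerance(ss: SSystem, params: Mapping[str, float],
                        name: str, bounds=None) -> tuple[float, float]:
    """Maximal interval for one parameter (others fixed) keeping the
    phenotype's boundaries satisfiable, intersected with global bounds."""
    if name not in ss.param_names:
        raise KeyError(f"unknown parameter {name!r}")
    q = _log_params(ss, params)
    slacks = ss.B @ q + ss.b0 if ss.n_boundaries else np.zeros(0)
    if ss.n_boundaries and slacks.min() < -1e-7:
        raise ValueError("parameter point is not valid for this phenotype")
    lo_all, hi_all = _log_bounds(ss, bounds)
    j = ss.param_names.index(name)
    lo, hi = tolerance_log10(ss, q, j, lo_all[j], hi_all[j])
    # the current value always belongs to the interval (up to round-off)
    lo = min(lo, q[j])
    hi = max(hi, q[j])
    return 10.0 ** lo, 10.0 ** hi


# ----------------------------------------------------------------------
# stability
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalue screen of a phenotype's steady state.

    ``has_oscillatory_pair`` flags a complex-conjugate pair with
    non-negative real part — the necessary condition for oscillations born
    at a Hopf bifurcation used by the screening pipeline.
    """

    steady_state: dict[str, float]
    eigenvalues: np.ndarray
    n_nonnegative_real: int
    has_oscillatory_pair: bool


def ssystem_jacobian(ss: SSystem, params: Mapping[str, float],
                     state: Mapping[str, float] | np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the dominant (two-term) subsystem."""
    q = _log_params(ss, params)
    if isinstance(state, Mapping):
        x = np.array([state[v] for v in ss.var_names], float)
    else:
        x = np.asarray(state, float)
    logx = np.log10(x)
    vp = 10.0 ** (ss.prod_consts + ss.prod_qrows @ q + ss.prod_exponents @ logx)
    vc = 10.0 ** (ss.cons_consts + ss.cons_qrows @ q + ss.cons_exponents @ logx)
    J = (vp[:, None] * ss.prod_exponents - vc[:, None] * ss.cons_exponents) / x[None, :]
    return J


def _report_from_eigs(state: dict[str, float], eig: np.ndarray,
                      rel_tol: float) -> StabilityReport:
    scale = max(float(np.abs(eig).max()), 1e-30)
    tol = rel_tol * scale
    nonneg = int(np.sum(eig.real >= -tol))
    osc = bool(np.any((eig.imag > tol) & (eig.real >= -tol)))
    return StabilityReport(state, eig, nonneg, osc)


def stability_report(ss: SSystem, params: Mapping[str, float],
                     rel_tol: float = 1e-9) -> StabilityReport:
    """Eigenvalues of the S-system Jacobian at its closed-form steady state."""
    state = ssystem_steady_state(ss, params)
    x = np.array([state[v] for v in ss.var_names])
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise DegeneratePhenotypeError("non-finite or non-positive steady state")
    J = ssystem_jacobian(ss, params, x)
    if not np.all(np.isfinite(J)):
        raise DegeneratePhenotypeError("non-finite Jacobian at steady state")
    return _report_from_eigs(state, np.linalg.eigvals(J), rel_tol)


def stability_reports_batch(ss: SSystem, param_sets: Sequence[Mapping[str, float]],
                            rel_tol: float = 1e-9,
                            ) -> list[StabilityReport | None]:
    """Vectorised :func:`stability_report` over many parameter points.

    Steady states, Jacobians and eigenvalues are evaluated as one batched
    computation; entries whose steady state or Jacobian is non-finite map
    to None (the per-point function raises instead).
    """
    if not param_sets:
        return []
    Q = np.log10([[ps[name] for name in ss.param_names] for ps in param_sets])
    U = Q @ ss.W.T + ss.w0          # (N, n) log10 steady states
    n = len(ss.var_names)
    LV_p = ss.prod_consts + Q @ ss.prod_qrows.T + U @ ss.prod_exponents.T
    LV_c = ss.cons_consts + Q @ ss.cons_qrows.T + U @ ss.cons_exponents.T
    with np.errstate(all="ignore"):
        vp = 10.0 ** LV_p
        vc = 10.0 ** LV_c
        X = 10.0 ** U
        J = (vp[:, :, None] * ss.prod_exponents[None]
             - vc[:, :, None] * ss.cons_exponents[None]) / X[:, None, :]
    out: list[StabilityReport | None] = []
    finite = np.isfinite(J).all(axis=(1, 2)) & np.isfinite(X).all(axis=1)
    eigs = np.full((len(param_sets), n), np.nan, complex)
    if finite.any():
        eigs[finite] = np.linalg.eigvals(J[finite])
    for k in range(len(param_sets)):
        if not finite[k]:
            out.append(None)
            continue
        state = {v: float(X[k, i]) for i, v in enumerate(ss.var_names)}
        out.append(_report_from_eigs(state, eigs[k], rel_tol))
    return out
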