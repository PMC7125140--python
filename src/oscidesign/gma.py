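"""Generalized Mass Action (GMA) kinetic models.

A GMA model is a system of ordinary differential equations in which every
rate is a signed sum of power-law monomials,

    dx_i/dt = sum_j  a_j * prod_k x_k^(g_jk)  -  sum_j  b_j * prod_k x_k^(h_jk),

where the coefficients ``a_j``, ``b_j`` are products of named, strictly
positive parameters and the exponents are arbitrary reals.  Besides the
dynamic variables a model may carry *algebraic auxiliaries*: either pure
power laws (e.g. a ternary complex at binding equilibrium, ``c = K_A*x*s``),
which can be substituted away exactly, or multi-term sums used as
denominators for rational (saturating) regulation (``D = K + z`` with a
synthesis term ``v*K*D^-1``), which are retained and contribute their own
dominance choices to the design space.

The plain-text serialisation has one line per equation, ``x' = expr`` for a
differential equation and ``x = expr`` for an algebraic auxiliary, with
``expr`` a +/- separated list of products of parameters and powered
variables.  ``@``-directives carry model metadata (name, observable species,
expected peak order, parameter bounds).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PowerLawTerm",
    "GMAEquation",
    "GMAModel",
    "GMAParseError",
    "GMAModelError",
    "parse_gma_model",
    "write_gma_model",
    "evaluate_rates",
    "analytic_jacobian",
    "substitute_auxiliaries",
    "CompiledGMA",
]

DEFAULT_BOUNDS = (1e-9, 1e3)


class GMAParseError(ValueError):
    """Raised when model-definition text cannot be parsed."""


class GMAModelError(ValueError):
    """Raised when a structurally invalid model is constructed."""


def _fmt_number(v: float) -> str:
    if float(v) == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(float(v))


@dataclass(frozen=True)
class PowerLawTerm:
    """One signed monomial: ``constant * prod(params^e) * prod(vars^g)``.

    ``parameters`` maps parameter names to exponents (a flattened term such
    as ``epsilon*K_A*x*s`` has two parameters, both with exponent 1);
    ``variables`` maps variable names to real exponents.  The sign lives on
    the owning equation (production vs consumption side), not here.
    """

    parameters: tuple[tuple[str, float], ...] = ()
    variables: tuple[tuple[str, float], ...] = ()
    constant: float = 1.0

    @staticmethod
    def make(parameters: Mapping[str, float] | None = None,
             variables: Mapping[str, float] | None = None,
             constant: float = 1.0) -> "PowerLawTerm":
        return PowerLawTerm(
            tuple((k, float(v)) for k, v in (parameters or {}).items() if v != 0),
            tuple((k, float(v)) for k, v in (variables or {}).items() if v != 0),
            float(constant),
        )

    @property
    def parameter_dict(self) -> dict[str, float]:
        return dict(self.parameters)

    @property
    def variable_dict(self) -> dict[str, float]:
        return dict(self.variables)

    def value(self, params: Mapping[str, float], state: Mapping[str, float]) -> float:
        v = self.constant
        for name, e in self.parameters:
            v *= params[name] ** e
        for name, e in self.variables:
            v *= state[name] ** e
        return v

    def format(self) -> str:
        factors: list[str] = []
        if self.constant != 1.0 or (not self.parameters and not self.variables):
            factors.append(_fmt_number(self.constant))
        for name, e in self.parameters:
            factors.append(name if e == 1 else f"{name}^{_fmt_number(e)}")
        for name, e in self.variables:
            factors.append(name if e == 1 else f"{name}^{_fmt_number(e)}")
        return "*".join(factors)


@dataclass(frozen=True)
class GMAEquation:
    """One equation: a differential rate law or an algebraic auxiliary.

    For a differential equation both term lists are as written.  For an
    algebraic auxiliary the production terms are the summands defining the
    variable and the consumption side is the variable itself (so dominance
    enumeration treats 'which summand dominates the denominator' exactly
    like any other choice).
    """

    variable: str
    production_terms: tuple[PowerLawTerm, ...]
    consumption_terms: tuple[PowerLawTerm, ...]
    is_algebraic: bool = False

    def __post_init__(self):
        if not self.is_algebraic:
            if not self.production_terms or not self.consumption_terms:
                raise GMAModelError(
                    f"differential equation for '{self.variable}' needs >=1 "
                    f"production and >=1 consumption term"
                )
        else:
            if not self.production_terms:
                raise GMAModelError(
                    f"algebraic auxiliary '{self.variable}' has no terms")


@dataclass(frozen=True)
class GMAModel:
    name: str
    equations: tuple[GMAEquation, ...]
    parameters: tuple[tuple[str, tuple[float, float]], ...]
    observables: tuple[tuple[str, str], ...] = ()
    expected_peak_order: tuple[str, ...] = ()

    # ---- derived views ------------------------------------------------
    @property
    def variables(self) -> list[str]:
        return [eq.variable for eq in self.equations]

    @property
    def dynamic_variables(self) -> list[str]:
        return [eq.variable for eq in self.equations if not eq.is_algebraic]

    @property
    def auxiliary_variables(self) -> list[str]:
        return [eq.variable for eq in self.equations if eq.is_algebraic]

    @property
    def dynamic_equations(self) -> list[GMAEquation]:
        return [eq for eq in self.equations if not eq.is_algebraic]

    @property
    def auxiliary_equations(self) -> list[GMAEquation]:
        return [eq for eq in self.equations if eq.is_algebraic]

    @property
    def parameter_names(self) -> list[str]:
        return [name for name, _ in self.parameters]

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        return dict(self.parameters)

    @property
    def observable_map(self) -> dict[str, str]:
        return dict(self.observables)

    def __post_init__(self):
        seen: set[str] = set()
        for eq in self.equations:
            if eq.variable in seen:
                raise GMAModelError(f"duplicate variable '{eq.variable}'")
            seen.add(eq.variable)
        hit_algebraic = False
        for eq in self.equations:
            if eq.is_algebraic:
                hit_algebraic = True
            elif hit_algebraic:
                raise GMAModelError(
                    "dynamic variables must precede algebraic auxiliaries")
        pnames = [n for n, _ in self.parameters]
        if len(pnames) != len(set(pnames)):
            raise GMAModelError("parameter registered more than once")
        for name, (lo, hi) in self.parameters:
            if not (0 < lo < hi):
                raise GMAModelError(
                    f"bounds for '{name}' must satisfy 0 < lower < upper")
        referenced = {
            p for eq in self.equations
            for t in eq.production_terms + eq.consumption_terms
            for p, _ in t.parameters
        }
        missing = referenced - set(pnames)
        if missing:
            raise GMAModelError(f"parameters not in registry: {sorted(missing)}")
        labels = [lab for lab, _ in self.observables]
        targets = [v for _, v in self.observables]
        if len(set(targets)) != len(targets):
            raise GMAModelError("observables map must be injective")
        if len(set(labels)) != len(labels):
            raise GMAModelError("duplicate observable label")
        for lab, v in self.observables:
            if v not in self.variables:
                raise GMAModelError(f"observable '{lab}' -> unknown variable '{v}'")
        for lab in self.expected_peak_order:
            if lab not in labels:
                raise GMAModelError(f"peak-order label '{lab}' not an observable")

    def with_bounds(self, bounds: tuple[float, float]) -> "GMAModel":
        """Return a copy with the global bounds applied to every parameter."""
        lo, hi = float(bounds[0]), float(bounds[1])
        return replace(self, parameters=tuple(
            (name, (lo, hi)) for name, _ in self.parameters))

    def to_text(self) -> str:
        return write_gma_model(self)


# ----------------------------------------------------------------------
# parsing
# ----------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<ident>[A-Za-z_][A-Za-z_0-9]*)"
    r"|(?P<op>\*\*|[-+*^]))"
)


def _tokenize(text: str, line_no: int) -> list[tuple[str, str]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            raise GMAParseError(
                f"line {line_no}: unexpected character {text[pos:].lstrip()[:1]!r}")
        if m.lastgroup == "op" and m.group("op") == "**":
            tokens.append(("op", "^"))
        else:
            tokens.append((m.lastgroup, m.group(m.lastgroup)))
        pos = m.end()
    return tokens


def _parse_terms(tokens: list[tuple[str, str]], line_no: int,
                 ) -> list[tuple[int, float, list[tuple[str, float]]]]:
    """Parse ``[sign] factor (*factor)* ((+|-) factor (*factor)*)*``.

    Returns a list of (sign, constant, [(ident, exponent), ...]).
    """
    terms = []
    i = 0
    n = len(tokens)

    def expect_factor(i):
        # factor := (num | ident) ['^' ['-'|'+'] num]
        if i >= n:
            raise GMAParseError(f"line {line_no}: expected a factor")
        kind, val = tokens[i]
        if kind not in ("num", "ident"):
            raise GMAParseError(f"line {line_no}: expected a factor, got {val!r}")
        i += 1
        exponent = 1.0
        if i < n and tokens[i] == ("op", "^"):
            i += 1
            sign = 1.0
            if i < n and tokens[i][0] == "op" and tokens[i][1] in "+-":
                sign = -1.0 if tokens[i][1] == "-" else 1.0
                i += 1
            if i >= n or tokens[i][0] != "num":
                raise GMAParseError(f"line {line_no}: malformed exponent")
            exponent = sign * float(tokens[i][1])
            i += 1
        return (kind, val, exponent), i

    sign = 1
    if n and tokens[0][0] == "op" and tokens[0][1] in "+-":
        sign = -1 if tokens[0][1] == "-" else 1
        i = 1
    while True:
        const = 1.0
        factors: list[tuple[str, float]] = []
        while True:
            (kind, val, exponent), i = expect_factor(i)
            if kind == "num":
                const *= float(val) ** exponent
            else:
                factors.append((val, exponent))
            if i < n and tokens[i] == ("op", "*"):
                i += 1
                continue
            break
        terms.append((sign, const, factors))
        if i >= n:
            return terms
        kind, val = tokens[i]
        if kind != "op" or val not in "+-":
            raise GMAParseError(
                f"line {line_no}: unknown operator {val!r} between terms")
        sign = -1 if val == "-" else 1
        i += 1


def parse_gma_model(text: str, name: str | None = None) -> GMAModel:
    """Parse model-definition text into a :class:`GMAModel`.

    Term order is preserved exactly as written (phenotype signatures index
    into it) and the result round-trips through :func:`write_gma_model`.
    """
    model_name = name or "model"
    observables: list[tuple[str, str]] = []
    peak_order: tuple[str, ...] = ()
    global_bounds = DEFAULT_BOUNDS
    per_param_bounds: dict[str, tuple[float, float]] = {}
    raw_eqs: list[tuple[int, str, bool, list]] = []  # line, var, algebraic, terms

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@"):
            parts = line.split()
            directive = parts[0]
            if directive == "@name":
                model_name = parts[1]
            elif directive == "@species":
                for spec in parts[1:]:
                    lab, _, var = spec.partition("=")
                    if not var:
                        raise GMAParseError(
                            f"line {line_no}: @species entries are LABEL=var")
                    observables.append((lab, var))
            elif directive == "@peak_order":
                peak_order = tuple(parts[1:])
            elif directive == "@bounds":
                global_bounds = (float(parts[1]), float(parts[2]))
            elif directive == "@bound":
                per_param_bounds[parts[1]] = (float(parts[2]), float(parts[3]))
            else:
                raise GMAParseError(f"line {line_no}: unknown directive {directive}")
            continue
        if "=" not in line:
            raise GMAParseError(f"line {line_no}: expected 'var = expr'")
        lhs, rhs = line.split("=", 1)
        lhs = lhs.strip()
        algebraic = not lhs.endswith("'")
        var = lhs[:-1].strip() if not algebraic else lhs
        if not re.fullmatch(r"[A-Za-z_][A-Za-z_0-9]*", var):
            raise GMAParseError(f"line {line_no}: invalid variable name {var!r}")
        terms = _parse_terms(_tokenize(rhs, line_no), line_no)
        raw_eqs.append((line_no, var, algebraic, terms))

    var_names = [v for _, v, _, _ in raw_eqs]
    if len(set(var_names)) != len(var_names):
        dup = [v for v in var_names if var_names.count(v) > 1][0]
        raise GMAModelError(f"duplicate variable '{dup}'")
    var_set = set(var_names)

    param_order: list[str] = []
    equations: list[GMAEquation] = []
    for line_no, var, algebraic, terms in raw_eqs:
        production, consumption = [], []
        for sign, const, factors in terms:
            pexp: dict[str, float] = {}
            vexp: dict[str, float] = {}
            for ident, exponent in factors:
                tgt = vexp if ident in var_set else pexp
                tgt[ident] = tgt.get(ident, 0.0) + exponent
                if ident not in var_set and ident not in param_order:
                    param_order.append(ident)
            term = PowerLawTerm.make(pexp, vexp, const)
            (production if sign > 0 else consumption).append(term)
        if algebraic:
            if consumption:
                raise GMAParseError(
                    f"line {line_no}: algebraic auxiliary '{var}' must be a "
                    f"positive sum of terms")
            consumption = [PowerLawTerm.make(variables={var: 1.0})]
        equations.append(GMAEquation(var, tuple(production), tuple(consumption),
                                     is_algebraic=algebraic))

    params = tuple(
        (p, per_param_bounds.get(p, global_bounds)) for p in param_order)
    return GMAModel(model_name, tuple(equations), params,
                    tuple(observables), peak_order)


def write_gma_model(model: GMAModel) -> str:
    """Serialise a model to its canonical text form (parser inverse)."""
    lines = [f"@name {model.name}"]
    if model.observables:
        lines.append("@species " + " ".join(
            f"{lab}={var}" for lab, var in model.observables))
    if model.expected_peak_order:
        lines.append("@peak_order " + " ".join(model.expected_peak_order))
    bounds = [b for _, b in model.parameters]
    global_bounds = max(set(bounds), key=bounds.count) if bounds else DEFAULT_BOUNDS
    lines.append(f"@bounds {_fmt_number(global_bounds[0])} "
                 f"{_fmt_number(global_bounds[1])}")
    for name, b in model.parameters:
        if b != global_bounds:
            lines.append(f"@bound {name} {_fmt_number(b[0])} {_fmt_number(b[1])}")
    for eq in model.equations:
        parts = [eq.production_terms[0].format()]
        for t in eq.production_terms[1:]:
            parts.append(f"+ {t.format()}")
        if not eq.is_algebraic:
            for t in eq.consumption_terms:
                parts.append(f"- {t.format()}")
        lhs = eq.variable if eq.is_algebraic else eq.variable + "'"
        lines.append(f"{lhs} = " + " ".join(parts))
    return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# auxiliary substitution
# ----------------------------------------------------------------------

def _substitute_term(term: PowerLawTerm, aux: str,
                     definition: PowerLawTerm) -> PowerLawTerm:
    """Replace ``aux^e`` inside ``term`` by ``definition^e`` (pure power law)."""
    vexp = term.variable_dict
    e = vexp.pop(aux, 0.0)
    if e == 0.0:
        return term
    pexp = term.parameter_dict
    for p, g in definition.parameters:
        pexp[p] = pexp.get(p, 0.0) + g * e
    for v, g in definition.variables:
        vexp[v] = vexp.get(v, 0.0) + g * e
    return PowerLawTerm.make(pexp, vexp, term.constant * definition.constant ** e)


def substitute_auxiliaries(model: GMAModel) -> GMAModel:
    """Substitute pure power-law auxiliaries exactly into referencing terms.

    Single-term auxiliaries (e.g. ``c = K_A*x*s``) close under power laws and
    are eliminated; multi-term auxiliaries (rational-regulation denominators)
    are retained so that they keep contributing dominance choices.  Cyclic
    definitions raise :class:`GMAModelError`.
    """
    pure = {eq.variable: eq.production_terms[0]
            for eq in model.auxiliary_equations
            if len(eq.production_terms) == 1}
    if not pure:
        return model

    # resolve pure-aux -> pure-aux references; detect cycles
    resolved: dict[str, PowerLawTerm] = {}

    def resolve(name: str, stack: tuple[str, ...]) -> PowerLawTerm:
        if name in resolved:
            return resolved[name]
        if name in stack:
            raise GMAModelError(f"cyclic auxiliary definitions involving '{name}'")
        term = pure[name]
        for v, _ in term.variables:
            if v in pure:
                term = _substitute_term(term, v, resolve(v, stack + (name,)))
        resolved[name] = term
        return term

    for name in pure:
        resolve(name, ())

    def rewrite(term: PowerLawTerm) -> PowerLawTerm:
        for aux, definition in resolved.items():
            term = _substitute_term(term, aux, definition)
        return term

    equations = []
    for eq in model.equations:
        if eq.is_algebraic and eq.variable in pure:
            continue
        equations.append(GMAEquation(
            eq.variable,
            tuple(rewrite(t) for t in eq.production_terms),
            tuple(rewrite(t) for t in eq.consumption_terms)
            if not eq.is_algebraic else eq.consumption_terms,
            eq.is_algebraic,
        ))
    return replace(model, equations=tuple(equations))


# ----------------------------------------------------------------------
# compiled evaluation
# ----------------------------------------------------------------------

_TINY = 1e-300
_EMPTY = np.empty(0)

try:  # optional JIT fast path for integration-heavy screens
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None

if _numba is not None:
    @_numba.njit(cache=False, fastmath=False)
    def _jit_f_log(u, c, X, M):
        uc = np.minimum(np.maximum(u, -690.0), 690.0)
        tv = c * np.exp(X @ uc)
        return (M @ tv) * np.exp(-uc)

    @_numba.njit(cache=False, fastmath=False)
    def _jit_jac_log(u, c, X, M):
        uc = np.minimum(np.maximum(u, -690.0), 690.0)
        tv = c * np.exp(X @ uc)
        einv = np.exp(-uc)
        g = (M @ tv) * einv
        W = (M * tv) @ X
        n = u.shape[0]
        out = W * einv.reshape(n, 1)
        for i in range(n):
            out[i, i] -= g[i]
        return out

    @_numba.njit(cache=False, fastmath=False)
    def _jit_f_log_aux(u, c, X, A, M, c_aux, X_aux, aux_id, n_aux):
        uc = np.minimum(np.maximum(u, -690.0), 690.0)
        tva = c_aux * np.exp(X_aux @ uc)
        av = np.zeros(n_aux)
        for t in range(tva.shape[0]):
            av[aux_id[t]] += tva[t]
        loga = np.log(np.maximum(av, 1e-300))
        tv = c * np.exp(X @ uc + A @ loga)
        return (M @ tv) * np.exp(-uc)

    @_numba.njit(cache=False, fastmath=False)
    def _jit_jac_log_aux(u, c, X, A, M, c_aux, X_aux, aux_id, n_aux):
        uc = np.minimum(np.maximum(u, -690.0), 690.0)
        n = u.shape[0]
        tva = c_aux * np.exp(X_aux @ uc)
        av = np.zeros(n_aux)
        for t in range(tva.shape[0]):
            av[aux_id[t]] += tva[t]
        av = np.maximum(av, 1e-300)
        # d log(aux_j) / du_k
        R = np.zeros((n_aux, n))
        for t in range(tva.shape[0]):
            j = aux_id[t]
            for k in range(n):
                R[j, k] += tva[t] * X_aux[t, k]
        for j in range(n_aux):
            for k in range(n):
                R[j, k] /= av[j]
        loga = np.log(av)
        tv = c * np.exp(X @ uc + A @ loga)
        D = X + A @ R
        einv = np.exp(-uc)
        g = (M @ tv) * einv
        out = ((M * tv) @ D) * einv.reshape(n, 1)
        for i in range(n):
            out[i, i] -= g[i]
        return out


class CompiledGMA:
    """Array-compiled evaluator for rates and the exact power-law Jacobian.

    Retained (multi-term) auxiliaries are evaluated exactly before the
    dynamic terms; the Jacobian chain-rules through them.  Auxiliaries may
    reference dynamic variables and earlier auxiliaries only.
    """

    def __init__(self, model: GMAModel):
        self.model = model
        self.dynamic_names = model.dynamic_variables
        self.aux_names = model.auxiliary_variables
        self.param_names = model.parameter_names
        n, m = len(self.dynamic_names), len(self.aux_names)
        np_ = len(self.param_names)
        pidx = {p: i for i, p in enumerate(self.param_names)}
        xidx = {v: i for i, v in enumerate(self.dynamic_names)}
        aidx = {v: i for i, v in enumerate(self.aux_names)}

        def term_rows(terms: Sequence[PowerLawTerm], var: str):
            for t in terms:
                prow = np.zeros(np_)
                xrow = np.zeros(n)
                arow = np.zeros(m)
                for p, e in t.parameters:
                    prow[pidx[p]] += e
                for v, e in t.variables:
                    if v in xidx:
                        xrow[xidx[v]] += e
                    elif v in aidx:
                        arow[aidx[v]] += e
                    else:
                        raise GMAModelError(
                            f"term references unknown variable '{v}'")
                yield t.constant, prow, xrow, arow

        # auxiliaries, in order
        self._aux = []
        for j, eq in enumerate(model.auxiliary_equations):
            consts, P, X, A = [], [], [], []
            for c, prow, xrow, arow in term_rows(eq.production_terms, eq.variable):
                if np.any(arow[j:] != 0):
                    raise GMAModelError(
                        f"auxiliary '{eq.variable}' references a later auxiliary")
                consts.append(c); P.append(prow); X.append(xrow); A.append(arow)
            self._aux.append((np.array(consts), np.array(P),
                              np.array(X), np.array(A)))

        consts, P, X, A, sign, eqix = [], [], [], [], [], []
        for i, eq in enumerate(model.dynamic_equations):
            for s, terms in ((1.0, eq.production_terms),
                             (-1.0, eq.consumption_terms)):
                for c, prow, xrow, arow in term_rows(terms, eq.variable):
                    consts.append(c); P.append(prow); X.append(xrow)
                    A.append(arow); sign.append(s); eqix.append(i)
        self._const = np.array(consts)
        self._P = np.array(P)
        self._X = np.array(X)
        self._A = np.array(A) if m else np.zeros((len(consts), 0))
        self._sign = np.array(sign)
        self._eqix = np.array(eqix)
        self.n, self.m = n, m

    # -- helpers --------------------------------------------------------
    def param_vector(self, params: Mapping[str, float]) -> np.ndarray:
        try:
            p = np.array([params[name] for name in self.param_names], float)
        except KeyError as err:
            raise KeyError(f"missing parameter {err.args[0]!r}") from None
        if np.any(p <= 0):
            bad = self.param_names[int(np.argmin(p))]
            raise ValueError(f"parameter '{bad}' must be strictly positive")
        return p

    def state_vector(self, state) -> np.ndarray:
        if isinstance(state, Mapping):
            x = np.array([state[v] for v in self.dynamic_names], float)
        else:
            x = np.asarray(state, float)
        if x.shape != (self.n,):
            raise ValueError(f"state must have length {self.n}")
        return x

    def _coeffs(self, logp: np.ndarray, P: np.ndarray,
                consts: np.ndarray) -> np.ndarray:
        return consts * np.exp(P @ logp)

    def aux_values(self, p: np.ndarray, x: np.ndarray) -> np.ndarray:
        logp = np.log(p)
        logx = np.log(np.maximum(x, _TINY))
        vals = np.empty(self.m)
        for j, (consts, P, X, A) in enumerate(self._aux):
            loga = np.log(np.maximum(vals[:j], _TINY)) if j else np.empty(0)
            tv = self._coeffs(logp, P, consts) * np.exp(
                X @ logx + A[:, :j] @ loga)
            vals[j] = tv.sum()
        return vals

    def rates(self, p: np.ndarray, x: np.ndarray) -> np.ndarray:
        tv = self._term_values(p, x)
        out = np.zeros(self.n)
        np.add.at(out, self._eqix, self._sign * tv)
        return out

    def _term_values(self, p: np.ndarray, x: np.ndarray) -> np.ndarray:
        logp = np.log(p)
        xc = np.maximum(x, _TINY)
        logx = np.log(xc)
        if self.m:
            aux = self.aux_values(p, x)
            loga = np.log(np.maximum(aux, _TINY))
            return self._coeffs(logp, self._P, self._const) * np.exp(
                self._X @ logx + self._A @ loga)
        return self._coeffs(logp, self._P, self._const) * np.exp(self._X @ logx)

    def jacobian(self, p: np.ndarray, x: np.ndarray) -> np.ndarray:
        xc = np.maximum(x, _TINY)
        logp = np.log(p)
        logx = np.log(xc)
        # aux values and d(aux)/dx (m x n), sequentially through the chain
        aux = np.empty(self.m)
        G = np.zeros((self.m, self.n))  # d aux_j / d x_k
        for j, (consts, P, X, A) in enumerate(self._aux):
            loga = np.log(np.maximum(aux[:j], _TINY)) if j else np.empty(0)
            tv = self._coeffs(logp, P, consts) * np.exp(X @ logx + A[:, :j] @ loga)
            aux[j] = tv.sum()
            # d term / dx = term * (X/x + A @ G_prev/aux_prev)
            dlog = X / xc[None, :]
            if j:
                dlog = dlog + (A[:, :j] / np.maximum(aux[:j], _TINY)[None, :]) @ G[:j]
            G[j] = (tv[:, None] * dlog).sum(axis=0)

        tv = self._coeffs(logp, self._P, self._const) * np.exp(
            self._X @ logx + (self._A @ np.log(np.maximum(aux, _TINY))
                              if self.m else 0.0))
        dlog = self._X / xc[None, :]
        if self.m:
            dlog = dlog + (self._A / np.maximum(aux, _TINY)[None, :]) @ G
        J = np.zeros((self.n, self.n))
        np.add.at(J, self._eqix, (self._sign * tv)[:, None] * dlog)
        return J

    def rhs(self, params: Mapping[str, float]):
        """Return ``f(t, x)`` and ``jac(t, x)`` closures for an integrator.

        All parameter-dependent coefficients are evaluated once here, so the
        per-call cost is a handful of small matrix products.
        """
        p = self.param_vector(params)
        logp = np.log(p)
        n, m = self.n, self.m
        tv_coeff = self._coeffs(logp, self._P, self._const)
        aux_coeff = [self._coeffs(logp, P, consts)
                     for consts, P, X, A in self._aux]
        # signed aggregation matrix: rates = M @ term_values
        T = len(self._const)
        M = np.zeros((n, T))
        M[self._eqix, np.arange(T)] = self._sign
        X_T = np.ascontiguousarray(self._X)
        A_T = np.ascontiguousarray(self._A)

        if m == 0:
            def f(t, x):
                logx = np.log(np.clip(x, _TINY, 1e300))
                return M @ (tv_coeff * np.exp(X_T @ logx))

            def jac(t, x):
                xc = np.clip(x, _TINY, 1e300)
                tv = tv_coeff * np.exp(X_T @ np.log(xc))
                return ((M * tv[None, :]) @ X_T) / xc[None, :]

            return f, jac

        aux_data = [(aux_coeff[j], self._aux[j][2], self._aux[j][3][:, :j])
                    for j in range(m)]

        def _aux_vals(logx):
            vals = np.empty(m)
            for j, (cj, Xj, Aj) in enumerate(aux_data):
                loga = np.log(np.maximum(vals[:j], _TINY)) if j else _EMPTY
                vals[j] = (cj * np.exp(Xj @ logx + Aj @ loga)).sum()
            return vals

        def f(t, x):
            logx = np.log(np.clip(x, _TINY, 1e300))
            aux = _aux_vals(logx)
            tv = tv_coeff * np.exp(X_T @ logx + A_T @ np.log(np.maximum(aux, _TINY)))
            return M @ tv

        def jac(t, x):
            xc = np.clip(x, _TINY, 1e300)
            logx = np.log(xc)
            aux = np.empty(m)
            G = np.zeros((m, n))
            for j, (cj, Xj, Aj) in enumerate(aux_data):
                loga = np.log(np.maximum(aux[:j], _TINY)) if j else _EMPTY
                tvj = cj * np.exp(Xj @ logx + Aj @ loga)
                aux[j] = tvj.sum()
                dlog = Xj / xc[None, :]
                if j:
                    dlog = dlog + (Aj / np.maximum(aux[:j], _TINY)[None, :]) @ G[:j]
                G[j] = (tvj[:, None] * dlog).sum(axis=0)
            tv = tv_coeff * np.exp(X_T @ logx + A_T @ np.log(np.maximum(aux, _TINY)))
            dlog = X_T / xc[None, :] + (A_T / np.maximum(aux, _TINY)[None, :]) @ G
            return (M * tv[None, :]) @ dlog

        return f, jac

    def rhs_log(self, params: Mapping[str, float]):
        """RHS and Jacobian for the dynamics of u = ln(x).

        Integrating in log-concentration space keeps every species strictly
        positive and gives uniform *relative* accuracy across species whose
        magnitudes differ by many orders — the typical situation after
        log-uniform parameter sampling.  du_i/dt = f_i(x)/x_i and
        d(du_i/dt)/du_k = J_ik x_k / x_i - delta_ik (du_i/dt).

        When numba is available a JIT kernel is used (term values are
        exp-affine in u, so the whole RHS is two small matrix products).
        """
        jit = self._rhs_log_jit(params)
        if jit is not None:
            return jit
        f_lin, jac_lin = self.rhs(params)

        def f(t, u):
            x = np.exp(np.clip(u, -690.0, 690.0))
            return f_lin(t, x) / x

        def jac(t, u):
            x = np.exp(np.clip(u, -690.0, 690.0))
            g = f_lin(t, x) / x
            J = jac_lin(t, x)
            return J * (x[None, :] / x[:, None]) - np.diag(g)

        return f, jac

    def _rhs_log_jit(self, params: Mapping[str, float]):
        if _numba is None:
            return None
        for consts, P, X, A in self._aux:
            if np.any(A != 0):
                return None  # aux chains: generic python path
        p = self.param_vector(params)
        logp = np.log(p)
        n, m = self.n, self.m
        T = len(self._const)
        M = np.zeros((n, T))
        M[self._eqix, np.arange(T)] = self._sign
        c = np.ascontiguousarray(self._coeffs(logp, self._P, self._const))
        X = np.ascontiguousarray(self._X)

        if m == 0:
            def f(t, u):
                return _jit_f_log(u, c, X, M)

            def jac(t, u):
                return _jit_jac_log(u, c, X, M)

            return f, jac

        A = np.ascontiguousarray(self._A)
        c_aux = np.concatenate([self._coeffs(logp, Pj, cj)
                                for cj, Pj, Xj, Aj in self._aux])
        X_aux = np.ascontiguousarray(np.vstack([Xj for _, _, Xj, _ in self._aux]))
        aux_id = np.concatenate([np.full(len(cj), j, dtype=np.int64)
                                 for j, (cj, _, _, _) in enumerate(self._aux)])
        c_aux = np.ascontiguousarray(c_aux)

        def f(t, u):
            return _jit_f_log_aux(u, c, X, A, M, c_aux, X_aux, aux_id, m)

        def jac(t, u):
            return _jit_jac_log_aux(u, c, X, A, M, c_aux, X_aux, aux_id, m)

        return f, jac


_COMPILED_CACHE: dict[int, CompiledGMA] = {}


def compile_model(model: GMAModel) -> CompiledGMA:
    key = id(model)
    hit = _COMPILED_CACHE.get(key)
    if hit is None or hit.model is not model:
        hit = _COMPILED_CACHE[key] = CompiledGMA(model)
    return hit


def evaluate_rates(model: GMAModel, params: Mapping[str, float], state) -> np.ndarray:
    """Net rate of every dynamic variable at a strictly positive state."""
    c = compile_model(model)
    x = c.state_vector(state)
    if np.any(x <= 0):
        raise ValueError("state entries must be strictly positive")
    r = c.rates(c.param_vector(params), x)
    if not np.all(np.isfinite(r)):
        raise FloatingPointError("non-finite rate encountered")
    return r


def analytic_jacobian(model: GMAModel, params: Mapping[str, float], state) -> np.ndarray:
    """Exact Jacobian d(rates)/d(state) from the power-law derivatives."""
    c = compile_model(model)
    x = c.state_vector(state)
    if np.any(x <= 0):
        raise ValueError("state entries must be strictly positive")
    return c.jacobian(c.param_vector(params), x)
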