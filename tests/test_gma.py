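"""GMA core: parsing, evaluation, Jacobians, auxiliary substitution."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

import oscidesign as od
from oscidesign.gma import (GMAModelError, GMAParseError, compile_model,
                            parse_gma_model, substitute_auxiliaries,
                            write_gma_model)


# ----------------------------------------------------------------------
# parsing
# ----------------------------------------------------------------------

def test_parse_minimal_equation():
    m = parse_gma_model("x' = a - b*x")
    eq = m.equations[0]
    assert len(m.equations) == 1
    assert len(eq.production_terms) == 1
    assert len(eq.consumption_terms) == 1
    assert eq.consumption_terms[0].variable_dict == {"x": 1.0}


def test_parse_term_counting():
    m = parse_gma_model("x' = a - b*x\ny' = a*x + c*y - d*y")
    eq = m.equations[1]
    assert len(eq.production_terms) == 2
    assert len(eq.consumption_terms) == 1


@pytest.mark.parametrize("bad, exc", [
    ("x' = a ? b", GMAParseError),
    ("x' = ", GMAParseError),
    ("x' = a - b*x\nx' = c - d*x", GMAModelError),
    ("x' = a^b - c*x", GMAParseError),       # malformed exponent
])
def test_parse_errors(bad, exc):
    with pytest.raises(exc):
        parse_gma_model(bad)


def test_parse_error_names_line():
    with pytest.raises(GMAParseError, match="line 2"):
        parse_gma_model("x' = a - b*x\ny' = a + + - b*y")


def test_roundtrip_is_identity_on_canonical_text():
    text = ("x' = a + c*x^2*y - b*x\n"
            "y' = d*x - f*y^0.5\n"
            "D = K + y\n")
    m = parse_gma_model(text)
    canonical = write_gma_model(m)
    assert write_gma_model(parse_gma_model(canonical)) == canonical


@pytest.mark.parametrize("design_id", ["1A", "1B", "1C", "2", "3", "4", "5",
                                       "6", "7", "8", "9"])
def test_design_files_roundtrip(design_id):
    m = od.get_design(design_id).model
    canonical = write_gma_model(m)
    assert write_gma_model(parse_gma_model(canonical)) == canonical


def test_design3_parameter_registry():
    # QSSA design: 21 rate constants (designs 4-9 add one inhibition K each)
    m = od.get_design("3").model
    assert len(m.parameter_names) == 21
    assert set(m.observable_map) == {"Sic1", "Clb5", "Clb3", "Clb2"}


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------

def test_rate_steady_state_point():
    m = parse_gma_model("x' = a - b*x")
    assert od.evaluate_rates(m, {"a": 2, "b": 4}, [0.5]) == pytest.approx([0.0])


def test_term_contribution_sign():
    m = parse_gma_model("x' = a - b*x*y\ny' = a - b*y")
    # consumption term b*x*y with b=3, x=2, y=5 contributes -30
    r = od.evaluate_rates(m, {"a": 1, "b": 3}, [2.0, 5.0])
    assert r[0] == pytest.approx(1 - 30)


def _sympy_rates(model, params, state):
    exprs = []
    subs = {sympy.Symbol(k): v for k, v in params.items()}
    subs.update({sympy.Symbol(k): v for k, v in state.items()})
    for eq in model.dynamic_equations:
        expr = sympy.Integer(0)
        for sign, terms in ((1, eq.production_terms), (-1, eq.consumption_terms)):
            for t in terms:
                e = sympy.Float(t.constant, 30)
                for p, g in t.parameters:
                    e *= sympy.Symbol(p) ** sympy.Rational(g)
                for v, g in t.variables:
                    e *= sympy.Symbol(v) ** sympy.Rational(g)
                expr += sign * e
        exprs.append(float(expr.evalf(30, subs=subs)))
    return np.array(exprs)


def test_rates_match_symbolic_oracle():
    m = parse_gma_model("x' = a + c*x*y^2 - b*x\ny' = d*x - f*y - g*x*y")
    rng = np.random.default_rng(42)
    for _ in range(100):
        params = {k: float(10 ** rng.uniform(-2, 2))
                  for k in m.parameter_names}
        state = {v: float(10 ** rng.uniform(-2, 2))
                 for v in m.dynamic_variables}
        got = od.evaluate_rates(m, params, state)
        want = _sympy_rates(m, params, state)
        assert np.allclose(got, want, rtol=1e-12, atol=1e-300)


def test_evaluate_rejects_nonpositive_state():
    m = parse_gma_model("x' = a - b*x")
    with pytest.raises(ValueError):
        od.evaluate_rates(m, {"a": 1, "b": 1}, [0.0])


def test_evaluate_missing_parameter():
    m = parse_gma_model("x' = a - b*x")
    with pytest.raises(KeyError, match="b"):
        od.evaluate_rates(m, {"a": 1}, [1.0])


def test_rates_homogeneous_in_coefficients():
    m = parse_gma_model("x' = a + c*x*y - b*x\ny' = d*x - f*y")
    params = {k: 0.7 + i * 0.3 for i, k in enumerate(m.parameter_names)}
    state = [0.4, 1.7]
    lam = 3.7
    r1 = od.evaluate_rates(m, params, state)
    r2 = od.evaluate_rates(m, {k: lam * v for k, v in params.items()}, state)
    assert np.allclose(r2, lam * r1, rtol=1e-12)


# ----------------------------------------------------------------------
# Jacobian
# ----------------------------------------------------------------------

def _fd_jacobian(model, params, state, rel=1e-6):
    x = np.asarray(state, float)
    n = len(x)
    J = np.zeros((n, n))
    for k in range(n):
        h = rel * x[k]
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        J[:, k] = (od.evaluate_rates(model, params, xp)
                   - od.evaluate_rates(model, params, xm)) / (2 * h)
    return J


def test_jacobian_linear_case():
    m = parse_gma_model("x' = a - b*x")
    J = od.analytic_jacobian(m, {"a": 1, "b": 4}, [2.0])
    assert J == pytest.approx(np.array([[-4.0]]))


def test_jacobian_matches_finite_differences():
    m = parse_gma_model(
        "w' = a + e1*x*z - b*w\n"
        "x' = c*w - d*x*y^2\n"
        "y' = f*x - g*y\n"
        "z' = h*y - k*z*w")
    rng = np.random.default_rng(7)
    for _ in range(50):
        params = {k: float(10 ** rng.uniform(-1, 1)) for k in m.parameter_names}
        state = 10 ** rng.uniform(-1, 1, size=4)
        J = od.analytic_jacobian(m, params, state)
        Jfd = _fd_jacobian(m, params, state)
        scale = np.abs(Jfd).max()
        assert np.allclose(J, Jfd, rtol=1e-6, atol=1e-6 * scale)


def test_lotka_volterra_trace_zero(lotka_volterra):
    params = {"a": 1.3, "b": 0.7, "c": 2.1, "d": 0.9}
    state = {"x": params["d"] / params["c"], "y": params["a"] / params["b"]}
    J = od.analytic_jacobian(lotka_volterra, params, state)
    assert np.trace(J) == pytest.approx(0.0, abs=1e-12)


@st.composite
def random_gma(draw):
    n = draw(st.integers(1, 5))
    names = [f"x{i}" for i in range(n)]
    lines = []
    pcount = 0
    for i, v in enumerate(names):
        n_p = draw(st.integers(1, 4))
        n_c = draw(st.integers(1, 4))
        def term(consume):
            nonlocal pcount
            pcount += 1
            factors = [f"p{pcount}"]
            for j in range(n):
                e = draw(st.sampled_from([0, 0, 0, 1, 2, -1])) \
                    if not (consume and j == i) else draw(st.sampled_from([1, 2]))
                if e:
                    factors.append(names[j] if e == 1 else f"{names[j]}^{e}")
            return "*".join(factors)
        prods = [term(False) for _ in range(n_p)]
        cons = [term(True) for _ in range(n_c)]
        lines.append(f"{v}' = " + " + ".join(prods) + " - " + " - ".join(cons))
    return parse_gma_model("\n".join(lines))


@settings(max_examples=25, derandomize=True, deadline=None)
@given(random_gma(), st.integers(0, 2 ** 31 - 1))
def test_jacobian_property_random_models(model, seed):
    rng = np.random.default_rng(seed)
    params = {k: float(10 ** rng.uniform(-1, 1)) for k in model.parameter_names}
    state = 10 ** rng.uniform(-0.5, 0.5, size=len(model.dynamic_variables))
    J = od.analytic_jacobian(model, params, state)
    Jfd = _fd_jacobian(model, params, state)
    scale = max(np.abs(Jfd).max(), 1.0)
    assert np.allclose(J, Jfd, rtol=1e-5, atol=1e-5 * scale)


# ----------------------------------------------------------------------
# auxiliary substitution
# ----------------------------------------------------------------------

def test_substitute_pure_power_law_closure():
    m = parse_gma_model("x' = a - d*c_x\ns' = v - b*s\nc_x = K_A*x*s")
    flat = substitute_auxiliaries(m)
    assert flat.auxiliary_variables == []
    term = flat.dynamic_equations[0].consumption_terms[0]
    assert term.parameter_dict == {"d": 1.0, "K_A": 1.0}
    assert term.variable_dict == {"x": 1.0, "s": 1.0}


def test_substitute_no_auxiliaries_identity():
    m = parse_gma_model("x' = a - b*x")
    assert substitute_auxiliaries(m) is m


def test_substitute_cyclic_error():
    m = parse_gma_model("x' = a - b*u\nu = K*w\nw = L*u")
    with pytest.raises(GMAModelError, match="cyclic"):
        substitute_auxiliaries(m)


def test_flattened_design3_rates_equivalent():
    m = od.get_design("3").model
    flat = substitute_auxiliaries(m)
    rng = np.random.default_rng(11)
    for _ in range(100):
        params = {k: float(10 ** rng.uniform(-3, 2)) for k in m.parameter_names}
        state = {v: float(10 ** rng.uniform(-2, 1))
                 for v in m.dynamic_variables}
        r1 = od.evaluate_rates(m, params, state)
        r2 = od.evaluate_rates(flat, params, state)
        assert np.allclose(r1, r2, rtol=1e-12)


def test_denominator_auxiliary_retained():
    m = od.get_design("4").model
    flat = substitute_auxiliaries(m)
    assert flat.auxiliary_variables == ["D_zx"]
    # and evaluation handles the rational term exactly
    params = {k: 1.0 for k in m.parameter_names}
    state = {v: 1.0 for v in m.dynamic_variables}
    r = od.evaluate_rates(flat, params, state)
    # x equation: v_x*K_zx/(K_zx+z) = 0.5 at unit values
    consumption = 1 + 1 + 1 + 1  # beta_x + gamma_yx + gamma_zx + epsilon*K_A
    assert r[0] == pytest.approx(0.5 - consumption)
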