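"""Design-space decomposition: signatures, S-systems, LP validity, stability."""

import itertools

import numpy as np
import pytest
import sympy

import oscidesign as od
from oscidesign.designspace import (DegeneratePhenotypeError, boundary_slacks,
                                    build_ssystem, case_id_to_signature,
                                    count_signatures, enumerate_signatures,
                                    parameter_tolerance, phenotype_validity,
                                    signature_to_case_id, ssystem_steady_state,
                                    stability_report)
from oscidesign.gma import parse_gma_model, substitute_auxiliaries


# ----------------------------------------------------------------------
# counting and enumeration
# ----------------------------------------------------------------------

def test_count_product_rule():
    m = parse_gma_model(
        "x' = a1 + a2 - b1*x - b2*x\n"
        "y' = c1 + c2 - d1*y - d2*y\n"
        "z' = e1 + e2 - f1*z - f2*z")
    assert count_signatures(m) == 64


def test_count_single():
    m = parse_gma_model("x' = a - b*x")
    assert count_signatures(m) == 1


def test_enumerate_four_signatures():
    m = parse_gma_model("x' = a1 + a2 - b1*x - b2*x")
    sigs = list(enumerate_signatures(m))
    assert [s.case_id for s in sigs] == [1, 2, 3, 4]
    assert sigs[0].choices == ((0, 0),)
    assert sigs[-1].choices == ((1, 1),)


def test_enumeration_length_matches_count_on_random_toys():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n_eq = rng.integers(1, 4)
        lines = []
        for i in range(n_eq):
            n_p, n_c = rng.integers(1, 4, size=2)
            prods = " + ".join(f"p{i}_{j}" for j in range(n_p))
            cons = " - ".join(f"q{i}_{j}*x{i}" for j in range(n_c))
            lines.append(f"x{i}' = {prods} - {cons}")
        m = parse_gma_model("\n".join(lines))
        assert len(list(enumerate_signatures(m))) == count_signatures(m)


def test_case_id_bijection():
    m = parse_gma_model(
        "x' = a1 + a2 - b*x\ny' = c - d1*y - d2*y\nz' = e1 + e2 + e3 - f*z")
    for sig in enumerate_signatures(m):
        assert signature_to_case_id(m, sig.choices) == sig.case_id
        assert case_id_to_signature(m, sig.case_id).choices == sig.choices


def test_design3_count_matches_enumeration_oracle():
    flat = substitute_auxiliaries(od.get_design("3").model)
    by_hand = 1
    for eq in flat.equations:
        by_hand *= len(eq.production_terms) * len(eq.consumption_terms)
    assert count_signatures(flat) == by_hand
    # exhaustive enumeration agrees (also exercises laziness on 2304 cases)
    assert sum(1 for _ in enumerate_signatures(flat)) == by_hand


# ----------------------------------------------------------------------
# S-system construction and steady states
# ----------------------------------------------------------------------

def test_minimal_ssystem_no_boundaries():
    m = parse_gma_model("x' = a - b*x")
    ss = build_ssystem(m, case_id_to_signature(m, 1))
    assert ss.n_boundaries == 0
    state = ssystem_steady_state(ss, {"a": 2.0, "b": 4.0})
    assert state["x"] == pytest.approx(0.5)
    # homogeneity of the toy: doubling a doubles x*
    state2 = ssystem_steady_state(ss, {"a": 4.0, "b": 4.0})
    assert state2["x"] == pytest.approx(1.0)


def test_two_production_terms_one_boundary(two_term_toy):
    ss = build_ssystem(two_term_toy, case_id_to_signature(two_term_toy, 1))
    assert ss.n_boundaries == 1
    # boundary is log a1 - log a2 >= 0
    slack = boundary_slacks(ss, {"a1": 100.0, "a2": 1.0, "b": 1.0})
    assert slack == pytest.approx([2.0])


def test_boundary_count_on_random_toys():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n_eq = int(rng.integers(1, 4))
        lines, total_terms = [], 0
        for i in range(n_eq):
            n_p, n_c = (int(v) for v in rng.integers(1, 4, size=2))
            total_terms += n_p + n_c
            prods = " + ".join(f"p{i}_{j}" for j in range(n_p))
            cons = " - ".join(f"q{i}_{j}*x{i}" for j in range(n_c))
            lines.append(f"x{i}' = {prods} - {cons}")
        m = parse_gma_model("\n".join(lines))
        sig = case_id_to_signature(m, 1)
        try:
            ss = build_ssystem(m, sig)
        except DegeneratePhenotypeError:
            continue
        assert ss.n_boundaries == total_terms - 2 * n_eq


def test_steady_state_matches_symbolic_closed_form(cross_toy):
    # dx = a - b*x*y ; dy = c*x - d*y  =>  x* = sqrt(a*d/(b*c)), y* = c*x*/d
    ss = build_ssystem(cross_toy, case_id_to_signature(cross_toy, 1))
    a, b, c, d = sympy.symbols("a b c d", positive=True)
    x_star = sympy.sqrt(a * d / (b * c))
    y_star = c * x_star / d
    rng = np.random.default_rng(17)
    for _ in range(50):
        vals = {k: float(10 ** rng.uniform(-3, 3)) for k in "abcd"}
        got = ssystem_steady_state(ss, vals)
        subs = {a: vals["a"], b: vals["b"], c: vals["c"], d: vals["d"]}
        assert got["x"] == pytest.approx(float(x_star.evalf(30, subs=subs)),
                                         rel=1e-12)
        assert got["y"] == pytest.approx(float(y_star.evalf(30, subs=subs)),
                                         rel=1e-12)


def test_degenerate_phenotype_flagged():
    # both dominant terms have identical state dependence -> singular system
    m = parse_gma_model("x' = a*x - b*x")
    with pytest.raises(DegeneratePhenotypeError):
        build_ssystem(m, case_id_to_signature(m, 1))


# ----------------------------------------------------------------------
# validity LP
# ----------------------------------------------------------------------

def test_single_signature_model_feasible_everywhere():
    m = parse_gma_model("x' = a - b*x")
    ss = build_ssystem(m, case_id_to_signature(m, 1))
    feasible, witness = phenotype_validity(ss)
    assert feasible
    for v in witness.values():
        assert 1e-9 <= v <= 1e3


def test_two_term_symmetry_both_feasible(two_term_toy):
    for case in (1, 2):
        ss = build_ssystem(two_term_toy, case_id_to_signature(two_term_toy, case))
        feasible, witness = phenotype_validity(ss)
        assert feasible
        # witness satisfies its own boundaries strictly
        assert boundary_slacks(ss, witness).min() > 0


def test_validity_agrees_with_brute_force_dominance(cross_toy_ext=None):
    """LP verdicts vs direct dominance testing at sampled parameter points.

    The toy's full-model steady state is computed numerically per point and
    term dominance evaluated directly; every sampled point must fall in an
    LP-feasible phenotype, and every LP-infeasible phenotype must receive
    no points (off boundaries).
    """
    m = parse_gma_model("x' = a1 + a2*y - b*x\ny' = c*x - d1*y - d2*y^2")
    sigs = list(enumerate_signatures(m))
    systems = {}
    verdicts = {}
    for sig in sigs:
        try:
            ss = build_ssystem(m, sig)
        except DegeneratePhenotypeError:
            continue
        systems[sig.case_id] = ss
        verdicts[sig.case_id] = phenotype_validity(ss)[0]

    from scipy.optimize import fsolve

    from oscidesign.gma import compile_model
    comp = compile_model(m)
    comp_params = list(m.parameter_names)
    rng = np.random.default_rng(23)
    hits = {cid: 0 for cid in systems}
    n_pts = 10_000
    for _ in range(n_pts):
        params = {k: float(10 ** rng.uniform(-3, 3)) for k in comp_params}
        f, _ = comp.rhs(params)

        def rhs(logx):
            with np.errstate(all="ignore"):
                r = f(0.0, np.exp(np.clip(logx, -50, 50)))
            return np.where(np.isfinite(r), r, 1e150)

        sol, info, ok, _ = fsolve(rhs, np.zeros(2), full_output=True)
        if ok != 1 or np.abs(info["fvec"]).max() > 1e-9:
            continue
        state = dict(zip(m.dynamic_variables, np.exp(sol)))
        # identify the dominant signature at this point
        choices = []
        margin = np.inf
        for eq in m.equations:
            pv = [t.value(params, state) for t in eq.production_terms]
            cv = [t.value(params, state) for t in eq.consumption_terms]
            pi, ci = int(np.argmax(pv)), int(np.argmax(cv))
            choices.append((pi, ci))
            for vals, j in ((pv, pi), (cv, ci)):
                if len(vals) > 1:
                    second = max(v for k, v in enumerate(vals) if k != j)
                    margin = min(margin, vals[j] / second)
        if margin < 1.05:
            continue  # too close to a dominance boundary
        cid = signature_to_case_id(m, choices)
        if cid not in systems:
            continue
        assert verdicts[cid], (
            f"point dominated by LP-infeasible phenotype {cid}")
        hits[cid] += 1
    # the oracle must have actually exercised a few thousand points
    assert sum(hits.values()) > n_pts * 0.2


def test_validity_monotone_under_bound_widening(two_term_toy):
    m = parse_gma_model(
        "x' = a1 + a2 - b1*x - b2*x^2\ny' = c*x - d*y")
    for sig in enumerate_signatures(m):
        try:
            ss = build_ssystem(m, sig)
        except DegeneratePhenotypeError:
            continue
        narrow, _ = phenotype_validity(ss, bounds=(1e-6, 1e2))
        wide, _ = phenotype_validity(ss, bounds=(1e-9, 1e3))
        if narrow:
            assert wide


# ----------------------------------------------------------------------
# tolerance
# ----------------------------------------------------------------------

def test_tolerance_unconstrained_parameter(two_term_toy):
    ss = build_ssystem(two_term_toy, case_id_to_signature(two_term_toy, 1))
    params = {"a1": 10.0, "a2": 1.0, "b": 1.0}
    lo, hi = parameter_tolerance(ss, params, "b")
    assert (lo, hi) == pytest.approx((1e-9, 1e3))


def test_tolerance_half_space(two_term_toy):
    # boundary a1 >= a2 with a2 = 1: a1 tolerance is [1, 1e3]
    ss = build_ssystem(two_term_toy, case_id_to_signature(two_term_toy, 1))
    lo, hi = parameter_tolerance(ss, {"a1": 10.0, "a2": 1.0, "b": 1.0}, "a1")
    assert lo == pytest.approx(1.0)
    assert hi == pytest.approx(1e3)


def test_tolerance_contains_current_value(two_term_toy):
    ss = build_ssystem(two_term_toy, case_id_to_signature(two_term_toy, 1))
    rng = np.random.default_rng(2)
    for _ in range(50):
        a2 = float(10 ** rng.uniform(-6, 2))
        a1 = a2 * float(10 ** rng.uniform(0, 1))
        params = {"a1": a1, "a2": a2, "b": float(10 ** rng.uniform(-6, 2))}
        for name in params:
            lo, hi = parameter_tolerance(ss, params, name)
            assert lo * (1 - 1e-9) <= params[name] <= hi * (1 + 1e-9)


def test_tolerance_requires_valid_point(two_term_toy):
    ss = build_ssystem(two_term_toy, case_id_to_signature(two_term_toy, 1))
    with pytest.raises(ValueError):
        parameter_tolerance(ss, {"a1": 1.0, "a2": 10.0, "b": 1.0}, "b")


# ----------------------------------------------------------------------
# stability
# ----------------------------------------------------------------------

def test_stability_linear_decay():
    m = parse_gma_model("x' = a - b*x")
    ss = build_ssystem(m, case_id_to_signature(m, 1))
    rep = stability_report(ss, {"a": 1.0, "b": 3.0})
    assert rep.eigenvalues == pytest.approx([-3.0])
    assert not rep.has_oscillatory_pair
    assert rep.n_nonnegative_real == 0


def test_stability_lotka_volterra_center(lotka_volterra):
    ss = build_ssystem(lotka_volterra,
                       case_id_to_signature(lotka_volterra, 1))
    params = {"a": 1.0, "b": 1.0, "c": 1.0, "d": 4.0}
    rep = stability_report(ss, params)
    # eigenvalues +-i*sqrt(a*d): conjugate pair with zero real part counts
    assert sorted(rep.eigenvalues.imag) == pytest.approx([-2.0, 2.0])
    assert np.abs(rep.eigenvalues.real).max() < 1e-9
    assert rep.has_oscillatory_pair
    assert rep.n_nonnegative_real >= 2


def test_eigenvalues_come_in_conjugate_pairs(goodwin):
    ss = build_ssystem(goodwin, case_id_to_signature(goodwin, 1))
    rep = stability_report(ss, {k: 1.0 for k in goodwin.parameter_names})
    eig = np.sort_complex(rep.eigenvalues)
    assert np.allclose(np.sort_complex(np.conj(eig)), eig)
    if rep.has_oscillatory_pair:
        assert rep.n_nonnegative_real >= 2


def test_stability_eigenvalues_match_fd_jacobian():
    m = parse_gma_model("x' = a - b*x*y\ny' = c*x - d*y")
    ss = build_ssystem(m, case_id_to_signature(m, 1))
    rng = np.random.default_rng(29)
    for _ in range(10):
        params = {k: float(10 ** rng.uniform(-1, 1)) for k in "abcd"}
        rep = stability_report(ss, params)
        state = [rep.steady_state[v] for v in m.dynamic_variables]
        x = np.asarray(state)
        J = np.zeros((2, 2))
        for k in range(2):
            h = 1e-6 * x[k]
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            J[:, k] = (od.evaluate_rates(m, params, xp)
                       - od.evaluate_rates(m, params, xm)) / (2 * h)
        want = np.sort_complex(np.linalg.eigvals(J))
        got = np.sort_complex(rep.eigenvalues)
        assert np.allclose(got, want, rtol=1e-6, atol=1e-6 * np.abs(want).max())
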