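"""Built-in cell-cycle network designs and small fixture oscillators.

Eleven designs of a minimal budding-yeast Clb/Cdk1 oscillator ship with the
package as plain-text GMA model files.  Designs 1A, 1B, 1C and 2 describe
the Clb/Cdk1/Sic1 ternary complexes with explicit mass-action kinetics
(association k_plus, dissociation k_minus); designs 3-9 replace them by a
quasi-steady-state binding equilibrium (association constant K_A), and
designs 4-9 each add one saturating transcriptional inhibition whose
strength is a design-specific K parameter.

The model files are a documented reconstruction of the interaction set
described for this network family: they are the package's single source of
truth for the equations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

from .gma import GMAModel, parse_gma_model

__all__ = ["CellCycleDesign", "get_design", "list_designs",
           "make_fixture_oscillator", "FIXTURE_KINDS"]

_GLOSSARY = {
    "v_x": "basal synthesis of Clb5/Cdk1 (x)",
    "v_y": "basal synthesis of Clb3/Cdk1 (y)",
    "v_z": "basal synthesis of Clb2/Cdk1 (z)",
    "v_s": "basal synthesis of Sic1 (s)",
    "beta_x": "basal degradation of Clb5/Cdk1",
    "beta_y": "basal degradation of Clb3/Cdk1",
    "beta_z": "basal degradation of Clb2/Cdk1",
    "beta_s": "basal degradation of Sic1",
    "alpha_xy": "activation of CLB3 synthesis by Clb5/Cdk1 (cascade step 1)",
    "alpha_yy": "Clb3 positive feedback loop (CLB3 synthesis by Clb3/Cdk1)",
    "alpha_xz": "activation of CLB2 synthesis by Clb5/Cdk1 (feed-forward)",
    "alpha_yz": "activation of CLB2 synthesis by Clb3/Cdk1 (cascade step 2)",
    "alpha_zz": "Clb2 positive feedback loop (CLB2 synthesis by Clb2/Cdk1)",
    "gamma_yx": "APC-mediated inhibition of Clb5 by Clb3/Cdk1",
    "gamma_zx": "APC-mediated inhibition of Clb5 by Clb2/Cdk1",
    "gamma_yy": "APC-mediated Clb3 self negative feedback loop",
    "gamma_zy": "APC-mediated inhibition of Clb3 by Clb2/Cdk1",
    "gamma_zz": "APC-mediated Clb2 self negative feedback loop",
    "delta": "degradation of Sic1 from the Clb/Cdk1/Sic1 ternary complex",
    "epsilon": "degradation of Clb from the Clb/Cdk1/Sic1 ternary complex",
    "K_A": "association constant of Clb/Cdk1 + Sic1 binding (QSSA designs)",
    "k_plus": "association rate of Clb/Cdk1 + Sic1 (mass-action designs)",
    "k_minus": "dissociation rate of the ternary complex (mass-action designs)",
    "k_cln": "lumped Cln/Cdk1-mediated degradation of free Sic1 (designs 1A-1C)",
    "K_zx": "transcriptional inhibition of Clb5 synthesis by Clb2/Cdk1 (design 4)",
    "K_zs": "transcriptional inhibition of Sic1 synthesis by Clb2/Cdk1 (design 5)",
    "K_cs": "inhibition of Sic1 synthesis by all Clb/Cdk1 complexes (design 6)",
    "K_sm": "inhibition of Clb3/Clb2 synthesis by Sic1 (design 7)",
    "K_sc": "inhibition of Clb5/Clb3/Clb2 synthesis by Sic1 (design 8)",
    "K_ss": "inhibition of Sic1 synthesis by Sic1 (design 9)",
}


@dataclass(frozen=True)
class CellCycleDesign:
    design_id: str
    model: GMAModel
    glossary: dict[str, str]
    k_parameter: str | None
    description: str
    file_sha256: str


def _manifest() -> dict:
    with resources.files("oscidesign.models").joinpath("manifest.json").open() as fh:
        return json.load(fh)


def list_designs() -> list[str]:
    """The available design identifiers, in canonical order."""
    return list(_manifest()["designs"])


def design_text(design_id: str) -> str:
    entry = _manifest()["designs"].get(str(design_id))
    if entry is None:
        raise KeyError(
            f"unknown design {design_id!r}; valid ids: {list_designs()}")
    return resources.files("oscidesign.models").joinpath(entry["file"]).read_text()


def get_design(design_id: str) -> CellCycleDesign:
    """Load one of the 11 built-in designs from its packaged definition file."""
    entry = _manifest()["designs"].get(str(design_id))
    if entry is None:
        raise KeyError(
            f"unknown design {design_id!r}; valid ids: {list_designs()}")
    text = design_text(design_id)
    model = parse_gma_model(text)
    glossary = {p: _GLOSSARY.get(p, "") for p in model.parameter_names}
    return CellCycleDesign(
        design_id=str(design_id),
        model=model,
        glossary=glossary,
        k_parameter=entry["k_parameter"],
        description=entry["description"],
        file_sha256=hashlib.sha256(text.encode()).hexdigest(),
    )


# ----------------------------------------------------------------------
# fixture oscillators for testing and examples
# ----------------------------------------------------------------------

_FIXTURES = {
    # Goodwin-type repressilator loop in power-law form: X3 represses X1
    # synthesis with exponent -10.  At equal rate constants the fixed point
    # is (1,1,1) and the Hopf threshold of the repression exponent is 8, so
    # this instance oscillates.  Peak order follows the cascade X1->X2->X3.
    "negative_feedback_3node": """\
@name negative_feedback_3node
@species X1=x1 X2=x2 X3=x3
@peak_order X1 X2 X3
x1' = a*x3^-10 - b*x1
x2' = c*x1 - d*x2
x3' = g*x2 - f*x3
""",
    # Conservative predator-prey oscillator: the fixed point (d/c, a/b) has
    # purely imaginary eigenvalues +-i*sqrt(a*d), the canonical
    # oscillatory-potential test case.
    "lotka_volterra": """\
@name lotka_volterra
@species Prey=x Predator=y
@peak_order Prey Predator
x' = a*x - b*x*y
y' = c*x*y - d*y
""",
    # Feed-forward chain with no feedback: all eigenvalues real negative,
    # globally stable fixed point, guaranteed screen-negative.
    "linear_chain": """\
@name linear_chain
@species X1=x1 X2=x2 X3=x3
@peak_order X1 X2 X3
x1' = a - b*x1
x2' = c*x1 - d*x2
x3' = g*x2 - f*x3
""",
}

FIXTURE_KINDS = tuple(_FIXTURES)


def make_fixture_oscillator(kind: str) -> GMAModel:
    """Small benchmark models with analytically known behaviour."""
    try:
        text = _FIXTURES[kind]
    except KeyError:
        raise KeyError(
            f"unknown fixture {kind!r}; valid kinds: {sorted(_FIXTURES)}"
        ) from None
    return parse_gma_model(text)
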