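"""End-to-end screening pipeline for one network design.

For every dominance phenotype of a (flattened) model the pipeline

1. builds the S-system and checks LP feasibility of its boundaries
   (invalid and degenerate phenotypes are counted and skipped),
2. draws ``samples_per_phenotype`` valid log-uniform parameter sets,
3. solves the phenotype's closed-form steady state per sample and screens
   its eigenvalues for a complex-conjugate pair with non-negative real
   part (the Hopf necessary condition),
4. integrates the *full* kinetic model from that steady state (one species
   nudged by 1%) for every sample passing the screen, and keeps every
   verified limit cycle.

The eigenvalue screen is a necessary-condition filter only: samples that
fail it are never integrated, so oscillations whose dominant-subsystem
stability differs from the full model can be missed — the price of making
large design spaces tractable.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .designs import CellCycleDesign, get_design
from .designspace import (DegeneratePhenotypeError, LPSolverError, SSystem,
                          build_ssystem, count_signatures, enumerate_signatures,
                          phenotype_validity, stability_report,
                          stability_reports_batch)
from .gma import GMAModel, substitute_auxiliaries
from .limitcycle import (VERDICT_LIMIT_CYCLE, LimitCycleRecord,
                         detect_limit_cycle)
from .sampling import sample_valid_phenotype

__all__ = ["ScreenResult", "SampleOutcome", "run_design_screen",
           "summarize_counts", "count_dominant_parameters"]

logger = logging.getLogger(__name__)


@dataclass
class SampleOutcome:
    """Per-sample summary retained for the aggregate tables."""

    case_id: int
    sample_index: int
    has_oscillatory_pair: bool
    n_nonnegative_real: int
    verdict: str | None = None   # None when the eigenvalue screen filtered it


@dataclass
class ScreenResult:
    """Aggregate of one design screen (one row of the summary table)."""

    design: str
    config: dict
    n_total: int = 0
    n_valid: int = 0
    n_degenerate: int = 0
    n_potential: int = 0          # phenotypes with >=1 oscillatory sample
    n_lc_phenotypes: int = 0      # distinct phenotypes with a limit cycle
    n_limit_cycles: int = 0
    records: list[LimitCycleRecord] = field(default_factory=list)
    samples: list[SampleOutcome] = field(default_factory=list)
    valid_case_ids: list[int] = field(default_factory=list)
    degenerate_case_ids: list[int] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)

    def check_invariants(self) -> None:
        assert self.n_potential <= self.n_valid <= self.n_total
        assert self.n_lc_phenotypes == len(
            {r.case_id for r in self.records})
        assert self.n_limit_cycles == len(self.records)


def _resolve_model(design) -> tuple[str, GMAModel]:
    if isinstance(design, CellCycleDesign):
        return design.design_id, design.model
    if isinstance(design, GMAModel):
        return design.name, design
    return str(design), get_design(str(design)).model


# Seed-independent per-design preparation (S-systems + LP validity) is
# cached so that multi-seed screens pay for the enumeration only once.
_PREP_CACHE: dict = {}


def _prepare_design(model: GMAModel, bounds):
    key = (model.to_text(), tuple(bounds) if bounds else None)
    hit = _PREP_CACHE.get(key)
    if hit is not None:
        return hit
    valid: list[SSystem] = []
    degenerate: list[int] = []
    failures: list[str] = []
    n_total = count_signatures(model)
    for sig in enumerate_signatures(model):
        try:
            ss = build_ssystem(model, sig)
        except DegeneratePhenotypeError:
            degenerate.append(sig.case_id)
            continue
        try:
            feasible, _ = phenotype_validity(ss, bounds=bounds)
        except LPSolverError as err:
            failures.append(f"case {sig.case_id}: LP failure: {err}")
            continue
        if feasible:
            valid.append(ss)
    prep = (n_total, valid, degenerate, failures)
    _PREP_CACHE[key] = prep
    return prep


def run_design_screen(design, samples_per_phenotype: int = 250,
                      seed: int = 0, bounds=None,
                      horizon: float = 10_000.0, window_length: float = 500.0,
                      dt: float = 0.1, perturbation: float = 1.01,
                      progress: bool = False,
                      case_ids: Iterable[int] | None = None) -> ScreenResult:
    """Screen one design for autonomous limit cycles.

    ``bounds`` overrides the global parameter range (default: the model's
    registry, normally [1e-9, 1e3]).  ``case_ids`` restricts the screen to a
    subset of phenotypes (used for follow-up analyses).  Deterministic for a
    fixed seed; per-sample substreams make the record set at a smaller
    ``samples_per_phenotype`` a prefix-subset of a larger one.
    """
    name, raw_model = _resolve_model(design)
    model = substitute_auxiliaries(raw_model)
    result = ScreenResult(design=name, config=dict(
        samples_per_phenotype=samples_per_phenotype, seed=seed,
        bounds=list(bounds) if bounds else None, horizon=horizon,
        window_length=window_length, dt=dt, perturbation=perturbation))
    n_total, valid_ss, degenerate_ids, prep_failures = _prepare_design(
        model, bounds)
    result.n_total = n_total
    result.failures.extend(prep_failures)
    restrict = set(case_ids) if case_ids is not None else None
    result.n_degenerate = len(degenerate_ids)
    result.degenerate_case_ids = list(degenerate_ids)

    obs_vars = [v for _, v in model.observables] or model.dynamic_variables
    t_start = time.monotonic()
    for ss in valid_ss:
        sig = ss.signature
        if restrict is not None and sig.case_id not in restrict:
            continue
        result.n_valid += 1
        result.valid_case_ids.append(sig.case_id)

        try:
            points = sample_valid_phenotype(ss, samples_per_phenotype, seed,
                                            bounds=bounds, design=name)
        except ValueError as err:
            result.failures.append(f"case {sig.case_id}: sampling: {err}")
            continue
        phenotype_potential = False
        reports = stability_reports_batch(ss, [p.as_dict for p in points])
        for point, rep in zip(points, reports):
            if rep is None:
                result.failures.append(
                    f"case {sig.case_id} sample {point.provenance.sample_index}: "
                    f"non-finite steady state or Jacobian")
                continue
            outcome = SampleOutcome(sig.case_id, point.provenance.sample_index,
                                    rep.has_oscillatory_pair,
                                    rep.n_nonnegative_real)
            if rep.has_oscillatory_pair:
                phenotype_potential = True
                x0 = {v: rep.steady_state[v] for v in ss.var_names}
                x0[obs_vars[0]] *= perturbation
                rec, _ = detect_limit_cycle(model, point.as_dict, x0,
                                            horizon=horizon,
                                            window_length=window_length, dt=dt)
                outcome.verdict = rec.verdict
                if rec.verdict == VERDICT_LIMIT_CYCLE:
                    rec.case_id = sig.case_id
                    rec.point = point
                    result.records.append(rec)
            result.samples.append(outcome)
        if phenotype_potential:
            result.n_potential += 1
        if progress:
            logger.info("case %d done (%.1fs elapsed, %d LC so far)",
                        sig.case_id, time.monotonic() - t_start,
                        len(result.records))

    result.n_limit_cycles = len(result.records)
    result.n_lc_phenotypes = len({r.case_id for r in result.records})
    result.check_invariants()
    return result


def summarize_counts(result: ScreenResult) -> dict:
    """One summary-table row: phenotype and limit-cycle counts for a design."""
    return {
        "design": result.design,
        "total_phenotypes": result.n_total,
        "valid_phenotypes": result.n_valid,
        "degenerate_phenotypes": result.n_degenerate,
        "oscillatory_potential": result.n_potential,
        "phenotypes_with_limit_cycles": result.n_lc_phenotypes,
        "limit_cycles_retrieved": result.n_limit_cycles,
    }


def count_dominant_parameters(result: ScreenResult, model: GMAModel,
                              ) -> tuple[dict[str, int], set[str]]:
    """Occurrence of parameters in dominant terms of limit-cycle phenotypes.

    Counts are per distinct phenotype (not per limit cycle).  Parameters
    contained in *every* term of some equation side are dominant in every
    phenotype by construction; they are returned separately rather than
    counted.
    """
    from .designspace import case_id_to_signature

    flat = substitute_auxiliaries(model)
    always: set[str] = set()
    for eq in flat.equations:
        sides = [eq.production_terms]
        if not eq.is_algebraic:
            sides.append(eq.consumption_terms)
        for terms in sides:
            common = set(dict(terms[0].parameters))
            for t in terms[1:]:
                common &= set(dict(t.parameters))
            always |= common

    counts = {p: 0 for p in flat.parameter_names}
    for case_id in sorted({r.case_id for r in result.records}):
        sig = case_id_to_signature(flat, case_id)
        dominant_params: set[str] = set()
        for eq, (p_i, c_i) in zip(flat.equations, sig.choices):
            dominant_params |= set(dict(eq.production_terms[p_i].parameters))
            if not eq.is_algebraic:
                dominant_params |= set(dict(eq.consumption_terms[c_i].parameters))
        for p in dominant_params - always:
            counts[p] += 1
    for p in always:
        counts.pop(p, None)
    return counts, always
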