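"""Random, valid, log-uniform parameter sets inside a phenotype's boundaries.

The sampler walks the parameters in a freshly shuffled order for every
point; each parameter in turn gets its 1D phenotypic tolerance (given the
values already fixed) and is drawn log-uniformly inside it.  Because every
draw stays inside the current tolerance, the finished point satisfies all
dominance boundaries by construction.  Log-uniform means uniform in log10
between the interval endpoints: equal relative changes are equally likely,
which is the natural measure for rate constants spanning many decades.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .designspace import (SSystem, boundary_slacks, phenotype_validity,
                          tolerance_log10, _log_bounds, _log_params)

__all__ = ["ParameterPoint", "sample_valid_phenotype", "point_rng"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Provenance:
    design: str
    case_id: int
    sample_index: int
    seed: int


@dataclass(frozen=True)
class ParameterPoint:
    """A concrete positive parameter assignment plus how to regenerate it."""

    values: tuple[tuple[str, float], ...]
    provenance: Provenance

    @property
    def as_dict(self) -> dict[str, float]:
        return dict(self.values)

    def __getitem__(self, name: str) -> float:
        return dict(self.values)[name]


def point_rng(seed: int, design: str, case_id: int,
              sample_index: int) -> np.random.Generator:
    """Deterministic per-sample substream.

    Hashing (design, case_id, sample index) into the seed sequence makes
    substreams independent and schedule-free: sample ``i`` of a phenotype is
    the same whether 10 or 250 samples are requested.
    """
    tag = zlib.crc32(design.encode())
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), tag, int(case_id), int(sample_index)]))


def sample_valid_phenotype(ss: SSystem, n: int, seed: int,
                           bounds=None, design: str | None = None,
                           max_retries: int = 10,
                           start: int = 0) -> list[ParameterPoint]:
    """Draw ``n`` valid log-uniform points for a feasible phenotype.

    Every returned point satisfies all boundary inequalities; phenotypes
    whose tolerance chain collapses numerically are retried with a fresh
    shuffle up to ``max_retries`` times, then the point is skipped (logged).
    """
    design = design or ss.model.name
    feasible, witness = phenotype_validity(ss, bounds=bounds)
    if not feasible:
        raise ValueError(
            f"phenotype case {ss.signature.case_id} is not feasible")
    q_witness = _log_params(ss, witness)
    lo_all, hi_all = _log_bounds(ss, bounds)

    points: list[ParameterPoint] = []
    for i in range(start, start + n):
        rng = point_rng(seed, design, ss.signature.case_id, i)
        q = None
        for attempt in range(max_retries):
            q_try = q_witness.copy()
            order = rng.permutation(len(ss.param_names))
            ok = True
            for j in order:
                try:
                    lo, hi = tolerance_log10(ss, q_try, j, lo_all[j], hi_all[j])
                except ValueError:
                    ok = False
                    break
                if hi < lo - 1e-12:
                    ok = False
                    break
                q_try[j] = rng.uniform(lo, max(hi, lo))
            if ok:
                q = q_try
                break
        if q is None:
            logger.warning(
                "tolerance collapse for design=%s case=%s sample=%d "
                "after %d retries; skipping", design, ss.signature.case_id,
                i, max_retries)
            continue
        values = tuple((p, 10.0 ** qi) for p, qi in zip(ss.param_names, q))
        point = ParameterPoint(values, Provenance(design, ss.signature.case_id,
                                                  i, seed))
        slack = boundary_slacks(ss, point.as_dict)
        if slack.size and slack.min() < -1e-7:
            logger.warning("sampled point violates boundaries (%.3g); skipped",
                           slack.min())
            continue
        points.append(point)
    return points
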