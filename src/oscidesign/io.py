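"""Run configuration, result persistence and logging helpers.

Results are written as a versioned JSON document (``result.json``) plus
derived CSV tables (summary row, per-sample outcomes, limit cycles); the
JSON alone is sufficient to regenerate every CSV.  Every result embeds the
seed, package version and the SHA-256 of the model definition it was run
on, so any published number is traceable to a command line.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .limitcycle import LimitCycleRecord, SpeciesStats
from .pipeline import SampleOutcome, ScreenResult, summarize_counts
from .sampling import ParameterPoint, Provenance

__all__ = ["RunConfig", "write_results", "read_results",
           "ResultSchemaError", "setup_logging"]

SCHEMA_VERSION = 1


class ResultSchemaError(ValueError):
    """Result file missing or carrying an incompatible schema version."""


@dataclass
class RunConfig:
    """Fully serialisable description of a screen run (re-runs identically)."""

    design: str = "3"
    samples_per_phenotype: int = 250
    seed: int = 0
    bounds: tuple[float, float] | None = None
    horizon: float = 10_000.0
    window_length: float = 500.0
    dt: float = 0.1
    out_dir: str = "results"
    analyses: list[str] = field(default_factory=list)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        if data["bounds"] is not None:
            data["bounds"] = list(data["bounds"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("bounds") is not None:
            data["bounds"] = tuple(data["bounds"])
        return cls(**data)


def _record_to_json(rec: LimitCycleRecord) -> dict:
    point = None
    if rec.point is not None:
        point = {
            "values": dict(rec.point.values),
            "provenance": dataclasses.asdict(rec.point.provenance),
        }
    return {
        "verdict": rec.verdict,
        "period": rec.period,
        "species_stats": {lab: dataclasses.asdict(s)
                          for lab, s in rec.species_stats.items()},
        "peak_order": list(rec.peak_order) if rec.peak_order else None,
        "case_id": rec.case_id,
        "point": point,
        "n_windows": rec.n_windows,
        "integrators": list(rec.integrators),
    }


def _record_from_json(d: dict) -> LimitCycleRecord:
    point = None
    if d.get("point"):
        point = ParameterPoint(
            tuple((k, float(v)) for k, v in d["point"]["values"].items()),
            Provenance(**d["point"]["provenance"]))
    return LimitCycleRecord(
        verdict=d["verdict"],
        period=d["period"],
        species_stats={lab: SpeciesStats(**s)
                       for lab, s in d["species_stats"].items()},
        peak_order=tuple(d["peak_order"]) if d.get("peak_order") else None,
        case_id=d.get("case_id"),
        point=point,
        n_windows=d.get("n_windows", 0),
        integrators=tuple(d.get("integrators", ())),
    )


def write_results(result: ScreenResult, out_dir: str | Path,
                  model_sha256: str | None = None) -> Path:
    """Write ``result.json`` plus derived CSV tables; returns the JSON path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "model_sha256": model_sha256,
        "design": result.design,
        "config": result.config,
        "counts": summarize_counts(result),
        "valid_case_ids": result.valid_case_ids,
        "degenerate_case_ids": result.degenerate_case_ids,
        "failures": result.failures,
        "samples": [dataclasses.asdict(s) for s in result.samples],
        "records": [_record_to_json(r) for r in result.records],
    }
    json_path = out / "result.json"
    json_path.write_text(json.dumps(doc, indent=1))

    pd.DataFrame([summarize_counts(result)]).to_csv(out / "table1.csv",
                                                    index=False)
    pd.DataFrame([dataclasses.asdict(s) for s in result.samples]).to_csv(
        out / "samples.csv", index=False)
    lc_rows = []
    for r in result.records:
        row = {"case_id": r.case_id, "period": r.period,
               "peak_order": "->".join(r.peak_order or ()),
               "n_windows": r.n_windows}
        if r.point is not None:
            row.update({"sample_index": r.point.provenance.sample_index,
                        **r.point.as_dict})
        lc_rows.append(row)
    pd.DataFrame(lc_rows).to_csv(out / "limit_cycles.csv", index=False)
    return json_path


def read_results(path: str | Path) -> ScreenResult:
    """Load a ``result.json`` back into a :class:`ScreenResult`."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ResultSchemaError(f"unreadable result file: {err}") from None
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ResultSchemaError(
            f"result schema {version!r} incompatible with {SCHEMA_VERSION}")
    counts = doc["counts"]
    result = ScreenResult(design=doc["design"], config=doc["config"])
    result.n_total = counts["total_phenotypes"]
    result.n_valid = counts["valid_phenotypes"]
    result.n_degenerate = counts["degenerate_phenotypes"]
    result.n_potential = counts["oscillatory_potential"]
    result.n_lc_phenotypes = counts["phenotypes_with_limit_cycles"]
    result.n_limit_cycles = counts["limit_cycles_retrieved"]
    result.valid_case_ids = list(doc["valid_case_ids"])
    result.degenerate_case_ids = list(doc["degenerate_case_ids"])
    result.failures = list(doc["failures"])
    result.samples = [SampleOutcome(**s) for s in doc["samples"]]
    result.records = [_record_from_json(r) for r in doc["records"]]
    result.check_invariants()
    return result


def setup_logging(out_dir: str | Path | None = None,
                  level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(out_dir) / "run.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True)
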