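"""Desk-scale reproduction suite.

Replays the small published numerics that can be recomputed from printed
inputs alone (efficiency ratio, preset-model evaluations, noiseless model
recovery) and reports pass/fail with observed values.  The case table and
the explicit list of quantities that are *not* reproducible live in
``data/repro_cases.yaml`` so both are auditable without reading code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import yaml

from .efficiency import (
    VariantRecord,
    fit_efficiency_model,
    model_regulatory_potential,
    predict_efficiency,
    preset_model,
    regulatory_potential,
)


@dataclass(frozen=True)
class ReproCase:
    case_id: str
    kind: str
    inputs: dict
    expected: object
    tolerance_rel: float
    note: str = ""


@dataclass(frozen=True)
class CaseResult:
    case: ReproCase
    observed: object
    passed: bool


@dataclass(frozen=True)
class ReproReport:
    results: tuple
    not_reproducible: tuple

    @property
    def all_passed(self) -> bool:
        return all(r.passed for r in self.results)

    def to_markdown(self) -> str:
        lines = ["# Reproduction report", "", "| case | expected | observed | pass |",
                 "|---|---|---|---|"]
        for r in self.results:
            lines.append(
                f"| {r.case.case_id} | {_fmt(r.case.expected)} | "
                f"{_fmt(r.observed)} | {'yes' if r.passed else 'NO'} |"
            )
        lines += ["", "## Not reproducible at desk scale", ""]
        lines += [f"- {item}" for item in self.not_reproducible]
        return "\n".join(lines) + "\n"


def _fmt(value) -> str:
    if isinstance(value, dict):
        return ", ".join(f"{k}={v:.6g}" for k, v in value.items())
    return f"{value:.6g}"


def load_cases() -> tuple[list[ReproCase], list[str]]:
    raw = yaml.safe_load(
        resources.files("dgscan").joinpath("data/repro_cases.yaml").read_text()
    )
    cases = [
        ReproCase(
            case_id=c["id"],
            kind=c["kind"],
            inputs=c["inputs"],
            expected=c["expected"],
            tolerance_rel=float(c["tolerance_rel"]),
            note=c.get("note", ""),
        )
        for c in raw["cases"]
    ]
    return cases, list(raw["not_reproducible"])


def run_case(case: ReproCase) -> CaseResult:
    inp = case.inputs
    if case.kind == "ratio":
        observed = regulatory_potential(inp["reference_eff"], inp["variant_eff"])
    elif case.kind == "preset_predict":
        observed = predict_efficiency(preset_model(inp["preset"]), inp["delta_g"])
    elif case.kind == "preset_potential":
        observed = model_regulatory_potential(
            preset_model(inp["preset"]), inp["reference_dg"], inp["variant_dg"]
        )
    elif case.kind == "noiseless_fit":
        model = preset_model(inp["preset"])
        records = [
            VariantRecord(f"x{i}", dg, predict_efficiency(model, dg))
            for i, dg in enumerate(inp["delta_g_values"])
        ]
        fit = fit_efficiency_model(records)
        observed = {"a": fit.a, "b": fit.b, "r_squared": fit.r_squared}
    else:
        raise ValueError(f"unknown case kind {case.kind!r}")
    passed = _within(observed, case.expected, case.tolerance_rel)
    return CaseResult(case=case, observed=observed, passed=passed)


def _within(observed, expected, tol_rel: float) -> bool:
    if isinstance(expected, dict):
        return all(_within(observed[k], expected[k], tol_rel) for k in expected)
    return math.isclose(observed, expected, rel_tol=tol_rel, abs_tol=tol_rel)


def run_repro_suite() -> ReproReport:
    """Execute every case; failures are report entries, not exceptions."""
    cases, not_repro = load_cases()
    return ReproReport(
        results=tuple(run_case(c) for c in cases),
        not_reproducible=tuple(not_repro),
    )
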