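"""Exponential model linking 5'UTR folding energy to translation efficiency.

Relative translation efficiency y (% of an unstructured-leader control)
rises exponentially with the folding Gibbs energy X (kcal/mol, X <= 0 for
folded UTRs):

    y = a * exp(b * X)

so ln(y) is linear in X and the parameters are estimated by ordinary least
squares of ln(efficiency) on delta_g.  ``a`` is the efficiency extrapolated
to an unfolded UTR (X = 0); ``b`` (per kcal/mol) is the relative efficiency
loss per kcal/mol of folding stability.  r^2 is reported on the log-linear
scale, matching the fitting procedure.

Two published parameterizations for the thyroid-hormone-receptor-beta
(TRbeta1) 5'UTR variant panel ship as named presets ("fig1c": a = 127.29,
b = 0.0248; "results-text": a = 140.46, b = 0.0307); the package hard-codes
neither as *the* model since the two cannot be adjudicated from the printed
record.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class VariantRecord:
    """One (variant, folding dG, measured efficiency) observation.

    ``delta_g`` in kcal/mol; ``efficiency`` in % of control, > 0 when the
    record is used for fitting (its log is taken).
    """

    name: str
    delta_g: float
    efficiency: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_g):
            raise ValueError(f"variant {self.name!r}: delta_g must be finite")


@dataclass(frozen=True)
class EfficiencyModel:
    """Fitted (or preset) exponential efficiency model y = a * exp(b * X)."""

    a: float
    b: float
    r_squared: float = float("nan")
    n_points: int = 0
    stderr_b: float = float("nan")
    fit_log: tuple = ()  # (delta_g, ln efficiency) pairs used in the fit

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("prefactor a must be > 0")

    def predict(self, delta_g: float):
        """Predicted efficiency (%) at folding energy ``delta_g`` (kcal/mol)."""
        return self.a * np.exp(self.b * np.asarray(delta_g, dtype=float))

    def to_json(self) -> str:
        d = asdict(self)
        d["fit_log"] = [list(p) for p in self.fit_log]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EfficiencyModel":
        d = json.loads(text)
        d["fit_log"] = tuple(tuple(p) for p in d.get("fit_log", ()))
        return cls(**d)


PRESETS = {
    "fig1c": EfficiencyModel(a=127.29, b=0.0248),
    "results-text": EfficiencyModel(a=140.46, b=0.0307),
}


def preset_model(name: str) -> EfficiencyModel:
    """A named published parameterization (see module docstring)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}") from None


def fit_efficiency_model(records) -> EfficiencyModel:
    """OLS of ln(efficiency) on delta_g; a = exp(intercept), b = slope.

    Requires at least two records with distinct delta_g and strictly
    positive efficiencies.  Deterministic (closed-form least squares).
    """
    records = list(records)
    for rec in records:
        if rec.efficiency <= 0:
            raise ValueError(
                f"variant {rec.name!r}: efficiency {rec.efficiency} must be > 0 for fitting"
            )
    x = np.array([r.delta_g for r in records], dtype=float)
    y = np.log([r.efficiency for r in records])
    if len(np.unique(x)) < 2:
        raise ValueError("degenerate fit: need >= 2 records with distinct delta_g")
    res = stats.linregress(x, y)
    return EfficiencyModel(
        a=float(np.exp(res.intercept)),
        b=float(res.slope),
        r_squared=float(res.rvalue**2),
        n_points=len(records),
        stderr_b=float(res.stderr),
        fit_log=tuple(zip(x.tolist(), y.tolist())),
    )


def predict_efficiency(model: EfficiencyModel, delta_g: float) -> float:
    """Efficiency (%) predicted at ``delta_g``; increasing in dG when b > 0."""
    return float(model.predict(delta_g))


def regulatory_potential(reference_eff: float, variant_eff: float) -> float:
    """Fold-headroom of a variant relative to a reference efficiency.

    A strongly folded (low-efficiency) variant has a large ratio: it has
    more room for oligo-mediated enhancement toward the reference level.
    """
    if reference_eff <= 0 or variant_eff <= 0:
        raise ValueError("efficiencies must be > 0")
    return reference_eff / variant_eff


def model_regulatory_potential(
    model: EfficiencyModel, reference_dg: float, variant_dg: float
) -> float:
    """Model-based potential: ratio of predicted efficiencies.

    Closed form exp(b * (reference_dg - variant_dg)); the prefactor cancels.
    """
    return regulatory_potential(
        predict_efficiency(model, reference_dg), predict_efficiency(model, variant_dg)
    )
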