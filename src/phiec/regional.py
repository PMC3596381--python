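"""Region-specific environmental algorithms for Phi_e,C.

A :class:`RegionalAlgorithm` is an ordinary linear model mapping raw-scale
environmental variables (temperature degC, salinity, NO3/PO4 umol L-1,
chl a mg m-3, Kd m-1, optical depth zeta) to the electron requirement for
carbon fixation. The package ships a registry of published algorithms for
a set of biogeographic regions plus a pooled global model; new algorithms
are fitted per cluster with :func:`fit_mlr` on variables selected by the
BEST procedure (no stepwise selection happens here — variable choice is
the subset-search stage's job).

Note the deliberate dual-scale convention: resemblance/clustering/BEST
operate on sqrt-transformed, normalised variables, while these regression
equations are expressed on raw variable scales so their coefficients carry
physical units (e.g. mol e- (mol C)-1 per degC).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionalAlgorithm",
    "PhiPrediction",
    "fit_mlr",
    "load_published_algorithms",
    "predict_phi",
]


@dataclass(frozen=True)
class RegionalAlgorithm:
    """Linear model environment -> Phi_e,C for one region or cluster."""

    region_id: str
    variables: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float = 0.0
    has_intercept: bool = True
    r_squared: Optional[float] = None
    p: Optional[str | float] = None
    provenance: str = "fitted"  # {'published', 'fitted'}
    description: str = ""
    symbols: tuple[str, ...] = ()
    coef_strings: tuple[str, ...] = ()   #: printed coefficient text, for round-trip
    intercept_string: Optional[str] = None
    envelope: Optional[dict] = None      #: per-variable (min, max) seen in training

    def __post_init__(self):
        if not self.variables:
            raise ValueError("an algorithm needs at least one variable")
        if len(self.variables) != len(self.coefficients):
            raise ValueError("one coefficient per variable required")

    def equation_string(self) -> str:
        """Human-readable equation; published entries reproduce the printed text."""
        if self.coef_strings:
            parts = []
            for cs, sym in zip(self.coef_strings, self.symbols or self.variables):
                if parts and not cs.startswith("-"):
                    parts.append("+")
                parts.append(f"{cs}{sym}")
            eq = "".join(parts)
            if self.has_intercept and self.intercept_string is not None:
                s = self.intercept_string
                eq += s if s.startswith("-") else f"+{s}"
            return eq
        terms = []
        for c, v in zip(self.coefficients, self.variables):
            terms.append(f"{c:+.4g}{v}")
        eq = "".join(terms).lstrip("+")
        if self.has_intercept:
            eq += f"{self.intercept:+.4g}"
        return eq


@dataclass(frozen=True)
class PhiPrediction:
    """A Phi_e,C prediction with validity and extrapolation flags."""

    value: float
    valid: bool                 #: False when the linear model returns <= 0
    extrapolated: bool = False  #: True when any input leaves the training envelope
    region_id: str = ""

    def __float__(self) -> float:
        return self.value


def load_published_algorithms() -> dict[str, RegionalAlgorithm]:
    """Registry of the published region-specific algorithms, keyed by region id.

    Includes the pooled global model (T, NO3, PO4) and the per-cluster and
    per-region models with a printed significant regression. One entry
    (``gof_cluster_b``) prints no intercept term; it is stored with
    intercept 0 and ``has_intercept=False``.
    """
    text = resources.files("phiec.data").joinpath("published_algorithms.json").read_text()
    raw = json.loads(text)
    registry: dict[str, RegionalAlgorithm] = {}
    for entry in raw["algorithms"]:
        terms = entry["terms"]
        intercept_s = entry["intercept"]
        registry[entry["region_id"]] = RegionalAlgorithm(
            region_id=entry["region_id"],
            variables=tuple(t["var"] for t in terms),
            coefficients=tuple(float(t["coef"]) for t in terms),
            intercept=float(intercept_s) if intercept_s is not None else 0.0,
            has_intercept=intercept_s is not None,
            r_squared=entry["r_squared"],
            p=entry["mlr_p"],
            provenance="published",
            description=entry["description"],
            symbols=tuple(t["symbol"] for t in terms),
            coef_strings=tuple(t["coef"] for t in terms),
            intercept_string=intercept_s,
        )
    return registry


def fit_mlr(
    table: pd.DataFrame,
    variables: Sequence[str],
    response: str = "phi_ec",
    region_id: str = "fitted",
    min_n: int = 5,
) -> RegionalAlgorithm:
    """Ordinary least squares of Phi_e,C on raw-scale variables.

    Refuses clusters with fewer than ``min_n`` complete rows (algorithms
    need a minimal support); a rank-deficient design raises an error
    listing the collinear variables. Returns coefficients, intercept, R2
    and the overall F-test p-value.
    """
    import statsmodels.api as sm

    variables = list(variables)
    data = table[variables + [response]].dropna()
    n = len(data)
    if n < min_n:
        raise ValueError(f"cluster has n={n} < {min_n} complete rows: refusing to fit")
    X = data[variables].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = _collinear_variables(X, variables)
        raise ValueError(f"rank-deficient design; collinear variables: {collinear}")
    model = sm.OLS(data[response].to_numpy(dtype=float), design).fit()
    params = model.params
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(model.rsquared)
        f_pvalue = float(model.f_pvalue)
    if not np.isfinite(r2):  # constant response: no variance to explain
        r2 = 0.0
    f_p = f_pvalue if np.isfinite(f_pvalue) else None
    envelope = {v: (float(data[v].min()), float(data[v].max())) for v in variables}
    return RegionalAlgorithm(
        region_id=region_id,
        variables=tuple(variables),
        coefficients=tuple(float(b) for b in params[1:]),
        intercept=float(params[0]),
        has_intercept=True,
        r_squared=r2,
        p=f_p,
        provenance="fitted",
        envelope=envelope,
    )


def _collinear_variables(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name the variables involved in exact linear dependence."""
    out = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(np.column_stack([others, np.ones(len(X))])) == np.linalg.matrix_rank(
            np.column_stack([others, np.ones(len(X)), X[:, j]])
        ):
            out.append(names[j])
    return out or list(names)


def predict_phi(
    alg: RegionalAlgorithm, env: Mapping[str, float] | pd.Series
) -> PhiPrediction:
    """Evaluate a regional algorithm on one environment record.

    Raises a KeyError naming any missing variable. A non-positive
    prediction is returned with ``valid=False`` (the electron requirement
    is physically positive) and a warning, never silently. When the
    algorithm records a training envelope, inputs outside it set
    ``extrapolated=True`` with a warning.
    """
    values = []
    for v in alg.variables:
        if v not in env or (isinstance(env, pd.Series) and pd.isna(env[v])):
            raise KeyError(f"environment record missing variable {v!r}")
        values.append(float(env[v]))
    pred = float(np.dot(alg.coefficients, values)) + (alg.intercept if alg.has_intercept else 0.0)
    extrapolated = False
    if alg.envelope:
        for v, x in zip(alg.variables, values):
            lo, hi = alg.envelope[v]
            if not (lo <= x <= hi):
                extrapolated = True
        if extrapolated:
            warnings.warn(
                f"{alg.region_id}: input outside training envelope; "
                "regional algorithms extrapolate poorly", stacklevel=2,
            )
    valid = pred > 0
    if not valid:
        warnings.warn(
            f"{alg.region_id}: predicted Phi_e,C={pred:.4g} <= 0 is unphysical",
            stacklevel=2,
        )
    return PhiPrediction(value=pred, valid=valid, extrapolated=extrapolated,
                         region_id=alg.region_id)
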