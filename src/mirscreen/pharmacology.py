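"""Dose-response fitting and ZIP synergy scoring.

Viability grids over two agents are summarised with the Zero Interaction
Potency (ZIP) model: four-parameter logistic (4PL) curves are fitted to the
two monotherapy margins, the zero-interaction expectation at each dose pair
is the Bliss combination of the fitted single-agent inhibition fractions,

    y_zip(a, b) = y_A(a) + y_B(b) - y_A(a) * y_B(b),

and the synergy signal is delta(a, b) = observed - expected inhibition (on
the percent scale).  The overall score is the unweighted mean delta over all
non-zero dose combinations; by the conventional thresholds a score < 0 is
antagonistic, 0-5 additive and > 5 synergistic.

The 4PL model is response = bottom + (top - bottom) / (1 + (dose/ec50)^hill)
with the relative (curve-midpoint) IC50 reported as ec50.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

ANTAGONISTIC = "antagonistic"
ADDITIVE = "additive"
SYNERGISTIC = "synergistic"


class FitError(RuntimeError):
    """A dose-response fit failed or degenerated."""


@dataclass(frozen=True)
class DoseResponseCurve:
    top: float
    bottom: float
    ec50: float
    hill: float
    residual_sd: float
    n_points: int

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.bottom > self.top:
            raise ValueError("bottom must not exceed top")

    def predict(self, dose) -> np.ndarray:
        return four_pl(np.asarray(dose, dtype=float),
                       self.top, self.bottom, self.ec50, self.hill)


@dataclass
class DoseResponseSurface:
    """Viability (%) grid over two agents, including zero-dose margins.

    ``response[i, j]`` is the viability at ``doses_a[i]`` x ``doses_b[j]``.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    response: np.ndarray
    agent_a: str = "A"
    agent_b: str = "B"

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValueError("response shape must be (len(doses_a), len(doses_b))")
        if 0.0 not in self.doses_a or 0.0 not in self.doses_b:
            raise ValueError("surface must include zero-dose monotherapy margins")
        if not np.isfinite(self.response).all():
            raise ValueError("responses must be finite")

    def to_csv(self) -> str:
        df = pd.DataFrame(self.response, index=self.doses_a, columns=self.doses_b)
        df.index.name = f"{self.agent_a}\\{self.agent_b}"
        return df.to_csv()

    @classmethod
    def from_csv(cls, text: str, agent_a: str = "A", agent_b: str = "B"):
        import io

        df = pd.read_csv(io.StringIO(text), index_col=0)
        return cls(
            doses_a=df.index.to_numpy(dtype=float),
            doses_b=df.columns.to_numpy(dtype=float),
            response=df.to_numpy(dtype=float),
            agent_a=agent_a, agent_b=agent_b,
        )


@dataclass
class ZipResult:
    overall_score: float
    delta: pd.DataFrame  # % scale, combination wells only (NaN on margins)
    interaction_class: str
    margin_fit_a: DoseResponseCurve = None
    margin_fit_b: DoseResponseCurve = None


def viability_normalize(raw, vehicle_control_values) -> np.ndarray:
    """Percent viability: 100 * raw / mean(vehicle controls)."""
    controls = np.asarray(vehicle_control_values, dtype=float)
    mean = controls.mean()
    if mean <= 0:
        raise ValueError(f"control mean must be positive, got {mean}")
    return 100.0 * np.asarray(raw, dtype=float) / mean


def four_pl(dose, top, bottom, ec50, hill):
    """4PL response; the dose = 0 limit is top for hill > 0, bottom for hill < 0."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(dose > 0, (dose / ec50) ** hill, np.where(hill > 0, 0.0, np.inf))
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_four_pl(doses, responses) -> DoseResponseCurve:
    """Least-squares 4PL fit with deterministic data-driven initialisation.

    Requires >= 4 distinct doses.  Flat response vectors are rejected as
    degenerate; non-convergence raises :class:`FitError` with diagnostics.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(np.unique(d)) < 4:
        raise ValueError("need >= 4 distinct doses for a 4PL fit")
    span = r.max() - r.min()
    if span < 1e-9 * max(1.0, abs(r.max())):
        raise FitError("flat responses: 4PL parameters unidentifiable")
    top0, bottom0 = float(r.max()), float(r.min())
    pos = d[d > 0]
    ec50_0 = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1.0
    # slope sign from response trend over dose order
    trend = np.polyfit(np.argsort(np.argsort(d)), r, 1)[0]
    hill0 = 1.0 if trend < 0 else -1.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                four_pl, d, r, p0=[top0, bottom0, ec50_0, hill0],
                bounds=([-np.inf, -np.inf, 1e-12, -50], [np.inf, np.inf, np.inf, 50]),
                maxfev=20000,
            )
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    top, bottom, ec50, hill = (float(v) for v in popt)
    if bottom > top:
        top, bottom, hill = bottom, top, -hill
    resid = r - four_pl(d, top, bottom, ec50, hill)
    return DoseResponseCurve(
        top=top, bottom=bottom, ec50=ec50, hill=hill,
        residual_sd=float(np.sqrt(np.mean(resid**2))), n_points=len(d),
    )


def _margin_inhibition(curve: DoseResponseCurve, doses: np.ndarray) -> np.ndarray:
    """Fitted single-agent inhibition fraction, clipped to [0, 1]."""
    return np.clip(1.0 - curve.predict(doses) / 100.0, 0.0, 1.0)


def zip_synergy_score(surface: DoseResponseSurface) -> ZipResult:
    """ZIP synergy score of a two-agent viability surface.

    Fits 4PL curves to both monotherapy margins, forms the Bliss
    zero-interaction expectation from the fitted inhibition fractions, and
    averages delta = (observed - expected inhibition) x 100 over all
    combination wells (both doses > 0).
    """
    ia = np.where(surface.doses_b == 0)[0]
    ib = np.where(surface.doses_a == 0)[0]
    margin_a = surface.response[:, ia[0]]
    margin_b = surface.response[ib[0], :]
    if len(surface.doses_a) < 4 or len(surface.doses_b) < 4:
        raise ValueError("each margin needs >= 4 doses (including zero)")
    try:
        fit_a = fit_four_pl(surface.doses_a, margin_a)
        fit_b = fit_four_pl(surface.doses_b, margin_b)
    except FitError as exc:
        raise FitError(f"monotherapy margin fit failed: {exc}") from exc
    y_a = _margin_inhibition(fit_a, surface.doses_a)
    y_b = _margin_inhibition(fit_b, surface.doses_b)
    expected = y_a[:, None] + y_b[None, :] - y_a[:, None] * y_b[None, :]
    observed = 1.0 - surface.response / 100.0
    delta = (observed - expected) * 100.0
    combo = (surface.doses_a[:, None] > 0) & (surface.doses_b[None, :] > 0)
    if not combo.any():
        raise ValueError("surface has no non-zero dose combinations")
    overall = float(delta[combo].mean())
    delta_df = pd.DataFrame(
        np.where(combo, delta, np.nan),
        index=pd.Index(surface.doses_a, name=surface.agent_a),
        columns=pd.Index(surface.doses_b, name=surface.agent_b),
    )
    return ZipResult(
        overall_score=overall, delta=delta_df,
        interaction_class=classify_interaction(overall),
        margin_fit_a=fit_a, margin_fit_b=fit_b,
    )


def classify_interaction(score: float) -> str:
    """< 0 antagonistic; 0-5 (closed) additive; > 5 synergistic."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    if score < 0:
        return ANTAGONISTIC
    if score <= 5:
        return ADDITIVE
    return SYNERGISTIC


def reporter_fold_change(
    wells: pd.DataFrame, control_condition: str
) -> pd.DataFrame:
    """Renilla/Firefly ratio fold changes relative to the control condition.

    ``wells`` needs columns condition, renilla, firefly.  Wells with zero
    firefly signal are excluded with a warning.  Fold change = well ratio /
    mean(control ratios).
    """
    required = {"condition", "renilla", "firefly"}
    if not required.issubset(wells.columns):
        raise ValueError(f"wells table needs columns {sorted(required)}")
    w = wells.copy()
    zero = w["firefly"] == 0
    if zero.any():
        logger.warning("excluding %d well(s) with zero firefly signal", int(zero.sum()))
        w = w[~zero]
    w["ratio"] = w["renilla"] / w["firefly"]
    controls = w.loc[w["condition"] == control_condition, "ratio"]
    if controls.empty:
        raise ValueError(f"no control wells for condition {control_condition!r}")
    w["fold_change"] = w["ratio"] / controls.mean()
    return w[["condition", "ratio", "fold_change"]]
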