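"""Interaction-evaluation statistics.

Implements the effect PK ratio (exposure under a genotype variant and/or
co-administration divided by the reference exposure), the geometric mean
fold error (GMFE) of predicted vs. observed ratios, and observed-ratio-
dependent prediction-success limits with a variability margin
(Guest-type limits), plus the stratified summary tables built from them.

GMFE convention: ``10 ** (mean |log10(pred/obs)|)`` — every fold error is
>= 1 and the statistic is invariant under swapping predicted and observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

EFFECT_CLASSES = ("DGI", "DDI", "DDGI")
DEFAULT_DELTA = 1.25  # the 20% predictive-variability margin


@dataclass
class EffectRatio:
    """Exposure ratio of one scenario against its reference condition
    (activity score 2 and/or victim monotherapy)."""

    scenario_id: str
    parameter: str                 # "AUC_last" | "Cmax" | "AUC_ss"
    pk_effect: float
    pk_reference: float
    ratio: float
    effect_class: str = "DDI"      # DGI | DDI | DDGI
    mechanism: str = "competitive"
    perpetrator: str = ""
    victim: str = ""


@dataclass
class GmfeSummary:
    group: str
    n: int
    gmfe: float
    range: tuple[float, float]     # (min fold error, max fold error)


def effect_ratio(pk_effect: float, pk_reference: float,
                 scenario_id: str = "", parameter: str = "AUC_last",
                 **tags) -> EffectRatio:
    """Eq.-1-style effect PK ratio: PK_effect / PK_reference."""
    if pk_effect <= 0 or pk_reference <= 0:
        raise DomainError("PK parameter values must be positive")
    return EffectRatio(scenario_id=scenario_id, parameter=parameter,
                       pk_effect=pk_effect, pk_reference=pk_reference,
                       ratio=pk_effect / pk_reference, **tags)


def fold_errors(pairs: Sequence[tuple[float, float]]) -> np.ndarray:
    """Per-pair fold error ``10 ** |log10(pred/obs)|`` (each >= 1)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise DomainError("at least one (predicted, observed) pair required")
    if np.any(arr <= 0):
        raise DomainError("predicted and observed values must be positive")
    return 10.0 ** np.abs(np.log10(arr[:, 0] / arr[:, 1]))


def gmfe(pairs: Sequence[tuple[float, float]],
         group: str = "all") -> GmfeSummary:
    """Geometric mean fold error of predicted vs. observed values."""
    fe = fold_errors(pairs)
    value = float(10.0 ** np.mean(np.abs(np.log10(fe))))
    return GmfeSummary(group=group, n=len(fe), gmfe=value,
                       range=(float(fe.min()), float(fe.max())))


def guest_limits(observed_ratio: float,
                 delta: float = DEFAULT_DELTA) -> tuple[float, float]:
    """Acceptance interval for a predicted interaction ratio given the
    observed ratio R.

    The limit fold is ``L = (delta + 2*(R - 1)) / R`` evaluated on
    ``max(R, 1/R)`` so the bounds are reciprocally symmetric; the interval
    is ``[R / L, R * L]``. ``delta`` is the variability margin: 1.25
    reproduces the 20% margin (interval [0.8, 1.25] at R = 1), and the
    bounds widen toward the classical twofold band for large effects.
    """
    if observed_ratio <= 0:
        raise DomainError("observed ratio must be positive")
    if delta < 1:
        raise DomainError("variability margin delta must be >= 1")
    r_major = max(observed_ratio, 1.0 / observed_ratio)
    limit = (delta + 2.0 * (r_major - 1.0)) / r_major
    return observed_ratio / limit, observed_ratio * limit


def classify_predictions(predicted: Sequence[float],
                         observed: Sequence[float],
                         delta: float = DEFAULT_DELTA) -> pd.DataFrame:
    """Per-pair success flags against three bands: the Guest-type limits,
    the 1.25-fold range and the twofold range.

    Returns a DataFrame with columns ``predicted``, ``observed``,
    ``within_guest``, ``within_1_25``, ``within_2``; the summary fractions
    are attached as ``df.attrs['fractions']``.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise DomainError("predicted and observed must have equal length")
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise DomainError("ratios must be positive")
    lo = np.empty_like(obs)
    hi = np.empty_like(obs)
    for i, r in enumerate(obs):
        lo[i], hi[i] = guest_limits(float(r), delta)
    fe = 10.0 ** np.abs(np.log10(pred / obs))
    df = pd.DataFrame({
        "predicted": pred,
        "observed": obs,
        "within_guest": (pred >= lo) & (pred <= hi),
        "within_1_25": fe <= 1.25,
        "within_2": fe <= 2.0,
    })
    df.attrs["fractions"] = {
        "guest": float(df["within_guest"].mean()),
        "1.25-fold": float(df["within_1_25"].mean()),
        "2-fold": float(df["within_2"].mean()),
    }
    return df


_GROUPINGS = ("mechanism", "perpetrator", "victim", "effect_class")


def summarize_by_group(
    pairs: Sequence[tuple[EffectRatio, EffectRatio]],
    grouping: str,
) -> list[GmfeSummary]:
    """Table-style GMFE summary of (predicted, observed) effect-ratio pairs
    stratified by mechanism, perpetrator, victim or effect class."""
    if grouping not in _GROUPINGS:
        raise DomainError(f"unknown grouping {grouping!r}; "
                          f"expected one of {_GROUPINGS}")
    buckets: dict[str, list[tuple[float, float]]] = {}
    for pred, obs in pairs:
        key = getattr(pred, grouping)
        buckets.setdefault(key, []).append((pred.ratio, obs.ratio))
    return [gmfe(buckets[k], group=k) for k in sorted(buckets)]


def summaries_to_frame(summaries: Iterable[GmfeSummary]) -> pd.DataFrame:
    """Render summaries as a tabular report (one row per group)."""
    return pd.DataFrame(
        [{"group": s.group, "n": s.n, "gmfe": s.gmfe,
          "fold_error_min": s.range[0], "fold_error_max": s.range[1]}
         for s in summaries])
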