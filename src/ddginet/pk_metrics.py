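"""Non-compartmental PK metrics and population summaries.

One integration rule is used throughout: the linear trapezoid, which is
well defined on observed grids containing zeros (log-linear methods are
not). No extrapolation to infinity is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, SteadyStateWarning
from .pbpk_engine import ConcentrationProfile


@dataclass
class PKParameters:
    auc_last: float        # µmol·h/L
    cmax: float            # µmol/L
    t_last: float          # h
    auc_ss: float | None = None  # µmol·h/L over one interval at steady state


def auc_last(profile: ConcentrationProfile) -> float:
    """Linear trapezoidal AUC from the first to the last observation."""
    if len(profile.times) < 2:
        raise DomainError("auc_last requires at least two time points")
    return float(np.trapezoid(profile.conc, profile.times))


def cmax(profile: ConcentrationProfile) -> float:
    if len(profile.times) < 1:
        raise DomainError("cmax requires at least one time point")
    return float(np.max(profile.conc))


def t_last(profile: ConcentrationProfile) -> float:
    return float(profile.times[-1])


def auc_ss(profile: ConcentrationProfile, interval: float,
           reached_steady_state: bool = True) -> float:
    """Trapezoidal AUC over the last full dosing interval of a profile.

    The profile must cover at least one interval; points inside
    ``[t_end - interval, t_end]`` are integrated, with linear
    interpolation to the window edge if no sample falls exactly on it.
    If the engine flagged the run as not converged, the value is still
    returned but a :class:`SteadyStateWarning` is raised.
    """
    if interval <= 0:
        raise DomainError("dosing interval must be positive")
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.conc, dtype=float)
    t_end = t[-1]
    t_start = t_end - interval
    if t_start < t[0] - 1e-9:
        raise DomainError("profile does not cover a full dosing interval")
    mask = t >= t_start - 1e-12
    tw, cw = t[mask], c[mask]
    if tw[0] > t_start + 1e-12:
        c0 = float(np.interp(t_start, t, c))
        tw = np.concatenate([[t_start], tw])
        cw = np.concatenate([[c0], cw])
    if not reached_steady_state:
        warnings.warn("AUC_ss computed from a run that did not meet the "
                      "steady-state criterion", SteadyStateWarning)
    return float(np.trapezoid(cw, tw))


def geo_stats(values) -> tuple[float, float]:
    """Geometric mean and geometric SD of a positive sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DomainError("geo_stats requires at least one value")
    bad = np.nonzero(~(v > 0))[0]
    if bad.size:
        raise DomainError(f"non-positive value at index {int(bad[0])}")
    logs = np.log(v)
    return float(np.exp(logs.mean())), float(np.exp(logs.std(ddof=1) if v.size > 1 else 0.0))


def pk_parameters(profile: ConcentrationProfile,
                  interval: float | None = None) -> PKParameters:
    return PKParameters(
        auc_last=auc_last(profile),
        cmax=cmax(profile),
        t_last=t_last(profile),
        auc_ss=auc_ss(profile, interval) if interval else None,
    )
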