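"""Gating statistics from idealized traces.

* :func:`extract_events` — one gating event per idealized level transition,
  converted to a conductance amplitude via the driving force
  ``|V - U_rev|`` (U_rev from the recording metadata, 0 for symmetric
  buffers).  Events below a conductance floor (default 20 pS) are dropped:
  they are indistinguishable from baseline wander and would otherwise
  dominate frequency counts.
* :func:`gating_frequency` — events per minute, the standard activity
  measure for constant-voltage recordings.
* :func:`fit_conductance_classes` — maximum-likelihood Gaussian mixture over
  event conductances; the conductance-change histogram of this channel shows
  three prominent classes (~460/~170/~60 pS at 250 mM KCl).
* :func:`open_probability` — mean current / maximum current, evaluated on the
  *idealized* levels.  Using raw samples would bias the denominator upward by
  noise; the largest fitted level is the honest "maximum current".

Negative-current recordings (negative holding potentials) are handled by
working with level magnitudes; polarity is recorded in the event sign.
"""

from __future__ import annotations

import dataclasses
from typing import Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .errors import (
    ConvergenceError,
    DegenerateComponentError,
    Tim23EphysError,
    ZeroDrivingForceError,
)
from .trace_io import EVENT_COLUMNS, EventTable, IdealizedTrace

#: Default conductance floor (pS) below which level changes are not counted.
DEFAULT_FLOOR_PS = 20.0

#: Variance floor (pS^2) for mixture components; identical amplitudes give
#: sd = sqrt(reg_covar) instead of a degenerate zero-width component.
_REG_COVAR = 1e-2


@dataclasses.dataclass(frozen=True)
class ConductanceClasses:
    """Gaussian mixture over event conductances, sorted by descending mean."""

    k: int
    means_pS: Tuple[float, ...]
    sds_pS: Tuple[float, ...]
    weights: Tuple[float, ...]
    n_events: int


def extract_events(ideal: IdealizedTrace, floor_pS: float = DEFAULT_FLOOR_PS) -> EventTable:
    """Turn idealized level transitions into a gating-event table.

    Raises :class:`ZeroDrivingForceError` when the holding potential equals
    the reversal potential (conductance amplitudes undefined).
    """
    meta = ideal.meta
    u_rev = meta.u_rev_mV if meta.u_rev_mV is not None else 0.0
    driving = meta.voltage_mV - u_rev
    if driving == 0:
        raise ZeroDrivingForceError(
            "holding potential equals reversal potential; zero driving force"
        )
    levels = ideal.levels
    starts = ideal.segments["start_s"].to_numpy()
    if len(levels) < 2:
        empty = pd.DataFrame({c: pd.Series(dtype=float) for c in EVENT_COLUMNS})
        empty["direction"] = empty["direction"].astype(str)
        return EventTable(events=empty, meta=meta)

    amp = np.diff(levels)
    cond = np.abs(amp) / abs(driving) * 1e3  # pA/mV -> nS -> pS
    opening = np.abs(levels[1:]) > np.abs(levels[:-1])
    df = pd.DataFrame(
        {
            "time_s": starts[1:],
            "amplitude_pA": amp,
            "conductance_pS": cond,
            "direction": np.where(opening, "opening", "closing"),
        }
    )
    df = df[df["conductance_pS"] >= floor_pS].reset_index(drop=True)
    return EventTable(events=df, meta=meta)


def gating_frequency(table: EventTable) -> float:
    """Gating events per minute over the recording duration."""
    duration = table.meta.duration_s
    if duration <= 0:
        raise ValueError("recording duration must be positive")
    return len(table) / duration * 60.0


def fit_conductance_classes(table: EventTable, k: int = 3) -> ConductanceClasses:
    """Fit a k-component Gaussian mixture to event conductance amplitudes.

    Deterministic: initialized from k-means (fixed seed, ties broken by
    lowest index), single EM run.  Components are reported sorted by
    descending mean.

    Raises
    ------
    Tim23EphysError
        if fewer than 10*k events are available.
    ConvergenceError
        if EM does not converge within its iteration budget.
    DegenerateComponentError
        if any component weight falls below 1%.
    """
    x = table.conductances_pS.reshape(-1, 1)
    if len(x) < 10 * k:
        raise Tim23EphysError(
            f"mixture fit needs >= {10 * k} events, got {len(x)}"
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(x)
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        means_init=km.cluster_centers_,
        weights_init=np.bincount(km.labels_, minlength=k) / len(x),
        reg_covar=_REG_COVAR,
        max_iter=500,
        random_state=0,
    ).fit(x)
    if not gm.converged_:
        raise ConvergenceError("Gaussian mixture EM did not converge in 500 iterations")
    weights = gm.weights_
    if np.any(weights < 0.01):
        raise DegenerateComponentError(
            f"mixture component collapsed (weights {np.round(weights, 4)})"
        )
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(k))
    order = np.argsort(means)[::-1]
    return ConductanceClasses(
        k=k,
        means_pS=tuple(float(m) for m in means[order]),
        sds_pS=tuple(float(s) for s in sds[order]),
        weights=tuple(float(w) for w in weights[order]),
        n_events=len(x),
    )


def open_probability(ideal: IdealizedTrace) -> float:
    """Time-weighted mean level divided by the maximum level (magnitudes).

    The mean/max-current estimate of the open probability, computed on the
    idealized levels.  Raises :class:`Tim23EphysError` when all levels are 0.
    """
    levels = np.abs(ideal.levels)
    durations = ideal.durations
    gmax = levels.max()
    if gmax <= 0:
        raise Tim23EphysError("all idealized levels are zero; Po undefined")
    mean_level = float(np.sum(levels * durations) / np.sum(durations))
    return mean_level / float(gmax)
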