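"""Presequence dose-response of channel gating.

Substrate peptides (mitochondrial presequences, e.g. the Cox4 presequence)
activate the channel to fast gating ("flickering").  The response is
quantified per titration step as the **fold increase** of the gating
frequency over the unstimulated recording, and across a titration series by
a Hill-saturating activation curve

    fold(c) = 1 + (a_max - 1) * c^h / (c^h + ec50^h)

whose plateau ``a_max`` is the saturating activation factor.  The Hill form
is a package choice of functional form; published titrations of this channel
plot relative increase vs concentration without naming a model.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConvergenceError


@dataclasses.dataclass(frozen=True)
class TitrationSeries:
    """One substrate titration: (concentration_uM, gating_freq_per_min)
    pairs plus the unstimulated baseline frequency."""

    concentrations_uM: Tuple[float, ...]
    freqs_per_min: Tuple[float, ...]
    baseline_freq_per_min: float
    label: str = ""

    def __post_init__(self):
        c = np.asarray(self.concentrations_uM, dtype=float)
        f = np.asarray(self.freqs_per_min, dtype=float)
        if len(c) != len(f):
            raise ValueError("concentrations and frequencies differ in length")
        if np.any(c < 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be non-negative, strictly increasing")
        if self.baseline_freq_per_min <= 0:
            raise ValueError("baseline frequency must be positive")

    @property
    def folds(self) -> np.ndarray:
        return np.asarray(self.freqs_per_min) / self.baseline_freq_per_min


@dataclasses.dataclass(frozen=True)
class TitrationFit:
    """Hill fit of a titration series."""

    a_max: float
    ec50_uM: float
    hill_h: float
    ec50_identifiable: bool


def relative_activation(freq_stim: float, freq_baseline: float) -> float:
    """Fold increase of gating frequency over the unstimulated baseline."""
    if freq_baseline <= 0:
        raise ValueError("baseline gating frequency must be positive")
    return freq_stim / freq_baseline


def activation_reduction_percent(fold_wt: float, fold_mut: float) -> float:
    """Percent reduction of substrate activation from reference to variant:
    100 * (1 - fold_variant / fold_reference)."""
    if fold_wt <= 0:
        raise ValueError("reference fold must be positive")
    return 100.0 * (1.0 - fold_mut / fold_wt)


def hill_fold(c, a_max, ec50, h):
    """Saturating activation: 1 + (a_max - 1) * c^h / (c^h + ec50^h)."""
    c = np.asarray(c, dtype=float)
    out = np.ones_like(c)
    pos = c > 0
    ch = np.power(c[pos], h)
    out[pos] = 1.0 + (a_max - 1.0) * ch / (ch + ec50 ** h)
    return out


def fit_titration(series: TitrationSeries) -> TitrationFit:
    """Least-squares Hill fit of fold-activation vs concentration.

    Returns the plateau ``a_max``, midpoint ``ec50_uM`` and Hill coefficient.
    ``ec50_identifiable`` is False when the series never approaches its
    plateau (fitted ec50 above the largest concentration tested) or shows no
    response at all (a_max ~ 1).

    Raises :class:`ConvergenceError` on optimizer failure and ``ValueError``
    for fewer than 4 concentrations.
    """
    c = np.asarray(series.concentrations_uM, dtype=float)
    folds = series.folds
    if len(c) < 4:
        raise ValueError("need >= 4 titration points")

    a0 = max(float(folds.max()), 1.0 + 1e-6)
    pos = c[c > 0]
    ec0 = float(np.median(pos)) if len(pos) else 1.0
    try:
        popt, _ = curve_fit(
            hill_fold, c, folds,
            p0=[a0, ec0, 1.0],
            bounds=([1.0, 1e-9, 0.1], [1e6, 1e9, 10.0]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise ConvergenceError(f"Hill fit did not converge: {exc}") from exc
    a_max, ec50, h = (float(p) for p in popt)
    identifiable = (a_max - 1.0) > 0.1 and ec50 <= float(c.max())
    return TitrationFit(a_max=a_max, ec50_uM=ec50, hill_h=h, ec50_identifiable=identifiable)


def titration_from_frequencies(
    concentrations_uM: Sequence[float],
    freqs_per_min: Sequence[float],
    baseline_freq_per_min: float,
    label: str = "",
) -> TitrationSeries:
    """Convenience constructor mirroring the TSV layout of the CLI."""
    return TitrationSeries(
        concentrations_uM=tuple(float(x) for x in concentrations_uM),
        freqs_per_min=tuple(float(x) for x in freqs_per_min),
        baseline_freq_per_min=float(baseline_freq_per_min),
        label=label,
    )
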