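"""Continuous-time Markov gating simulator for Tim23-like channels.

The channel is modeled as a four-state star topology centered on the fully
open state (main conductance 460 pS at 250 mM KCl):

===========  ================  =====================================
state        conductance (pS)  transition from open / amplitude (pS)
===========  ================  =====================================
open         460               --
sub400       400               partial closure, amplitude  60
sub290       290               partial closure, amplitude 170
closed         0               full closure,    amplitude 460
===========  ================  =====================================

Transition *amplitudes* — not state conductances — therefore reproduce the
three characteristic conductance-change classes (~460, ~170, ~60 pS) seen in
gating-event histograms of this channel.

Model features
--------------
* **Exact-jump simulation.**  The state path is simulated with Gillespie
  exponential waiting times and only afterwards sampled onto the uniform
  digitization grid, so dwell-time statistics are exact at any sample rate.
* **Ohmic states with a common GHK offset.**  Instantaneous current is
  ``g_state * (V - U_rev)`` with the reversal potential from the
  Goldman-Hodgkin-Katz equation for the model's P_K/P_Cl and the buffer
  gradient, plus iid Gaussian noise.
* **Voltage-dependent closure.**  The open->closed rate is multiplied by
  ``exp((|V| - v_half)/v_slope)`` while closed->open stays fixed, so the
  open/closed balance follows a Boltzmann curve in |V| with midpoint
  ``v_half`` and slope ``v_slope``.
* **Substrate-induced flickering.**  Presequence peptide multiplies both
  rates of the two partial-closure ("flicker") pairs by
  ``1 + (a_max - 1) * c^h / (c^h + ec50^h)``; full closures are untouched.
  Scaling a pair symmetrically leaves state occupancies (hence the open
  probability) unchanged while the flicker event frequency scales exactly
  with the factor — matching a substrate response that is pure fast gating.
* **Tim50 receptor.**  Presence of the IMS receptor domain is modeled as a
  negative shift of ``v_half`` (closure promoted at lower voltages).

Baseline rate magnitudes are package calibration choices (no dwell-time or
absolute gating-rate values are available for this channel); see
``docs/methods.md`` for the constraints that fix them.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pydantic

from . import selectivity as _sel
from .trace_io import IdealizedTrace, RecordingMeta, Trace

STATE_NAMES = ("closed", "sub290", "sub400", "open")

#: Index of the fully open state in ``levels_pS``/``rate_matrix``.
OPEN_STATE = 3

_DEFAULT_LEVELS = (0.0, 290.0, 400.0, 460.0)

# Baseline transition rates (s^-1). Rows/cols ordered as STATE_NAMES. The
# open->closed entry is further scaled by the Boltzmann voltage factor at
# simulation time.  Magnitudes are package calibration (see docs/methods.md):
# fast enough that constant-voltage recordings of practical length collect
# >=2000 events, slow enough that dwell times at 50-fold substrate
# acceleration stay well clear of the 0.5 ms analysis dead time.
_DEFAULT_RATES = (
    (0.0, 0.0, 0.0, 0.30),    # closed -> open
    (0.0, 0.0, 0.0, 1.10),    # sub290 -> open
    (0.0, 0.0, 0.0, 0.45),    # sub400 -> open
    (0.30, 0.60, 0.30, 0.0),  # open -> closed / sub290 / sub400
)


class ChannelModel(pydantic.BaseModel):
    """Full parameterization of the simulated channel."""

    model_config = pydantic.ConfigDict(frozen=True)

    levels_pS: Tuple[float, ...] = _DEFAULT_LEVELS
    rate_matrix: Tuple[Tuple[float, ...], ...] = _DEFAULT_RATES
    pk_over_pcl: float = pydantic.Field(default=15.0, gt=0)
    v_half_mV: float = 120.0
    v_slope_mV: float = pydantic.Field(default=15.0, gt=0)
    flicker_amax: float = pydantic.Field(default=50.0, ge=1.0)
    ec50_uM: float = pydantic.Field(default=1.0, gt=0)
    hill_h: float = pydantic.Field(default=1.5, gt=0)
    noise_sd_pA: float = pydantic.Field(default=2.0, ge=0)
    filter_cutoff_Hz: Optional[float] = None
    tim50_vhalf_shift_mV: float = -40.0

    @pydantic.model_validator(mode="after")
    def _check(self):
        g = np.asarray(self.levels_pS)
        if np.any(g < 0) or len(np.unique(g)) != len(g):
            raise ValueError("levels_pS must be distinct and non-negative")
        q = np.asarray(self.rate_matrix, dtype=float)
        if q.shape != (len(g), len(g)):
            raise ValueError("rate_matrix shape must match levels_pS")
        off = q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        return self

    # -- derived structure ---------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.levels_pS)

    @property
    def open_state(self) -> int:
        return int(np.argmax(self.levels_pS))

    @property
    def flicker_states(self) -> Tuple[int, ...]:
        """Conducting sub-states: 0 < g < g_open.  Transitions between these
        and the open state are the substrate-sensitive 'flicker' pairs."""
        g = np.asarray(self.levels_pS)
        return tuple(int(i) for i in np.flatnonzero((g > 0) & (g < g.max())))

    def substrate_factor(self, substrate_uM: float) -> float:
        """Hill-saturating multiplier applied to flicker rates."""
        if substrate_uM <= 0:
            return 1.0
        c = substrate_uM ** self.hill_h
        return 1.0 + (self.flicker_amax - 1.0) * c / (c + self.ec50_uM ** self.hill_h)

    def effective_rate_matrix(
        self,
        voltage_mV: float,
        substrate_uM: float = 0.0,
        tim50_present: bool = False,
    ) -> np.ndarray:
        """Generator matrix (diagonal completed to zero row sums) at the given
        holding potential and substrate concentration."""
        q = np.asarray(self.rate_matrix, dtype=float).copy()
        np.fill_diagonal(q, 0.0)
        o = self.open_state
        a = self.substrate_factor(substrate_uM)
        for s in self.flicker_states:
            q[o, s] *= a
            q[s, o] *= a
        v_half = self.v_half_mV + (self.tim50_vhalf_shift_mV if tim50_present else 0.0)
        closed = [i for i in range(self.n_states) if self.levels_pS[i] == 0]
        boltz = np.exp((abs(voltage_mV) - v_half) / self.v_slope_mV)
        for c in closed:
            q[o, c] *= boltz
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


@dataclasses.dataclass(frozen=True)
class Protocol:
    """One recording protocol: voltage, duration, digitization and bath."""

    voltage_mV: float
    duration_s: float
    sample_rate_Hz: float = 10_000.0
    substrate_uM: float = 0.0
    tim50_present: bool = False
    cis_K_mM: float = 250.0
    trans_K_mM: float = 250.0
    temperature_K: float = 298.15
    label: str = ""

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate_Hz <= 0:
            raise ValueError("sample_rate_Hz must be positive")


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """True state path and events of one simulated recording."""

    jump_times_s: np.ndarray      # entry times; jump_times_s[0] == 0
    states: np.ndarray            # state index occupied from each entry time
    levels_pS: np.ndarray         # conductance per state index
    u_rev_mV: float
    duration_s: float
    voltage_mV: float

    @property
    def n_events(self) -> int:
        return len(self.states) - 1

    @property
    def event_times_s(self) -> np.ndarray:
        return self.jump_times_s[1:]

    @property
    def event_amplitudes_pS(self) -> np.ndarray:
        g = self.levels_pS[self.states]
        return np.diff(g)

    def occupancy(self) -> np.ndarray:
        """Time-weighted fraction spent in each state."""
        bounds = np.append(self.jump_times_s, self.duration_s)
        dwell = np.diff(bounds)
        occ = np.zeros(len(self.levels_pS))
        np.add.at(occ, self.states, dwell)
        return occ / self.duration_s

    def n_events_above(self, floor_pS: float) -> int:
        return int(np.sum(np.abs(self.event_amplitudes_pS) >= floor_pS))

    def to_idealized(self, meta: RecordingMeta) -> IdealizedTrace:
        """Noise-free idealization of the true path (current levels in pA)."""
        bounds = np.append(self.jump_times_s, self.duration_s)
        driving = self.voltage_mV - self.u_rev_mV
        seg = pd.DataFrame(
            {
                "start_s": bounds[:-1],
                "duration_s": np.diff(bounds),
                "level_pA": self.levels_pS[self.states] * driving * 1e-3,
            }
        )
        return IdealizedTrace(segments=seg, meta=meta)


def default_model(variant: str = "wildtype") -> ChannelModel:
    """Default channel parameterization for a variant.

    Wild type and the selectivity-filter mutant N150A share conductance
    levels, gating rates, voltage dependence and noise; they differ only in

    * ``pk_over_pcl`` — mutant cation preference is 33% of wild type
      (4.95 vs 15), and
    * ``flicker_amax`` — saturating substrate activation factor 6 vs 50.
    """
    key = variant.strip().lower()
    if key in ("wildtype", "wt", "tim23"):
        return ChannelModel()
    if key in ("n150a", "tim23n150a"):
        return ChannelModel(pk_over_pcl=15.0 * 0.33, flicker_amax=6.0)
    raise ValueError(f"unknown variant {variant!r} (expected 'wildtype' or 'N150A')")


def _meta_for(protocol: Protocol, model: ChannelModel, u_rev: float) -> RecordingMeta:
    return RecordingMeta(
        voltage_mV=protocol.voltage_mV,
        cis_K_mM=protocol.cis_K_mM,
        trans_K_mM=protocol.trans_K_mM,
        temperature_K=protocol.temperature_K,
        sample_rate_Hz=protocol.sample_rate_Hz,
        duration_s=protocol.duration_s,
        label=protocol.label,
        u_rev_mV=u_rev,
    )


def reversal_potential(model: ChannelModel, meta: RecordingMeta) -> float:
    """GHK reversal potential (mV) of the model under the given buffers."""
    return _sel.ghk_reversal(model.pk_over_pcl, meta)


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator matrix (zero row sums)."""
    n = q.shape[0]
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.sum(np.clip(pi, 0.0, None))


def stationary_open_probability(
    model: ChannelModel, voltage_mV: float, substrate_uM: float = 0.0,
    tim50_present: bool = False,
) -> float:
    """Stationary mean conductance over max conductance (the mean/max current
    ratio a noise-free infinitely long recording would give)."""
    q = model.effective_rate_matrix(voltage_mV, substrate_uM, tim50_present)
    pi = stationary_distribution(q)
    g = np.asarray(model.levels_pS)
    return float(pi @ g / g.max())


def expected_event_rate(
    model: ChannelModel, voltage_mV: float, substrate_uM: float = 0.0,
    tim50_present: bool = False,
) -> float:
    """Expected gating events per second at stationarity: sum_i pi_i * (-Q_ii).

    Used to size recording durations for a target event count.
    """
    q = model.effective_rate_matrix(voltage_mV, substrate_uM, tim50_present)
    pi = stationary_distribution(q)
    return float(-pi @ np.diag(q))


def simulate_states(
    q: np.ndarray,
    duration_s: float,
    rng: np.random.Generator,
    initial_state: Optional[int] = None,
    max_jumps: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Gillespie exact-jump simulation of a CTMC state path.

    Returns (entry_times, states). The initial state is drawn from the
    stationary distribution unless given.  ``max_jumps`` stops the path early
    (entry times then end before ``duration_s``).
    """
    n = q.shape[0]
    out_rates = -np.diag(q)
    probs = np.where(np.eye(n, dtype=bool), 0.0, q)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = probs / np.where(out_rates[:, None] > 0, out_rates[:, None], 1.0)
    cum = np.cumsum(probs, axis=1)

    if initial_state is None:
        state = int(rng.choice(n, p=stationary_distribution(q)))
    else:
        state = int(initial_state)

    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        r = out_rates[state]
        if r <= 0:
            break
        t += rng.exponential(1.0 / r)
        if t >= duration_s:
            break
        state = int(np.searchsorted(cum[state], rng.random()))
        times.append(t)
        states.append(state)
        if max_jumps is not None and len(times) - 1 >= max_jumps:
            break
    return np.asarray(times), np.asarray(states, dtype=np.int64)


def _single_pole_lowpass(x: np.ndarray, cutoff_Hz: float, fs: float) -> np.ndarray:
    from scipy.signal import lfilter

    alpha = 1.0 - np.exp(-2.0 * np.pi * cutoff_Hz / fs)
    return lfilter([alpha], [1.0, alpha - 1.0], x, zi=[x[0] * (1 - alpha)])[0]


def simulate_trace(
    model: ChannelModel,
    protocol: Protocol,
    seed: int,
    initial_state: Optional[int] = None,
) -> Tuple[Trace, GroundTruth]:
    """Simulate one constant-voltage recording.

    The state path is simulated with exact jumps, sampled onto the uniform
    grid (a sample takes the state occupied at its timestamp), converted to
    current ``g * (V - U_rev)`` and overlaid with iid Gaussian noise (plus an
    optional single-pole low-pass).  The initial state is drawn from the
    stationary distribution unless given.  Identical arguments give
    bit-identical output.
    """
    rng = np.random.default_rng(seed)
    meta_probe = RecordingMeta(
        voltage_mV=protocol.voltage_mV,
        cis_K_mM=protocol.cis_K_mM,
        trans_K_mM=protocol.trans_K_mM,
        temperature_K=protocol.temperature_K,
        sample_rate_Hz=protocol.sample_rate_Hz,
        duration_s=protocol.duration_s,
        label=protocol.label,
    )
    u_rev = _sel.ghk_reversal(model.pk_over_pcl, meta_probe)
    q = model.effective_rate_matrix(
        protocol.voltage_mV, protocol.substrate_uM, protocol.tim50_present
    )
    times, states = simulate_states(q, protocol.duration_s, rng, initial_state=initial_state)

    n = int(round(protocol.duration_s * protocol.sample_rate_Hz))
    grid = np.arange(n) / protocol.sample_rate_Hz
    idx = np.searchsorted(times, grid, side="right") - 1
    g = np.asarray(model.levels_pS)[states[idx]]
    current = g * (protocol.voltage_mV - u_rev) * 1e-3  # pS * mV -> pA
    if model.noise_sd_pA > 0:
        current = current + rng.normal(0.0, model.noise_sd_pA, size=n)
    if model.filter_cutoff_Hz is not None:
        current = _single_pole_lowpass(
            current, model.filter_cutoff_Hz, protocol.sample_rate_Hz
        )

    meta = _meta_for(protocol, model, u_rev)
    gt = GroundTruth(
        jump_times_s=times,
        states=states,
        levels_pS=np.asarray(model.levels_pS, dtype=float),
        u_rev_mV=u_rev,
        duration_s=protocol.duration_s,
        voltage_mV=protocol.voltage_mV,
    )
    return Trace(meta=meta, samples=current), gt


def simulate_iv(
    model: ChannelModel,
    voltages: Sequence[float],
    meta: RecordingMeta,
    seed: int,
    per_voltage_duration: float = 10.0,
) -> "_sel.IVDataset":
    """Mean open-level current at each voltage under the given buffers.

    The channel is held fully open (I-V curves of this channel are taken from
    open-level currents); the reported mean carries the Monte-Carlo noise of
    averaging ``duration * rate`` noisy samples, so the noiseless means cross
    zero exactly at the model's reversal potential.
    """
    v = np.asarray(voltages, dtype=float)
    if len(v) < 2 or np.any(np.diff(v) <= 0):
        raise ValueError("voltages must be >= 2, sorted and distinct")
    rng = np.random.default_rng(seed)
    u_rev = _sel.ghk_reversal(model.pk_over_pcl, meta)
    g_open = max(model.levels_pS)
    n = max(1, int(round(per_voltage_duration * meta.sample_rate_Hz)))
    mean_i = g_open * (v - u_rev) * 1e-3
    if model.noise_sd_pA > 0:
        mean_i = mean_i + rng.normal(0.0, model.noise_sd_pA / np.sqrt(n), size=len(v))
    points = pd.DataFrame(
        {
            "voltage_mV": v,
            "mean_current_pA": mean_i,
            "sd_pA": np.full(len(v), float(model.noise_sd_pA)),
            "n": np.full(len(v), n, dtype=int),
        }
    )
    return _sel.IVDataset(points=points, meta=meta)
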