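"""DAR-2 conjugation reaction kinetics in an ideal-mixed (0D) fed-batch reactor.

The reaction network describes site-specific conjugation of a maleimide
payload to antibodies carrying engineered cysteines.  Antibody molecules are
partitioned by the number of conjugation-competent ("activated") cysteines:

* ``A2`` — antibody with two activated cysteines,
* ``A1`` — antibody with one activated cysteine (the second is pre-inactivated),
* ``A0`` — antibody with no activated cysteine (inert dead-end species).

Conjugation proceeds by two consecutive bimolecular steps with a parallel
first-order payload-inactivation sink:

.. math::

    A2 + D \\xrightarrow{k_1} M_{1a}, \\qquad
    A1 + D \\xrightarrow{k_1} M_{1b}, \\qquad
    M_{1a} + D \\xrightarrow{k_2} M_2, \\qquad
    D \\xrightarrow{k_3} D_{inact}

where ``D`` is the free payload, ``M1a`` the mono-conjugate that can still
react, ``M1b`` the terminal mono-conjugate and ``M2`` the bi-conjugate.
Backward rates are zero; the system is isothermal and constant-volume (the
payload stock volume is ~1.7% v/v and is neglected).

All concentrations are in mM and all times in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParameters",
    "ActivationDistribution",
    "SpeciesState",
    "FeedSchedule",
    "Trajectory",
    "SPECIES",
    "molar_from_mass",
    "payload_volume_fraction",
    "initial_state",
    "reaction_rates",
    "simulate_0d",
    "dar",
    "completion_time",
    "NOT_REACHED",
]

#: Canonical ordering of the state vector used throughout the package.
SPECIES = ("A2", "A1", "A0", "M1a", "M1b", "M2", "D", "Dinact")

#: Sentinel returned by :func:`completion_time` when the residual criterion
#: is never met within the simulated horizon.
NOT_REACHED = math.inf


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the conjugation network.

    Parameters
    ----------
    k1 : float
        Second-order rate constant of payload conjugation to an activated
        cysteine on unconjugated antibody (per mM per s).
    k2 : float
        Second-order rate constant of the second conjugation step
        (mono- to bi-conjugate, per mM per s).
    k3 : float
        First-order payload inactivation ("drug sink") rate constant (per s).

    Defaults are the calibrated small-scale values for the DAR-2 system.
    """

    k1: float = 0.797
    k2: float = 1.476
    k3: float = 0.00155

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")


@dataclass(frozen=True)
class ActivationDistribution:
    """Fractions of antibody with two / one / zero activated cysteines.

    The default distribution reproduces the end-state species ratio of the
    validation conjugation run (88.59% / 8.60% / 2.81%).
    """

    p2: float = 0.8859
    p1: float = 0.0860
    p0: float = 0.0281

    def __post_init__(self) -> None:
        for name in ("p2", "p1", "p0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.p2 + self.p1 + self.p0 - 1.0) > 1e-9:
            raise ValueError("activation fractions must sum to 1")

    @property
    def max_dar(self) -> float:
        """DAR reached at full conversion of all activated sites."""
        return 2.0 * self.p2 + self.p1


#: Distribution collapsing the 7-ODE variant onto the plain 3-reaction model.
ALL_ACTIVATED = ActivationDistribution(p2=1.0, p1=0.0, p0=0.0)


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations (mM) of the conjugation species in one well-mixed volume.

    ``Dinact`` is a bookkeeping accumulator for inactivated payload so the
    drug balance can be checked exactly.
    """

    A2: float = 0.0
    A1: float = 0.0
    A0: float = 0.0
    M1a: float = 0.0
    M1b: float = 0.0
    M2: float = 0.0
    D: float = 0.0
    Dinact: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SpeciesState":
        return cls(**dict(zip(SPECIES, map(float, y))))

    @property
    def total_mab(self) -> float:
        """Total antibody concentration (conserved quantity)."""
        return self.A2 + self.A1 + self.A0 + self.M1a + self.M1b + self.M2

    def validate(self, tol: float = 1e-12) -> None:
        for s in SPECIES:
            if getattr(self, s) < -tol:
                raise ValueError(f"negative concentration {s}={getattr(self, s)}")


@dataclass(frozen=True)
class FeedSchedule:
    """Payload addition schedule on a vessel-concentration basis.

    ``total_payload`` is the payload concentration that would result if the
    full dose were homogenized over the vessel; ``stock_concentration`` is the
    concentration of the added stock solution (used only for the volume-
    fraction bookkeeping, default 10 mM).
    """

    mode: str = "constant-rate"
    duration: float = 60.0
    total_payload: float = 0.1667
    stock_concentration: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("batch-instant", "constant-rate"):
            raise ValueError(f"unknown feed mode {self.mode!r}")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.total_payload < 0:
            raise ValueError("total_payload must be >= 0")
        if (self.mode == "batch-instant") != (self.duration == 0):
            raise ValueError("batch-instant mode requires duration == 0 and vice versa")

    @classmethod
    def batch(cls, total_payload: float, stock_concentration: float = 10.0) -> "FeedSchedule":
        return cls("batch-instant", 0.0, total_payload, stock_concentration)

    @property
    def rate(self) -> float:
        """Constant feed rate (mM/s) during the addition window; 0 for batch."""
        if self.mode == "batch-instant" or self.duration == 0:
            return 0.0
        return self.total_payload / self.duration

    def volume_fraction_percent(self) -> float:
        """Added stock volume as percent of vessel volume (v/v)."""
        return payload_volume_fraction(self.total_payload, self.stock_concentration)


def molar_from_mass(mass_conc: float, molar_mass: float) -> float:
    """Convert a mass concentration (mg/mL) to mM given a molar mass (g/mol)."""
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    if mass_conc < 0:
        raise ValueError("mass concentration must be >= 0")
    return mass_conc / molar_mass * 1000.0


def payload_volume_fraction(total_payload: float, stock_concentration: float) -> float:
    """Percent (v/v) of vessel volume occupied by the added payload stock.

    A dose that homogenizes to ``total_payload`` mM delivered from a stock at
    ``stock_concentration`` mM occupies ``total/stock`` of the vessel volume.
    """
    if stock_concentration <= 0:
        raise ValueError("stock concentration must be positive")
    return total_payload / stock_concentration * 100.0


def initial_state(
    c_mab0: float,
    distribution: ActivationDistribution = ActivationDistribution(),
) -> SpeciesState:
    """Homogeneous pre-reaction state: antibody split by activation class."""
    if c_mab0 < 0:
        raise ValueError("c_mab0 must be >= 0")
    return SpeciesState(
        A2=distribution.p2 * c_mab0,
        A1=distribution.p1 * c_mab0,
        A0=distribution.p0 * c_mab0,
    )


def _rhs(y: np.ndarray, params: KineticParameters, feed_rate: float = 0.0) -> np.ndarray:
    """Mass-action right-hand side on the raw state vector (mM/s)."""
    A2, A1, _A0, M1a, _M1b, _M2, D, _ = y
    k1, k2, k3 = params.k1, params.k2, params.k3
    r1 = k1 * A2 * D
    r1b = k1 * A1 * D
    r2 = k2 * M1a * D
    r3 = k3 * D
    return np.array([
        -r1,                 # A2
        -r1b,                # A1
        0.0,                 # A0
        r1 - r2,             # M1a
        r1b,                 # M1b
        r2,                  # M2
        -r1 - r1b - r2 - r3 + feed_rate,  # D
        r3,                  # Dinact
    ])


def reaction_rates(state: SpeciesState, params: KineticParameters) -> SpeciesState:
    """Per-species time derivatives (mM/s) of the conjugation network.

    The returned object reuses the :class:`SpeciesState` container for its
    field names; its entries are derivatives, not concentrations.  The feed
    source term is added by the simulator, not here.
    """
    state.validate()
    return SpeciesState.from_array(_rhs(state.as_array(), params))


@dataclass
class Trajectory:
    """Time-resolved 0D (or volume-averaged) state with derived DAR series."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 8), columns in SPECIES order
    c_mab0: float
    fed_payload: np.ndarray = field(default=None)  # cumulative fed payload (mM)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing 1D array")
        if self.states.shape != (self.times.size, len(SPECIES)):
            raise ValueError("states shape incompatible with times")
        if self.fed_payload is None:
            self.fed_payload = np.zeros_like(self.times)

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    @property
    def dar(self) -> np.ndarray:
        m1 = self.species("M1a") + self.species("M1b")
        return (m1 + 2.0 * self.species("M2")) / self.c_mab0

    def state_at(self, i: int) -> SpeciesState:
        return SpeciesState.from_array(self.states[i])

    def mab_conservation_error(self) -> float:
        """Max relative drift of total antibody over the trajectory."""
        tot = self.states[:, :6].sum(axis=1)
        return float(np.max(np.abs(tot - tot[0])) / tot[0]) if tot[0] > 0 else 0.0

    def drug_balance_error(self) -> float:
        """Max relative mismatch of free + conjugated + inactivated vs fed payload."""
        bound = (
            self.species("M1a") + self.species("M1b") + 2.0 * self.species("M2")
            + self.species("D") + self.species("Dinact")
        )
        fed = self.fed_payload + bound[0] - self.fed_payload[0]
        scale = max(float(fed[-1]), 1e-30)
        return float(np.max(np.abs(bound - fed)) / scale)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time_s", self.times)
        df["DAR"] = self.dar
        return df


def simulate_0d(
    initial: SpeciesState,
    params: KineticParameters,
    feed: FeedSchedule,
    t_end: float,
    output_grid: float | np.ndarray = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the conjugation ODEs in an ideal-mixed fed-batch reactor.

    Parameters
    ----------
    initial : SpeciesState
        Pre-addition state (payload field is augmented at t=0 in batch mode).
    feed : FeedSchedule
        Batch mode adds ``total_payload`` instantaneously at t=0;
        constant-rate mode adds ``total_payload / duration`` per second while
        ``t <= duration``.
    output_grid : float or array
        Either a reporting interval (s) or an explicit strictly increasing
        time grid starting at 0.

    Volume change from the payload addition is neglected (constant-volume
    model); the trajectory records the cumulative fed payload so drug-balance
    checks close exactly.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    initial.validate()
    if np.isscalar(output_grid):
        times = np.arange(0.0, t_end + 0.5 * float(output_grid), float(output_grid))
        times[-1] = min(times[-1], t_end)
    else:
        times = np.asarray(output_grid, dtype=float)
        if times[0] != 0.0 or times[-1] > t_end:
            raise ValueError("explicit output grid must start at 0 and end <= t_end")

    y0 = initial.as_array()
    if feed.mode == "batch-instant":
        y0 = y0.copy()
        y0[SPECIES.index("D")] += feed.total_payload
        fed = np.full_like(times, feed.total_payload)
        segments = [(0.0, t_end, 0.0)]
    else:
        t_feed = min(feed.duration, t_end)
        fed = np.minimum(times, feed.duration) * feed.rate
        segments = [(0.0, t_feed, feed.rate)]
        if t_end > t_feed:
            segments.append((t_feed, t_end, 0.0))

    out = np.empty((times.size, len(SPECIES)))
    y = y0
    for (t0, t1, rate) in segments:
        mask = (times >= t0) & (times <= t1)
        t_eval = times[mask]
        # segment endpoints must be evaluated to chain the integration
        eval_pts = np.unique(np.concatenate([t_eval, [t0, t1]]))
        sol = solve_ivp(
            lambda t, yy: _rhs(yy, params, rate),
            (t0, t1),
            y,
            method="LSODA",
            t_eval=eval_pts,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed: {sol.message}")
        for t, col in zip(sol.t, sol.y.T):
            idx = np.searchsorted(times, t)
            if idx < times.size and times[idx] == t:
                out[idx] = col
        y = sol.y[:, -1]

    if np.any(out < -1e-9):
        raise RuntimeError("negative concentrations beyond solver tolerance")
    np.clip(out, 0.0, None, out=out)
    return Trajectory(times=times, states=out, c_mab0=initial.total_mab, fed_payload=fed)


def dar(state: SpeciesState, c_mab0: float) -> float:
    """Drug-to-antibody ratio: (mono + 2·bi) conjugate per initial antibody."""
    if c_mab0 <= 0:
        raise ValueError("c_mab0 must be positive")
    return (state.M1a + state.M1b + 2.0 * state.M2) / c_mab0


def completion_time(traj: Trajectory, residual_fraction: float = 0.01) -> float:
    """First time at which the unreacted activated antibody fraction
    (A2+A1)/(A2(0)+A1(0)) drops to ``residual_fraction``.

    Linear interpolation between output points; returns :data:`NOT_REACHED`
    (``inf``) if the criterion is never met within the trajectory.
    """
    if not 0 < residual_fraction < 1:
        raise ValueError("residual_fraction must be in (0, 1)")
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    active0 = traj.species("A2")[0] + traj.species("A1")[0]
    if active0 <= 0:
        raise ValueError("no activated antibody at t=0")
    frac = (traj.species("A2") + traj.species("A1")) / active0
    below = np.nonzero(frac <= residual_fraction)[0]
    if below.size == 0:
        return NOT_REACHED
    i = below[0]
    if i == 0:
        return float(traj.times[0])
    t0, t1 = traj.times[i - 1], traj.times[i]
    f0, f1 = frac[i - 1], frac[i]
    if f0 == f1:
        return float(t1)
    return float(t0 + (f0 - residual_fraction) / (f0 - f1) * (t1 - t0))
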