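"""Kinetic parameter estimation from conjugation time-course data.

Fits the rate constants of the conjugation network to observed species
time courses (unconjugated antibody, mono-conjugate, bi-conjugate — the
quantities a quenched RP-UHPLC assay reports) by weighted nonlinear least
squares against the ideal-mixed 0D model, and recovers the cysteine
activation distribution from the end-state species ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import (
    ActivationDistribution,
    FeedSchedule,
    KineticParameters,
    SpeciesState,
    Trajectory,
    initial_state,
    simulate_0d,
)

__all__ = [
    "KineticDataset",
    "FitResult",
    "fit_rate_constants",
    "fit_activation_distribution",
    "r_squared",
    "read_dataset_csv",
    "write_dataset_csv",
]

#: Observable species groups reported by the quenched chromatographic assay.
OBSERVABLES = ("mab", "mono", "bi")


@dataclass
class KineticDataset:
    """Observed conjugation time course.

    ``observations`` maps observable names (``mab``, ``mono``, ``bi``) to
    arrays congruent with ``times``.  Values may be concentrations (mM) or
    fractions of total antibody — the fit is invariant to this choice given
    the default per-species max-normalized weighting.  ``c_mab0`` and
    ``feed`` describe the experiment; ``truth`` optionally carries the
    generating parameters of a synthetic dataset.
    """

    times: np.ndarray
    observations: dict[str, np.ndarray]
    c_mab0: float
    feed: FeedSchedule
    distribution: ActivationDistribution = ActivationDistribution()
    fractional: bool = False
    noise_sd: float = 0.0
    truth: KineticParameters | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        for name, arr in self.observations.items():
            if name not in OBSERVABLES:
                raise ValueError(f"unknown observable {name!r}")
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"observable {name!r} not congruent with times")
            self.observations[name] = arr
        if self.fractional:
            total = sum(self.observations.values())
            if np.any(total > 1.0 + max(0.1, 5 * self.noise_sd)):
                raise ValueError("fractional observations exceed 1 per timepoint")
        if self.c_mab0 <= 0:
            raise ValueError("c_mab0 must be positive")


@dataclass
class FitResult:
    """Estimated rate constants with uncertainty and goodness of fit."""

    params: KineticParameters
    stderr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    r2: float
    residuals: np.ndarray
    cost: float
    at_bound: list[str] = field(default_factory=list)
    unidentifiable: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "k1": self.params.k1,
                "k2": self.params.k2,
                "k3": self.params.k3,
                "stderr": self.stderr,
                "ci95": {k: list(v) for k, v in self.ci95.items()},
                "r_squared": self.r2,
                "at_bound": self.at_bound,
                "unidentifiable": self.unidentifiable,
            }
        )


def _observables_from_trajectory(traj: Trajectory, fractional: bool) -> dict[str, np.ndarray]:
    scale = traj.c_mab0 if fractional else 1.0
    return {
        "mab": (traj.species("A2") + traj.species("A1") + traj.species("A0")) / scale,
        "mono": (traj.species("M1a") + traj.species("M1b")) / scale,
        "bi": traj.species("M2") / scale,
    }


def _simulate_observables(
    theta: np.ndarray,
    free: list[str],
    fixed_values: dict[str, float],
    data: KineticDataset,
    rtol: float,
) -> dict[str, np.ndarray]:
    kw = dict(fixed_values)
    kw.update(dict(zip(free, theta)))
    params = KineticParameters(**{k: max(v, 0.0) for k, v in kw.items()})
    grid = data.times if data.times[0] == 0.0 else np.concatenate([[0.0], data.times])
    traj = simulate_0d(
        initial_state(data.c_mab0, data.distribution),
        params,
        data.feed,
        t_end=float(data.times[-1]),
        output_grid=grid,
        rtol=rtol,
        atol=1e-12,
    )
    obs = _observables_from_trajectory(traj, data.fractional)
    if data.times[0] != 0.0:
        obs = {k: v[1:] for k, v in obs.items()}
    return obs


def fit_rate_constants(
    data: KineticDataset,
    initial_guess: KineticParameters = KineticParameters(),
    fixed: tuple[str, ...] = (),
    n_starts: int = 5,
    rtol: float = 1e-8,
) -> FitResult:
    """Weighted least-squares estimation of the conjugation rate constants.

    Residuals are weighted per observable by 1/max(observed) so species of
    different magnitude (or unit) contribute comparably.  Parameters are
    bounded below by zero.  To mitigate local minima the optimization is
    restarted from ``n_starts`` log-spaced multiples (1/10x .. 10x) of the
    initial guess in a fixed order; the best solution wins, so the result is
    deterministic given the data and the guess.

    Structurally flat directions (an observable set that carries no
    information on a free parameter) are reported in ``unidentifiable``;
    estimates pinned at the zero bound are reported in ``at_bound``.
    """
    if data.times.size < 6:
        raise ValueError("need at least 6 timepoints spanning the rise phase")
    if data.feed.total_payload <= 0:
        raise ValueError("non-degenerate feed required for identifiability")
    names = ("k1", "k2", "k3")
    for f in fixed:
        if f not in names:
            raise ValueError(f"unknown parameter {f!r}")
    free = [p for p in names if p not in fixed]
    if not free:
        raise ValueError("at least one parameter must be free")
    fixed_values = {p: getattr(initial_guess, p) for p in names if p in fixed}

    present = [k for k in OBSERVABLES if k in data.observations]
    if not present:
        raise ValueError("dataset contains no observables")
    # per-species max normalization, floored at 5% of the overall data scale
    # so an identically-zero species cannot dominate the objective
    global_max = max(float(np.max(np.abs(data.observations[k]))) for k in present)
    weights = {
        k: 1.0
        / max(float(np.max(np.abs(data.observations[k]))), 0.05 * global_max, 1e-12)
        for k in present
    }
    y_obs = np.concatenate([data.observations[k] * weights[k] for k in present])

    def residual(theta: np.ndarray) -> np.ndarray:
        model = _simulate_observables(theta, free, fixed_values, data, rtol)
        y_mod = np.concatenate([model[k] * weights[k] for k in present])
        return y_mod - y_obs

    guess0 = np.array([getattr(initial_guess, p) for p in free], dtype=float)
    guess0 = np.where(guess0 > 0, guess0, 1e-3)
    best = None
    for factor in np.logspace(-1.0, 1.0, n_starts):
        sol = least_squares(
            residual,
            guess0 * factor,
            bounds=(np.zeros_like(guess0), np.full_like(guess0, np.inf)),
            x_scale=guess0,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None

    m, p = best.fun.size, len(free)
    dof = max(m - p, 1)
    s2 = 2.0 * best.cost / dof
    J = best.jac
    col_norms = np.linalg.norm(J, axis=0)
    unident = [free[i] for i in range(p) if col_norms[i] < 1e-10 * max(col_norms.max(), 1e-30)]
    stderr: dict[str, float] = {}
    ci95: dict[str, tuple[float, float]] = {}
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    for i, name in enumerate(free):
        stderr[name] = float(se[i])
        ci95[name] = (float(best.x[i] - 1.96 * se[i]), float(best.x[i] + 1.96 * se[i]))

    est = dict(fixed_values)
    est.update(dict(zip(free, best.x)))
    at_bound = [
        name for name in free
        if est[name] < 1e-6 * max(getattr(initial_guess, name), 1e-12)
    ]
    model = _simulate_observables(best.x, free, fixed_values, data, rtol)
    r2 = r_squared(
        np.concatenate([model[k] for k in present]),
        np.concatenate([data.observations[k] for k in present]),
    )
    return FitResult(
        params=KineticParameters(**est),
        stderr=stderr,
        ci95=ci95,
        r2=r2,
        residuals=best.fun,
        cost=float(best.cost),
        at_bound=at_bound,
        unidentifiable=unident,
    )


def fit_activation_distribution(
    mab_fraction: float, mono_fraction: float, bi_fraction: float
) -> ActivationDistribution:
    """Activation distribution from the end-state species ratio.

    At reaction completion every activated site has reacted, so the final
    unconjugated / mono / bi fractions map directly onto the fractions of
    antibody with zero / one / two activated cysteines.
    """
    fracs = np.array([mab_fraction, mono_fraction, bi_fraction], dtype=float)
    if np.any(fracs < 0):
        raise ValueError("fractions must be non-negative")
    total = fracs.sum()
    if total <= 0 or abs(total - 1.0) > 0.05:
        raise ValueError(f"fractions not normalizable (sum={total:.4f})")
    fracs = fracs / total
    return ActivationDistribution(p2=fracs[2], p1=fracs[1], p0=fracs[0])


def fit_distribution_from_trajectory(traj: Trajectory) -> ActivationDistribution:
    """End-state activation distribution of a completed simulation."""
    end = traj.state_at(-1)
    tot = end.total_mab
    return fit_activation_distribution(
        (end.A2 + end.A1 + end.A0) / tot,
        (end.M1a + end.M1b) / tot,
        end.M2 / tot,
    )


def r_squared(model: np.ndarray, observed: np.ndarray) -> float:
    """Coefficient of determination over all observed points jointly."""
    model = np.asarray(model, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if model.shape != observed.shape or model.size < 3:
        raise ValueError("need congruent series with at least 3 points")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed series has zero variance")
    ss_res = float(np.sum((observed - model) ** 2))
    return 1.0 - ss_res / ss_tot


def read_dataset_csv(
    path,
    c_mab0: float,
    feed: FeedSchedule,
    distribution: ActivationDistribution = ActivationDistribution(),
    fractional: bool = False,
) -> KineticDataset:
    """Read a long-format dataset CSV (``time_s, species, value[, sd]``)."""
    df = pd.read_csv(path)
    missing = {"time_s", "species", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
    wide = df.pivot_table(index="time_s", columns="species", values="value").sort_index()
    return KineticDataset(
        times=wide.index.to_numpy(),
        observations={k: wide[k].to_numpy() for k in wide.columns},
        c_mab0=c_mab0,
        feed=feed,
        distribution=distribution,
        fractional=fractional,
    )


def write_dataset_csv(data: KineticDataset, path) -> None:
    rows = []
    for name, arr in data.observations.items():
        for t, v in zip(data.times, arr):
            rows.append({"time_s": t, "species": name, "value": v})
    pd.DataFrame(rows).sort_values(["time_s", "species"]).to_csv(path, index=False)
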