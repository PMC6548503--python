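"""Chemostat model of a single consumer/releaser strain and its steady-state
exchange-phenotype estimators.

A chemostat feeds fresh medium carrying the limiting metabolite at reservoir
concentration ``L0`` and washes culture out at dilution rate ``dil``::

    d n / dt = (g(L) - dil) * n            g = b(L) - d - c
    d L / dt = L0*dil - L*dil - u * b(L) * n
    d H / dt = r * n - dil * H

At steady state the net growth rate equals the dilution rate (g_ss = dil),
which turns the balances into estimators that need only the steady-state
readouts:

    u = (L0*dil - L_ss*dil) / (g_ss * n_ss)   ≈ L0 / n_ss      (L_ss << L0)
    r = dil * H_ss / n_ss
    r/u = (H_ss / L0) * dil

The last line — the exchange ratio — depends only on the released-metabolite
steady state and the feed, not on cell density, which is why two strains with
proportionally scaled (r, u) produce indistinguishable H_ss despite different
steady-state densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import ATOL, RTOL, StrainParams, _integrate

__all__ = [
    "ChemostatParams",
    "ChemostatState",
    "SteadyStateSummary",
    "flow_rate",
    "simulate_chemostat",
    "estimate_utilization_ss",
    "estimate_release_ss",
    "exchange_ratio_ss",
    "estimate_from_run",
    "inoculation_state",
]


@dataclass(frozen=True)
class ChemostatParams:
    """Operating point of a chemostat culture.

    L0 : reservoir limiting-metabolite concentration (fmole/ml)
    dil : dilution rate (per hr)
    volume : culture volume (ml), used only for flow-rate bookkeeping
    strain : phenotype of the cultured strain
    """

    L0: float
    dil: float
    strain: StrainParams
    volume: float = 19.0

    def __post_init__(self) -> None:
        if self.L0 <= 0 or self.dil <= 0 or self.volume <= 0:
            raise ValueError("L0, dil and volume must all be > 0")


@dataclass(frozen=True)
class ChemostatState:
    """Live density (cells/ml) plus limiting (L) and released (H) metabolite
    concentrations (fmole/ml)."""

    t: float
    n_live: float
    L: float
    H: float = 0.0

    def __post_init__(self) -> None:
        if self.n_live < 0 or self.L < 0 or self.H < 0:
            raise ValueError("densities and concentrations must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.n_live, self.L, self.H], dtype=float)


@dataclass(frozen=True)
class SteadyStateSummary:
    """End-of-run summary with a stationarity verdict.

    ``attained`` is True when n, L and H each changed by less than
    ``rel_change_tol`` over the final dilution time of the run; in that case
    the net growth rate g_ss equals the dilution rate within tolerance.
    """

    n_ss: float
    L_ss: float
    H_ss: float
    g_ss: float
    attained: bool
    rel_change: float


def flow_rate(volume: float, doubling_time: float) -> float:
    """Pump flow rate (ml/hr) giving the desired culture doubling time:
    volume * ln(2) / doubling_time."""
    if volume <= 0 or doubling_time <= 0:
        raise ValueError("volume and doubling_time must be > 0")
    return volume * np.log(2.0) / doubling_time


def inoculation_state(params: ChemostatParams, fill_frac: float = 0.4) -> ChemostatState:
    """Protocol-style starting state: inoculate at one third of the expected
    steady-state density L0/u, with the vessel topped up with reservoir
    medium so the starting metabolite is ``fill_frac * L0``."""
    n0 = params.L0 / params.strain.u / 3.0
    return ChemostatState(t=0.0, n_live=n0, L=fill_frac * params.L0, H=0.0)


def simulate_chemostat(
    params: ChemostatParams,
    init: ChemostatState,
    times: Sequence[float] | np.ndarray,
    rel_change_tol: float = 1e-3,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> tuple[pd.DataFrame, SteadyStateSummary]:
    """Integrate the chemostat ODEs and summarize the end state.

    Returns ``(trajectory, summary)`` where the trajectory is a DataFrame
    with columns t, n_live, L, H.  Metabolite consumption is proportional to
    the birth rate b(L) (utilization is per birth); the net growth rate
    g = b - d - c is what balances the dilution rate at steady state.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid")
    sp = params.strain

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        n, L, H = y
        b = sp.birth_law.rate(max(L, 0.0))
        g = b - sp.d - sp.c
        return np.array(
            [
                (g - params.dil) * n,
                params.L0 * params.dil - L * params.dil - sp.u * b * n,
                sp.r * n - params.dil * H,
            ]
        )

    y = _integrate(rhs, init.as_array(), times, rtol, atol)
    traj = pd.DataFrame({"t": times, "n_live": y[:, 0], "L": y[:, 1], "H": y[:, 2]})

    # stationarity: relative change of each tracked component over the final
    # dilution time 1/dil
    t_back = times[-1] - 1.0 / params.dil
    i0 = int(np.searchsorted(times, t_back))
    i0 = min(max(i0, 0), len(times) - 2)
    final, earlier = y[-1], y[i0]
    scale = np.maximum(np.abs(final), atol)
    rel_change = float(np.max(np.abs(final - earlier) / scale))
    n_ss, L_ss, H_ss = final
    g_ss = float(sp.net_rate(L_ss)) if n_ss > 0 else 0.0
    attained = rel_change < rel_change_tol and n_ss > 0
    return traj, SteadyStateSummary(
        n_ss=float(n_ss),
        L_ss=float(L_ss),
        H_ss=float(H_ss),
        g_ss=g_ss,
        attained=attained,
        rel_change=rel_change,
    )


def estimate_utilization_ss(
    L0: float,
    dil: float,
    L_ss: float,
    g_ss: float,
    n_ss: float,
) -> tuple[float, float]:
    """Metabolite utilized per birth (fmole/cell) from steady-state readouts.

    Returns ``(exact, approximate)``: the exact balance
    (L0 - L_ss) * dil / (g_ss * n_ss) and the reservoir approximation
    L0 / n_ss, valid when the residual concentration L_ss is much smaller
    than the reservoir concentration.
    """
    if n_ss <= 0:
        raise ValueError("steady-state density must be positive")
    if g_ss <= 0:
        raise ValueError("steady-state growth rate must be positive")
    exact = (L0 * dil - L_ss * dil) / (g_ss * n_ss)
    approx = L0 / n_ss
    return float(exact), float(approx)


def estimate_release_ss(dil: float, H_ss: float, n_ss: float) -> float:
    """Per-cell release rate (fmole/cell/hr): dil * H_ss / n_ss."""
    if n_ss <= 0:
        raise ValueError("steady-state density must be positive")
    return float(dil * H_ss / n_ss)


def estimate_from_run(
    traj: pd.DataFrame,
    L0: float,
    dil: float,
    tail_frac: float = 0.25,
) -> dict[str, float]:
    """Apply the steady-state estimators to a sampled (possibly noisy) run.

    Steady-state readouts are taken as the mean of the trailing
    ``tail_frac`` of samples of each tracked column (t, n_live, L, H); the
    growth rate is taken as the dilution rate, which it equals at steady
    state.  Returns u (exact and reservoir-approximation forms), r, and the
    exchange ratio.
    """
    if not 0 < tail_frac <= 1:
        raise ValueError("tail_frac must be in (0, 1]")
    k = max(2, int(np.ceil(tail_frac * len(traj))))
    tail = traj.iloc[-k:]
    n_ss = float(tail["n_live"].mean())
    H_ss = float(tail["H"].mean())
    L_ss = float(tail["L"].mean()) if "L" in tail.columns else 0.0
    u_exact, u_approx = estimate_utilization_ss(L0, dil, L_ss, dil, n_ss)
    r = estimate_release_ss(dil, H_ss, n_ss)
    return {
        "n_ss": n_ss,
        "L_ss": L_ss,
        "H_ss": H_ss,
        "u_exact": u_exact,
        "u_approx": u_approx,
        "r": r,
        "exchange_ratio": exchange_ratio_ss(H_ss, L0, dil),
    }


def exchange_ratio_ss(H_ss: float, L0: float, dil: float) -> float:
    """Exchange ratio r/u (per hr) directly from supernatant readouts:
    (H_ss / L0) * dil.  Independent of cell density."""
    if L0 <= 0:
        raise ValueError("reservoir concentration L0 must be positive")
    return float(H_ss / L0 * dil)
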