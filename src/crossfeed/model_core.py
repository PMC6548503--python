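"""Obligate cross-feeding mutualism: community ODE model and its steady state.

Two reproductively isolated strains exchange essential metabolites: the
``lh`` strain requires lysine (L) and releases hypoxanthine (H), while the
complementary ``hl`` strain requires hypoxanthine and releases lysine.
Neither strain can grow alone, so the coculture settles into balanced
exponential growth in which both strains, and hence the community, grow at a
single rate ``g_comm`` with a fixed strain ratio and stationary free
metabolite concentrations.

The model tracks live-cell densities of both strains and the two free
metabolite pools::

    d n_lh / dt = (b_L(L) - d_L - c_L) * n_lh
    d n_hl / dt = (b_H(H) - d_H - c_H) * n_hl
    d L    / dt = r_L * n_hl - u_L * b_L(L) * n_lh
    d H    / dt = r_H * n_lh - u_H * b_H(H) * n_hl

where ``b(m)`` is a Moser (sigmoidal Monod) birth law in the required
metabolite, ``d`` a death rate, ``c`` the growth-rate cost of constitutive
metabolite overproduction, ``r`` the per-live-cell metabolite release rate
(fmole/cell/hr), and ``u`` the metabolite amount consumed per cell birth
(fmole/cell).

Balancing the four equations gives the closed-form community growth rate

    g_comm = -(d_H + c_H + d_L + c_L)/2
             + sqrt( r_H r_L / (u_L u_H) + (d_H + c_H - d_L - c_L)^2 / 4 )

whose leading term sqrt(r_H r_L / (u_L u_H)) is the geometric mean of the two
"exchange ratios" r_H/u_L and r_L/u_H (benefit release rate per unit benefit
invested to build the releasing cell).  Scaling one strain's release rate and
its partner-metabolite utilization by a common factor — e.g. a cell-size
mutation making bigger cells that release more but also cost more to build —
leaves g_comm exactly unchanged.

Canonical units throughout: hours, cells/ml, fmole/ml (1 µM = 1e6 fmole/ml).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "MoserParams",
    "StrainParams",
    "CommunityParams",
    "CommunityState",
    "Trajectory",
    "community_rhs",
    "simulate_community",
    "steady_state_growth_rate",
    "approx_growth_rate",
    "steady_state_strain_ratio",
    "log_slope",
]

#: Default solver tolerances (stiff-capable integrator).
RTOL = 1e-8
ATOL = 1e-12


# ---------------------------------------------------------------------------
# parameter and state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoserParams:
    """Moser birth law b(m) = gmax * m^n / (K^n + m^n).

    Parameters
    ----------
    gmax : float
        Maximal birth rate in excess metabolite (per hr).
    K : float
        Metabolite concentration supporting gmax/2 (fmole/ml).
    n : float
        Growth cooperativity (dimensionless); n = 1 recovers Monod kinetics.
    """

    gmax: float
    K: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.gmax < 0:
            raise ValueError(f"gmax must be >= 0, got {self.gmax}")
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.n <= 0:
            raise ValueError(f"n must be > 0, got {self.n}")

    def rate(self, conc: float | np.ndarray) -> float | np.ndarray:
        """Birth rate at metabolite concentration ``conc`` (fmole/ml)."""
        conc = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            cn = np.where(conc > 0, conc, 0.0) ** self.n
            out = self.gmax * cn / (self.K**self.n + cn)
        return float(out) if out.ndim == 0 else out

    def inverse(self, rate: float) -> float:
        """Concentration at which the birth law attains ``rate`` (< gmax)."""
        if not 0 <= rate < self.gmax:
            raise ValueError(f"rate must be in [0, gmax={self.gmax}), got {rate}")
        if rate == 0:
            return 0.0
        x = rate / self.gmax
        return self.K * (x / (1.0 - x)) ** (1.0 / self.n)


@dataclass(frozen=True)
class StrainParams:
    """One strain's exchange phenotype.

    Attributes
    ----------
    r : float
        Release rate of the partner's required metabolite (fmole/cell/hr).
    u : float
        Own required metabolite utilized per cell birth (fmole/cell).
    d : float
        Death rate (per hr).
    c : float
        Growth-rate cost of constitutive overproduction (per hr),
        subtracted from the birth rate.
    birth_law : MoserParams
        Birth rate as a function of the required metabolite.
    """

    r: float
    u: float
    d: float = 0.0
    c: float = 0.0
    birth_law: MoserParams = field(default_factory=lambda: MoserParams(0.45, 1e6, 1.0))

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"release rate r must be >= 0, got {self.r}")
        if self.u <= 0:
            raise ValueError(f"utilization per birth u must be > 0, got {self.u}")
        if self.d < 0 or self.c < 0:
            raise ValueError("death rate d and cost c must be >= 0")

    @property
    def loss(self) -> float:
        """Total per-capita loss rate d + c (per hr)."""
        return self.d + self.c

    def net_rate(self, conc: float | np.ndarray) -> float | np.ndarray:
        """Net per-capita growth rate b(conc) - d - c."""
        return self.birth_law.rate(conc) - self.d - self.c


def birth_law_from_net_fit(net: MoserParams, loss: float) -> MoserParams:
    """Convert a Moser law fitted to *net* growth rates into a birth law.

    Growth assays measure net rates g = b - (d + c); the ODEs are written in
    the birth rate b.  With a subtractive loss the fitted curve is shifted up
    by ``loss`` uniformly, i.e. only gmax changes.
    """
    return replace(net, gmax=net.gmax + loss)


@dataclass(frozen=True)
class CommunityParams:
    """Phenotypes of the two complementary strains.

    ``lh`` consumes lysine and releases hypoxanthine; ``hl`` consumes
    hypoxanthine and releases lysine.  In the notation of the model,
    r_H = lh.r, u_L = lh.u, r_L = hl.r, u_H = hl.u.
    """

    lh: StrainParams
    hl: StrainParams

    # -- flat-key config I/O -------------------------------------------------
    _FIELDS = ("r", "u", "d", "c", "gmax", "K", "n")

    def to_dict(self) -> dict[str, float]:
        """Flat mapping with dotted keys: lh.r, lh.u, ..., hl.n."""
        out: dict[str, float] = {}
        for name, sp in (("lh", self.lh), ("hl", self.hl)):
            out.update(
                {
                    f"{name}.r": sp.r,
                    f"{name}.u": sp.u,
                    f"{name}.d": sp.d,
                    f"{name}.c": sp.c,
                    f"{name}.gmax": sp.birth_law.gmax,
                    f"{name}.K": sp.birth_law.K,
                    f"{name}.n": sp.birth_law.n,
                }
            )
        return out

    @classmethod
    def from_dict(cls, mapping: Mapping[str, object]) -> "CommunityParams":
        """Build from a flat dotted-key mapping or a nested two-level mapping."""
        flat: dict[str, float] = {}
        for key, val in mapping.items():
            if isinstance(val, Mapping):
                for sub, v in val.items():
                    flat[f"{key}.{sub}"] = float(v)  # type: ignore[arg-type]
            else:
                flat[str(key)] = float(val)  # type: ignore[arg-type]
        strains = {}
        for name in ("lh", "hl"):
            missing = [f for f in cls._FIELDS if f"{name}.{f}" not in flat]
            if missing:
                raise KeyError(f"missing parameter keys for {name}: {missing}")
            strains[name] = StrainParams(
                r=flat[f"{name}.r"],
                u=flat[f"{name}.u"],
                d=flat[f"{name}.d"],
                c=flat[f"{name}.c"],
                birth_law=MoserParams(
                    flat[f"{name}.gmax"], flat[f"{name}.K"], flat[f"{name}.n"]
                ),
            )
        return cls(**strains)


@dataclass(frozen=True)
class CommunityState:
    """Instantaneous state: strain densities (cells/ml) and free metabolite
    concentrations (fmole/ml)."""

    t: float
    n_lh: float
    n_hl: float
    L: float
    H: float

    def __post_init__(self) -> None:
        for name in ("n_lh", "n_hl", "L", "H"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.n_lh, self.n_hl, self.L, self.H], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """Solution of the community ODEs on a strictly increasing time grid."""

    times: np.ndarray          # (T,) hr
    states: np.ndarray         # (T, 4): n_lh, n_hl, L, H
    rtol: float = RTOL
    atol: float = ATOL

    COLUMNS = ("t", "n_lh", "n_hl", "L", "H")

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.states.shape != (len(self.times), 4):
            raise ValueError("states must have shape (len(times), 4)")

    @property
    def n_lh(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def n_hl(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def L(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def H(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def total_density(self) -> np.ndarray:
        return self.n_lh + self.n_hl

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "n_lh": self.n_lh,
                "n_hl": self.n_hl,
                "L": self.L,
                "H": self.H,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, sep="\t")
        return cls(
            times=df["t"].to_numpy(float),
            states=df[["n_lh", "n_hl", "L", "H"]].to_numpy(float),
        )


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def community_rhs(state: CommunityState, params: CommunityParams) -> CommunityState:
    """Time derivatives of the community state.

    Returns a :class:`CommunityState` whose fields hold d/dt of each
    component (``t`` holds dt/dt = 1).  Negative inputs are rejected by the
    state constructor.
    """
    d = _rhs(state.as_array(), params)
    out = object.__new__(CommunityState)
    object.__setattr__(out, "t", 1.0)
    object.__setattr__(out, "n_lh", d[0])
    object.__setattr__(out, "n_hl", d[1])
    object.__setattr__(out, "L", d[2])
    object.__setattr__(out, "H", d[3])
    return out


def _rhs(y: np.ndarray, params: CommunityParams) -> np.ndarray:
    n_lh, n_hl, L, H = y
    bl = params.lh.birth_law.rate(max(L, 0.0))
    bh = params.hl.birth_law.rate(max(H, 0.0))
    return np.array(
        [
            (bl - params.lh.d - params.lh.c) * n_lh,
            (bh - params.hl.d - params.hl.c) * n_hl,
            params.hl.r * n_hl - params.lh.u * bl * n_lh,
            params.lh.r * n_lh - params.hl.u * bh * n_hl,
        ]
    )


class SolverError(RuntimeError):
    """Raised when the ODE integrator fails or produces invalid states."""


def _integrate(
    fun,
    y0: np.ndarray,
    times: np.ndarray,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """Integrate with a stiff-capable method; clip tiny negative excursions."""
    sol = solve_ivp(
        fun,
        (times[0], times[-1]),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(f"ODE integration failed: {sol.message}")
    y = sol.y.T
    # scale the negativity guard with the solution magnitude: rtol-level
    # undershoot on a large component is solver noise, not a model error
    floor = -np.maximum(atol, rtol * np.max(np.abs(y), axis=0))
    if np.any(y < floor[None, :]):
        worst = float(y.min())
        raise SolverError(f"state went significantly negative (min={worst:g})")
    return np.clip(y, 0.0, None)


def simulate_community(
    params: CommunityParams,
    init: CommunityState,
    times: Sequence[float] | np.ndarray,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the community ODEs on the given time grid.

    ``times`` must be strictly increasing with ``times[0] == init.t``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid")
    if not np.isclose(times[0], init.t):
        raise ValueError(f"times[0]={times[0]} must equal init.t={init.t}")
    y = _integrate(lambda t, y: _rhs(y, params), init.as_array(), times, rtol, atol)
    return Trajectory(times=times, states=y, rtol=rtol, atol=atol)


# ---------------------------------------------------------------------------
# closed-form steady state
# ---------------------------------------------------------------------------

def steady_state_growth_rate(params: CommunityParams) -> float:
    """Community steady-state growth rate (per hr), closed form.

    g_comm = -(δ_H + δ_L)/2 + sqrt(r_H r_L/(u_L u_H) + (δ_H - δ_L)²/4)
    with δ = d + c for each strain.  The square-root form has no catastrophic
    cancellation for non-negative parameters.
    """
    rh, ul = params.lh.r, params.lh.u
    rl, uh = params.hl.r, params.hl.u
    if rh * rl <= 0:
        raise ValueError("both release rates must be positive")
    dl, dh = params.lh.loss, params.hl.loss
    return -(dh + dl) / 2.0 + np.sqrt(rh * rl / (ul * uh) + (dh - dl) ** 2 / 4.0)


def approx_growth_rate(params: CommunityParams) -> float:
    """Small-loss approximation sqrt(r_H r_L / (u_H u_L)) (per hr).

    Exact when both strains' death rates and overproduction costs vanish;
    this is the geometric mean of the two exchange ratios r_H/u_L and
    r_L/u_H.
    """
    rh, ul = params.lh.r, params.lh.u
    rl, uh = params.hl.r, params.hl.u
    if rh * rl <= 0:
        raise ValueError("both release rates must be positive")
    return float(np.sqrt(rh * rl / (ul * uh)))


def steady_state_strain_ratio(params: CommunityParams) -> float:
    """Steady-state density ratio n_hl / n_lh (dimensionless).

    From the lysine balance r_L n_hl = u_L b_L n_lh at steady state, with
    b_L = g_comm + d_L + c_L.
    """
    if params.hl.r <= 0:
        raise ValueError("hl release rate r_L must be positive")
    g = steady_state_growth_rate(params)
    return params.lh.u * (g + params.lh.loss) / params.hl.r


# ---------------------------------------------------------------------------
# trajectory summaries
# ---------------------------------------------------------------------------

def log_slope(
    times: np.ndarray,
    values: np.ndarray,
    window_frac: float = 0.25,
    stationarity_rtol: float = 0.01,
) -> tuple[float, bool]:
    """Least-squares slope of ln(values) over the trailing fraction of a grid.

    Returns ``(slope, stationary)`` where ``stationary`` compares the slope
    over the last ``window_frac`` of points against the preceding window of
    equal size (relative difference below ``stationarity_rtol``).
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if np.any(values <= 0):
        raise ValueError("values must be positive to take logs")
    n = len(times)
    k = max(3, int(np.ceil(window_frac * n)))
    if 2 * k > n:
        raise ValueError("grid too short for the requested window")

    def _slope(sl: slice) -> float:
        t, v = times[sl], np.log(values[sl])
        return float(np.polyfit(t, v, 1)[0])

    last = _slope(slice(n - k, n))
    prev = _slope(slice(n - 2 * k, n - k))
    scale = max(abs(last), abs(prev), 1e-30)
    return last, abs(last - prev) / scale < stationarity_rtol
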