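"""Seeded synthetic-data generators with known ground truth.

Each generator emulates one assay that the estimator modules consume —
microscopy growth curves, starvation release assays, yield (utilization)
assays, chemostat runs, whole-genome depth tracks, and RAD marker tables
for backcross tetrads — and returns the data together with a
:class:`TruthRecord` holding every true parameter used, so recovery can be
checked without any external dataset.

Measurement noise is multiplicative lognormal throughout (the tracked
quantities are positive), parameterized by a single coefficient of
variation and scaled to have mean exactly 1, so the noiseless limit of
every generator is exactly invertible by its matched estimator.  All
randomness flows through one integer seed per call; identical seeds give
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from .chemostat import ChemostatParams, ChemostatState, inoculation_state, simulate_chemostat
from .model_core import MoserParams, StrainParams
from .phenotyping import UM_TO_FMOLE_PER_ML, AssayTable
from .ploidy import DepthTrack, RadMarkerTable

__all__ = [
    "TruthRecord",
    "gen_growth_curves",
    "gen_release_assay",
    "gen_yield_assay",
    "gen_chemostat_run",
    "gen_depth_track",
    "gen_rad_tetrads",
    "expected_rad_proportions",
    "DEFAULT_CHROM_LENGTHS",
]


@dataclass
class TruthRecord:
    """Ground truth for one generated dataset."""

    generator: str
    seed: int
    params: dict
    files: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        """Write as a YAML text file."""
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "generator": self.generator,
                    "seed": self.seed,
                    "params": self.params,
                    "files": self.files,
                },
                fh,
                sort_keys=False,
            )


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-sigma**2 / 2.0, sigma, size))


# ---------------------------------------------------------------------------
# batch assays
# ---------------------------------------------------------------------------

def gen_growth_curves(
    moser: MoserParams,
    concentrations: Sequence[float] = tuple(
        c * UM_TO_FMOLE_PER_ML for c in (0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 16.0, 32.0)
    ),
    noise_cv: float = 0.02,
    n_replicates: int = 1,
    seed: int = 0,
    u: float = 2.0,
    n0: float = 5e3,
    times: Optional[np.ndarray] = None,
    residual_hr: float = 3.0,
) -> tuple[AssayTable, TruthRecord]:
    """Microscopy-style growth curves: fluorescence vs time per concentration.

    Biomass grows under the Moser birth law with metabolite depletion
    (dL/dt = -u*b(L)*n).  For the first ``residual_hr`` hours growth runs at
    gmax regardless of the external concentration, emulating residual
    growth on stored intracellular metabolite after starvation; estimators
    should exclude this phase (``max_growth_rate(..., exclude_before=...)``).
    Fluorescence is biomass normalized to its time-zero value, with
    multiplicative lognormal noise per time point.
    """
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.arange(0.0, 24.0 + 1e-9, 0.5)
    times = np.asarray(times, float)
    rows = []
    for L0 in concentrations:
        def rhs(t, y, L0=L0):
            n, L = y
            b = moser.gmax if t < residual_hr else moser.rate(max(L, 0.0))
            return [b * n, -u * moser.rate(max(L, 0.0)) * n * (t >= residual_hr)]

        sol = solve_ivp(
            rhs, (times[0], times[-1]), [n0, L0], t_eval=times, rtol=1e-9, atol=1e-9,
            max_step=0.25,
        )
        biomass = np.clip(sol.y[0], 1e-300, None)
        for rep in range(n_replicates):
            fluor = biomass / biomass[0] * _lognormal_factor(rng, noise_cv, len(times))
            rows.append(
                pd.DataFrame(
                    {
                        "time": times,
                        "fluorescence": fluor,
                        "concentration": L0,
                        "replicate": rep,
                    }
                )
            )
    data = pd.concat(rows, ignore_index=True)
    truth = TruthRecord(
        "gen_growth_curves",
        seed,
        {
            "gmax": moser.gmax,
            "K": moser.K,
            "n": moser.n,
            "u": u,
            "n0": n0,
            "noise_cv": noise_cv,
            "residual_hr": residual_hr,
            "concentrations": list(map(float, concentrations)),
        },
    )
    return AssayTable(data, units={"concentration": "fmole/ml"}), truth


def gen_release_assay(
    r_true: float = 0.3,
    death_rate: float = 0.01,
    n0: float = 1e6,
    times: Sequence[float] = (0.0, 6.0, 12.0, 18.0, 24.0),
    noise_cv: float = 0.05,
    seed: int = 0,
) -> tuple[AssayTable, TruthRecord]:
    """Starvation release assay: live/dead densities and supernatant
    metabolite concentration sampled over ~24 hr.

    Live density decays exponentially at the starvation death rate; the
    released concentration is ``r_true`` times the exact time integral of
    live density, with lognormal noise on the concentration readings.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times, float)
    live = n0 * np.exp(-death_rate * t)
    integral = n0 * (1.0 - np.exp(-death_rate * t)) / death_rate if death_rate > 0 else n0 * t
    conc = r_true * integral * _lognormal_factor(rng, noise_cv, len(t))
    data = pd.DataFrame(
        {
            "time": t,
            "live_density": live,
            "dead_density": n0 - live,
            "concentration": conc,
        }
    )
    truth = TruthRecord(
        "gen_release_assay",
        seed,
        {"r": r_true, "death_rate": death_rate, "n0": n0, "noise_cv": noise_cv},
    )
    return AssayTable(data, units={"concentration": "fmole/ml"}), truth


def gen_yield_assay(
    u_true: float = 2.0,
    linear_max: float = 25.0 * UM_TO_FMOLE_PER_ML,
    concentrations: Sequence[float] = tuple(
        c * UM_TO_FMOLE_PER_ML for c in (2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 40.0, 60.0)
    ),
    noise_cv: float = 0.03,
    seed: int = 0,
    inoculum: float = 1e5,
) -> tuple[AssayTable, TruthRecord]:
    """Yield assay: final saturated density vs input metabolite concentration.

    Linear (final = inoculum + conc/u) up to ``linear_max``, flat above —
    past that input the culture saturates on something else, which is why
    the utilization regression must be restricted to the linear range.
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, float)
    final = inoculum + np.minimum(conc, linear_max) / u_true
    final = final * _lognormal_factor(rng, noise_cv, len(conc))
    data = pd.DataFrame({"input_concentration": conc, "final_density": final})
    truth = TruthRecord(
        "gen_yield_assay",
        seed,
        {
            "u": u_true,
            "linear_max": float(linear_max),
            "inoculum": inoculum,
            "noise_cv": noise_cv,
        },
    )
    return AssayTable(data, units={"input_concentration": "fmole/ml"}), truth


# ---------------------------------------------------------------------------
# chemostat
# ---------------------------------------------------------------------------

def gen_chemostat_run(
    params: Optional[ChemostatParams] = None,
    t_end: float = 150.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    n_samples: int = 60,
):
    """Chemostat trajectory with measurement noise on sampled n, L and H.

    Returns ``(noisy_samples, clean_summary, truth)``.  The default
    operating point is a 20 µM reservoir diluted for a 6-hr doubling time,
    culturing a consumer/releaser with u = 2 fmole/cell and
    r = 0.4 fmole/cell/hr (losses folded to zero so the steady-state
    balances are exact).
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = ChemostatParams(
            L0=20.0 * UM_TO_FMOLE_PER_ML,
            dil=np.log(2.0) / 6.0,
            strain=StrainParams(
                r=0.4, u=2.0, d=0.0, c=0.0, birth_law=MoserParams(0.45, 1e6, 2.0)
            ),
        )
    times = np.linspace(0.0, t_end, n_samples)
    traj, summary = simulate_chemostat(params, inoculation_state(params), times)
    noisy = traj.copy()
    for col in ("n_live", "L", "H"):
        noisy[col] = traj[col] * _lognormal_factor(rng, noise_cv, len(traj))
    truth = TruthRecord(
        "gen_chemostat_run",
        seed,
        {
            "L0": params.L0,
            "dil": params.dil,
            "r": params.strain.r,
            "u": params.strain.u,
            "d": params.strain.d,
            "c": params.strain.c,
            "noise_cv": noise_cv,
            "t_end": t_end,
        },
    )
    return noisy, summary, truth


# ---------------------------------------------------------------------------
# sequencing
# ---------------------------------------------------------------------------

#: 16 chromosomes, 20-65 kb: window statistics are length-invariant, so a
#: compact genome exercises the caller at a fraction of the cost of real
#: chromosome sizes.
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    f"chr{i + 1:02d}": 20_000 + 3_000 * i for i in range(16)
}


def gen_depth_track(
    chrom_lengths: Optional[Mapping[str, int]] = None,
    base_coverage: float = 30.0,
    duplicated_chroms: Sequence[str] = (),
    seed: int = 0,
) -> tuple[DepthTrack, TruthRecord]:
    """Per-base depth ~ Poisson(base_coverage * copy_number) per chromosome."""
    rng = np.random.default_rng(seed)
    if chrom_lengths is None:
        chrom_lengths = DEFAULT_CHROM_LENGTHS
    depths = {}
    for chrom, length in chrom_lengths.items():
        copy = 2 if chrom in duplicated_chroms else 1
        depths[chrom] = rng.poisson(base_coverage * copy, size=int(length)).astype(float)
    truth = TruthRecord(
        "gen_depth_track",
        seed,
        {
            "base_coverage": base_coverage,
            "duplicated_chroms": list(duplicated_chroms),
            "chrom_lengths": {k: int(v) for k, v in chrom_lengths.items()},
        },
    )
    return DepthTrack(depths), truth


def default_marker_map(
    n_markers: int = 3000,
    n_contigs: int = 16,
    target: str = "chr14",
    target_frac: float = 0.06,
    seed: int = 0,
    mismatch_frac: float = 0.01,
) -> pd.DataFrame:
    """Marker layout: id, supercontig, expected_len, observed_len, weight.

    A fraction ``target_frac`` of markers sits on the target supercontig;
    the rest are spread evenly over the other contigs.  Expected fragment
    lengths are drawn in 100-450 bp — within and around the (125, 400) gel
    retention window so the length filter has work to do — and a small
    fraction of markers get a discordant observed length.  Per-marker base
    weights are lognormal, emulating uneven digestion/amplification
    efficiency.
    """
    rng = np.random.default_rng(seed)
    contigs = [f"chr{i + 1:02d}" for i in range(n_contigs)]
    if target not in contigs:
        raise ValueError(f"target {target!r} not among generated contigs")
    n_target = int(round(target_frac * n_markers))
    others = [c for c in contigs if c != target]
    assignment = [target] * n_target + [
        others[i % len(others)] for i in range(n_markers - n_target)
    ]
    rng.shuffle(assignment)
    expected = rng.integers(100, 451, size=n_markers)
    observed = expected.copy()
    n_mismatch = int(round(mismatch_frac * n_markers))
    if n_mismatch:
        idx = rng.choice(n_markers, size=n_mismatch, replace=False)
        observed[idx] = expected[idx] + rng.integers(5, 50, size=n_mismatch)
    weight = rng.lognormal(mean=0.0, sigma=0.5, size=n_markers)
    return pd.DataFrame(
        {
            "id": [f"m{i:05d}" for i in range(n_markers)],
            "supercontig": assignment,
            "expected_len": expected,
            "observed_len": observed,
            "weight": weight / weight.sum(),
        }
    )


def expected_rad_proportions(
    marker_map: pd.DataFrame, copy_numbers: Mapping[str, int]
) -> pd.Series:
    """Infinite-read marker proportions for a given karyotype.

    Marker weight is multiplied by its supercontig's copy number and the
    whole vector renormalized, so duplicating a supercontig carrying weight
    fraction f maps its proportions to 2w/(1+f) and everything else to
    w/(1+f).
    """
    copies = marker_map["supercontig"].map(lambda c: copy_numbers.get(c, 1)).to_numpy()
    w = marker_map["weight"].to_numpy() * copies
    return pd.Series(w / w.sum(), index=pd.Index(marker_map["id"], name="id"))


def gen_rad_tetrads(
    n_markers: int = 3000,
    marker_map: Optional[pd.DataFrame] = None,
    reads_per_spore: int = 1_000_000,
    n_tetrads: int = 20,
    panel_size: int = 10,
    seed: int = 0,
    target: str = "chr14",
    target_frac: float = 0.06,
) -> tuple[RadMarkerTable, pd.DataFrame, TruthRecord]:
    """RAD read counts for tetrads from a disomic x euploid backcross.

    The zygote is trisomic for the target chromosome; meiosis I segregates
    the three homologs 2:1, so each tetrad's four spores carry target copy
    numbers [2, 2, 1, 1] in random order (nondisjunction is not modeled).
    Per-spore counts are multinomial draws of ``reads_per_spore`` reads with
    marker weight proportional to base weight times copy number.  A euploid
    panel of ``panel_size`` samples is drawn the same way.

    Returns ``(table, spore_truth, truth)``: one marker table whose sample
    columns are ``panel01..`` then ``t01_s1..t<N>_s4``, a tidy DataFrame of
    true per-spore target copy numbers, and the TruthRecord.
    """
    rng = np.random.default_rng(seed)
    if marker_map is None:
        marker_map = default_marker_map(
            n_markers=n_markers, target=target, target_frac=target_frac,
            seed=int(rng.integers(2**31)),
        )
    base_w = marker_map["weight"].to_numpy()
    on_target = (marker_map["supercontig"] == target).to_numpy()

    def draw(copies_target: int) -> np.ndarray:
        w = base_w * np.where(on_target, copies_target, 1)
        return rng.multinomial(reads_per_spore, w / w.sum())

    counts: dict[str, np.ndarray] = {}
    for i in range(panel_size):
        counts[f"panel{i + 1:02d}"] = draw(1)
    spore_rows = []
    for t in range(n_tetrads):
        copies = np.array([2, 2, 1, 1])
        rng.shuffle(copies)
        for s, cp in enumerate(copies):
            name = f"t{t + 1:02d}_s{s + 1}"
            counts[name] = draw(int(cp))
            spore_rows.append({"tetrad": t + 1, "spore": name, "target_copies": int(cp)})
    data = pd.concat(
        [
            marker_map[["id", "supercontig", "expected_len", "observed_len"]],
            pd.DataFrame(counts),
        ],
        axis=1,
    )
    truth = TruthRecord(
        "gen_rad_tetrads",
        seed,
        {
            "n_markers": int(len(marker_map)),
            "reads_per_spore": int(reads_per_spore),
            "n_tetrads": n_tetrads,
            "panel_size": panel_size,
            "target": target,
            "target_weight_frac": float(base_w[on_target].sum() / base_w.sum()),
        },
    )
    return RadMarkerTable(data), pd.DataFrame(spore_rows), truth
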