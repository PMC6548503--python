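"""Aneuploidy detection from sequencing read depth and RAD marker counts.

Two independent routes to the same question — does a strain carry an extra
chromosome copy?

**Whole-genome depth route.** Per-base read depth is averaged in successive
non-overlapping 1000-bp windows, each window mean is divided by the
genome-wide median of window means, and the normalized value is log2
transformed.  A euploid chromosome sits at log2 ≈ 0 and a duplicated
chromosome in a haploid background at log2 ≈ 1; a chromosome is called
duplicated when its mean window value clears a configurable threshold
(default 0.6).

**RAD marker route.** Restriction-site-associated markers give one read
count per marker per sample.  Markers are quality-filtered (median
per-sample coverage >= 2; cross-strain coefficient of variation of the
normalized proportion < 0.6; expected digest fragment length strictly
between 125 and 400 bp; observed alignment length matching expected), read
counts are converted to proportions of each sample's retained-marker total,
and each marker's proportion is compared to the median proportion across a
euploid panel.  A supercontig is called duplicated when the mean
sample/panel ratio over its markers clears the fold threshold.

Because proportions are renormalized per sample, duplicating a supercontig
that carries a fraction ``f`` of the marker weight depresses the on-target
ratio to 2/(1+f) and the off-target ratio to 1/(1+f); the default fold
threshold of 1.6 sits between those values for realistic ``f`` (≈1.89 vs
0.94 at f = 6%), whereas a literal 2-fold rule would miss even noiseless
duplications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthTrack",
    "PloidyProfile",
    "RadMarkerTable",
    "DisomyCallSet",
    "TetradSegregation",
    "windowed_log2_profile",
    "call_duplicated_chromosomes",
    "rad_filter_markers",
    "rad_call_disomy",
    "tetrad_segregation",
]

#: default marker quality filters
MIN_MEDIAN_COVERAGE = 2.0
MAX_CV = 0.6
LEN_BOUNDS = (125, 400)  # exclusive on both ends
MIN_MARKERS_PER_CONTIG = 5


# ---------------------------------------------------------------------------
# depth route
# ---------------------------------------------------------------------------

@dataclass
class DepthTrack:
    """Per-base read depth for each chromosome (0-based coordinates)."""

    depths: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.depths.items():
            arr = np.asarray(arr)
            if (arr < 0).any():
                raise ValueError(f"negative depth on {chrom}")
            self.depths[chrom] = arr

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.depths.items()}

    @classmethod
    def from_bedgraph(cls, path) -> "DepthTrack":
        """Read a bedGraph (chrom, start, end, depth; 0-based half-open)."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "depth"],
            comment="#",
        )
        depths: dict[str, np.ndarray] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            length = int(grp["end"].max())
            arr = np.zeros(length, dtype=float)
            for start, end, depth in grp[["start", "end", "depth"]].itertuples(index=False):
                arr[int(start) : int(end)] = depth
            depths[str(chrom)] = arr
        return cls(depths)

    def to_bedgraph(self, path) -> None:
        """Write as run-length-encoded bedGraph."""
        rows = []
        for chrom, arr in self.depths.items():
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                rows.append((chrom, int(s), int(e), arr[s]))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class PloidyProfile:
    """Windowed, median-normalized, log2-transformed depth profile.

    ``windows`` columns: chrom, start, end (0-based half-open), mean_depth,
    log2_norm, zero_flagged.  Zero-depth windows carry the profile's minimum
    finite log2 minus 1 and are flagged instead of being -inf.
    """

    windows: pd.DataFrame
    median_window_depth: float
    window_bp: int

    def mean_log2(self) -> pd.Series:
        """Mean log2 value per chromosome."""
        return self.windows.groupby("chrom", sort=False)["log2_norm"].mean()

    def to_tsv(self, path) -> None:
        self.windows.to_csv(path, sep="\t", index=False)


def windowed_log2_profile(track: DepthTrack, window_bp: int = 1000) -> PloidyProfile:
    """Mean depth in successive full windows, normalized by the genome-wide
    median window mean, log2 transformed.

    Trailing partial windows are dropped (they are short, hence noisy, and
    contribute nothing to a chromosome-scale call).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for chrom, depth in track.depths.items():
        n_win = len(depth) // window_bp
        if n_win == 0:
            continue
        means = depth[: n_win * window_bp].reshape(n_win, window_bp).mean(axis=1)
        starts = np.arange(n_win) * window_bp
        for s, m in zip(starts, means):
            rows.append((chrom, int(s), int(s) + window_bp, float(m)))
    if not rows:
        raise ValueError("no full window anywhere in the genome")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_depth"])
    median = float(np.median(df["mean_depth"]))
    if median <= 0:
        raise ValueError("genome median window depth is zero")
    with np.errstate(divide="ignore"):
        log2 = np.log2(df["mean_depth"].to_numpy() / median)
    zero = ~np.isfinite(log2)
    if zero.any():
        finite_min = log2[~zero].min() if (~zero).any() else 0.0
        log2[zero] = finite_min - 1.0
    df["log2_norm"] = log2
    df["zero_flagged"] = zero
    return PloidyProfile(windows=df, median_window_depth=median, window_bp=window_bp)


@dataclass(frozen=True)
class DisomyCallSet:
    """Per-chromosome/supercontig duplication calls.

    ``table`` columns: name, score (mean log2 or mean fold-change),
    n_markers (RAD route only), called (True/False, or pandas NA for
    no-call when too few markers survive filtering).
    """

    table: pd.DataFrame
    threshold: float
    metric: str  # "mean_log2" or "mean_fold"

    def called(self) -> list[str]:
        """Names called duplicated (no-calls excluded)."""
        mask = self.table["called"].fillna(False).astype(bool)
        return self.table.loc[mask, "name"].tolist()

    def call_for(self, name: str) -> Optional[bool]:
        row = self.table.loc[self.table["name"] == name]
        if row.empty:
            raise KeyError(f"no call record for {name!r}")
        val = row["called"].iloc[0]
        return None if pd.isna(val) else bool(val)


def call_duplicated_chromosomes(
    profile: PloidyProfile, log2_threshold: float = 0.6
) -> DisomyCallSet:
    """Call a chromosome duplicated when its mean window log2 >= threshold.

    The default of 0.6 sits between a euploid chromosome (≈0 after median
    normalization) and a duplicated chromosome in a haploid (≈1).
    """
    means = profile.mean_log2()
    table = pd.DataFrame(
        {
            "name": means.index,
            "score": means.to_numpy(),
            "called": means.to_numpy() >= log2_threshold,
        }
    )
    return DisomyCallSet(table=table, threshold=log2_threshold, metric="mean_log2")


# ---------------------------------------------------------------------------
# RAD marker route
# ---------------------------------------------------------------------------

@dataclass
class RadMarkerTable:
    """RAD marker read counts: one row per marker, one count column per sample.

    Required metadata columns: ``id``, ``supercontig``, ``expected_len``;
    ``observed_len`` defaults to ``expected_len`` when absent.  All other
    columns are per-sample read counts.
    """

    data: pd.DataFrame
    META_COLS = ("id", "supercontig", "expected_len", "observed_len")

    def __post_init__(self) -> None:
        for col in ("id", "supercontig", "expected_len"):
            if col not in self.data.columns:
                raise ValueError(f"missing required column {col!r}")
        if "observed_len" not in self.data.columns:
            self.data = self.data.copy()
            self.data["observed_len"] = self.data["expected_len"]
        if (self.data[self.sample_columns] < 0).to_numpy().any():
            raise ValueError("read counts must be >= 0")

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.META_COLS]

    def proportions(self) -> pd.DataFrame:
        """Per-sample read proportions over the markers in this table
        (columns sum to 1)."""
        counts = self.data[self.sample_columns].astype(float)
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0].tolist()
            raise ValueError(f"samples with zero total reads: {bad}")
        out = counts / totals
        out.index = self.data["id"]
        return out

    def median_coverage(self) -> pd.Series:
        """Per-marker median read count across samples."""
        return self.data[self.sample_columns].median(axis=1).set_axis(self.data["id"])

    def cross_strain_cv(self) -> pd.Series:
        """Per-marker CV (sd/mean) of the normalized proportion across all
        samples in the table."""
        props = self.proportions()
        mean = props.mean(axis=1)
        sd = props.std(axis=1, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = sd / mean
        return cv.fillna(np.inf)

    @classmethod
    def read(cls, path) -> "RadMarkerTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def rad_filter_markers(
    table: RadMarkerTable,
    min_median_coverage: float = MIN_MEDIAN_COVERAGE,
    max_cv: float = MAX_CV,
    len_bounds: tuple[int, int] = LEN_BOUNDS,
) -> tuple[RadMarkerTable, pd.DataFrame]:
    """Quality-filter RAD markers; returns (retained table, removal log).

    Filter predicates (independent, order-free):

    * median per-sample coverage >= ``min_median_coverage``;
    * cross-strain CV of the normalized proportion < ``max_cv``
      (CV >= 0.6 markers are discarded);
    * expected fragment length strictly inside ``len_bounds`` — the gel cut
      retains > 125 bp and < 400 bp, bounds exclusive;
    * observed alignment length equal to the expected digest length.

    The removal log has one row per discarded marker with the reasons.
    """
    cov = table.median_coverage().to_numpy()
    cv = table.cross_strain_cv().to_numpy()
    exp_len = table.data["expected_len"].to_numpy()
    obs_len = table.data["observed_len"].to_numpy()
    lo, hi = len_bounds

    reasons = []
    for i in range(len(table.data)):
        why = []
        if cov[i] < min_median_coverage:
            why.append(f"median_coverage<{min_median_coverage}")
        if cv[i] >= max_cv:
            why.append(f"cv>={max_cv}")
        if not (lo < exp_len[i] < hi):
            why.append(f"length_outside({lo},{hi})")
        if obs_len[i] != exp_len[i]:
            why.append("length_mismatch")
        reasons.append(";".join(why))
    reasons = np.array(reasons)
    keep = reasons == ""
    if not keep.any():
        raise ValueError(
            "no markers survive filtering "
            f"(of {len(keep)}: {np.sum(cov < min_median_coverage)} low-coverage, "
            f"{np.sum(cv >= max_cv)} high-CV, "
            f"{np.sum(~((lo < exp_len) & (exp_len < hi)))} out-of-size, "
            f"{np.sum(obs_len != exp_len)} length-mismatched)"
        )
    removed = pd.DataFrame(
        {"id": table.data["id"].to_numpy()[~keep], "reason": reasons[~keep]}
    )
    retained = RadMarkerTable(table.data.loc[keep].reset_index(drop=True))
    return retained, removed


def rad_call_disomy(
    sample: pd.Series,
    panel: pd.Series,
    supercontigs: pd.Series,
    fold_threshold: float = 1.6,
    min_markers: int = MIN_MARKERS_PER_CONTIG,
) -> DisomyCallSet:
    """Call duplicated supercontigs from marker proportion fold-changes.

    ``sample`` holds one sample's normalized marker proportions, ``panel``
    the euploid panel's per-marker median proportions, ``supercontigs`` the
    marker -> supercontig assignment; all three are indexed by marker id and
    must share the retained marker set.  Per marker the ratio sample/panel
    is computed; per supercontig the mean ratio over its markers is compared
    to ``fold_threshold``.  Supercontigs with fewer than ``min_markers``
    retained markers are reported as no-call (NA), not as euploid.
    """
    if not (sample.index.equals(panel.index) and sample.index.equals(supercontigs.index)):
        raise ValueError("sample, panel and supercontigs must share the same marker index")
    if (panel <= 0).any():
        raise ValueError("panel median proportions must all be positive")
    ratio = sample / panel
    grouped = ratio.groupby(supercontigs, sort=False)
    mean_fold = grouped.mean()
    n_markers = grouped.size()
    called = pd.array(mean_fold.to_numpy() >= fold_threshold, dtype="boolean")
    called[(n_markers < min_markers).to_numpy()] = pd.NA
    table = pd.DataFrame(
        {
            "name": mean_fold.index,
            "score": mean_fold.to_numpy(),
            "n_markers": n_markers.to_numpy(),
            "called": called,
        }
    )
    return DisomyCallSet(table=table, threshold=fold_threshold, metric="mean_fold")


def panel_median_proportions(panel_table: RadMarkerTable) -> pd.Series:
    """Per-marker median normalized proportion across a euploid panel."""
    return panel_table.proportions().median(axis=1)


# ---------------------------------------------------------------------------
# tetrad check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TetradSegregation:
    n_duplicated: int
    n_euploid: int
    n_no_call: int
    is_2_2: Optional[bool]  # None when any spore is a no-call


def tetrad_segregation(
    calls: Sequence[DisomyCallSet], target: str
) -> TetradSegregation:
    """Count duplicated vs euploid calls for ``target`` across the four
    spores of a tetrad.

    A trisomic zygote (disomic x euploid cross) segregates its three
    homologs 2:1 at meiosis I, so perfect calls give exactly two duplicated
    and two euploid spores.  Any no-call spore makes the 2:2 verdict
    indeterminate (``is_2_2 = None``).
    """
    if len(calls) != 4:
        raise ValueError(f"a tetrad has exactly 4 spores, got {len(calls)}")
    verdicts = [c.call_for(target) for c in calls]
    n_dup = sum(v is True for v in verdicts)
    n_eu = sum(v is False for v in verdicts)
    n_nc = sum(v is None for v in verdicts)
    is22 = None if n_nc else (n_dup == 2 and n_eu == 2)
    return TetradSegregation(n_dup, n_eu, n_nc, is22)
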