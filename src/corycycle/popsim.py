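"""Steady-state, age-structured forward simulation of the cell cycle.

A steady-state exponential culture has the classic age distribution
phi(a) = (2 ln2 / td) * 2**(-a/td) on [0, td): newborns are twice as
frequent as dividers.  Every per-cell observable here is a deterministic
function of cell age given the cycle parameters, because initiation and
termination happen on a fixed schedule shared by all chromosome sets
(synchronous initiation, no cell-to-cell period variability).  Sampling
ages from phi and evaluating the schedule therefore reproduces every
closed-form population average in :mod:`corycycle.cycle_core`, which the
test suite exploits in both directions.

The per-age replication state is a small fork tree per chromosome set.
Within the supported regimes (round order <= 2, D < td) a set is, at any
age, one of: a complete chromosome; a chromosome replicated to fraction
p (holding 1+p genome equivalents); the same with a second, younger
round at fraction q running on both of its origins (1 + p + 2q); or two
complete chromosomes each carrying the younger round (2 * (1+q)).

Downstream observables derived from the state:

* replication-runout histograms — blocking new initiations lets ongoing
  rounds finish, so the final chromosome count equals the origin count
  at the time of the block;
* genome-coverage (marker-frequency) profiles — the population-average
  copy number of a locus at replichore fraction x is 2**(C(1-x)/td)
  relative to the terminus;
* microscopy focus counts — sister origins stay cohered (one focus) for
  a variable time after initiation, and sister termini may colocalize,
  so observed focus counts undershoot true copy numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cycle_core import (
    LN2,
    CellCycleParams,
    CycleModelError,
    cycle_timeline,
    mean_oris as _mean_oris_closed,
)

__all__ = [
    "ForkRound",
    "CellState",
    "PopulationSnapshot",
    "RunoutHistogram",
    "CoverageProfile",
    "CohesionModel",
    "age_pdf",
    "age_cdf",
    "mean_age",
    "sample_ages",
    "cell_state_at_age",
    "sample_population",
    "runout_histogram",
    "marker_frequency_profile",
    "relative_copy_number",
    "locus_copy_number",
    "observed_focus_counts",
]


# ---------------------------------------------------------------------------
# steady-state age distribution

def _check_age(a, td: float) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if td <= 0:
        raise CycleModelError(f"td must be positive, got {td}")
    if np.any(a < 0) or np.any(a > td):
        raise CycleModelError(f"age must lie in [0, td={td}]")
    return a


def age_pdf(a, td: float):
    """Steady-state age density phi(a) = (2 ln2 / td) * 2**(-a/td)."""
    a = _check_age(a, td)
    out = (2.0 * LN2 / td) * 2.0 ** (-a / td)
    return out if out.ndim else float(out)


def age_cdf(a, td: float):
    """Cumulative fraction of cells younger than age a: 2(1 - 2**(-a/td))."""
    a = _check_age(a, td)
    out = 2.0 * (1.0 - 2.0 ** (-a / td))
    return out if out.ndim else float(out)


def mean_age(td: float) -> float:
    """Mean cell age, td (1/ln2 - 1) ~= 0.4427 td."""
    return td * (1.0 / LN2 - 1.0)


def sample_ages(n: int, td: float, rng: np.random.Generator | int) -> np.ndarray:
    """Draw n ages by inverse-CDF sampling: a = -td * log2(1 - u/2)."""
    if n < 1:
        raise CycleModelError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    u = rng.random(n)
    return -td * np.log2(1.0 - u / 2.0)


# ---------------------------------------------------------------------------
# per-cell replication state

@dataclass(frozen=True)
class ForkRound:
    """An active replication round: replicated fraction and the number of
    origin pairs (whole-cell count) currently running it."""

    fraction: float
    multiplicity: int


@dataclass(frozen=True)
class CellState:
    """Replication state of one cell at a given age (whole-cell counts)."""

    age: float
    ori_count: int
    ter_count: int
    fork_rounds: tuple[ForkRound, ...]
    dna_content: float


def cell_state_at_age(a: float, params: CellCycleParams) -> CellState:
    """Evaluate the deterministic event schedule at cell age ``a``.

    All origins fire together at the initiation age; the round due in
    this generation terminates at age td - D.  Active rounds are listed
    oldest first; the j-th oldest round (0-based) contributes
    2**j * fraction genome equivalents per leaf chromosome.
    """
    td = params.td
    if a < 0 or a >= td:
        raise CycleModelError(f"age must lie in [0, td={td}), got {a}")
    tl = cycle_timeline(params)
    c = params.c
    a_i, a_t, n = tl.initiation_age, tl.termination_age, tl.n_rounds

    # elapsed replication time of the round initiated k generations back
    fractions: list[float] = []
    k = 0 if a >= a_i else 1
    while True:
        elapsed = a - a_i + k * td
        if elapsed >= c:
            break
        fractions.append(elapsed / c)
        k += 1
    fractions.sort(reverse=True)  # oldest (largest fraction) first

    leaves = 1 if a < a_t else 2          # complete chromosomes per set
    oris_per_set = 2 ** (n - 1) if a < a_i else 2 ** n
    dna_per_set = leaves * (1.0 + sum(2.0 ** j * p for j, p in enumerate(fractions)))

    p_ = params.ploidy
    rounds = tuple(
        ForkRound(fraction=p, multiplicity=p_ * leaves * 2 ** j)
        for j, p in enumerate(fractions)
    )
    return CellState(
        age=float(a),
        ori_count=p_ * oris_per_set,
        ter_count=p_ * leaves,
        fork_rounds=rounds,
        dna_content=p_ * dna_per_set,
    )


@dataclass
class PopulationSnapshot:
    """A sampled steady-state culture: params, seed and per-cell states."""

    params: CellCycleParams
    seed: int
    cells: list[CellState]

    @property
    def ages(self) -> np.ndarray:
        return np.array([c.age for c in self.cells])

    @property
    def ori_counts(self) -> np.ndarray:
        return np.array([c.ori_count for c in self.cells])

    @property
    def ter_counts(self) -> np.ndarray:
        return np.array([c.ter_count for c in self.cells])

    @property
    def dna_contents(self) -> np.ndarray:
        return np.array([c.dna_content for c in self.cells])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_min": self.ages,
                "ori_count": self.ori_counts,
                "ter_count": self.ter_counts,
                "dna_content": self.dna_contents,
                "n_fork_rounds": [len(c.fork_rounds) for c in self.cells],
            }
        )

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed} td={self.params.td} c={self.params.c} "
                     f"d={self.params.d} ploidy={self.params.ploidy}\n")
            df.to_csv(fh, sep="\t", index=False)


def sample_population(n: int, params: CellCycleParams, seed: int) -> PopulationSnapshot:
    """Sample ``n`` cells from the steady-state age distribution."""
    ages = sample_ages(n, params.td, np.random.default_rng(seed))
    cells = [cell_state_at_age(a, params) for a in ages]
    return PopulationSnapshot(params=params, seed=seed, cells=cells)


# ---------------------------------------------------------------------------
# replication runout

@dataclass(frozen=True)
class RunoutHistogram:
    """Distribution of fully replicated chromosomes after a runout.

    Blocking initiation lets every active round finish, so a cell ends
    with as many complete chromosomes as it had origins when the block
    was applied.  In the synchronous model the support has exactly two
    integers: cells younger than the initiation age still carry the
    pre-initiation origin count; older cells carry double.
    """

    counts: dict[int, float]
    mean: float

    def to_dataframe(self) -> pd.DataFrame:
        items = sorted(self.counts.items())
        return pd.DataFrame({"chromosomes": [k for k, _ in items],
                             "fraction": [v for _, v in items]})

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# mean_chromosomes={self.mean:.4f}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    def plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.to_dataframe()
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(df["chromosomes"], df["fraction"], width=0.6, color="0.3")
        ax.set_xlabel("chromosomes per cell")
        ax.set_ylabel("fraction of cells")
        ax.set_xticks(df["chromosomes"])
        ax.set_title(f"runout, mean = {self.mean:.2f}")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def runout_histogram(
    params: CellCycleParams,
    mode: Literal["analytic", "monte_carlo"] = "analytic",
    n: int = 100_000,
    seed: int = 0,
) -> RunoutHistogram:
    """Chromosome-number distribution after replication runout.

    Analytic mode puts the age-CDF mass below the initiation age on the
    lower origin count; Monte-Carlo mode tallies origin counts over a
    sampled snapshot and converges to the same histogram.
    """
    tl = cycle_timeline(params)
    low = params.ploidy * 2 ** (tl.n_rounds - 1)
    if mode == "analytic":
        f_low = age_cdf(tl.initiation_age, params.td)
        counts = {low: f_low, 2 * low: 1.0 - f_low}
        counts = {k: v for k, v in counts.items() if v > 0.0}
    elif mode == "monte_carlo":
        snap = sample_population(n, params, seed)
        vals, freq = np.unique(snap.ori_counts, return_counts=True)
        counts = {int(v): f / n for v, f in zip(vals, freq)}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mean = sum(k * v for k, v in counts.items())
    return RunoutHistogram(counts=counts, mean=mean)


# ---------------------------------------------------------------------------
# marker-frequency / coverage profile

def relative_copy_number(x, params: CellCycleParams):
    """Population-average copy number at replichore fraction x, relative
    to the terminus: 2**(C (1-x) / td).  x = 0 is oriC, x = 1 is terC."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise CycleModelError("replichore fraction must be in [0, 1]")
    out = 2.0 ** (params.c * (1.0 - x) / params.td)
    return out if out.ndim else float(out)


def locus_copy_number(x: float, state: CellState, ploidy: int) -> float:
    """Copies of the locus at replichore fraction x in one cell.

    A locus is duplicated by a round once its fork has passed it, i.e.
    once the round's replicated fraction exceeds x; each passage doubles
    the locus within its chromosome set.
    """
    if not 0.0 <= x <= 1.0:
        raise CycleModelError(f"replichore fraction must be in [0, 1], got {x}")
    per_pair = state.ter_count // ploidy  # leaves per set
    doublings = sum(1 for r in state.fork_rounds if r.fraction > x)
    return ploidy * per_pair * 2 ** doublings


@dataclass(frozen=True)
class CoverageProfile:
    """Relative copy number per genomic window on the circular map.

    Coordinates are 0-based bp with oriC at 0 and terC at L/2; the two
    replichores are mirror images.  Values are either relative to the
    terminus window or expressed as percent of the profile mean.
    """

    genome_length: float
    window_bp: int
    starts: np.ndarray
    values: np.ndarray
    normalization: Literal["terminus", "percent_of_mean"]

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + self.window_bp / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"midpoint_bp": self.midpoints, "value": self.values})

    def to_bedgraph(self, path, chrom: str = "chr") -> None:
        L = int(self.genome_length)
        with open(path, "w") as fh:
            for s, v in zip(self.starts, self.values):
                e = min(int(s) + self.window_bp, L)
                fh.write(f"{chrom}\t{int(s)}\t{e}\t{v:.6g}\n")

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _replichore_fraction(pos: np.ndarray, genome_length: float) -> np.ndarray:
    half = genome_length / 2.0
    dist = np.minimum(pos % genome_length, genome_length - pos % genome_length)
    return dist / half


def marker_frequency_profile(
    params: CellCycleParams,
    window_bp: int = 50_000,
    normalization: Literal["terminus", "percent_of_mean"] = "terminus",
    mode: Literal["analytic", "monte_carlo"] = "analytic",
    snapshot: Optional[PopulationSnapshot] = None,
) -> CoverageProfile:
    """Genome-wide relative copy-number profile (idealized coverage).

    The closed form for the population average at replichore fraction x
    is c(x)/c(ter) = 2**(C (1-x) / td): a symmetric V (peak at oriC,
    trough at terC) on the circular map.  Monte-Carlo mode averages
    per-cell locus copies over a snapshot instead and agrees with the
    closed form up to sampling error.
    """
    if window_bp < 1:
        raise CycleModelError(f"window must be >= 1 bp, got {window_bp}")
    L = params.genome_length
    starts = np.arange(0, L, window_bp, dtype=float)
    x = _replichore_fraction(starts + window_bp / 2.0, L)
    if mode == "analytic":
        values = 2.0 ** (params.c * (1.0 - x) / params.td)
    elif mode == "monte_carlo":
        if snapshot is None:
            raise ValueError("monte_carlo mode needs a snapshot")
        p = params.ploidy
        vals = np.zeros_like(x)
        for cell in snapshot.cells:
            per_pair = cell.ter_count // p
            base = p * per_pair
            v = np.full_like(x, float(base))
            for j, r in enumerate(sorted(cell.fork_rounds,
                                         key=lambda r: r.fraction, reverse=True)):
                v = np.where(r.fraction > x, base * 2.0 ** (j + 1), v)
            vals += v
        values = vals / len(snapshot.cells)
        ter_val = values[np.argmax(x)]
        values = values / ter_val
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if normalization == "percent_of_mean":
        values = 100.0 * values / values.mean()
    elif normalization != "terminus":
        raise ValueError(f"unknown normalization {normalization!r}")
    return CoverageProfile(
        genome_length=L,
        window_bp=window_bp,
        starts=starts,
        values=values,
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# focus-count observation model

@dataclass
class CohesionModel:
    """Sister-origin cohesion / sister-terminus colocalization model.

    Newly replicated sister origins stay together as a single focus for
    a variable cohesion time after initiation (measured mean 36 min,
    range 5-80 min under fast growth).  The default family is a gamma
    distribution truncated to [min, max] with its scale calibrated so
    the *truncated* mean equals ``mean``; "uniform" and "fixed" are
    degenerate alternatives.  Sister termini, which cluster at midcell,
    merge into one focus with probability ``ter_merge_prob``.
    """

    mean: float = 36.0
    minimum: float = 5.0
    maximum: float = 80.0
    family: Literal["gamma", "uniform", "fixed"] = "gamma"
    shape: float = 3.0
    ter_merge_prob: float = 0.5
    _gamma_scale: float = field(init=False, default=float("nan"), repr=False)

    def __post_init__(self) -> None:
        if self.minimum > self.maximum:
            raise ValueError("cohesion minimum exceeds maximum")
        if not self.minimum <= self.mean <= self.maximum:
            raise ValueError("cohesion mean must lie within [minimum, maximum]")
        if not 0.0 <= self.ter_merge_prob <= 1.0:
            raise ValueError("ter_merge_prob must be in [0, 1]")
        if self.family == "gamma" and self.maximum > self.minimum:
            self._gamma_scale = self._calibrate_gamma_scale()

    def _truncated_gamma_mean(self, scale: float) -> float:
        dist = stats.gamma(self.shape, scale=scale)
        lo, hi = dist.cdf(self.minimum), dist.cdf(self.maximum)
        if hi - lo < 1e-12:
            # essentially no mass inside the window: the truncated mean
            # collapses onto whichever bound the mass sits beyond
            return self.minimum if lo > 0.5 else self.maximum
        # E[X | lo<X<hi] via the gamma identity x f_k(x) = k theta f_{k+1}(x)
        dist1 = stats.gamma(self.shape + 1.0, scale=scale)
        return self.shape * scale * (dist1.cdf(self.maximum) - dist1.cdf(self.minimum)) / (hi - lo)

    def _calibrate_gamma_scale(self) -> float:
        target = self.mean

        def f(log_scale: float) -> float:
            return self._truncated_gamma_mean(math.exp(log_scale)) - target

        return math.exp(optimize.brentq(f, math.log(1e-3), math.log(1e4), xtol=1e-10))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n cohesion times (min), exactly truncated to [min, max]."""
        if self.family == "fixed":
            return np.full(n, self.mean)
        if self.family == "uniform":
            return rng.uniform(self.minimum, self.maximum, n)
        dist = stats.gamma(self.shape, scale=self._gamma_scale)
        lo, hi = dist.cdf(self.minimum), dist.cdf(self.maximum)
        return dist.ppf(lo + rng.random(n) * (hi - lo))


def observed_focus_counts(
    snapshot: PopulationSnapshot,
    cohesion: CohesionModel,
    channel: Literal["ori", "ter"] = "ori",
    seed: int = 0,
) -> np.ndarray:
    """Microscopy-style focus counts per cell, undershooting true copies.

    ori channel: each sister pair created at this generation's
    initiation draws a cohesion time; pairs younger than their cohesion
    time count as one focus.  Cells that have not yet initiated show
    their birth configuration.  ter channel: each sister pair created at
    this generation's termination merges with ``ter_merge_prob``.

    Cross-generation cohesion (a pair still merged at division) is not
    tracked; its effect at the measured time scales is small and it
    would break the even-segregation bookkeeping of the schedule.
    """
    if channel not in ("ori", "ter"):
        raise ValueError(f"unknown channel {channel!r}")
    rng = np.random.default_rng(seed)
    tl = cycle_timeline(snapshot.params)
    out = np.empty(len(snapshot.cells), dtype=int)
    for i, cell in enumerate(snapshot.cells):
        if channel == "ori":
            true = cell.ori_count
            if cell.age < tl.initiation_age:
                out[i] = true
                continue
            n_pairs = true // 2
            elapsed = cell.age - tl.initiation_age
            taus = cohesion.sample(n_pairs, rng)
            merged = int(np.sum(taus > elapsed))
            out[i] = true - merged
        else:
            true = cell.ter_count
            if cell.age < tl.termination_age:
                out[i] = true
                continue
            n_pairs = true // 2
            merged = int(np.sum(rng.random(n_pairs) < cohesion.ter_merge_prob))
            out[i] = true - merged
    return out
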