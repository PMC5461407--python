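"""Closed-form cell-cycle arithmetic for a diploid bacterium.

The classic bacterial cell cycle splits a generation of length ``td``
(doubling time) into a replication period C (time for a pair of forks to
copy one chromosome), a post-replication period D (termination to
division) and, under slow growth, a pre-replication B period.  In an
exponentially growing steady-state culture the average copy numbers of
the replication origin (oriC) and terminus (terC) follow from (C, D, td)
alone, which is what makes the periods measurable from bulk data.

*Corynebacterium glutamicum* adds a twist: newborn cells carry two
complete chromosomes whose origins fire synchronously, so every copy
number is doubled relative to the monoploid textbook model.  With
``ploidy`` sets of chromosomes per newborn cell:

    mean oriC per cell   I = ploidy * 2**((C + D) / td)
    mean terC per cell   T = ploidy * 2**(D / td)
    oriC/terC ratio        = 2**(C / td)

Inverting these gives the inference route used throughout this package:
the marker-frequency (qPCR) ratio yields C, and the mean origin count
per cell (replication runout flow cytometry) then yields D:

    C = ln(I/T) * td / ln 2
    D = ln(I/ploidy) * td / ln 2 - C

``ploidy=1`` recovers the standard monoploid Cooper–Helmstetter
relations, which serves as an independent oracle in the test suite.

All internal values are exact floats; the reporting layer rounds
periods to the nearest minute and fork speeds to the nearest 10 bases/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

LN2 = math.log(2.0)

#: Genome length (bp) of the C. glutamicum chromosome used as default.
DEFAULT_GENOME_LENGTH = 3_210_000

__all__ = [
    "CycleModelError",
    "GrowthCondition",
    "CellCycleParams",
    "CycleTimeline",
    "CycleReport",
    "doubling_time_from_rate",
    "c_period",
    "d_period",
    "mean_oris",
    "mean_ters",
    "predicted_ori_ter_ratio",
    "cycle_timeline",
    "fork_speed",
    "mean_dna_content",
    "build_report",
    "report_to_tsv",
    "round_minutes",
    "round_fork_speed",
]


class CycleModelError(ValueError):
    """A parameter combination outside the model's domain."""


def round_minutes(x: float) -> int:
    """Round a period to the nearest integer minute (half away from zero)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def round_fork_speed(v: float) -> int:
    """Round a fork speed to the nearest 10 bases/s."""
    return 10 * int(math.floor(v / 10.0 + 0.5))


@dataclass(frozen=True)
class GrowthCondition:
    """A labelled growth condition with its rate and/or doubling time.

    Either ``mu`` (growth rate, 1/h) or ``td`` (doubling time, min) may
    be given; the missing one is derived via td = 60 ln2 / mu.  When
    both are given they must agree to within one minute, the precision
    at which doubling times are tabulated.
    """

    label: str
    mu: Optional[float] = None
    td: Optional[float] = None

    def __post_init__(self) -> None:
        mu, td = self.mu, self.td
        if mu is None and td is None:
            raise CycleModelError("GrowthCondition needs mu or td")
        if mu is not None and mu <= 0:
            raise CycleModelError(f"growth rate must be positive, got {mu}")
        if td is not None and td <= 0:
            raise CycleModelError(f"doubling time must be positive, got {td}")
        if mu is None:
            object.__setattr__(self, "mu", 60.0 * LN2 / td)
        elif td is None:
            object.__setattr__(self, "td", doubling_time_from_rate(mu))
        elif abs(td - 60.0 * LN2 / mu) > 1.0:
            raise CycleModelError(
                f"inconsistent mu={mu}/h and td={td} min for {self.label!r}: "
                f"60*ln2/mu = {60.0 * LN2 / mu:.2f} min differs by more than 1 min"
            )


@dataclass(frozen=True)
class CellCycleParams:
    """Parameter vector of the cell-cycle model.

    td, c, d in minutes; ploidy is the number of complete chromosome
    sets per newborn cell (2 for C. glutamicum); genome_length in bp.
    """

    td: float
    c: float
    d: float
    ploidy: int = 2
    genome_length: float = DEFAULT_GENOME_LENGTH

    def __post_init__(self) -> None:
        for name in ("td", "c", "d", "genome_length"):
            v = getattr(self, name)
            if v <= 0:
                raise CycleModelError(f"{name} must be strictly positive, got {v}")
        if self.ploidy < 1 or int(self.ploidy) != self.ploidy:
            raise CycleModelError(f"ploidy must be an integer >= 1, got {self.ploidy}")
        if self.d >= self.td:
            raise CycleModelError(
                f"d={self.d} must be < td={self.td}: exactly one termination "
                "occurs per generation"
            )


def doubling_time_from_rate(mu: float) -> float:
    """Doubling time (min) from exponential growth rate (1/h)."""
    if mu <= 0:
        raise CycleModelError(f"growth rate must be positive, got {mu}")
    return 60.0 * LN2 / mu


def c_period(ori_ter_ratio: float, td: float) -> float:
    """C period (min) from the population oriC/terC ratio.

    C = ln(I/T) * td / ln2.  A ratio of 1 means instantaneous
    replication; a ratio of 2 means replication takes exactly one
    generation.  Ratios below 1 are impossible in this model.
    """
    if td <= 0:
        raise CycleModelError(f"td must be positive, got {td}")
    if ori_ter_ratio < 1.0:
        raise CycleModelError(
            f"oriC/terC ratio must be >= 1, got {ori_ter_ratio}: the model "
            "never has more termini than origins"
        )
    return math.log(ori_ter_ratio) * td / LN2


def d_period(mean_oris_per_cell: float, td: float, c: float, ploidy: int = 2) -> float:
    """D period (min) from mean origins per cell, td and C.

    D = ln(I / ploidy) * td / ln2 - C, the ploidy-adapted inversion of
    I = ploidy * 2**((C+D)/td).
    """
    if td <= 0 or c <= 0:
        raise CycleModelError("td and c must be positive")
    if mean_oris_per_cell < ploidy:
        raise CycleModelError(
            f"mean origins per cell ({mean_oris_per_cell}) cannot be below "
            f"ploidy ({ploidy})"
        )
    return math.log(mean_oris_per_cell / ploidy) * td / LN2 - c


def mean_oris(c: float, d: float, td: float, ploidy: int = 2) -> float:
    """Mean oriC copies per cell: ploidy * 2**((C+D)/td)."""
    if td <= 0:
        raise CycleModelError(f"td must be positive, got {td}")
    if c < 0 or d < 0:
        raise CycleModelError("c and d must be non-negative")
    return ploidy * 2.0 ** ((c + d) / td)


def mean_ters(d: float, td: float, ploidy: int = 2) -> float:
    """Mean terC copies per cell: ploidy * 2**(D/td)."""
    if td <= 0:
        raise CycleModelError(f"td must be positive, got {td}")
    if d < 0 or d >= td:
        raise CycleModelError(f"d must be in [0, td), got d={d}, td={td}")
    return ploidy * 2.0 ** (d / td)


def predicted_ori_ter_ratio(c: float, td: float) -> float:
    """Model-predicted oriC/terC ratio: 2**(C/td) (ploidy-independent)."""
    if td <= 0:
        raise CycleModelError(f"td must be positive, got {td}")
    if c < 0:
        raise CycleModelError(f"c must be non-negative, got {c}")
    return 2.0 ** (c / td)


@dataclass(frozen=True)
class CycleTimeline:
    """Event ages (min after division) within one generation.

    n_rounds is the replication-round order: the number of concurrent
    rounds running just after initiation, ceil((C+D)/td).  With
    overlap (C + D > td) a round started in one generation terminates
    in the next; initiation then precedes the previous round's
    termination by ``init_to_prev_term`` minutes and there is no B
    period.  Without overlap the B period equals the initiation age.
    """

    n_rounds: int
    overlap: bool
    initiation_age: float
    termination_age: float
    b_period: Optional[float] = None
    init_to_prev_term: Optional[float] = None


def cycle_timeline(params: CellCycleParams) -> CycleTimeline:
    """Deterministic event schedule for one generation.

    Initiation of all origins happens once per generation at age
    n*td - (C+D); the round that terminates in this generation does so
    at age td - D.  Round orders above 2 (C + D > 2 td) are outside
    the growth regimes this model is built for and are rejected.
    """
    td, c, d = params.td, params.c, params.d
    if c + d > 2.0 * td:
        raise CycleModelError(
            f"higher-order overlap: C+D = {c + d} min exceeds 2*td = {2 * td} min "
            "(replication-round order above 2 is not supported)"
        )
    n_rounds = math.ceil((c + d) / td)
    overlap = c + d > td
    initiation_age = n_rounds * td - (c + d)
    termination_age = td - d
    b = None if overlap else td - c - d
    gap = c - (n_rounds - 1) * td if overlap else None
    return CycleTimeline(
        n_rounds=n_rounds,
        overlap=overlap,
        initiation_age=initiation_age,
        termination_age=termination_age,
        b_period=b,
        init_to_prev_term=gap,
    )


def fork_speed(genome_length: float, c: float) -> float:
    """Replication speed per fork (bases/s).

    Replication is bidirectional: two forks leave oriC and each copies
    one replichore (half the chromosome) during the C period.
    """
    if genome_length <= 0 or c <= 0:
        raise CycleModelError("genome_length and c must be positive")
    return (genome_length / 2.0) / (c * 60.0)


def mean_dna_content(params: CellCycleParams) -> float:
    """Population-mean DNA content in genome equivalents per cell.

    Averaging the per-age fork tree over the steady-state age
    distribution gives, per chromosome set,
    (td / (C ln2)) * (2**((C+D)/td) - 2**(D/td)); the ploidy factor
    scales it to the whole cell.  As C -> 0 the limit is the mean
    terminus count (every chromosome complete at all times).
    """
    td, c, d, p = params.td, params.c, params.d, params.ploidy
    return p * (td / (c * LN2)) * (2.0 ** ((c + d) / td) - 2.0 ** (d / td))


def _mean_dna_c_limit(d: float, td: float, ploidy: int) -> float:
    # C -> 0 limit used when callers construct the degenerate case directly
    return ploidy * 2.0 ** (d / td)


@dataclass(frozen=True)
class CycleReport:
    """One row of the condition-by-condition cell-cycle summary.

    Measured quantities (ratio, mean origins) sit next to the inferred
    periods and the model's own predictions, mirroring how the analysis
    is tabulated: measured ratio -> C, measured mean origins -> D, then
    B, event ages and fork speed follow from (td, C, D).
    """

    condition: str
    mu_per_h: float
    td_min: float
    ratio: float
    mean_oris: float
    c_min: int
    d_min: int
    b_min: Optional[int]
    n_rounds: int
    init_age_min: float
    term_age_min: float
    fork_speed_bases_per_s: int
    predicted_ratio: float = field(default=float("nan"))
    predicted_mean_oris: float = field(default=float("nan"))


def build_report(
    condition: GrowthCondition,
    ori_ter_ratio: float,
    mean_oris_per_cell: float,
    ploidy: int = 2,
    genome_length: float = DEFAULT_GENOME_LENGTH,
) -> CycleReport:
    """Infer (C, D, B) from measured ratio and mean origins, then derive
    the timeline and fork speed.  Rounding: periods to the nearest
    minute, fork speed to the nearest 10 bases/s; the unrounded C is
    used for downstream quantities."""
    td = condition.td
    c = c_period(ori_ter_ratio, td)
    d = d_period(mean_oris_per_cell, td, c, ploidy)
    params = CellCycleParams(td=td, c=c, d=d, ploidy=ploidy, genome_length=genome_length)
    tl = cycle_timeline(params)
    return CycleReport(
        condition=condition.label,
        mu_per_h=condition.mu,
        td_min=td,
        ratio=ori_ter_ratio,
        mean_oris=mean_oris_per_cell,
        c_min=round_minutes(c),
        d_min=round_minutes(d),
        b_min=None if tl.overlap else round_minutes(tl.b_period),
        n_rounds=tl.n_rounds,
        init_age_min=tl.initiation_age,
        term_age_min=tl.termination_age,
        fork_speed_bases_per_s=round_fork_speed(fork_speed(genome_length, c)),
        predicted_ratio=predicted_ori_ter_ratio(c, td),
        predicted_mean_oris=mean_oris(c, d, td, ploidy),
    )


_REPORT_COLUMNS = (
    "condition",
    "mu_per_h",
    "td_min",
    "ratio",
    "mean_oris",
    "C_min",
    "D_min",
    "B_min",
    "n_rounds",
    "init_age_min",
    "term_age_min",
    "fork_speed_bases_per_s",
)


def report_to_tsv(reports: list[CycleReport]) -> str:
    """Serialize report rows to the canonical TSV layout."""
    lines = ["\t".join(_REPORT_COLUMNS)]
    for r in reports:
        lines.append(
            "\t".join(
                [
                    r.condition,
                    f"{r.mu_per_h:.2f}",
                    f"{r.td_min:g}",
                    f"{r.ratio:.2f}",
                    f"{r.mean_oris:.2f}",
                    str(r.c_min),
                    str(r.d_min),
                    "NA" if r.b_min is None else str(r.b_min),
                    str(r.n_rounds),
                    f"{r.init_age_min:g}",
                    f"{r.term_age_min:g}",
                    str(r.fork_speed_bases_per_s),
                ]
            )
        )
    return "\n".join(lines) + "\n"
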