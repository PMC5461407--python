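"""Marker-frequency analysis from qPCR threshold-cycle tables.

The copy-number ratio between an origin-proximal and a
terminus-proximal marker is read out with the 2**(-dCt) method: with
ideal doubling per cycle, a locus present at twice the copy number
crosses the detection threshold one cycle earlier, so

    ratio = 2**-(Ct_ori - Ct_ter)

Technical replicates are averaged (arithmetic mean of Ct) per
(sample, marker class) before the difference is taken.  A replication
runout sample — in which ongoing rounds were allowed to finish, so the
true ratio is 1 — serves as the reference: normalized ratios are
2**(dCt_ref - dCt_sample), which cancels marker-specific offsets
(amplicon efficiency, primer context) common to both samples.

Primer efficiencies are estimated from template dilution series: the
slope s of Ct against log10(template amount) gives E = 10**(-1/s), with
s = -1/log10(2) ~= -3.32 for perfect doubling.  Efficiencies are
reported as a quality check; ratios are not efficiency-corrected by
default (an explicit corrected mode is available).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cycle_core import (
    DEFAULT_GENOME_LENGTH,
    CycleReport,
    GrowthCondition,
    build_report,
)

__all__ = [
    "QPCRPlate",
    "DilutionSeries",
    "EfficiencyResult",
    "MarkerRatioResult",
    "read_plate",
    "primer_efficiency",
    "ori_ter_ratio",
    "ratios_to_cycle_report",
]

PLATE_COLUMNS = ["sample", "marker", "marker_class", "pair", "replicate", "ct"]


@dataclass
class QPCRPlate:
    """A set of qPCR wells plus the identity of the runout reference.

    ``wells`` holds one row per well with columns
    sample, marker, marker_class (ori|ter), pair, replicate, ct.
    """

    wells: pd.DataFrame
    reference_sample: Optional[str] = None

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"plate table missing columns: {missing}")
        if (self.wells["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        bad = set(self.wells["marker_class"]) - {"ori", "ter"}
        if bad:
            raise ValueError(f"unknown marker classes: {sorted(bad)}")
        if (
            self.reference_sample is not None
            and self.reference_sample not in set(self.wells["sample"])
        ):
            raise ValueError(
                f"reference sample {self.reference_sample!r} not on plate"
            )

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.wells["sample"]))

    @property
    def pairs(self) -> list[str]:
        return sorted(set(self.wells["pair"]))

    def to_csv(self, path) -> None:
        self.wells[PLATE_COLUMNS].to_csv(path, index=False)


def read_plate(path, reference_sample: Optional[str] = None) -> QPCRPlate:
    """Read a plate CSV (columns sample,marker,marker_class,pair,replicate,ct)."""
    return QPCRPlate(pd.read_csv(path), reference_sample=reference_sample)


@dataclass(frozen=True)
class DilutionSeries:
    """(log10 relative template amount, Ct) pairs for one primer pair."""

    log10_amount: np.ndarray
    ct: np.ndarray

    @classmethod
    def from_csv(cls, path) -> "DilutionSeries":
        df = pd.read_csv(path)
        return cls(df["log10_amount"].to_numpy(float), df["ct"].to_numpy(float))


@dataclass(frozen=True)
class EfficiencyResult:
    slope: float
    efficiency: float
    r_squared: float
    n: int


def primer_efficiency(series: DilutionSeries) -> EfficiencyResult:
    """Amplification efficiency from a dilution curve.

    Least-squares slope of Ct on log10(amount); E = 10**(-1/s).
    Requires at least three distinct dilution levels.
    """
    amounts = np.asarray(series.log10_amount, float)
    ct = np.asarray(series.ct, float)
    if len(np.unique(amounts)) < 3:
        raise ValueError("need >= 3 distinct dilution levels for an efficiency fit")
    fit = stats.linregress(amounts, ct)
    if fit.slope >= 0:
        raise ValueError(
            f"dilution-curve slope must be negative (got {fit.slope:.3g}): "
            "Ct decreases with template amount"
        )
    return EfficiencyResult(
        slope=fit.slope,
        efficiency=10.0 ** (-1.0 / fit.slope),
        r_squared=fit.rvalue**2,
        n=len(ct),
    )


@dataclass(frozen=True)
class MarkerRatioResult:
    """oriC/terC ratio for one (sample, marker pair)."""

    sample: str
    pair: str
    raw_ratio: float
    normalized_ratio: Optional[float]
    dispersion: float
    n: int


def _mean_cts(plate: QPCRPlate, sample: str, pair: str) -> tuple[float, float, int, np.ndarray, np.ndarray]:
    sel = plate.wells[(plate.wells["sample"] == sample) & (plate.wells["pair"] == pair)]
    ori = sel.loc[sel["marker_class"] == "ori", "ct"].to_numpy(float)
    ter = sel.loc[sel["marker_class"] == "ter", "ct"].to_numpy(float)
    if len(ori) == 0 or len(ter) == 0:
        raise ValueError(
            f"sample {sample!r}, pair {pair!r}: need at least one ori and one "
            "ter well"
        )
    return float(ori.mean()), float(ter.mean()), len(sel), ori, ter


def _delta_ct(plate: QPCRPlate, sample: str, pair: str) -> float:
    ori, ter, _, _, _ = _mean_cts(plate, sample, pair)
    return ori - ter


def ori_ter_ratio(
    plate: QPCRPlate,
    sample: str,
    pair: str,
    normalize: bool = True,
    dispersion: str = "pairings",
    n_boot: int = 200,
    seed: int = 0,
) -> MarkerRatioResult:
    """oriC/terC ratio via 2**(-dCt), optionally runout-normalized.

    dCt = mean(Ct_ori) - mean(Ct_ter) per (sample, pair); the raw ratio
    is 2**(-dCt) and the normalized ratio 2**(dCt_ref - dCt_sample)
    against the plate's runout reference.  Dispersion is the standard
    deviation of the ratio over all (ori replicate, ter replicate)
    pairings — exact for triplicates — or over bootstrap resamples.
    """
    mean_ori, mean_ter, n, ori, ter = _mean_cts(plate, sample, pair)
    dct = mean_ori - mean_ter
    raw = 2.0 ** (-dct)

    normalized: Optional[float] = None
    if normalize:
        if plate.reference_sample is None:
            raise ValueError("normalization requested but plate has no runout reference")
        dct_ref = _delta_ct(plate, plate.reference_sample, pair)
        normalized = 2.0 ** (dct_ref - dct)

    if dispersion == "pairings":
        combos = [2.0 ** (-(o - t)) for o, t in itertools.product(ori, ter)]
        disp = float(np.std(combos, ddof=1)) if len(combos) > 1 else 0.0
    elif dispersion == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            o = rng.choice(ori, size=len(ori), replace=True).mean()
            t = rng.choice(ter, size=len(ter), replace=True).mean()
            reps.append(2.0 ** (-(o - t)))
        disp = float(np.std(reps, ddof=1))
    else:
        raise ValueError(f"unknown dispersion mode {dispersion!r}")

    return MarkerRatioResult(
        sample=sample, pair=pair, raw_ratio=raw,
        normalized_ratio=normalized, dispersion=disp, n=n,
    )


def efficiency_corrected_ratio(
    plate: QPCRPlate,
    sample: str,
    pair: str,
    e_ori: float,
    e_ter: float,
) -> float:
    """Ratio with marker-specific efficiencies: E_ori**-Ct_ori / E_ter**-Ct_ter.

    Off by default in the standard analysis; provided for plates whose
    two markers amplify with measurably different efficiencies.
    """
    mean_ori, mean_ter, _, _, _ = _mean_cts(plate, sample, pair)
    return e_ori ** (-mean_ori) / e_ter ** (-mean_ter)


def ratios_to_cycle_report(
    ratios: Mapping[str, float],
    mean_oris_per_condition: Mapping[str, float],
    conditions: Sequence[GrowthCondition],
    ploidy: int = 2,
    genome_length: float = DEFAULT_GENOME_LENGTH,
) -> list[CycleReport]:
    """Turn measured (ratio, mean origins) per condition into report rows."""
    labels = {c.label for c in conditions}
    missing = (set(ratios) | set(mean_oris_per_condition)) - labels
    extra = labels - (set(ratios) & set(mean_oris_per_condition))
    if missing or extra:
        raise ValueError(
            f"condition labels do not match: unmatched measurements {sorted(missing)}, "
            f"conditions without both measurements {sorted(extra)}"
        )
    return [
        build_report(
            cond,
            ratios[cond.label],
            mean_oris_per_condition[cond.label],
            ploidy=ploidy,
            genome_length=genome_length,
        )
        for cond in conditions
    ]
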