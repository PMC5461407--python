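"""Replication-runout flow cytometry: gating, calibration, counting.

After a replication runout every chromosome is complete, so a cell's
total DNA fluorescence is an integer multiple of one chromosome's
worth.  Absolute DNA amounts are calibrated against an internal
standard: *B. subtilis* runout cells (mainly 4 or 8 complete
chromosomes, genome 4.22 Mb) carry a cell-wall label that separates
them from the sample on a second channel.  The analysis is:

1. gate  — split events into standard and sample by the label signal
   (threshold at the density minimum between the two highest modes);
2. calibrate — locate the standard's DNA-signal peaks and fit the
   fluorescence-per-Mb unit k so peaks sit at count * genome_Mb * k;
3. count — convert sample events to chromosome equivalents via
   dna_signal / (k * sample_genome_Mb) and assign integers.

Fluorescence is assumed linear in DNA mass, so the cross-species
conversion is purely by genome length.  Densities are smoothed on the
log-signal axis with a Silverman-style bandwidth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "FlowEventTable",
    "StandardSpec",
    "CalibrationResult",
    "read_events",
    "gate_standard",
    "calibrate",
    "count_chromosomes",
    "analyze_runout",
]

EVENT_COLUMNS = ["dna_signal", "label_signal"]


@dataclass
class FlowEventTable:
    """Event-level flow data: one row per event, two signal channels."""

    events: pd.DataFrame
    sample_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        if (self.events[EVENT_COLUMNS] < 0).to_numpy().any():
            raise ValueError("signals must be non-negative")

    def __len__(self) -> int:
        return len(self.events)

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)


def read_events(path, sample_label: str = "") -> FlowEventTable:
    """Read an event CSV (columns dna_signal,label_signal[,truth_*])."""
    return FlowEventTable(pd.read_csv(path), sample_label=sample_label)


@dataclass(frozen=True)
class StandardSpec:
    """Internal standard: its known chromosome counts and genome sizes."""

    counts: tuple[int, ...] = (4, 8)
    standard_genome_mb: float = 4.22
    sample_genome_mb: float = 3.21

    def __post_init__(self) -> None:
        if len(set(self.counts)) != len(self.counts) or any(c <= 0 for c in self.counts):
            raise ValueError("standard counts must be distinct positive integers")
        if self.standard_genome_mb <= 0 or self.sample_genome_mb <= 0:
            raise ValueError("genome lengths must be positive")


def _smoothed_log_density(
    values: np.ndarray, n_grid: int = 2048, bandwidth: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram-based density of log(values) under a Gaussian kernel.

    Bandwidth defaults to the Silverman rule on the log scale; the
    returned grid is in log units.
    """
    v = np.log(values[values > 0])
    if len(v) < 2:
        raise ValueError("need at least 2 positive events for a density estimate")
    if bandwidth is None:
        sd = np.std(v)
        iqr = np.subtract(*np.percentile(v, [75, 25]))
        scale = min(sd, iqr / 1.34) if iqr > 0 else sd
        bandwidth = 0.9 * scale * len(v) ** (-0.2)
    lo, hi = v.min(), v.max()
    span = hi - lo if hi > lo else 1.0
    # pad beyond the kernel reach so modes cannot sit on the grid edge
    pad = max(0.05 * span, 4.0 * bandwidth)
    lo -= pad
    hi += pad
    grid = np.linspace(lo, hi, n_grid)
    step = grid[1] - grid[0]
    hist, _ = np.histogram(v, bins=n_grid, range=(lo, hi))
    bandwidth = max(bandwidth, 2 * step)
    dens = ndimage.gaussian_filter1d(
        hist.astype(float), sigma=bandwidth / step, mode="constant"
    )
    return grid, dens / (dens.sum() * step)


def _density_modes(grid: np.ndarray, dens: np.ndarray, min_rel_height: float = 0.05):
    """Local maxima of a smoothed density, highest first."""
    peaks, props = signal.find_peaks(dens, height=min_rel_height * dens.max())
    order = np.argsort(props["peak_heights"])[::-1]
    return peaks[order]


def _refine_peak(grid: np.ndarray, dens: np.ndarray, idx: int) -> float:
    """Parabolic sub-bin refinement of a peak position."""
    if 0 < idx < len(grid) - 1:
        y0, y1, y2 = dens[idx - 1], dens[idx], dens[idx + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            return grid[idx] + 0.5 * (y0 - y2) / denom * (grid[1] - grid[0])
    return float(grid[idx])


def gate_standard(
    table: FlowEventTable,
    threshold: Optional[float] = None,
    bandwidth: Optional[float] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Split events into (standard, sample) by the label channel.

    With an explicit ``threshold``, events at or above it are standard.
    In auto mode the threshold is the minimum of the smoothed
    log-label density between its two highest modes; a unimodal label
    distribution is an error (pass a threshold explicitly).
    """
    lab = table.events["label_signal"].to_numpy(float)
    if threshold is None:
        grid, dens = _smoothed_log_density(lab, bandwidth=bandwidth)
        modes = _density_modes(grid, dens)
        if len(modes) < 2:
            raise ValueError(
                "label-signal density is unimodal; pass an explicit gate threshold"
            )
        a, b = sorted(modes[:2])
        valley = a + int(np.argmin(dens[a : b + 1]))
        threshold = float(np.exp(grid[valley]))
    mask = lab >= threshold
    return table.events[mask], table.events[~mask], float(threshold)


def calibrate(
    standard_events: pd.DataFrame,
    spec: StandardSpec,
    bandwidth: Optional[float] = None,
) -> float:
    """Fluorescence-per-Mb unit k from the standard's DNA-signal peaks.

    Peak positions are the modes of the smoothed log-density of the DNA
    signal (refined to sub-bin precision).  The |counts| highest modes,
    sorted ascending, are matched to the known chromosome counts and k
    is the least-squares fit of peak = count * genome_Mb * k.
    """
    sig = np.asarray(standard_events["dna_signal"], float)
    grid, dens = _smoothed_log_density(sig, bandwidth=bandwidth)
    modes = _density_modes(grid, dens)
    if len(modes) < len(spec.counts):
        raise ValueError(
            f"found {len(modes)} DNA-signal modes in the standard, expected "
            f">= {len(spec.counts)}"
        )
    top = sorted(modes[: len(spec.counts)])
    peaks = np.array([np.exp(_refine_peak(grid, dens, i)) for i in top])
    targets = np.array(sorted(spec.counts), float) * spec.standard_genome_mb
    k = float(peaks @ targets / (targets @ targets))
    if k <= 0:
        raise ValueError("calibration produced non-positive k")
    return k


@dataclass
class CalibrationResult:
    """Chromosome-count assignment for the sample population."""

    k: float
    gate_threshold: Optional[float]
    assignments: np.ndarray
    fractions: dict[int, float]
    mean: float
    n_assigned: int
    n_excluded: int


def count_chromosomes(
    sample_events: pd.DataFrame,
    k: float,
    genome_mb: float,
    method: Literal["nearest", "mixture"] = "nearest",
    debris_threshold: float = 0.5,
    max_debris_fraction: float = 0.05,
    gate_threshold: Optional[float] = None,
) -> CalibrationResult:
    """Assign integer chromosome counts to sample events.

    Per-event chromosome equivalents are dna_signal / (k * genome_Mb).
    Events below ``debris_threshold`` equivalents are excluded as
    debris (warned about beyond ``max_debris_fraction``).  The default
    assignment is the nearest integer; the mixture method fits a
    constrained 1-D Gaussian mixture with means at integer multiples
    and a shared coefficient of variation, for overlapping peaks.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    est = np.asarray(sample_events["dna_signal"], float) / (k * genome_mb)
    debris = est < debris_threshold
    frac_debris = debris.mean() if len(est) else 0.0
    if frac_debris > max_debris_fraction:
        warnings.warn(
            f"{frac_debris:.1%} of events fall below {debris_threshold} chromosome "
            "equivalents and were excluded as debris",
            stacklevel=2,
        )
    est = est[~debris]
    if len(est) == 0:
        raise ValueError("no events above the debris threshold")

    if method == "nearest":
        assign = np.maximum(np.rint(est).astype(int), 1)
        vals, freq = np.unique(assign, return_counts=True)
        fractions = {int(v): f / len(assign) for v, f in zip(vals, freq)}
        mean = float(assign.mean())
    elif method == "mixture":
        # component weights, not assignment tallies: with overlapping
        # peaks the hard-assignment histogram is biased but the EM
        # weights are not
        assign, weights = _mixture_fit(est)
        fractions = {c: w for c, w in weights.items() if w > 1e-4}
        mean = float(sum(c * w for c, w in weights.items()))
    else:
        raise ValueError(f"unknown assignment method {method!r}")

    return CalibrationResult(
        k=k,
        gate_threshold=gate_threshold,
        assignments=assign,
        fractions=fractions,
        mean=mean,
        n_assigned=len(assign),
        n_excluded=int(debris.sum()),
    )


def _mixture_fit(est: np.ndarray, max_count: Optional[int] = None, n_iter: int = 100):
    """EM for a mixture with means fixed at integers and shared CV."""
    if max_count is None:
        max_count = max(1, int(np.ceil(est.max())))
    comps = np.arange(1, max_count + 1)
    w = np.full(len(comps), 1.0 / len(comps))
    cv = 0.1
    x = est[:, None]
    for _ in range(n_iter):
        sd = np.maximum(cv * comps, 1e-6)
        logp = (
            -0.5 * ((x - comps) / sd) ** 2
            - np.log(sd)
            + np.log(np.maximum(w, 1e-300))
        )
        logp -= logp.max(axis=1, keepdims=True)
        resp = np.exp(logp)
        resp /= resp.sum(axis=1, keepdims=True)
        w = resp.mean(axis=0)
        cv = float(
            np.sqrt(np.sum(resp * ((x - comps) / comps) ** 2) / len(est))
        )
        cv = min(max(cv, 1e-3), 0.5)
    weights = {int(c): float(wi) for c, wi in zip(comps, w)}
    return comps[np.argmax(resp, axis=1)], weights


def analyze_runout(
    table: FlowEventTable,
    spec: StandardSpec = StandardSpec(),
    threshold: Optional[float] = None,
    method: Literal["nearest", "mixture"] = "nearest",
    min_events: int = 10_000,
) -> CalibrationResult:
    """Full pipeline: gate -> calibrate -> count, on one event table."""
    if len(table) < min_events:
        raise ValueError(
            f"{len(table)} events; at least {min_events} required "
            "(lower min_events to override)"
        )
    standard, sample, thr = gate_standard(table, threshold=threshold)
    k = calibrate(standard, spec)
    return count_chromosomes(
        sample, k, spec.sample_genome_mb, method=method, gate_threshold=thr
    )
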