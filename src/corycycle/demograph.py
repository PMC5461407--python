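"""Downstream analytics on tabular per-cell microscopy data.

Input is one record per cell: length, per-channel focus positions
(relative coordinates in [0, 1] along the long axis) and/or binned
fluorescence profiles, and the polar intensities of an old-pole marker
(DivIVA accumulates at the older pole).  From these the module builds
demographs (per-cell profiles stacked in order of increasing length —
the standard visualization of localization through the cell cycle),
counts fluorescent foci, and regresses focus count on cell length.

Cells can be oriented so the old pole sits at coordinate 0, which
makes pole-asymmetric patterns visible in the stacked image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "CellProfileRecord",
    "Demograph",
    "RegressionResult",
    "orient_by_pole",
    "build_demograph",
    "count_foci",
    "focus_length_regression",
    "records_to_csv",
    "records_from_csv",
]


@dataclass(frozen=True)
class CellProfileRecord:
    """One segmented cell: length, per-channel foci/profiles, pole marks.

    ``foci`` maps channel name to relative focus coordinates in [0, 1];
    ``profiles`` maps channel name to a binned intensity profile along
    the long axis.  ``pole_a`` is the marker intensity at coordinate 0,
    ``pole_b`` at coordinate 1.  ``orientation`` records whether the
    record has been oriented old-pole-first ("oriented"), left as is
    ("unoriented") or hit the equal-intensity tie rule ("tie").
    """

    cell_id: str
    length_um: float
    foci: dict[str, np.ndarray] = field(default_factory=dict)
    profiles: dict[str, np.ndarray] = field(default_factory=dict)
    pole_a: Optional[float] = None
    pole_b: Optional[float] = None
    orientation: str = "unoriented"
    truth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError(f"cell length must be positive, got {self.length_um}")
        for ch, pos in self.foci.items():
            pos = np.asarray(pos, float)
            if len(pos) and (pos.min() < 0 or pos.max() > 1):
                raise ValueError(f"focus positions for {ch!r} outside [0, 1]")
            object.__setattr__(self, "foci", {**self.foci, ch: pos})
        for ch, prof in self.profiles.items():
            prof = np.asarray(prof, float)
            if len(prof) and prof.min() < 0:
                raise ValueError(f"profile for {ch!r} has negative intensities")
            object.__setattr__(self, "profiles", {**self.profiles, ch: prof})


def orient_by_pole(record: CellProfileRecord) -> CellProfileRecord:
    """Flip a record so the brighter (old) pole sits at coordinate 0.

    Records without both polar intensities pass through unchanged with
    orientation "unoriented"; exact ties are not flipped and flagged
    "tie".
    """
    if record.pole_a is None or record.pole_b is None:
        return replace(record, orientation="unoriented")
    if record.pole_a == record.pole_b:
        return replace(record, orientation="tie")
    if record.pole_a > record.pole_b:
        return replace(record, orientation="oriented")
    return replace(
        record,
        foci={ch: 1.0 - pos[::-1] for ch, pos in record.foci.items()},
        profiles={ch: prof[::-1] for ch, prof in record.profiles.items()},
        pole_a=record.pole_b,
        pole_b=record.pole_a,
        orientation="oriented",
    )


@dataclass(frozen=True)
class Demograph:
    """Length-sorted stack of normalized per-cell profiles."""

    matrix: np.ndarray
    lengths: np.ndarray
    cell_ids: tuple[str, ...]
    bins: int
    channel: str
    normalization: str
    orientation: str

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix, index=self.cell_ids)
        df.insert(0, "length_um", self.lengths)
        df.to_csv(path, sep="\t", index_label="cell_id")

    def plot(self, path, cmap: str = "viridis") -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 5))
        ax.imshow(self.matrix, aspect="auto", cmap=cmap, origin="lower",
                  extent=(0, 1, 0, len(self.lengths)))
        ax.set_xlabel("relative cell coordinate")
        ax.set_ylabel("cells (sorted by length)")
        ax.set_title(self.channel)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _render_foci(positions: np.ndarray, bins: int, kernel_bins: float = 2.0) -> np.ndarray:
    """Drop a triangular kernel (full width ``kernel_bins`` bins) at each
    focus position and bin to a profile — a simple point-spread stand-in."""
    prof = np.zeros(bins)
    centers = (np.arange(bins) + 0.5) / bins
    half_width = kernel_bins / (2.0 * bins)
    for p in positions:
        w = np.maximum(0.0, 1.0 - np.abs(centers - p) / half_width)
        prof += w
    return prof


def build_demograph(
    records: Sequence[CellProfileRecord],
    bins: int = 50,
    channel: str = "ori",
    normalization: Literal["max", "sum"] = "max",
    orient: bool = True,
    kernel_bins: float = 2.0,
) -> Demograph:
    """Stack per-cell profiles sorted by ascending cell length.

    Profile inputs are resampled to ``bins``; focus-position inputs are
    rendered with a fixed-width triangular kernel first.  Rows are
    normalized per cell (max = 1 or sum = 1) so the image reflects
    localization, not expression level.
    """
    if not records:
        raise ValueError("no records given")
    if orient:
        records = [orient_by_pole(r) for r in records]
    rows, lengths, ids = [], [], []
    for r in records:
        if channel in r.profiles and len(r.profiles[channel]):
            prof = np.asarray(r.profiles[channel], float)
            if len(prof) != bins:
                x_old = (np.arange(len(prof)) + 0.5) / len(prof)
                x_new = (np.arange(bins) + 0.5) / bins
                prof = np.interp(x_new, x_old, prof)
        elif channel in r.foci:
            prof = _render_foci(r.foci[channel], bins, kernel_bins)
        else:
            raise ValueError(f"record {r.cell_id!r} has no channel {channel!r}")
        if normalization == "max":
            m = prof.max()
            prof = prof / m if m > 0 else prof
        elif normalization == "sum":
            s = prof.sum()
            prof = prof / s if s > 0 else prof
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        rows.append(prof)
        lengths.append(r.length_um)
        ids.append(r.cell_id)
    order = np.argsort(lengths, kind="stable")
    return Demograph(
        matrix=np.asarray(rows)[order],
        lengths=np.asarray(lengths)[order],
        cell_ids=tuple(np.asarray(ids, dtype=object)[order]),
        bins=bins,
        channel=channel,
        normalization=normalization,
        orientation="oriented" if orient else "unoriented",
    )


def count_foci(
    record: CellProfileRecord,
    channel: str,
    min_separation: float = 0.1,
    rel_threshold: float = 0.3,
) -> int:
    """Number of distinct foci in one channel of one cell.

    Focus-position input: positions closer than ``min_separation``
    (relative units) chain into one focus.  Profile input: local maxima
    above ``rel_threshold`` of the profile maximum, at least
    ``min_separation`` apart.
    """
    if channel in record.foci:
        pos = np.sort(np.asarray(record.foci[channel], float))
        if len(pos) == 0:
            return 0
        gaps = np.diff(pos)
        return 1 + int(np.sum(gaps >= min_separation))
    if channel in record.profiles:
        prof = np.asarray(record.profiles[channel], float)
        if prof.max() <= 0:
            return 0
        distance = max(1, int(round(min_separation * len(prof))))
        peaks, _ = signal.find_peaks(
            prof, height=rel_threshold * prof.max(), distance=distance
        )
        return len(peaks)
    raise ValueError(f"record {record.cell_id!r} has no channel {channel!r}")


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of focus count on cell length."""

    slope: float
    intercept: float
    r: float
    n: int


def focus_length_regression(
    records: Sequence[CellProfileRecord],
    channel: str,
    min_separation: float = 0.1,
) -> RegressionResult:
    """Ordinary least squares of per-cell focus count on cell length."""
    if len(records) < 3:
        raise ValueError("need >= 3 records for a regression")
    lengths = np.array([r.length_um for r in records])
    counts = np.array(
        [count_foci(r, channel, min_separation=min_separation) for r in records],
        float,
    )
    if np.ptp(lengths) == 0:
        raise ValueError("zero variance in cell lengths")
    fit = stats.linregress(lengths, counts)
    return RegressionResult(
        slope=fit.slope, intercept=fit.intercept, r=fit.rvalue, n=len(records)
    )


# ---------------------------------------------------------------------------
# CSV round trip (long format: one row per cell and channel)

_CSV_COLUMNS = [
    "cell_id",
    "length_um",
    "channel",
    "focus_positions",
    "profile",
    "pole_a",
    "pole_b",
]


def _semicolon(arr: Optional[np.ndarray]) -> str:
    if arr is None or len(arr) == 0:
        return ""
    return ";".join(f"{v:.6g}" for v in arr)


def records_to_csv(records: Sequence[CellProfileRecord], path) -> None:
    rows = []
    truth_keys = sorted({k for r in records for k in r.truth})
    for r in records:
        channels = sorted(set(r.foci) | set(r.profiles))
        for ch in channels:
            row = {
                "cell_id": r.cell_id,
                "length_um": r.length_um,
                "channel": ch,
                "focus_positions": _semicolon(r.foci.get(ch)),
                "profile": _semicolon(r.profiles.get(ch)),
                "pole_a": "" if r.pole_a is None else f"{r.pole_a:.6g}",
                "pole_b": "" if r.pole_b is None else f"{r.pole_b:.6g}",
            }
            for k in truth_keys:
                row[f"truth_{k}"] = r.truth.get(k, "")
            rows.append(row)
    cols = _CSV_COLUMNS + [f"truth_{k}" for k in truth_keys]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _parse_list(cell) -> Optional[np.ndarray]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return None
    return np.array([float(v) for v in str(cell).split(";")])


def records_from_csv(path) -> list[CellProfileRecord]:
    df = pd.read_csv(path)
    records = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        first = grp.iloc[0]
        foci, profiles = {}, {}
        for _, row in grp.iterrows():
            pos = _parse_list(row.get("focus_positions"))
            prof = _parse_list(row.get("profile"))
            if pos is not None:
                foci[row["channel"]] = pos
            if prof is not None:
                profiles[row["channel"]] = prof
            if pos is None and prof is None:
                foci[row["channel"]] = np.array([])
        pa = first.get("pole_a")
        pb = first.get("pole_b")
        truth = {
            c[len("truth_"):]: float(first[c])
            for c in df.columns
            if c.startswith("truth_") and not pd.isna(first[c])
        }
        records.append(
            CellProfileRecord(
                cell_id=str(cell_id),
                length_um=float(first["length_um"]),
                foci=foci,
                profiles=profiles,
                pole_a=None if pd.isna(pa) else float(pa),
                pole_b=None if pd.isna(pb) else float(pb),
                truth=truth,
            )
        )
    return records
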