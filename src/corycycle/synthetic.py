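"""Synthetic inputs for every stage of the pipeline.

The generator emulates the three measured data kinds — per-cell
microscopy records, qPCR Ct tables and runout flow-cytometry events —
under the study conditions: doubling times 63/83/130 min with
(C, D) = (78, 20)/(96, 18)/(97, 26) min, two chromosome sets per
newborn cell, newborn length 2.01 um growing to 3.94 um at division,
sister-origin cohesion averaging 36 min within 5-80 min, and a
B. subtilis-like internal standard carrying 4 or 8 chromosomes.

Each output carries truth columns so every downstream estimator can be
scored against the generating values, and every generator is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .cycle_core import CellCycleParams, cycle_timeline, predicted_ori_ter_ratio
from .demograph import CellProfileRecord
from .flow import FlowEventTable, StandardSpec
from .popsim import (
    CohesionModel,
    cell_state_at_age,
    observed_focus_counts,
    runout_histogram,
    sample_ages,
    sample_population,
)
from .qpcr import QPCRPlate, PLATE_COLUMNS

__all__ = [
    "GeneratorConfig",
    "condition_presets",
    "make_cell_table",
    "make_ct_table",
    "make_flow_events",
]

#: qPCR marker pairs used as plain labels (origin-/terminus-proximal loci).
MARKER_PAIRS = {
    "cg0002/cg1702": ("cg0002", "cg1702"),
    "cg0018/cg2361": ("cg0018", "cg2361"),
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-data generator for one growth condition."""

    label: str
    params: CellCycleParams
    mu_per_h: Optional[float] = None
    # morphology
    newborn_length_um: float = 2.01
    newborn_length_sd: float = 0.20
    division_length_um: float = 3.94
    division_length_sd: float = 0.40
    elongation: Literal["exponential", "linear"] = "exponential"
    focus_jitter_sd: float = 0.02
    pole_anchor: float = 0.05
    # pole marker (old:new intensity contrast, lognormal noise)
    pole_contrast: float = 2.0
    pole_noise_sd: float = 0.3
    # observation model
    cohesion: CohesionModel = field(default_factory=CohesionModel)
    # qPCR
    ct_baseline: float = 20.0
    ct_noise_sd: float = 0.1
    ct_replicates: int = 3
    # flow cytometry
    flow_cv: float = 0.06
    flow_events: int = 50_000
    flow_k: float = 10.0
    standard: StandardSpec = field(default_factory=StandardSpec)
    standard_fraction: float = 0.25
    debris_fraction: float = 0.02
    label_signal_sample: float = 10.0
    label_signal_standard: float = 1000.0
    label_noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("newborn_length_sd", "division_length_sd", "ct_noise_sd",
                     "flow_cv", "pole_noise_sd", "label_noise_sd", "focus_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.flow_events < 1 or self.ct_replicates < 1:
            raise ValueError("event and replicate counts must be >= 1")
        if not 0.0 <= self.standard_fraction < 1.0:
            raise ValueError("standard_fraction must be in [0, 1)")
        if not 0.0 <= self.debris_fraction < 1.0:
            raise ValueError("debris_fraction must be in [0, 1)")


def condition_presets(seed: int = 0) -> dict[str, GeneratorConfig]:
    """The three study growth conditions with their cycle parameters."""
    rows = {
        "BHI": (0.66, 63.0, 78.0, 20.0),
        "BHI+Gluc": (0.50, 83.0, 96.0, 18.0),
        "MMI": (0.32, 130.0, 97.0, 26.0),
    }
    out = {}
    for label, (mu, td, c, d) in rows.items():
        out[label] = GeneratorConfig(
            label=label,
            params=CellCycleParams(td=td, c=c, d=d, ploidy=2),
            mu_per_h=mu,
            seed=seed,
        )
    return out


# ---------------------------------------------------------------------------
# per-cell microscopy records

def _cell_length(config: GeneratorConfig, age: np.ndarray,
                 l0: np.ndarray, ld: np.ndarray) -> np.ndarray:
    frac = age / config.params.td
    if config.elongation == "exponential":
        return l0 * (ld / l0) ** frac
    if config.elongation == "linear":
        return l0 + (ld - l0) * frac
    raise ValueError(f"unknown elongation model {config.elongation!r}")


def make_cell_table(
    config: GeneratorConfig, n: int, seed: Optional[int] = None
) -> list[CellProfileRecord]:
    """Generate per-cell records with ori/ter foci and pole markers.

    Ages come from the steady-state distribution; lengths interpolate
    from the newborn to the division length.  Two origin foci anchor
    near the poles; sister origins released from cohesion appear as
    extra foci that move linearly from their pole toward midcell over
    the remainder of the cycle.  Terminus foci sit near midcell.  The
    old pole carries the brighter polar marker, and whole records are
    randomly reflected to emulate arbitrary imaging orientation.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    params = config.params
    tl = cycle_timeline(params)
    ages = sample_ages(n, params.td, rng)
    snap_cells = [cell_state_at_age(a, params) for a in ages]

    l0 = np.maximum(rng.normal(config.newborn_length_um, config.newborn_length_sd, n), 0.5)
    ld = np.maximum(rng.normal(config.division_length_um, config.division_length_sd, n),
                    l0 + 0.1)
    lengths = _cell_length(config, ages, l0, ld)

    records: list[CellProfileRecord] = []
    for i, (a, cell) in enumerate(zip(ages, snap_cells)):
        jit = lambda m: float(np.clip(m + rng.normal(0.0, config.focus_jitter_sd), 0.0, 1.0))
        anchor_lo, anchor_hi = config.pole_anchor, 1.0 - config.pole_anchor
        ori_pos = [jit(anchor_lo), jit(anchor_hi)]

        # sister origins released from cohesion migrate pole -> midcell
        extra = 0
        if a >= tl.initiation_age:
            n_pairs = cell.ori_count // 2
            taus = config.cohesion.sample(n_pairs, rng)
            elapsed = a - tl.initiation_age
            extra = int(np.sum(taus <= elapsed))
        # released sisters migrate to positions flanking the future septum
        # (third, fourth, fifth focus between pole and midcell)
        septal_targets = (0.42, 0.58, 0.30, 0.70)
        for j in range(extra):
            source = anchor_lo if j % 2 == 0 else anchor_hi
            target = septal_targets[j % len(septal_targets)]
            progress = (
                (a - tl.initiation_age) / (params.td - tl.initiation_age)
                if params.td > tl.initiation_age
                else 1.0
            )
            ori_pos.append(jit(source + (target - source) * progress))

        ter_pos = [
            jit(0.5 + rng.normal(0.0, 0.05))
            for _ in range(_observed_ter(cell, tl, config.cohesion, rng))
        ]

        old_pole = config.pole_contrast * float(
            rng.lognormal(mean=0.0, sigma=config.pole_noise_sd)
        )
        new_pole = float(rng.lognormal(mean=0.0, sigma=config.pole_noise_sd))

        foci = {"ori": np.sort(ori_pos), "ter": np.sort(ter_pos)}
        pole_a, pole_b = old_pole, new_pole
        if rng.random() < 0.5:  # random imaging orientation
            foci = {ch: np.sort(1.0 - p) for ch, p in foci.items()}
            pole_a, pole_b = new_pole, old_pole

        records.append(
            CellProfileRecord(
                cell_id=f"{config.label}_{i:05d}",
                length_um=float(lengths[i]),
                foci=foci,
                pole_a=pole_a,
                pole_b=pole_b,
                truth={
                    "age_min": float(a),
                    "ori_count": float(cell.ori_count),
                    "ter_count": float(cell.ter_count),
                    "old_pole_is_a": float(pole_a == old_pole),
                },
            )
        )
    return records


def _observed_ter(cell, tl, cohesion: CohesionModel, rng: np.random.Generator) -> int:
    if cell.age < tl.termination_age:
        return cell.ter_count
    merged = int(np.sum(rng.random(cell.ter_count // 2) < cohesion.ter_merge_prob))
    return cell.ter_count - merged


# ---------------------------------------------------------------------------
# qPCR Ct tables

def make_ct_table(
    config: GeneratorConfig,
    true_ratios: Optional[dict[str, float]] = None,
    seed: Optional[int] = None,
    reference_label: str = "runout",
) -> QPCRPlate:
    """Generate a Ct plate with a runout reference sample.

    For each sample and marker pair, Ct_ter = baseline + noise and
    Ct_ori = Ct_ter_baseline - log2(true ratio) + noise, in technical
    replicates.  The reference sample has true ratio 1 by construction.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if true_ratios is None:
        true_ratios = {
            config.label: predicted_ori_ter_ratio(config.params.c, config.params.td)
        }
    if any(r < 1.0 for r in true_ratios.values()):
        raise ValueError("true ratios must be >= 1")
    rows = []
    all_samples = dict(true_ratios)
    all_samples[reference_label] = 1.0
    for sample, ratio in all_samples.items():
        for pair, (ori_marker, ter_marker) in MARKER_PAIRS.items():
            for rep in range(1, config.ct_replicates + 1):
                ct_ter = config.ct_baseline + rng.normal(0.0, config.ct_noise_sd)
                ct_ori = (
                    config.ct_baseline
                    - np.log2(ratio)
                    + rng.normal(0.0, config.ct_noise_sd)
                )
                rows.append((sample, ori_marker, "ori", pair, rep, ct_ori))
                rows.append((sample, ter_marker, "ter", pair, rep, ct_ter))
    wells = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    return QPCRPlate(wells, reference_sample=reference_label)


# ---------------------------------------------------------------------------
# flow-cytometry event tables

def make_flow_events(
    config: GeneratorConfig, seed: Optional[int] = None
) -> FlowEventTable:
    """Generate a runout event table with internal standard and debris.

    Sample chromosome counts follow the analytic runout histogram of
    the condition's parameters; standard counts are 4 or 8 with equal
    weight.  DNA signal is count * genome_Mb * k with multiplicative
    Gaussian noise of the configured CV; the label channel separates
    standard from sample.  Truth columns tag source and count.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = config.flow_events
    n_std = int(round(n * config.standard_fraction))
    n_debris = int(round(n * config.debris_fraction))
    n_sample = n - n_std - n_debris

    hist = runout_histogram(config.params, mode="analytic")
    counts = np.array(sorted(hist.counts))
    probs = np.array([hist.counts[c] for c in counts])
    sample_counts = rng.choice(counts, size=n_sample, p=probs)
    std_counts = rng.choice(np.array(config.standard.counts), size=n_std)

    k = config.flow_k
    noise = lambda m: 1.0 + rng.normal(0.0, config.flow_cv, m)
    sample_dna = sample_counts * config.standard.sample_genome_mb * k * noise(n_sample)
    std_dna = std_counts * config.standard.standard_genome_mb * k * noise(n_std)
    debris_dna = rng.uniform(
        0.0, 0.4 * config.standard.sample_genome_mb * k, n_debris
    )

    lab = lambda mu, m: mu * np.exp(rng.normal(0.0, config.label_noise_sd, m))
    frames = [
        pd.DataFrame(
            {
                "dna_signal": np.abs(sample_dna),
                "label_signal": lab(config.label_signal_sample, n_sample),
                "truth_source": "sample",
                "truth_count": sample_counts,
            }
        ),
        pd.DataFrame(
            {
                "dna_signal": np.abs(std_dna),
                "label_signal": lab(config.label_signal_standard, n_std),
                "truth_source": "standard",
                "truth_count": std_counts,
            }
        ),
    ]
    if n_debris:
        frames.append(
            pd.DataFrame(
                {
                    "dna_signal": debris_dna,
                    "label_signal": lab(config.label_signal_sample, n_debris),
                    "truth_source": "debris",
                    "truth_count": 0,
                }
            )
        )
    events = pd.concat(frames, ignore_index=True)
    events = events.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )
    return FlowEventTable(events, sample_label=config.label)
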