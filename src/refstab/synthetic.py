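"""Seedable synthetic Ct data with known ground truth.

The generator emulates a plant abiotic-stress RT-qPCR study: a panel of
candidate reference genes plus mogroside-pathway target genes, measured over
five treatments (two hormone elicitors, salicylic acid, heat, cold), a 0-48 h
time course and three biological replicates.  Each gene has a designed role —
stable, group-biased, time-drifting, noisy, or target with a designed
log2 fold-change trajectory — and each sample carries a common "loading"
offset emulating cDNA input variation, the very nuisance normalization is
meant to remove.  Ct values are

    Ct = baseline + designed shift + sample loading + N(0, noise_sd).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import DilutionSeries
from .ct_data import CtTable, SampleKey, _sample_index

__all__ = [
    "GeneModel",
    "DesignSpec",
    "TruthTable",
    "generate",
    "paper_like_fixture",
    "candidate_panel",
    "target_panel",
    "dilution_series",
    "HORMONE_TIMEPOINTS",
    "TEMPERATURE_TIMEPOINTS",
]

ROLES = ("stable", "group_biased", "time_drifting", "noisy", "target")

HORMONE_TIMEPOINTS: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0, 24.0, 48.0)
TEMPERATURE_TIMEPOINTS: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0)

HORMONE_TREATMENTS = ("MeJA", "EtH", "SA")
TEMPERATURE_TREATMENTS = ("HighTem", "LowTem")


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """Designed behavior of one gene.

    ``shifts`` maps (treatment, timepoint) to a Ct shift in cycles; for
    targets the shift encodes the designed expression trajectory
    (shift = -log2 fold change, since one PCR cycle is one doubling).
    """

    name: str
    baseline: float
    role: str = "stable"
    shifts: Mapping[tuple[str, float], float] = field(default_factory=dict)
    noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SyntheticError(f"{self.name}: unknown role {self.role!r}")
        if self.noise_sd < 0:
            raise SyntheticError(f"{self.name}: negative noise SD")
        if self.role == "stable" and any(v != 0 for v in self.shifts.values()):
            raise SyntheticError(f"{self.name}: stable genes cannot carry shifts")

    def shift(self, treatment: str, timepoint: float) -> float:
        return float(self.shifts.get((treatment, float(timepoint)), 0.0))


@dataclass(frozen=True)
class DesignSpec:
    """Experimental layout: treatments, per-treatment timepoint grid,
    biological replicates and the per-sample loading-effect SD (cycles)."""

    treatments: tuple[str, ...] = HORMONE_TREATMENTS + TEMPERATURE_TREATMENTS
    timepoints: Mapping[str, tuple[float, ...]] | None = None
    replicates: int = 3
    loading_sd: float = 0.3
    #: replicate noise is Gaussian by default; True switches to a unit-variance
    #: Student-t (3 df) for robustness experiments with outlier-prone runs
    heavy_tail: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise SyntheticError("replicates must be >= 1")
        if self.loading_sd < 0:
            raise SyntheticError("loading SD must be >= 0")
        for tr in self.treatments:
            if 0.0 not in self.grid(tr):
                raise SyntheticError(f"{tr}: timepoint grid must contain 0")

    def grid(self, treatment: str) -> tuple[float, ...]:
        if self.timepoints is not None and treatment in self.timepoints:
            return tuple(float(t) for t in self.timepoints[treatment])
        if treatment in TEMPERATURE_TREATMENTS:
            return TEMPERATURE_TIMEPOINTS
        return HORMONE_TIMEPOINTS

    def samples(self) -> list[SampleKey]:
        out = []
        for tr in self.treatments:
            for tp in self.grid(tr):
                for rep in range(1, self.replicates + 1):
                    out.append(SampleKey(tr, float(tp), rep))
        return out


@dataclass
class TruthTable:
    """Ground truth behind a generated table: per-gene role, the designed
    stable/unstable labels, and per-target designed log2 fold-change grids."""

    roles: pd.Series
    stable_genes: list[str]
    unstable_genes: list[str]
    target_log2fc: pd.DataFrame | None = None   # targets x (treatment, timepoint)

    def designed_trajectory(self, target: str, treatment: str) -> pd.Series:
        if self.target_log2fc is None:
            raise SyntheticError("no targets in this truth table")
        row = self.target_log2fc.loc[target]
        return row.xs(treatment, level="treatment")


def generate(
    design: DesignSpec, genes: Sequence[GeneModel], seed: int
) -> tuple[CtTable, TruthTable]:
    """Draw one replicate-resolved Ct table; identical seeds give identical
    tables bit for bit (a single Generator consumed in a fixed order)."""
    names = [g.name for g in genes]
    if len(set(names)) != len(names):
        raise SyntheticError("duplicate gene names")
    rng = np.random.default_rng(seed)
    samples = design.samples()
    loading = rng.normal(0.0, design.loading_sd, size=len(samples))
    if design.heavy_tail:
        df = 3.0
        noise = rng.standard_t(df, size=(len(genes), len(samples))) / np.sqrt(df / (df - 2))
    else:
        noise = rng.normal(0.0, 1.0, size=(len(genes), len(samples)))
    ct = np.empty((len(genes), len(samples)))
    for i, g in enumerate(genes):
        for j, s in enumerate(samples):
            ct[i, j] = (
                g.baseline
                + g.shift(s.treatment, s.timepoint)
                + loading[j]
                + g.noise_sd * noise[i, j]
            )
    frame = pd.DataFrame(ct, index=pd.Index(names, name="gene"), columns=_sample_index(samples))
    roles = pd.Series({g.name: g.role for g in genes})
    stable = [g.name for g in genes if g.role == "stable"]
    unstable = [g.name for g in genes if g.role == "time_drifting"]
    targets = [g for g in genes if g.role == "target"]
    target_fc = None
    if targets:
        cols = pd.MultiIndex.from_tuples(
            [(tr, tp) for tr in design.treatments for tp in design.grid(tr)],
            names=("treatment", "timepoint"),
        )
        target_fc = pd.DataFrame(
            [[-g.shift(tr, tp) for tr, tp in cols] for g in targets],
            index=pd.Index([g.name for g in targets], name="gene"),
            columns=cols,
        )
    return CtTable(frame), TruthTable(
        roles=roles, stable_genes=stable, unstable_genes=unstable, target_log2fc=target_fc
    )


# ---------------------------------------------------------------------------
# The study-like gene panel
# ---------------------------------------------------------------------------

def _ramp(treatments: Sequence[str], grids: Mapping[str, tuple[float, ...]],
          amplitude: float) -> dict[tuple[str, float], float]:
    """Linear drift from 0 at 0 h to ``amplitude`` cycles at 48 h."""
    shifts = {}
    for tr in treatments:
        for tp in grids[tr]:
            shifts[(tr, tp)] = amplitude * tp / 48.0
    return shifts


def _const(treatments: Sequence[str], grids: Mapping[str, tuple[float, ...]],
           value: float) -> dict[tuple[str, float], float]:
    """Constant treatment-wide bias (0 h included: a group effect, not a drift)."""
    return {(tr, tp): value for tr in treatments for tp in grids[tr]}


def candidate_panel(drift: float = 2.0, noise_sd: float = 0.15) -> list[GeneModel]:
    """Twelve candidate reference genes with designed stability structure.

    SsCDC6 and SsNCBP2 are designed stable (no treatment response, tight
    replicate noise); SsPP2A is the designed-unstable gene, drifting
    ``drift`` cycles over every 48 h time course; the other nine carry
    intermediate treatment biases, mild drifts or inflated noise.
    """
    grids = {tr: HORMONE_TIMEPOINTS for tr in HORMONE_TREATMENTS}
    grids |= {tr: TEMPERATURE_TIMEPOINTS for tr in TEMPERATURE_TREATMENTS}
    all_tr = HORMONE_TREATMENTS + TEMPERATURE_TREATMENTS
    s = noise_sd  # generic replicate-noise level; roles scale around it
    g = GeneModel
    return [
        g("SsCDC6", 23.8, "stable", {}, 0.67 * s),
        g("SsNCBP2", 21.5, "stable", {}, 0.67 * s),
        g("SsPP2A", 21.3, "time_drifting", _ramp(all_tr, grids, drift), 2.0 * s),
        g("SsRPL13", 20.5, "noisy", {}, 2.0 * s),
        g("SsTIP41", 22.0, "group_biased", _const(["MeJA"], grids, 0.5), 1.3 * s),
        g("SstubB2", 20.0, "group_biased", _const(["EtH"], grids, 0.4), 1.7 * s),
        g("SstubB3", 21.0, "time_drifting", _ramp(["LowTem"], grids, 0.8), 1.3 * s),
        g("SsGAPDH", 19.6, "group_biased", _const(["HighTem"], grids, 0.7), 1.3 * s),
        g("SstubA", 20.8, "noisy", {}, 2.3 * s),
        g("SsEF1a", 18.5, "group_biased", _const(["SA"], grids, 0.5), 1.7 * s),
        g("SsUBQC", 19.0, "time_drifting", _ramp(all_tr, grids, 0.4), 1.5 * s),
        g("SsPCACO", 17.4, "time_drifting", _ramp(["HighTem"], grids, 1.5), 2.7 * s),
    ]


#: Designed log2 fold-change trajectories on the hormone grid (0,3,6,12,24,48 h)
#: and the temperature grid (0,6,12,24,36,48 h), following the study's
#: qualitative patterns: SA peaks every pathway gene at 3 h then collapses;
#: EtH/MeJA split the panel into up-peaking and down-then-up groups; cold is
#: transient induction fading by 36 h; heat either a brief 6 h bump or
#: sustained repression.
_TRAJ = {
    "up_peak3": {"MeJA": (0, 2.0, 1.2, 0.8, 0.5, 0.3), "EtH": (0, 1.5, 0.8, 0.2, 0.1, 0.0)},
    "up_down_up": {"EtH": (0, -0.5, -1.0, -1.5, 1.5, 0.8), "MeJA": (0, -0.8, -1.2, -0.6, 0.4, 1.0)},
    "sa_spike": (0, 2.5, 0.5, -0.5, -1.0, -0.8),
    "cold_transient": (0, 0.8, 1.5, 1.8, 0.3, 0.1),
    "cold_mk": (0, -0.3, -0.6, -0.8, -1.0, -1.2),
    "heat_bump": (0, 1.0, 0.3, 0.0, -0.1, 0.0),
    "heat_down": (0, -0.6, -1.0, -1.4, -1.6, -1.8),
}

_UP_PEAK3 = {"SsAACT", "SsMK", "SsIPI", "SsGPS", "SsMVD", "SsEPH", "SsSQS", "SsPMK"}
_HEAT_BUMP = {"SsAACT", "SsIPI", "SsGPS", "SsSQE", "SsPMK"}

_TARGET_BASELINES = {
    "SsAACT": 22.5, "SsHMGS": 21.0, "SsHMGR": 22.8, "SsMK": 23.5, "SsPMK": 24.0,
    "SsMVD": 22.2, "SsIPI": 21.8, "SsGPS": 23.0, "SsFPS": 20.5, "SsSQS": 21.2,
    "SsSQE": 22.0, "SsCS": 24.5, "SsCYP": 23.2, "SsEPH": 22.6,
}


def target_panel(noise_sd: float = 0.15) -> list[GeneModel]:
    """Fourteen mogroside-pathway target genes with designed trajectories."""
    out = []
    for name, baseline in _TARGET_BASELINES.items():
        fc: dict[tuple[str, float], float] = {}
        # hormone treatments
        group = "up_peak3" if name in _UP_PEAK3 else "up_down_up"
        for tr in ("MeJA", "EtH"):
            for tp, v in zip(HORMONE_TIMEPOINTS, _TRAJ[group][tr]):
                fc[(tr, tp)] = v
        for tp, v in zip(HORMONE_TIMEPOINTS, _TRAJ["sa_spike"]):
            fc[("SA", tp)] = v
        # temperature treatments
        cold = _TRAJ["cold_mk"] if name == "SsMK" else _TRAJ["cold_transient"]
        for tp, v in zip(TEMPERATURE_TIMEPOINTS, cold):
            fc[("LowTem", tp)] = v
        heat = _TRAJ["heat_bump"] if name in _HEAT_BUMP else _TRAJ["heat_down"]
        for tp, v in zip(TEMPERATURE_TIMEPOINTS, heat):
            fc[("HighTem", tp)] = v
        shifts = {k: -v for k, v in fc.items()}      # 1 doubling = -1 cycle
        out.append(GeneModel(name, baseline, "target", shifts, noise_sd))
    return out


def paper_like_fixture(
    seed: int,
    include_targets: bool = True,
    drift: float = 2.0,
    noise_sd: float = 0.15,
    loading_sd: float = 0.3,
    replicates: int = 3,
) -> tuple[CtTable, TruthTable]:
    """The full study-like dataset: 12 candidates (+14 targets), 5 treatments,
    6 timepoints each, 3 biological replicates -> 90 samples."""
    genes = candidate_panel(drift=drift, noise_sd=noise_sd)
    if include_targets:
        genes = genes + target_panel(noise_sd=noise_sd)
    design = DesignSpec(replicates=replicates, loading_sd=loading_sd)
    return generate(design, genes, seed)


def dilution_series(
    primer: str,
    efficiency: float,
    base: float = 5.0,
    levels: int = 5,
    intercept: float = 20.0,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
) -> DilutionSeries:
    """Synthesize a standard-curve series with a known true efficiency.

    Ct at level i is intercept + i*log10(base)/log10(1+E) (+ noise), so the
    fitted slope is exactly -1/log10(1+E) in the noiseless case.
    """
    if efficiency <= 0:
        raise SyntheticError("efficiency must be positive")
    rng = np.random.default_rng(seed)
    step = np.log10(base) / np.log10(1.0 + efficiency)
    points = []
    for lvl in range(levels):
        for _ in range(replicates):
            ct = intercept + lvl * step + rng.normal(0.0, noise_sd)
            points.append((lvl, float(ct)))
    return DilutionSeries(primer=primer, points=tuple(points), base=base)
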