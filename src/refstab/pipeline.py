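"""End-to-end orchestration: aggregate -> calibrate -> rank -> validate.

``run_pipeline`` executes the whole reference-gene selection procedure from a
declarative :class:`RunConfig`: replicate aggregation, optional standard-curve
QC, the four stability methods per treatment subset, the pairwise-variation
curve, the consensus ranking with its best pair, and 2^-ddCt expression
profiles for the configured targets under each configured normalizer.  All
outputs are plain TSV; a report is regenerable byte-for-byte from its config.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .calibration import curves_to_frame, fit_standard_curve, primer_qc, read_dilution_series
from .consensus import ConsensusRanking, aggregate_ranks, best_pair
from .ct_data import CtTable, aggregate_replicates, read_ct_table, screen_ct_range
from .expression import (
    ExpressionProfile,
    NormalizerSpec,
    normalizer_concordance,
    relative_expression,
    timepoint_significance,
)
from .stability import (
    bestkeeper,
    bestkeeper_index,
    delta_ct_stability,
    genorm_m,
    genorm_v,
    normfinder,
    to_relative_quantities,
)

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for actionable errors."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Declarative run description (YAML-serializable)."""

    ct_path: str
    layout: str = "long"
    dilution_path: str | None = None
    dilution_base: float = 5.0
    candidate_genes: list[str] | None = None   # None -> all genes are candidates
    target_genes: list[str] = field(default_factory=list)
    subsets: dict[str, list[str]] | None = None  # None -> each treatment + "all"
    v_threshold: float = 0.15
    sd_cutoff: float = 1.0
    efficiency_lo: float = 0.90
    efficiency_hi: float = 1.20
    r2_min: float = 0.99
    ct_band: tuple[float, float] = (10.0, 40.0)
    normalizers: list[list[str]] = field(default_factory=list)
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        for name, val in [
            ("v_threshold", self.v_threshold),
            ("sd_cutoff", self.sd_cutoff),
            ("efficiency_lo", self.efficiency_lo),
            ("efficiency_hi", self.efficiency_hi),
            ("r2_min", self.r2_min),
        ]:
            if val <= 0:
                raise PipelineError("config", f"{name} must be positive, got {val}")
        if self.efficiency_lo >= self.efficiency_hi:
            raise PipelineError("config", "efficiency_lo must be below efficiency_hi")
        if not Path(self.ct_path).exists():
            raise PipelineError("config", f"ct table not found: {self.ct_path}")
        if self.dilution_path and not Path(self.dilution_path).exists():
            raise PipelineError("config", f"dilution table not found: {self.dilution_path}")

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = self.__dict__.copy()
        d["ct_band"] = list(self.ct_band)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if "ct_band" in d:
            d["ct_band"] = tuple(d["ct_band"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        # identifies the analysis, not where its outputs land
        d = self.to_dict()
        d.pop("outdir", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """All pipeline outputs plus the provenance needed to regenerate them."""

    config: RunConfig
    stability_tables: dict[str, dict[str, pd.DataFrame]]    # subset -> method -> table
    v_curves: dict[str, pd.DataFrame]
    recommended_n: dict[str, int]
    consensus: dict[str, ConsensusRanking]
    chosen_pair: tuple[str, str] | None
    calibration: pd.DataFrame | None
    violations: pd.DataFrame
    profiles: list[ExpressionProfile]
    significance: dict[str, pd.DataFrame]                   # "target|normalizer" -> stars
    concordance: dict[str, pd.DataFrame]                    # target -> pairwise report
    provenance: dict[str, Any]

    def write(self, outdir: str | Path) -> list[Path]:
        """Write every table as TSV under ``outdir``; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        def _put(frame: pd.DataFrame, name: str, index: bool = True) -> None:
            path = outdir / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=index)
            written.append(path)

        for subset, methods in self.stability_tables.items():
            for method, table in methods.items():
                _put(table, f"stability_{method}_{subset}")
        for subset, curve in self.v_curves.items():
            _put(curve, f"pairwise_variation_{subset}")
        for subset, cons in self.consensus.items():
            _put(cons.table, f"consensus_{subset}")
        if self.calibration is not None:
            _put(self.calibration, "calibration")
        if len(self.violations):
            _put(self.violations, "ct_violations", index=False)
        for prof in self.profiles:
            name = f"expression_{prof.target}_{prof.normalizer.replace('+', '_')}"
            _put(prof.summary, name)
        for key, table in self.significance.items():
            _put(table, f"significance_{key.replace('|', '_').replace('+', '_')}")
        for target, table in self.concordance.items():
            _put(table, f"concordance_{target}", index=False)
        prov = dict(self.provenance)
        if self.chosen_pair:
            prov["chosen_pair"] = list(self.chosen_pair)
        prov["recommended_n"] = self.recommended_n
        with open(outdir / "provenance.yaml", "w") as fh:
            yaml.safe_dump(prov, fh, sort_keys=True)
        written.append(outdir / "provenance.yaml")
        self.config.to_yaml(outdir / "config.yaml")
        written.append(outdir / "config.yaml")
        return written


def _default_subsets(table: CtTable) -> dict[str, list[str]]:
    subsets = {tr: [tr] for tr in table.treatments}
    subsets["all"] = list(table.treatments)
    return subsets


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full procedure; deterministic for a given config."""
    cfg.validate()

    def stage(name: str):
        log.info("stage: %s", name)
        return name

    current = stage("read")
    try:
        table = read_ct_table(cfg.ct_path, layout=cfg.layout)
        violations = screen_ct_range(table, *cfg.ct_band)
        if len(violations):
            log.warning("%d Ct values outside band %s", len(violations), cfg.ct_band)

        current = stage("calibration")
        calibration = None
        if cfg.dilution_path:
            series = read_dilution_series(cfg.dilution_path, base=cfg.dilution_base)
            curves = [fit_standard_curve(s) for s in series]
            qc = [
                primer_qc(c, cfg.efficiency_lo, cfg.efficiency_hi, cfg.r2_min)
                for c in curves
            ]
            calibration = curves_to_frame(curves, qc)
            failed = calibration.index[~calibration["qc_pass"].astype(bool)].tolist()
            if failed:
                log.warning("primers failing QC (E in [%.0f%%, %.0f%%], R^2 >= %s): %s",
                            cfg.efficiency_lo * 100, cfg.efficiency_hi * 100,
                            cfg.r2_min, failed)

        current = stage("aggregate")
        agg = aggregate_replicates(table)
        candidates = cfg.candidate_genes or [
            g for g in table.genes if g not in set(cfg.target_genes)
        ]
        agg_cand = agg.subset_genes(candidates)

        current = stage("stability")
        subsets = cfg.subsets or _default_subsets(table)
        stability_tables: dict[str, dict[str, pd.DataFrame]] = {}
        v_curves: dict[str, pd.DataFrame] = {}
        recommended: dict[str, int] = {}
        consensus: dict[str, ConsensusRanking] = {}
        for subset, treatments in subsets.items():
            frame = agg_cand.subset_treatments(treatments).frame()
            q = to_relative_quantities(frame)
            gm = genorm_m(q, subset=subset)
            curve = genorm_v(
                q, gm.extras["stability_order"], threshold=cfg.v_threshold, subset=subset
            )
            log.info("%s: V threshold %.2f -> %d reference genes",
                     subset, cfg.v_threshold, curve.recommended_n)
            groups = (
                {c: c[0] for c in frame.columns} if len(treatments) > 1 else None
            )
            nf = normfinder(frame, groups=groups, subset=subset)
            bk = bestkeeper(frame, sd_cutoff=cfg.sd_cutoff, subset=subset)
            bk_index = bestkeeper_index(frame, sd_cutoff=cfg.sd_cutoff, subset=subset)
            dc = delta_ct_stability(frame, subset=subset)
            cons = aggregate_ranks([gm, nf, bk, dc], subset=subset)
            methods = {r.method: r.to_frame() for r in (gm, nf, bk, dc)}
            if bk_index is not None:
                methods["bestkeeper_index"] = bk_index
            stability_tables[subset] = methods
            v_curves[subset] = curve.to_frame()
            recommended[subset] = curve.recommended_n
            consensus[subset] = cons

        current = stage("consensus")
        pool = "all" if "all" in consensus else next(iter(consensus))
        pair = best_pair(consensus[pool])
        log.info("chosen reference pair (%s subset): %s", pool, pair)

        current = stage("expression")
        profiles: list[ExpressionProfile] = []
        significance: dict[str, pd.DataFrame] = {}
        concordance: dict[str, pd.DataFrame] = {}
        normalizers = [list(n) for n in cfg.normalizers] or ([list(pair)] if pair else [])
        for target in cfg.target_genes:
            per_target = []
            for refs in normalizers:
                prof = relative_expression(table, target, NormalizerSpec(tuple(refs)))
                per_target.append(prof)
                significance[f"{target}|{prof.normalizer}"] = timepoint_significance(prof)
            profiles.extend(per_target)
            if len(per_target) >= 2:
                concordance[target] = normalizer_concordance(per_target)
    except PipelineError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise PipelineError(current, str(exc)) from exc

    provenance = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "version": __version__,
        "thresholds": {
            "v_threshold": cfg.v_threshold,
            "sd_cutoff": cfg.sd_cutoff,
            "efficiency_bounds": [cfg.efficiency_lo, cfg.efficiency_hi],
            "r2_min": cfg.r2_min,
        },
    }
    report = RunReport(
        config=cfg,
        stability_tables=stability_tables,
        v_curves=v_curves,
        recommended_n=recommended,
        consensus=consensus,
        chosen_pair=pair,
        calibration=calibration,
        violations=violations,
        profiles=profiles,
        significance=significance,
        concordance=concordance,
        provenance=provenance,
    )
    if cfg.outdir:
        report.write(cfg.outdir)
    return report
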