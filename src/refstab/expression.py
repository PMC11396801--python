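"""Relative target-gene expression by the comparative 2^-ddCt method.

A target's Ct is first normalized within each replicate against the
arithmetic-mean T of the chosen reference genes (dCt), then referenced to a
calibrator condition (ddCt; by default the 0 h sample of the same treatment),
giving a fold change RQ = 2^-ddCt per replicate.  An efficiency-corrected
ratio mode generalizes the base 2 to per-gene (1 + E).  Time-course
significance uses Welch's t-test on log2 fold changes versus the baseline
timepoint.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import CtTable

__all__ = [
    "NormalizerSpec",
    "ExpressionProfile",
    "relative_expression",
    "timepoint_significance",
    "normalizer_concordance",
    "stars_for_p",
]


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizerSpec:
    """Reference-gene set used for normalization.

    Multiple references combine by the arithmetic mean of their Ct, which is
    the geometric mean of their linear quantities (the geNorm NF convention).
    ``efficiencies`` optionally supplies per-gene amplification efficiencies
    (fraction, 1.0 = perfect doubling); genes not listed default to E = 1.
    """

    references: tuple[str, ...]
    efficiencies: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if len(self.references) < 1:
            raise ExpressionError("need at least one reference gene")
        if len(set(self.references)) != len(self.references):
            raise ExpressionError("duplicate reference genes")

    @property
    def label(self) -> str:
        return "+".join(self.references)

    def efficiency(self, gene: str) -> float:
        if self.efficiencies is None:
            return 1.0
        return float(self.efficiencies.get(gene, 1.0))


@dataclass
class ExpressionProfile:
    """Per-condition relative quantity of one target under one normalizer.

    ``summary`` is indexed by (treatment, timepoint) with columns rq_mean,
    rq_sem, n; ``replicate_rq`` keeps the per-replicate fold changes for
    significance testing.  RQ averages to 1 at each calibrator condition by
    construction.
    """

    target: str
    normalizer: str
    summary: pd.DataFrame
    replicate_rq: pd.Series      # MultiIndex (treatment, timepoint, replicate)
    calibrator: tuple[str, float] | None = None

    def conditions(self) -> list[tuple[str, float]]:
        return [(t, float(tp)) for t, tp in self.summary.index]

    def log2_means(self) -> pd.Series:
        return np.log2(self.summary["rq_mean"])

    def peak_timepoint(self, treatment: str) -> float:
        sub = self.summary.xs(treatment, level="treatment")["rq_mean"]
        return float(sub.idxmax())


def relative_expression(
    t: CtTable,
    target: str,
    norm: NormalizerSpec,
    calibrator: tuple[str, float] | None = None,
) -> ExpressionProfile:
    """Fold change of ``target`` versus the calibrator, normalized per replicate.

    With ``calibrator=None`` each treatment is calibrated against its own
    0 h condition (within-treatment time course); an explicit
    (treatment, timepoint) pins one global calibrator instead.  Replicates
    missing the target or any reference are dropped with a warning.
    """
    if target in norm.references:
        raise ExpressionError(f"target {target!r} cannot be its own reference")
    genes = [target, *norm.references]
    missing = [g for g in genes if g not in t.ct.index]
    if missing:
        raise ExpressionError(f"genes not in table: {missing}")
    sub = t.ct.loc[genes]
    # per-replicate log2 quantity relative to nothing yet: -dCt with per-gene base
    log2q = {}
    for g in genes:
        base = 1.0 + norm.efficiency(g)
        log2q[g] = -sub.loc[g] * np.log2(base)
    target_l = log2q[target]
    ref_l = pd.concat([log2q[g] for g in norm.references], axis=1).mean(axis=1)
    log2_dq = target_l - ref_l                      # -dCt when all E = 1
    usable = log2_dq.dropna()
    dropped = log2_dq.index.difference(usable.index)
    if len(dropped):
        warnings.warn(
            f"{target}: {len(dropped)} replicates dropped for missing Ct", stacklevel=2
        )
    if usable.empty:
        raise ExpressionError(f"{target}: no usable replicates")

    cond = usable.groupby(level=["treatment", "timepoint"])
    cond_mean = cond.mean()

    def _cal_value(treatment: str) -> float:
        key = calibrator if calibrator is not None else (treatment, 0.0)
        if key not in cond_mean.index:
            raise ExpressionError(f"{target}: calibrator condition {key} absent")
        return float(cond_mean.loc[key])

    cal = pd.Series(
        [_cal_value(tr) for tr in usable.index.get_level_values("treatment")],
        index=usable.index,
    )
    log2_rq = usable - cal                          # -ddCt
    rq = np.power(2.0, log2_rq)

    grp = rq.groupby(level=["treatment", "timepoint"])
    summary = pd.DataFrame(
        {
            "rq_mean": grp.mean(),
            "rq_sem": grp.std(ddof=1) / np.sqrt(grp.count()),
            "n": grp.count(),
        }
    )
    return ExpressionProfile(
        target=target,
        normalizer=norm.label,
        summary=summary,
        replicate_rq=rq,
        calibrator=calibrator,
    )


def stars_for_p(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def timepoint_significance(
    profile: ExpressionProfile, baseline: float = 0.0
) -> pd.DataFrame:
    """Welch t-test of each timepoint against the baseline, per treatment.

    The test runs on log2 fold changes (equivalently -ddCt), the scale on
    which replicate variation is closest to Gaussian.  Conditions with fewer
    than two replicates on either side get NaN p and an ``undefined`` flag.
    """
    log2rq = np.log2(profile.replicate_rq)
    rows = []
    for (treatment, timepoint), vals in log2rq.groupby(level=["treatment", "timepoint"]):
        if timepoint == baseline:
            continue
        try:
            base = log2rq.xs((treatment, baseline), level=["treatment", "timepoint"])
        except KeyError:
            rows.append((treatment, timepoint, np.nan, "", True))
            continue
        if len(vals) < 2 or len(base) < 2:
            rows.append((treatment, timepoint, np.nan, "", True))
            continue
        t_res = stats.ttest_ind(vals.to_numpy(), base.to_numpy(), equal_var=False)
        p = float(t_res.pvalue)
        rows.append((treatment, timepoint, p, stars_for_p(p), False))
    out = pd.DataFrame(
        rows, columns=["treatment", "timepoint", "p_value", "stars", "undefined"]
    ).set_index(["treatment", "timepoint"])
    return out


def normalizer_concordance(
    profiles: Sequence[ExpressionProfile], r_threshold: float = 0.9
) -> pd.DataFrame:
    """Pairwise agreement of expression profiles under different normalizers.

    For each profile pair: Pearson correlation of log2 mean fold changes over
    the shared condition grid, the fraction of treatments whose peak
    timepoint matches, and a flag when the correlation falls below
    ``r_threshold``.  Mismatched condition grids are an error.
    """
    if len(profiles) < 2:
        raise ExpressionError("need at least two profiles to compare")
    grid = profiles[0].conditions()
    for p in profiles[1:]:
        if p.conditions() != grid:
            raise ExpressionError(
                f"condition grids differ between normalizers {profiles[0].normalizer!r} "
                f"and {p.normalizer!r}"
            )
    treatments = sorted({t for t, _ in grid})
    rows = []
    for a, b in itertools.combinations(profiles, 2):
        la, lb = a.log2_means(), b.log2_means()
        if np.allclose(la, lb):
            r = 1.0
        else:
            r = float(stats.pearsonr(la, lb)[0])
        agree = np.mean(
            [a.peak_timepoint(tr) == b.peak_timepoint(tr) for tr in treatments]
        )
        rows.append(
            {
                "normalizer_a": a.normalizer,
                "normalizer_b": b.normalizer,
                "pearson_r_log2": r,
                "peak_agreement": float(agree),
                "flagged": r < r_threshold,
            }
        )
    return pd.DataFrame(rows)
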