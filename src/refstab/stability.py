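"""Expression-stability statistics for candidate reference genes.

Four classical screens operate on the replicate-mean Ct matrix of one
treatment subset:

* geNorm — mean pairwise SD of log2 expression ratios (M), with stepwise
  exclusion of the least stable gene, plus the pairwise-variation curve
  V(n/n+1) that sizes the reference-gene set;
* NormFinder — a variance-decomposition score combining within-group
  variability and shrunken between-group bias of centered Ct;
* BestKeeper — raw-Ct dispersion (SD, CV%), with the SD > 1 exclusion rule
  and correlation against the BestKeeper index;
* comparative ΔCt — mean SD of all pairwise Ct differences.

All scores are "lower is more stable"; ranks use average ranks on ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import AggregatedCtTable

__all__ = [
    "StabilityResult",
    "GenormResult",
    "PairwiseVariationCurve",
    "to_relative_quantities",
    "genorm_m",
    "genorm_v",
    "recommend_n_references",
    "normfinder",
    "bestkeeper",
    "bestkeeper_index",
    "delta_ct_stability",
    "tie_average_ranks",
]


class StabilityError(ValueError):
    pass


def _as_frame(t: AggregatedCtTable | pd.DataFrame, min_genes: int = 2) -> pd.DataFrame:
    frame = t.mean if isinstance(t, AggregatedCtTable) else t
    if frame.isna().any(axis=None):
        raise StabilityError(
            "Ct frame contains missing cells; drop incomplete genes/subsets first"
        )
    if frame.shape[0] < min_genes or frame.shape[1] < 2:
        raise StabilityError(f"need at least {min_genes} genes and 2 samples")
    return frame.astype(float)


def tie_average_ranks(scores: pd.Series) -> pd.Series:
    """Ascending ranks (1 = most stable), ties sharing the average rank."""
    return scores.rank(method="average")


@dataclass
class StabilityResult:
    """Per-gene stability scores and ranks for one method on one subset."""

    method: str
    subset: str
    scores: pd.Series          # lower = more stable; method-specific units
    ranks: pd.Series
    extras: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"score": self.scores, "rank": self.ranks})
        for key, val in self.extras.items():
            if isinstance(val, pd.Series) and val.index.equals(out.index):
                out[key] = val
        out.index.name = "gene"
        return out


# ---------------------------------------------------------------------------
# Relative quantities (geNorm's Q transform)
# ---------------------------------------------------------------------------

def to_relative_quantities(
    t: AggregatedCtTable | pd.DataFrame,
    efficiency: float | Mapping[str, float] = 1.0,
) -> pd.DataFrame:
    """Transform Ct to relative quantities Q = (1+E)^(Ct_min - Ct) per gene.

    With the default E = 1 this is the classical Q = 2^-dCt: each gene's most
    abundant sample gets Q = 1 and every other sample a value in (0, 1].
    """
    frame = _as_frame(t, min_genes=1)
    if isinstance(efficiency, Mapping):
        eff = pd.Series({g: float(efficiency.get(g, 1.0)) for g in frame.index})
    else:
        eff = pd.Series(float(efficiency), index=frame.index)
    if (eff <= -1).any():
        raise StabilityError("efficiency must exceed -1")
    delta = frame.min(axis=1).to_numpy()[:, None] - frame.to_numpy()
    q = np.power((1.0 + eff.to_numpy())[:, None], delta)
    return pd.DataFrame(q, index=frame.index, columns=frame.columns)


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

@dataclass
class GenormResult(StabilityResult):
    """geNorm output: scores are M at each gene's exclusion round.

    ``exclusion_order`` lists genes from first (least stable) to last
    excluded; the surviving pair shares average rank 1.5 because geNorm cannot
    separate its final two genes.  ``rounds`` keeps the full per-round M
    series for charting stepwise stability.
    """

    exclusion_order: list[str] = field(default_factory=list)
    rounds: list[pd.Series] = field(default_factory=list)
    degenerate: bool = False


def _pairwise_logratio_sd(logq: np.ndarray) -> np.ndarray:
    """J x J matrix of SDs (ddof=1) of pairwise log-ratio profiles."""
    diffs = logq[:, None, :] - logq[None, :, :]
    return diffs.std(axis=2, ddof=1)


def _m_values(logq: pd.DataFrame) -> pd.Series:
    sd = _pairwise_logratio_sd(logq.to_numpy())
    j = sd.shape[0]
    m = sd.sum(axis=1) / (j - 1)  # diagonal contributes 0
    return pd.Series(m, index=logq.index)


def genorm_m(q: pd.DataFrame, subset: str = "all") -> GenormResult:
    """geNorm expression-stability measure with stepwise exclusion.

    M_j is the mean over partners k of the SD across samples of
    log2(Q_j / Q_k).  The gene with the highest M is removed and M recomputed
    until two genes remain; a gene's score is its M at the round of removal,
    the survivors keep the final-round M.
    """
    if (q <= 0).any(axis=None):
        raise StabilityError("relative quantities must be positive")
    if q.shape[1] < 2:
        raise StabilityError("geNorm needs at least 2 samples")
    logq = np.log2(q.astype(float))
    remaining = list(q.index)
    scores: dict[str, float] = {}
    exclusion: list[str] = []
    rounds: list[pd.Series] = []
    while len(remaining) > 2:
        m = _m_values(logq.loc[remaining])
        rounds.append(m)
        worst_score = m.max()
        # deterministic under gene-order permutation: break ties by name
        worst = max(sorted(m.index[m == worst_score]))
        scores[worst] = float(m[worst])
        exclusion.append(worst)
        remaining.remove(worst)
    final_m = _m_values(logq.loc[remaining])
    rounds.append(final_m)
    for g in remaining:
        scores[g] = float(final_m[g])
    ranks = pd.Series(index=q.index, dtype=float)
    ranks[remaining] = 1.5  # the final pair cannot be resolved by geNorm
    for pos, g in enumerate(reversed(exclusion)):
        ranks[g] = 3 + pos
    score_s = pd.Series(scores).reindex(q.index)
    degenerate = bool(np.allclose(score_s.to_numpy(), 0.0))
    if degenerate:
        warnings.warn("all geNorm M values are 0 (degenerate, proportional profiles)", stacklevel=2)
    return GenormResult(
        method="genorm",
        subset=subset,
        scores=score_s,
        ranks=ranks,
        exclusion_order=exclusion,
        rounds=rounds,
        degenerate=degenerate,
        extras={"stability_order": _stability_order(remaining, exclusion)},
    )


def _stability_order(remaining: Sequence[str], exclusion: Sequence[str]) -> list[str]:
    # most stable first: surviving pair (name order), then reverse exclusion
    return sorted(remaining) + list(reversed(exclusion))


@dataclass
class PairwiseVariationCurve:
    subset: str
    values: list[tuple[int, float]]        # (n, V_{n/n+1})
    threshold: float
    recommended_n: int
    converged: bool                        # False if no V fell under threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=["n", "v"]).set_index("n")


def recommend_n_references(
    values: Sequence[tuple[int, float]], threshold: float = 0.15
) -> tuple[int, bool]:
    """Smallest n with V(n/n+1) strictly below the threshold; if none, the
    total gene count with converged=False."""
    for n, v in sorted(values):
        if v < threshold:
            return n, True
    last_n = max(n for n, _ in values)
    return last_n + 1, False


def genorm_v(
    q: pd.DataFrame,
    stability_order: Sequence[str],
    threshold: float = 0.15,
    subset: str = "all",
) -> PairwiseVariationCurve:
    """Pairwise-variation curve V(n/n+1) sizing the reference-gene set.

    NF_n per sample is the geometric mean of Q over the n most stable genes;
    V_n is the SD over samples of log2(NF_n / NF_{n+1}).  The recommended set
    size is the smallest n with V_n below the threshold (default 0.15).
    """
    j = len(stability_order)
    if j < 3:
        raise StabilityError("pairwise-variation curve needs at least 3 genes")
    logq = np.log2(q.loc[list(stability_order)].astype(float)).to_numpy()
    values = []
    for n in range(2, j):
        nf_n = logq[:n].mean(axis=0)       # log2 of geometric-mean NF
        nf_n1 = logq[: n + 1].mean(axis=0)
        v = float(np.std(nf_n - nf_n1, ddof=1))
        values.append((n, v))
    rec, converged = recommend_n_references(values, threshold)
    if not converged:
        warnings.warn(
            f"no V(n/n+1) under {threshold}; recommending all {rec} genes", stacklevel=2
        )
    return PairwiseVariationCurve(
        subset=subset, values=values, threshold=threshold,
        recommended_n=rec, converged=converged,
    )


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def normfinder(
    t: AggregatedCtTable | pd.DataFrame,
    groups: Mapping | pd.Series | None = None,
    subset: str = "all",
) -> StabilityResult:
    """Variance-decomposition stability on (log-scale) Ct values.

    Every sample column is first centered by its cross-gene mean, removing
    sample-loading effects, giving residuals w.  Without groups the score is
    simply the SD of w across samples.  With groups the score combines the
    within-group sampling error with an empirical-Bayes-shrunken estimate of
    the gene's between-group expression bias: genes that react to treatment
    grouping are penalized even if tight within each group.
    """
    frame = _as_frame(t)
    if frame.shape[0] < 3:
        raise StabilityError("NormFinder needs at least 3 genes")
    w = frame - frame.mean(axis=0)
    if groups is not None:
        grp = pd.Series(
            [groups[c] for c in frame.columns] if not isinstance(groups, pd.Series)
            else groups.reindex(frame.columns),
            index=frame.columns,
        )
        labels = grp.unique()
    else:
        labels = np.array(["_all"])
        grp = pd.Series("_all", index=frame.columns)
    sizes = grp.value_counts()
    tiny = sizes[sizes < 2]
    if len(tiny):
        raise StabilityError(f"groups with a single sample: {list(tiny.index)}")
    if len(labels) == 1:
        scores = w.std(axis=1, ddof=1)
    else:
        m = w.T.groupby(grp).mean().T                      # genes x groups
        var = w.T.groupby(grp).var(ddof=1).T               # within-group variance
        n = sizes.reindex(m.columns)
        z = m.sub(m.mean(axis=1), axis=0)                  # between-group deviation
        noise = var.div(n, axis=1)                         # sampling variance of m
        gamma2 = max(0.0, float(z.to_numpy().var(ddof=1)) - float(noise.to_numpy().mean()))
        shrink = gamma2 / (gamma2 + noise)
        z_tilde = z * shrink
        spread = np.sqrt(noise + gamma2 * noise / (gamma2 + noise))
        scores = (z_tilde.abs() + spread).mean(axis=1)
    scores = scores.astype(float)
    return StabilityResult(
        method="normfinder", subset=subset, scores=scores,
        ranks=tie_average_ranks(scores),
        extras={"n_groups": len(labels)},
    )


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper(
    t: AggregatedCtTable | pd.DataFrame,
    sd_cutoff: float = 1.0,
    use_mad: bool = False,
    subset: str = "all",
) -> StabilityResult:
    """Raw-Ct dispersion screen: per-gene mean, SD, CV% and the SD > 1 rule.

    ``use_mad`` switches the dispersion to the mean absolute deviation about
    the mean, the convention of the original spreadsheet tool; the default is
    the sample SD.  Genes whose SD exceeds ``sd_cutoff`` (strictly) are
    flagged unstable but still ranked so consensus aggregation stays total.
    Ranks order by SD with CV% as tiebreak.
    """
    frame = _as_frame(t)
    mean = frame.mean(axis=1)
    if use_mad:
        sd = (frame.sub(mean, axis=0)).abs().mean(axis=1)
    else:
        sd = frame.std(axis=1, ddof=1)
    cv = 100.0 * sd / mean
    flagged = sd > sd_cutoff
    # SD primary, CV tiebreak, gene name as final deterministic tiebreak;
    # full (SD, CV) ties share the average rank.
    order = sorted(frame.index, key=lambda g: (sd[g], cv[g], g))
    pos = pd.Series({g: i + 1.0 for i, g in enumerate(order)})
    key = pd.Series([(sd[g], cv[g]) for g in pos.index], index=pos.index)
    ranks = pos.groupby(key).transform("mean").reindex(frame.index)
    return StabilityResult(
        method="bestkeeper", subset=subset,
        scores=sd.astype(float), ranks=ranks,
        extras={"mean_ct": mean, "cv_pct": cv, "sd_flag": flagged, "sd_cutoff": sd_cutoff},
    )


def bestkeeper_index(
    t: AggregatedCtTable | pd.DataFrame,
    candidates: Sequence[str] | None = None,
    sd_cutoff: float = 1.0,
    subset: str = "all",
) -> pd.DataFrame | None:
    """Correlation of each gene's Ct with the BestKeeper index.

    The index is the per-sample geometric mean of the Ct of the candidates
    that survive the SD filter; the return frame holds Pearson r and the
    two-sided p-value per gene.  With fewer than three survivors the step is
    skipped (None) with a warning.
    """
    frame = _as_frame(t)
    cand = list(candidates) if candidates is not None else list(frame.index)
    sd = frame.loc[cand].std(axis=1, ddof=1)
    survivors = [g for g in cand if sd[g] <= sd_cutoff]
    if len(survivors) < 3:
        warnings.warn(
            f"only {len(survivors)} candidates survive SD <= {sd_cutoff}; index skipped",
            stacklevel=2,
        )
        return None
    index = np.exp(np.log(frame.loc[survivors]).mean(axis=0))
    rows = {}
    for g in frame.index:
        r, p = stats.pearsonr(frame.loc[g], index)
        rows[g] = {"pearson_r": float(r), "p_value": float(p)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    out.attrs["survivors"] = survivors
    return out


# ---------------------------------------------------------------------------
# Comparative delta-Ct
# ---------------------------------------------------------------------------

def delta_ct_stability(
    t: AggregatedCtTable | pd.DataFrame, subset: str = "all"
) -> StabilityResult:
    """Mean SD of a gene's Ct differences against every other gene.

    For each gene pair the SD across samples of (Ct_g - Ct_h) is computed;
    a gene's score is the mean over its partners, smallest SD = most stable.
    """
    frame = _as_frame(t)
    if frame.shape[0] < 3:
        raise StabilityError("delta-Ct comparison needs at least 3 genes")
    sd = _pairwise_logratio_sd(frame.to_numpy())  # same arithmetic on raw Ct
    scores = pd.Series(sd.sum(axis=1) / (sd.shape[0] - 1), index=frame.index)
    return StabilityResult(
        method="delta_ct", subset=subset, scores=scores,
        ranks=tie_average_ranks(scores),
    )
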