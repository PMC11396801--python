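"""Ct tables: the replicate-resolved data model behind every downstream algorithm.

A quantitative PCR experiment yields one cycle-threshold (Ct) value per
(gene, biological sample) pair, where a sample is identified by its treatment
group, sampling timepoint (hours) and biological-replicate index.  This module
holds the validated container for such data, readers/writers for the two
delimited layouts, replicate aggregation, and a simple plausibility screen on
the Ct range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleKey",
    "CtTable",
    "AggregatedCtTable",
    "read_ct_table",
    "write_ct_table",
    "aggregate_replicates",
    "screen_ct_range",
    "CtDataError",
]

#: Ct values above this are physically implausible on a 40-45 cycle run.
CT_MAX = 45.0

SAMPLE_LEVELS = ("treatment", "timepoint", "replicate")
CONDITION_LEVELS = ("treatment", "timepoint")


class CtDataError(ValueError):
    """Raised for malformed or inconsistent Ct input."""


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one biological sample: (treatment, timepoint h, replicate)."""

    treatment: str
    timepoint: float
    replicate: int

    def __post_init__(self) -> None:
        if self.timepoint < 0:
            raise CtDataError(f"negative timepoint {self.timepoint!r}")
        if self.replicate < 1:
            raise CtDataError(f"replicate index must be >= 1, got {self.replicate!r}")

    @property
    def label(self) -> str:
        tp = int(self.timepoint) if float(self.timepoint).is_integer() else self.timepoint
        return f"{self.treatment}:{tp}:{self.replicate}"

    @classmethod
    def from_label(cls, label: str) -> "SampleKey":
        parts = label.split(":")
        if len(parts) != 3:
            raise CtDataError(f"sample header {label!r} is not 'treatment:timepoint:replicate'")
        return cls(parts[0], float(parts[1]), int(parts[2]))

    def astuple(self) -> tuple[str, float, int]:
        return (self.treatment, self.timepoint, self.replicate)


def _sample_index(samples: Iterable[SampleKey]) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples([s.astuple() for s in samples], names=SAMPLE_LEVELS)


class CtTable:
    """Gene x sample grid of raw Ct values with replicate-level sample keys.

    Missing measurements are NaN; every non-missing Ct must lie in (0, CT_MAX].
    Genes and samples are kept in a canonical sorted order so that the table is
    invariant to input row/column ordering.
    """

    def __init__(self, ct: pd.DataFrame):
        if not isinstance(ct.columns, pd.MultiIndex) or tuple(ct.columns.names) != SAMPLE_LEVELS:
            raise CtDataError("CtTable columns must be a (treatment, timepoint, replicate) MultiIndex")
        if ct.index.has_duplicates:
            dups = ct.index[ct.index.duplicated()].unique().tolist()
            raise CtDataError(f"duplicate gene identifiers: {dups}")
        if ct.columns.has_duplicates:
            dups = ct.columns[ct.columns.duplicated()].unique().tolist()
            raise CtDataError(f"duplicate samples: {dups}")
        ct = ct.sort_index(axis=0).sort_index(axis=1)
        values = ct.to_numpy(dtype=float)
        bad = np.isfinite(values) & ((values <= 0) | (values > CT_MAX))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise CtDataError(
                f"Ct {values[g, s]} for gene {ct.index[g]!r}, sample "
                f"{ct.columns[s]} outside (0, {CT_MAX}]"
            )
        if np.isinf(values).any():
            raise CtDataError("infinite Ct value encountered")
        self.ct = ct.astype(float)

    # -- basic introspection ------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.ct.index)

    @property
    def samples(self) -> list[SampleKey]:
        return [SampleKey(t, float(tp), int(r)) for t, tp, r in self.ct.columns]

    @property
    def n_genes(self) -> int:
        return self.ct.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ct.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.ct.isna()

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.ct.columns.get_level_values("treatment")))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CtTable):
            return NotImplemented
        return self.ct.equals(other.ct)

    def __repr__(self) -> str:
        return f"CtTable({self.n_genes} genes x {self.n_samples} samples)"

    # -- subsetting ---------------------------------------------------------
    def subset_genes(self, genes: Sequence[str]) -> "CtTable":
        missing = [g for g in genes if g not in self.ct.index]
        if missing:
            raise CtDataError(f"unknown genes: {missing}")
        return CtTable(self.ct.loc[list(genes)])

    def subset_treatments(self, treatments: Sequence[str]) -> "CtTable":
        mask = self.ct.columns.get_level_values("treatment").isin(treatments)
        if not mask.any():
            raise CtDataError(f"no samples for treatments {list(treatments)}")
        return CtTable(self.ct.loc[:, mask])

    # -- serialization ------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        long = self.ct.stack(SAMPLE_LEVELS, future_stack=True).rename("ct").reset_index()
        long = long.rename(columns={"level_0": "gene"})
        if "gene" not in long.columns:  # index name already set
            long = long.rename(columns={self.ct.index.name or "index": "gene"})
        return long.dropna(subset=["ct"]).reset_index(drop=True)


@dataclass
class AggregatedCtTable:
    """Replicate means per (treatment, timepoint) condition.

    ``mean`` is the arithmetic mean Ct of the non-missing biological
    replicates, ``n`` the replicate count behind each cell, and ``sem`` the
    standard error SD/sqrt(n) kept for reporting.  Cells with zero usable
    replicates are NaN with n = 0.
    """

    mean: pd.DataFrame
    n: pd.DataFrame
    sem: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.mean.index)

    @property
    def conditions(self) -> list[tuple[str, float]]:
        return [(t, float(tp)) for t, tp in self.mean.columns]

    def subset_genes(self, genes: Sequence[str]) -> "AggregatedCtTable":
        idx = list(genes)
        return AggregatedCtTable(self.mean.loc[idx], self.n.loc[idx], self.sem.loc[idx])

    def subset_treatments(self, treatments: Sequence[str]) -> "AggregatedCtTable":
        mask = self.mean.columns.get_level_values("treatment").isin(treatments)
        return AggregatedCtTable(
            self.mean.loc[:, mask], self.n.loc[:, mask], self.sem.loc[:, mask]
        )

    def frame(self, treatments: Sequence[str] | None = None, drop_incomplete: bool = True) -> pd.DataFrame:
        """Mean-Ct frame for the given treatment subset, optionally dropping
        genes with any missing condition (required by the stability methods)."""
        sub = self if treatments is None else self.subset_treatments(treatments)
        frame = sub.mean
        if drop_incomplete and frame.isna().any(axis=None):
            bad = frame.index[frame.isna().any(axis=1)].tolist()
            warnings.warn(f"dropping genes with incomplete conditions: {bad}", stacklevel=2)
            frame = frame.drop(index=bad)
        return frame


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["gene", "treatment", "timepoint", "replicate", "ct"]


def read_ct_table(path: str | Path, layout: str = "long", sep: str = ",") -> CtTable:
    """Read a delimited Ct table.

    ``layout='long'`` expects columns gene,treatment,timepoint,replicate,ct
    (one measurement per row; empty/NA ct marks a missing replicate).
    ``layout='wide'`` expects a first column of gene names and one column per
    sample headed ``treatment:timepoint:replicate``.
    """
    path = Path(path)
    if layout == "long":
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        missing_cols = [c for c in LONG_COLUMNS if c not in raw.columns]
        if missing_cols:
            raise CtDataError(f"{path}: missing required columns {missing_cols}")
        ct_num = pd.to_numeric(raw["ct"].replace({"": None, "NA": None, "nan": None}), errors="coerce")
        nonnum = (
            raw["ct"].astype(str).str.strip().ne("")
            & ~raw["ct"].isin(["NA", "nan"])
            & ct_num.isna()
        )
        if nonnum.any():
            row = int(nonnum.idxmax()) + 2  # header is line 1
            raise CtDataError(f"{path}: non-numeric ct {raw.loc[nonnum.idxmax(), 'ct']!r} on line {row}")
        # Python's float() is correctly rounded, giving exact text round-trips
        ct_num = raw["ct"].map(lambda v: float(v) if str(v).strip() not in ("", "NA", "nan") else np.nan)
        df = pd.DataFrame(
            {
                "gene": raw["gene"].astype(str),
                "treatment": raw["treatment"].astype(str),
                "timepoint": pd.to_numeric(raw["timepoint"]),
                "replicate": pd.to_numeric(raw["replicate"]).astype(int),
                "ct": ct_num,
            }
        )
        dup = df.duplicated(subset=["gene", "treatment", "timepoint", "replicate"], keep=False)
        if dup.any():
            first = df[dup].iloc[0]
            raise CtDataError(
                f"{path}: duplicate record for gene {first['gene']!r}, sample "
                f"{first['treatment']}:{first['timepoint']}:{first['replicate']}"
            )
        wide = df.pivot(index="gene", columns=["treatment", "timepoint", "replicate"], values="ct")
        wide.columns = wide.columns.set_names(SAMPLE_LEVELS)
        return CtTable(wide)
    if layout == "wide":
        raw = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        keys = [SampleKey.from_label(str(c)) for c in raw.columns]
        raw.columns = _sample_index(keys)
        raw.index = raw.index.astype(str)
        raw.index.name = "gene"
        return CtTable(raw.apply(pd.to_numeric))
    raise CtDataError(f"unknown layout {layout!r}; expected 'long' or 'wide'")


def write_ct_table(t: CtTable, path: str | Path, layout: str = "long", sep: str = ",") -> None:
    """Write a CtTable; the long layout is canonical and round-trips exactly
    (Python's shortest float repr is parsed back to the identical double)."""
    path = Path(path)
    if layout == "long":
        long = t.to_long()
        long["ct"] = long["ct"].map(repr)
        long.to_csv(path, sep=sep, index=False)
    elif layout == "wide":
        out = t.ct.copy()
        out.columns = [SampleKey(tr, float(tp), int(r)).label for tr, tp, r in out.columns]
        out.index.name = "gene"
        out.to_csv(path, sep=sep)
    else:
        raise CtDataError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# Aggregation and screening
# ---------------------------------------------------------------------------

def aggregate_replicates(t: CtTable) -> AggregatedCtTable:
    """Collapse biological replicates to their arithmetic mean Ct per
    (treatment, timepoint), recording replicate count and SEM = SD/sqrt(n).

    Ct is already a log-scale quantity, so the arithmetic mean of Ct
    corresponds to a geometric mean of transcript abundance.
    """
    by = t.ct.T.groupby(level=list(CONDITION_LEVELS), sort=True)
    mean = by.mean().T
    n = by.count().T
    sd = by.std(ddof=1).T
    sem = sd / np.sqrt(n.where(n > 0))
    if (n == 0).any(axis=None):
        empty = [
            (g, c)
            for g in n.index
            for c in n.columns[(n.loc[g] == 0)]
        ]
        warnings.warn(
            f"{len(empty)} (gene, condition) cells have no usable replicate: "
            f"{empty[:5]}{'...' if len(empty) > 5 else ''}",
            stacklevel=2,
        )
    mean.columns = mean.columns.set_names(CONDITION_LEVELS)
    return AggregatedCtTable(mean=mean, n=n, sem=sem)


def screen_ct_range(t: CtTable, lo: float, hi: float) -> pd.DataFrame:
    """List every non-missing Ct outside [lo, hi] (plausible-abundance band).

    Returns a frame with columns gene, treatment, timepoint, replicate, ct;
    the table itself is never modified.
    """
    if not lo < hi:
        raise CtDataError(f"invalid band [{lo}, {hi}]")
    values = t.ct.to_numpy()
    out = ~np.isnan(values) & ((values < lo) | (values > hi))
    rows = []
    for g_idx, s_idx in np.argwhere(out):
        tr, tp, rep = t.ct.columns[s_idx]
        rows.append((t.ct.index[g_idx], tr, float(tp), int(rep), values[g_idx, s_idx]))
    return pd.DataFrame(rows, columns=LONG_COLUMNS)
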