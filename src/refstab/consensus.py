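"""Comprehensive (RefFinder-style) ranking across stability methods.

Each contributing method supplies a per-gene rank; the composite score is the
geometric mean of those ranks, and the final ordering re-ranks the composite
with average ranks on ties.  All methods are weighted equally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .stability import StabilityResult, tie_average_ranks

__all__ = ["ConsensusRanking", "aggregate_ranks", "best_pair"]

log = logging.getLogger(__name__)


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusRanking:
    subset: str
    table: pd.DataFrame          # rank_<method> columns + geomean + final_rank
    methods: list[str] = field(default_factory=list)
    flags: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def ordered_genes(self) -> list[str]:
        return list(self.table.sort_values(["final_rank", "geomean"]).index)


def aggregate_ranks(
    results: Sequence[StabilityResult], subset: str | None = None
) -> ConsensusRanking:
    """Geometric-mean rank aggregation over >=2 stability methods.

    Genes absent from any method are dropped with a warning; disjoint gene
    sets are an error.  G_g = (prod_m rank_mg)^(1/M); final ranks ascend in G
    with average ranks on ties.
    """
    if len(results) < 2:
        raise ConsensusError("need at least two methods to aggregate")
    gene_sets = [set(r.genes) for r in results]
    common = set.intersection(*gene_sets)
    if not common:
        raise ConsensusError("methods share no genes")
    union = set.union(*gene_sets)
    if union - common:
        warnings.warn(
            f"genes missing from some methods dropped: {sorted(union - common)}",
            stacklevel=2,
        )
    genes = sorted(common)
    table = pd.DataFrame(
        {f"rank_{r.method}": r.ranks.reindex(genes) for r in results}, index=genes
    )
    geomean = np.exp(np.log(table.to_numpy(dtype=float)).mean(axis=1))
    table["geomean"] = geomean
    table["final_rank"] = tie_average_ranks(table["geomean"])
    table.index.name = "gene"
    flags = {}
    for r in results:
        flag = r.extras.get("sd_flag")
        if isinstance(flag, pd.Series):
            flags[f"{r.method}_flag"] = flag.reindex(genes)
    return ConsensusRanking(
        subset=subset or results[0].subset,
        table=table,
        methods=[r.method for r in results],
        flags=flags,
    )


def best_pair(c: ConsensusRanking) -> tuple[str, str]:
    """The two top-ranked genes of a consensus; ties resolved by gene name."""
    if len(c.genes) < 2:
        raise ConsensusError("need at least two ranked genes")
    ordered = sorted(c.genes, key=lambda g: (c.table.loc[g, "final_rank"], g))
    top = ordered[:2]
    third = ordered[2] if len(ordered) > 2 else None
    if third is not None and (
        c.table.loc[third, "final_rank"] == c.table.loc[top[1], "final_rank"]
    ):
        log.info("consensus tie at rank 2 broken lexicographically (%s over %s)", top[1], third)
    return (top[0], top[1])
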