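"""The comparative-dCt screening statistic.

For every pair of candidate regions (j, k) the per-sample difference
dCt = Ct_j - Ct_k is formed and its sample standard deviation (n-1) taken
across samples; a region's score is the mean of these SDs over all partners,
and regions are ranked ascending (smaller = more stable). The method sees
only Ct differences, so per-sample loading shifts cancel, and it needs no
standard curves — which is what makes it suitable as a cheap first screen
before geNorm/NormFinder. Amplification-efficiency differences between
regions are *not* corrected for; that is the method's documented limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CtTable
from .errors import DomainError


@dataclass
class DeltaCtResult:
    """Pairwise dCt SDs, per-region mean SDs and the resulting ranking."""

    pair_sd: pd.DataFrame          # symmetric region x region matrix, NaN diag
    mean_sd: pd.Series             # region -> average SD over partners (cycles)
    ranking: list[str]             # ascending mean_sd, ties lexicographic
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)
    dropped_regions: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.ranking) + 1),
                "region": self.ranking,
                "mean_sd": [self.mean_sd[r] for r in self.ranking],
            }
        )


def deltact_rank(table: CtTable, regions=None) -> DeltaCtResult:
    """Rank candidate regions by mean SD of pairwise Ct differences.

    Operates on collapsed Cts (replicates are averaged if still present);
    masked cells and undetermined values are excluded. Pairs sharing fewer
    than 2 samples are omitted and flagged; a region left without any valid
    pair is dropped with a warning.
    """
    ct = table.ct_matrix(respect_mask=True)
    regions = list(regions) if regions is not None else list(ct.columns)
    if len(regions) < 2:
        raise DomainError("dCt ranking needs >=2 regions")
    missing = [r for r in regions if r not in ct.columns]
    if missing:
        raise DomainError(f"unknown regions: {missing}")

    pair_sd = pd.DataFrame(np.nan, index=regions, columns=regions)
    skipped: list[tuple[str, str]] = []
    for i, rj in enumerate(regions):
        for rk in regions[i + 1 :]:
            d = (ct[rj] - ct[rk]).dropna()
            if len(d) < 2:
                skipped.append((rj, rk))
                continue
            sd = float(d.std(ddof=1))
            pair_sd.loc[rj, rk] = pair_sd.loc[rk, rj] = sd

    mean_sd = pair_sd.mean(axis=1, skipna=True)
    dropped = [r for r in regions if np.isnan(mean_sd[r])]
    if dropped:
        warnings.warn(
            f"regions with no valid pair dropped from dCt ranking: {dropped}",
            stacklevel=2,
        )
    kept = [r for r in regions if r not in dropped]
    ranking = sorted(kept, key=lambda r: (mean_sd[r], r))
    return DeltaCtResult(
        pair_sd=pair_sd,
        mean_sd=mean_sd.drop(index=dropped),
        ranking=ranking,
        skipped_pairs=skipped,
        dropped_regions=dropped,
    )


def screen_candidates(table: CtTable, regions=None, keep: int = 6) -> list[str]:
    """Select the ``keep`` most stable regions by dCt mean SD.

    This is the first stage of the two-stage screen: rank a large candidate
    panel without standard curves, keep the best few (default 6) for
    curve-based evaluation.
    """
    result = deltact_rank(table, regions)
    n = len(result.ranking)
    if not 3 <= keep <= n:
        raise DomainError(f"keep must be in [3, {n}], got {keep}")
    return result.ranking[:keep]


def iqr_prefilter(table: CtTable, regions=None) -> list[str]:
    """One region per gene symbol: the one with the narrowest Ct IQR.

    Optional pre-filter mirroring selection of a single representative
    amplicon per homologous gene group before dCt screening; avoids
    inflating apparent stability with trivially correlated homologues.
    Ties break lexicographically.
    """
    ct = table.ct_matrix(respect_mask=True)
    regions = list(regions) if regions is not None else list(ct.columns)
    by_gene: dict[str, list[str]] = {}
    for r in regions:
        by_gene.setdefault(table.regions[r].gene_symbol, []).append(r)
    chosen = []
    for gene in sorted(by_gene):
        candidates = by_gene[gene]
        iqr = {
            r: float(ct[r].quantile(0.75) - ct[r].quantile(0.25))
            for r in candidates
        }
        chosen.append(min(candidates, key=lambda r: (iqr[r], r)))
    return chosen
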