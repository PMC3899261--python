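"""geNorm: pairwise-variation gene-stability ranking.

For two regions j, k the pairwise variation V_jk is the sample standard
deviation (n-1 denominator) of log2(q_j / q_k) across samples; a region's
stability M_j is the mean of V_jk over all other active regions. The least
stable region (largest M) is eliminated and M recomputed, repeatedly, until
three remain. Because V_jk only sees ratios, any per-sample global scaling
(cDNA loading) cancels exactly.

The normalization factor NF_n is the per-sample geometric mean of the n most
stable regions; V_{n/n+1} — the SD of log2(NF_n / NF_{n+1}) — measures how
much adding the (n+1)-th gene changes the factor, with 0.15 the conventional
cutoff below which n genes are considered sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from .quantification import QuantityMatrix

DEFAULT_V_CUTOFF = 0.15


def pairwise_variation(q: QuantityMatrix, region_j: str, region_k: str) -> float:
    """V_jk = SD over samples of log2(q_j / q_k), pairwise-complete."""
    logq = q.log2()
    ratios = (logq[region_j] - logq[region_k]).dropna()
    if len(ratios) < 2:
        raise InsufficientDataError(
            f"<2 shared usable samples for pair ({region_j}, {region_k})"
        )
    return float(ratios.std(ddof=1))


def m_value(q: QuantityMatrix, region_j: str, active_set) -> float:
    """M_j = mean of V_jk over all k != j in the active set."""
    active = list(active_set)
    if len(active) < 3:
        raise DomainError("geNorm M requires an active set of >=3 regions")
    if region_j not in active:
        raise DomainError(f"{region_j!r} not in the active set")
    return float(
        np.mean([pairwise_variation(q, region_j, k) for k in active if k != region_j])
    )


def _m_all(logq: pd.DataFrame, active: list[str]) -> pd.Series:
    """M for every active region at once.

    Complete matrices use the covariance identity
    Var(x_j - x_k) = S_jj + S_kk - 2 S_jk (one covariance computation for
    all pairs); matrices with missing cells fall back to a pairwise-complete
    loop requiring >=2 shared samples per pair.
    """
    sub = logq[active]
    arr = sub.to_numpy(dtype=float)
    k = len(active)
    if not np.isnan(arr).any():
        if arr.shape[0] < 2:
            raise InsufficientDataError("geNorm needs >=2 samples")
        s = np.cov(arr, rowvar=False, ddof=1)
        diag = np.diag(s)
        v = np.sqrt(np.maximum(diag[:, None] + diag[None, :] - 2.0 * s, 0.0))
        np.fill_diagonal(v, np.nan)
        return pd.Series(np.nanmean(v, axis=1), index=active)
    v = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(a + 1, k):
            d = arr[:, a] - arr[:, b]
            d = d[~np.isnan(d)]
            if len(d) < 2:
                raise InsufficientDataError(
                    f"<2 shared usable samples for pair "
                    f"({active[a]}, {active[b]})"
                )
            v[a, b] = v[b, a] = d.std(ddof=1)
    return pd.Series(np.nanmean(v, axis=1), index=active)


@dataclass
class GenormResult:
    """Outcome of the stepwise geNorm elimination."""

    m_values: dict[str, float]          # M at the stage the region left (or final)
    elimination_order: list[str]        # least stable first
    final_trio: frozenset[str]
    final_trio_m: float                 # mean M of the retained trio
    ranking: list[str]                  # best-first; trio in lexicographic order
    v_curve: list[tuple[int, float]]    # (n, V_{n/n+1})
    sufficient_n: int | None
    trace: list[str]

    def ranking_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.ranking) + 1),
                "region": self.ranking,
                "m_value": [self.m_values[r] for r in self.ranking],
            }
        )

    def v_curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.v_curve, columns=["n", "v"])


def stepwise_rank(
    q: QuantityMatrix, v_cutoff: float = DEFAULT_V_CUTOFF
) -> GenormResult:
    """Rank regions by stepwise elimination of the highest-M region.

    Ties in M are broken by removing the lexicographically last display
    name (recorded in the trace). The retained trio is reported as a set
    with a single M (the mean of the three members' final M values), and the
    V_{n/n+1} curve is computed on the resulting best-first ordering.
    """
    logq = q.log2()
    active = list(q.region_names)
    if len(active) < 4:
        raise DomainError(
            "stepwise elimination needs >=4 regions; call m_value directly"
        )
    m_values: dict[str, float] = {}
    elimination: list[str] = []
    trace: list[str] = []
    while len(active) > 3:
        m = _m_all(logq, active)
        worst_m = m.max()
        # M values within 1e-12 are treated as tied (numerical noise floor)
        ties = sorted(m.index[np.isclose(m, worst_m, rtol=0, atol=1e-12)])
        victim = ties[-1]
        if len(ties) > 1:
            trace.append(
                f"tie at M={worst_m:.6f} among {ties}; removed {victim} "
                "(lexicographically last)"
            )
        trace.append(f"eliminated {victim} with M={m[victim]:.6f} "
                     f"({len(active)} regions active)")
        m_values[victim] = float(m[victim])
        elimination.append(victim)
        active.remove(victim)

    final_m = _m_all(logq, active)
    for r in active:
        m_values[r] = float(final_m[r])
    trio = frozenset(active)
    trio_m = float(final_m.mean())
    ranking = sorted(active) + list(reversed(elimination))

    v_curve, sufficient_n = v_pairwise_nf(q, ranking, cutoff=v_cutoff)
    return GenormResult(
        m_values=m_values,
        elimination_order=elimination,
        final_trio=trio,
        final_trio_m=trio_m,
        ranking=ranking,
        v_curve=v_curve,
        sufficient_n=sufficient_n,
        trace=trace,
    )


def normalization_factor(q: QuantityMatrix, regions, n: int | None = None) -> pd.Series:
    """Per-sample NF_n: geometric mean of the selected regions' quantities.

    A sample with any selected region missing gets a missing NF. Masked
    cells count as missing here as well (a masked reference should not feed
    a normalization factor).
    """
    regions = list(regions)
    if n is None:
        n = len(regions)
    if n != len(regions) or n < 2:
        raise DomainError(f"need n = |regions| >= 2, got n={n}, |regions|={len(regions)}")
    vals = q.usable()[regions]
    if ((vals <= 0) & vals.notna()).any().any():
        raise DomainError("normalization factor requires strictly positive quantities")
    nf = np.exp(np.log(vals).mean(axis=1, skipna=False))
    nf.name = f"NF_{n}"
    return nf


def v_pairwise_nf(
    q: QuantityMatrix, ranked_regions, cutoff: float = DEFAULT_V_CUTOFF
) -> tuple[list[tuple[int, float]], int | None]:
    """V_{n/n+1} curve over a best-first ranking, and the smallest sufficient n.

    V_{n/n+1} = SD over samples of log2(NF_n / NF_{n+1}) for n = 2 ..
    len(ranking)-1; ``sufficient_n`` is the smallest n with V below the
    cutoff (None if the curve never drops below it).
    """
    ranked = list(ranked_regions)
    if len(ranked) < 3:
        raise DomainError("V_{n/n+1} needs >=3 ranked regions")
    curve: list[tuple[int, float]] = []
    sufficient: int | None = None
    for n in range(2, len(ranked)):
        nf_n = normalization_factor(q, ranked[:n])
        nf_n1 = normalization_factor(q, ranked[: n + 1])
        d = np.log2(nf_n / nf_n1).dropna()
        if len(d) < 2:
            raise InsufficientDataError(f"<2 samples with complete NF_{n}/NF_{n+1}")
        v = float(d.std(ddof=1))
        curve.append((n, v))
        if sufficient is None and v < cutoff:
            sufficient = n
    return curve, sufficient
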