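"""NormFinder: model-based stability estimation.

Log quantities are modelled, within each sample group, as an additive
two-way layout

    y_igj = (gene level)_ig + (sample effect)_gj + e_igj,   Var(e_igj) = s2_ig,

so a gene's *intra-group* variation is its gene-specific residual variance
s2_ig, and its *inter-group* variation is the deviation d_ig of its
group-level expression from the gene's average across groups (centred over
genes within each group, so the d's sum to zero within a group). Per-sample
effects — cDNA loading — are absorbed by the sample term, which is why the
stability value is exactly invariant to global per-sample scaling.

Estimators
----------
With k genes and n_g samples in group g, let v_ig be the mean square of the
two-way residuals of gene i (denominator n_g - 1). Under gene-specific error
variances E[v_ig] = (1 - 2/k) s2_ig + s2bar_g / k, which inverts to the
bias-corrected, method-of-moments estimator

    s2hat_ig = k/(k-2) * (v_ig - vbar_g / (k-1)),     truncated at 0.

The raw group deviations dhat_ig are shrunk toward 0 by the normal-normal
factor gamma2 / (gamma2 + s2hat_ig / n_g), where gamma2 is a
method-of-moments estimate of the variance of the true d's. The per-group
stability of gene i is |dtilde_ig| + sqrt(s2hat_ig / n_g) — magnitude of
systematic bias plus intra-group standard error — and the reported rho_i
averages this over groups. Lower is more stable.

Single-group mode has no group deviations and reduces to ranking by the
corrected residual variance (rho_i = sqrt(s2hat_i)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from .quantification import QuantityMatrix


def two_way_residuals(z: np.ndarray) -> np.ndarray:
    """Residuals of the additive two-way layout: z - row means - col means + grand."""
    return z - z.mean(axis=1, keepdims=True) - z.mean(axis=0, keepdims=True) + z.mean()


def corrected_intra_variance(z: np.ndarray) -> np.ndarray:
    """Bias-corrected gene-specific residual variances for one group.

    ``z`` is genes x samples (log scale). Returns the untruncated estimates
    (callers truncate at 0 for reporting).
    """
    k, n = z.shape
    if k < 3:
        raise DomainError("variance decomposition needs >=3 genes")
    if n < 2:
        raise InsufficientDataError("variance decomposition needs >=2 samples")
    r = two_way_residuals(z)
    v = (r**2).sum(axis=1) / (n - 1)
    return k / (k - 2) * (v - v.mean() / (k - 1))


@dataclass
class NormfinderResult:
    """Stability values with the underlying variance decomposition."""

    mode: str                      # "multi_group" | "single_group"
    stability: pd.Series           # region -> rho, lower = more stable
    ranking: list[str]             # best-first
    intra_var: pd.DataFrame        # region x group, truncated s2hat
    inter_dev: pd.DataFrame        # region x group, raw dhat
    shrunk_dev: pd.DataFrame       # region x group, dtilde
    gamma2: float                  # estimated variance of true group deviations
    group_sizes: dict[str, int]
    dropped_regions: list[str] = field(default_factory=list)

    @property
    def best_region(self) -> str:
        return self.ranking[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.ranking) + 1),
                "region": self.ranking,
                "stability": [self.stability[r] for r in self.ranking],
            }
        )


def _complete_log_matrix(q: QuantityMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Regions x samples log2 matrix restricted to complete regions."""
    y = q.log2().T  # regions x samples
    dropped = [r for r in y.index if y.loc[r].isna().any()]
    if dropped:
        warnings.warn(
            f"NormFinder requires complete data; dropping regions with "
            f"missing or masked cells: {dropped}",
            stacklevel=3,
        )
        y = y.drop(index=dropped)
    return y, dropped


def normfinder_rank(q: QuantityMatrix, mode: str = "multi_group") -> NormfinderResult:
    """Rank regions by the NormFinder stability value.

    ``multi_group`` uses the sample->group map carried by the quantity
    matrix; ``single_group`` pools all samples into one group and ranks by
    corrected intra-group variance alone.
    """
    if mode not in ("multi_group", "single_group"):
        raise DomainError(f"unknown mode {mode!r}")
    y, dropped = _complete_log_matrix(q)
    regions = list(y.index)
    k = len(regions)
    if k < 3:
        raise InsufficientDataError(f"NormFinder needs >=3 usable regions, got {k}")

    if mode == "single_group":
        group_map = {s: "all" for s in y.columns}
    else:
        group_map = {s: q.groups[s] for s in y.columns}
    group_names = sorted(set(group_map.values()))
    if mode == "multi_group":
        if len(group_names) < 2:
            raise InsufficientDataError("multi_group mode needs >=2 groups")
        for g in group_names:
            n_g = sum(1 for s in y.columns if group_map[s] == g)
            if n_g < 2:
                raise InsufficientDataError(
                    f"group {g!r} has {n_g} sample(s); multi_group needs >=2 per group"
                )

    G = len(group_names)
    n_g: dict[str, int] = {}
    raw_s2 = pd.DataFrame(index=regions, columns=group_names, dtype=float)
    a = pd.DataFrame(index=regions, columns=group_names, dtype=float)
    for g in group_names:
        cols = [s for s in y.columns if group_map[s] == g]
        n_g[g] = len(cols)
        z = y[cols].to_numpy(dtype=float)
        raw_s2[g] = corrected_intra_variance(z)
        # gene means with sample effects removed; centred over genes
        gene_means = z.mean(axis=1)
        a[g] = gene_means - gene_means.mean()
    s2 = raw_s2.clip(lower=0.0)

    # inter-group deviation: centre each gene's a_ig across groups (equal weight)
    d = a.sub(a.mean(axis=1), axis=0)
    if mode == "single_group" or G == 1:
        d[:] = 0.0

    se2 = s2.div(pd.Series(n_g))  # s2hat_ig / n_g
    if G > 1:
        gamma2 = max(
            0.0,
            float((d**2).to_numpy().sum()) / ((G - 1) * (k - 1))
            - float(se2.to_numpy().mean()),
        )
    else:
        gamma2 = 0.0
    with np.errstate(invalid="ignore"):
        shrink = gamma2 / (gamma2 + se2) if gamma2 > 0 else se2 * 0.0
    d_tilde = d * shrink

    if mode == "single_group":
        # rank by (untruncated) corrected residual variance
        order_stat = raw_s2[group_names[0]]
        rho = np.sqrt(s2[group_names[0]])
        ranking = sorted(regions, key=lambda r: (order_stat[r], r))
    else:
        per_group = d_tilde.abs() + np.sqrt(se2)
        rho = per_group.mean(axis=1)
        ranking = sorted(regions, key=lambda r: (rho[r], r))
    rho = pd.Series(rho, index=regions, name="stability")

    return NormfinderResult(
        mode=mode,
        stability=rho,
        ranking=ranking,
        intra_var=s2,
        inter_dev=d,
        shrunk_dev=d_tilde,
        gamma2=gamma2,
        group_sizes=n_g,
        dropped_regions=dropped,
    )


def pair_stability(result: NormfinderResult, region_a: str, region_b: str) -> float:
    """Combined stability of averaging two regions' log quantities.

    The pair behaves like a pseudo-gene with group deviation
    (d_a + d_b)/2 — opposite-sign deviations cancel — and residual variance
    (s2_a + s2_b)/4 under independent errors; the same shrinkage and
    |bias| + standard-error formula then applies per group.
    """
    if result.mode != "multi_group":
        raise DomainError("pair selection is defined for multi_group results")
    n = pd.Series(result.group_sizes)
    s2_pair = (result.intra_var.loc[region_a] + result.intra_var.loc[region_b]) / 4.0
    d_pair = (result.inter_dev.loc[region_a] + result.inter_dev.loc[region_b]) / 2.0
    se2 = s2_pair / n
    g2 = result.gamma2
    shrink = g2 / (g2 + se2) if g2 > 0 else se2 * 0.0
    per_group = (d_pair * shrink).abs() + np.sqrt(se2)
    return float(per_group.mean())


def best_pair(result: NormfinderResult) -> tuple[str, str, float]:
    """Pair of regions minimising the combined stability value.

    Returns (region_a, region_b, stability) with the pair in lexicographic
    order; (a, b) and (b, a) are the same pair.
    """
    if result.mode != "multi_group":
        raise DomainError("best_pair requires a multi_group result")
    regions = list(result.stability.index)
    if len(regions) < 2:
        raise InsufficientDataError("best_pair needs >=2 regions")
    best: tuple[str, str, float] | None = None
    for i, ra in enumerate(regions):
        for rb in regions[i + 1 :]:
            a, b = sorted((ra, rb))
            s = pair_stability(result, a, b)
            if best is None or s < best[2] or (s == best[2] and (a, b) < best[:2]):
                best = (a, b, s)
    assert best is not None
    return best
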