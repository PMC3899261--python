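"""End-to-end orchestration of the reference-gene validation study.

The two-stage screen: (1) rank a large candidate panel with the
curve-free dCt statistic and keep the best few; (2) quantify the kept
regions via standard curves and rank them with geNorm and NormFinder,
overall and per sample group; (3) build the normalization factor NF_n from
the geNorm trio, check V_{n/n+1} against the sufficiency cutoff; (4)
normalize target genes and compare best- vs worst-reference normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import deltact as dct
from . import genorm as gn
from . import normfinder as nf
from .data import (
    CtTable,
    apply_mask,
    collapse_replicates,
    subset_regions as _subset_regions,
    subset_samples as _subset_samples,
)
from .errors import ConfigurationError, InsufficientDataError
from .quantification import QuantityMatrix, fit_curves_from_frame, curves_to_frame, quantify


class StudyConfig(BaseModel):
    """Run configuration for the screening pipeline."""

    mask: list[tuple[str, str]] = Field(default_factory=list)
    methods: list[str] = Field(default=["deltact", "genorm", "normfinder"])
    nf_size: int = Field(default=3, ge=2)
    v_cutoff: float = Field(default=gn.DEFAULT_V_CUTOFF, gt=0)
    keep: int | None = 6            # None = keep all (skip stage-1 selection)
    collapse_policy: str = "mean"
    max_spread: float = 1.0
    per_group: bool = True
    seed: int = 0


@dataclass
class PipelineReport:
    """Consolidated result of one pipeline run."""

    config: StudyConfig
    deltact_overall: dct.DeltaCtResult
    deltact_per_group: dict[str, dct.DeltaCtResult]
    kept_regions: list[str]
    curves: pd.DataFrame
    genorm_overall: gn.GenormResult
    genorm_per_group: dict[str, gn.GenormResult]
    normfinder_overall: nf.NormfinderResult | None
    normfinder_per_group: dict[str, nf.NormfinderResult]
    normfinder_best_pair: tuple[str, str, float] | None
    nf_regions: list[str]
    nf_values: pd.Series
    v_3_4: float | None
    sufficient_n: int | None
    verdict: str
    quantities: QuantityMatrix = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        g = self.genorm_overall
        return {
            "config": self.config.model_dump(),
            "deltact": {
                "ranking": self.deltact_overall.ranking,
                "mean_sd": {
                    r: round(float(v), 10)
                    for r, v in self.deltact_overall.mean_sd.items()
                },
            },
            "kept_regions": self.kept_regions,
            "standard_curves": self.curves.round(10).to_dict(orient="records"),
            "genorm": {
                "ranking": g.ranking,
                "m_values": {r: round(float(v), 10) for r, v in g.m_values.items()},
                "final_trio": sorted(g.final_trio),
                "final_trio_m": round(g.final_trio_m, 10),
                "elimination_order": g.elimination_order,
                "v_curve": [[n, round(v, 10)] for n, v in g.v_curve],
                "sufficient_n": g.sufficient_n,
            },
            "normfinder": None
            if self.normfinder_overall is None
            else {
                "ranking": self.normfinder_overall.ranking,
                "stability": {
                    r: round(float(v), 10)
                    for r, v in self.normfinder_overall.stability.items()
                },
                "best_region": self.normfinder_overall.best_region,
                "best_pair": None
                if self.normfinder_best_pair is None
                else [
                    self.normfinder_best_pair[0],
                    self.normfinder_best_pair[1],
                    round(self.normfinder_best_pair[2], 10),
                ],
            },
            "normalization": {
                "regions": self.nf_regions,
                "nf": {s: round(float(v), 10) for s, v in self.nf_values.items()},
                "v_3_4": None if self.v_3_4 is None else round(self.v_3_4, 10),
                "sufficient_n": self.sufficient_n,
                "verdict": self.verdict,
            },
        }

    def write(self, outdir) -> None:
        """Write report.json, report.md and ranking CSVs (deterministic)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        self.deltact_overall.to_frame().to_csv(
            outdir / "deltact_ranking.csv", index=False, float_format="%.10g"
        )
        self.genorm_overall.ranking_frame().to_csv(
            outdir / "genorm_ranking.csv", index=False, float_format="%.10g"
        )
        self.genorm_overall.v_curve_frame().to_csv(
            outdir / "genorm_v_curve.csv", index=False, float_format="%.10g"
        )
        if self.normfinder_overall is not None:
            self.normfinder_overall.to_frame().to_csv(
                outdir / "normfinder_ranking.csv", index=False, float_format="%.10g"
            )
        self.curves.to_csv(
            outdir / "standard_curves.csv", index=False, float_format="%.10g"
        )
        with open(outdir / "report.md", "w") as fh:
            fh.write(self._markdown())

    def _markdown(self) -> str:
        lines = ["# Reference-gene validation report", ""]
        lines += ["## Stage 1 — dCt screen", ""]
        lines.append(self.deltact_overall.to_frame().to_string(index=False))
        lines += ["", f"Kept for curve-based evaluation: {', '.join(self.kept_regions)}", ""]
        lines += ["## Stage 3 — geNorm", ""]
        lines.append(self.genorm_overall.ranking_frame().to_string(index=False))
        lines += [
            "",
            f"Final trio: {', '.join(sorted(self.genorm_overall.final_trio))} "
            f"(M = {self.genorm_overall.final_trio_m:.3f})",
            "",
        ]
        if self.normfinder_overall is not None:
            lines += ["## Stage 3 — NormFinder", ""]
            lines.append(self.normfinder_overall.to_frame().to_string(index=False))
            if self.normfinder_best_pair is not None:
                a, b, s = self.normfinder_best_pair
                lines += ["", f"Best pair: {a} + {b} (stability {s:.3f})", ""]
        lines += ["## Stage 4 — normalization factor", ""]
        lines += [
            f"NF_{len(self.nf_regions)} regions: {', '.join(self.nf_regions)}",
            "",
            f"Verdict: {self.verdict}",
            "",
        ]
        return "\n".join(lines)


def run_screening_pipeline(
    table: CtTable, dilution_series: pd.DataFrame, config: StudyConfig | None = None
) -> PipelineReport:
    """Run the full two-stage screen on a raw (well-level) Ct table."""
    config = config or StudyConfig()
    collapsed = collapse_replicates(
        table, policy=config.collapse_policy, max_spread=config.max_spread
    )
    if config.mask:
        collapsed = apply_mask(collapsed, config.mask)

    # stage 1: curve-free dCt screen
    delta = dct.deltact_rank(collapsed)
    delta_groups: dict[str, dct.DeltaCtResult] = {}
    if config.per_group:
        for g, members in collapsed.groups.items():
            if len(members) >= 2:
                sub = _subset_samples(collapsed, members)
                delta_groups[g] = dct.deltact_rank(sub)
    if config.keep is None:
        kept = list(delta.ranking)
    else:
        kept = dct.screen_candidates(collapsed, keep=config.keep)

    # stage 2: standard-curve quantification of the kept panel
    dil = dilution_series[dilution_series["region"].isin(kept)]
    curves = fit_curves_from_frame(dil)
    missing = set(kept) - set(curves)
    if missing:
        raise ConfigurationError(f"no dilution series for kept regions: {sorted(missing)}")
    kept_table = _subset_regions(collapsed, kept)
    q = quantify(kept_table, curves)

    # stage 3: geNorm + NormFinder, overall and per group
    genorm_overall = gn.stepwise_rank(q, v_cutoff=config.v_cutoff)
    genorm_groups: dict[str, gn.GenormResult] = {}
    if config.per_group:
        for g, members in _groups_of(q).items():
            if len(members) >= 2:
                try:
                    genorm_groups[g] = gn.stepwise_rank(
                        q.subset_samples(members), v_cutoff=config.v_cutoff
                    )
                except InsufficientDataError:
                    continue
    normfinder_overall = None
    best_pair = None
    try:
        normfinder_overall = nf.normfinder_rank(q, mode="multi_group")
        best_pair = nf.best_pair(normfinder_overall)
    except InsufficientDataError:
        pass
    normfinder_groups: dict[str, nf.NormfinderResult] = {}
    if config.per_group:
        for g, members in _groups_of(q).items():
            if len(members) >= 2:
                try:
                    normfinder_groups[g] = nf.normfinder_rank(
                        q.subset_samples(members), mode="single_group"
                    )
                except InsufficientDataError:
                    continue

    # stage 4: NF from the geNorm trio, sufficiency verdict
    nf_regions = genorm_overall.ranking[: config.nf_size]
    nf_values = gn.normalization_factor(q, nf_regions)
    v34 = dict(genorm_overall.v_curve).get(3)
    sufficient = genorm_overall.sufficient_n
    if v34 is not None and v34 < config.v_cutoff:
        verdict = "3 genes sufficient"
    elif v34 is None:
        verdict = "V_3/4 not computable"
    else:
        verdict = (
            f"V_3/4 = {v34:.3f} >= cutoff {config.v_cutoff}; "
            f"smallest sufficient n = {sufficient}"
        )

    return PipelineReport(
        config=config,
        deltact_overall=delta,
        deltact_per_group=delta_groups,
        kept_regions=kept,
        curves=curves_to_frame(curves),
        genorm_overall=genorm_overall,
        genorm_per_group=genorm_groups,
        normfinder_overall=normfinder_overall,
        normfinder_per_group=normfinder_groups,
        normfinder_best_pair=best_pair,
        nf_regions=nf_regions,
        nf_values=nf_values,
        v_3_4=None if v34 is None else float(v34),
        sufficient_n=sufficient,
        verdict=verdict,
        quantities=q,
    )


def _groups_of(q: QuantityMatrix) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for s in q.sample_ids:
        out.setdefault(q.groups[s], []).append(s)
    return out


# -- target normalization ------------------------------------------------------


@dataclass
class NormalizedExpression:
    """A target region's expression divided by the reference NF."""

    target_region: str
    reference_set: list[str]
    values: pd.Series            # per-sample normalized quantity
    group_means: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return self.values.rename("normalized").to_frame()


def normalize_target(
    q: QuantityMatrix, target_region: str, reference_set
) -> NormalizedExpression:
    """normalized(sample) = q_target / NF over the reference set.

    Uses raw (mask-ignoring) quantities for the target — masking governs
    stability ranking, not quantification — but missing components make the
    sample's normalized value missing.
    """
    refs = list(reference_set)
    if target_region in refs:
        raise ConfigurationError("target region must not be in the reference set")
    if target_region not in q.values.columns:
        raise ConfigurationError(f"unknown target region {target_region!r}")
    nf_vals = _nf_raw(q, refs)
    values = q.values[target_region] / nf_vals
    values.name = target_region
    groups = pd.Series(q.groups)
    group_means = values.groupby(groups).mean()
    group_means.index.name = "group"
    return NormalizedExpression(target_region, refs, values, group_means)


def _nf_raw(q: QuantityMatrix, refs: list[str]) -> pd.Series:
    """Geometric-mean NF on raw values (mask ignored; NaN propagates)."""
    if len(refs) < 2:
        raise ConfigurationError("reference set must have >=2 regions")
    vals = q.values[refs]
    if ((vals <= 0) & vals.notna()).any().any():
        raise ConfigurationError("reference quantities must be strictly positive")
    return np.exp(np.log(vals).mean(axis=1, skipna=False))


@dataclass
class RobustnessComparison:
    """Best- vs worst-reference normalization of the same target."""

    target_region: str
    best: NormalizedExpression
    worst: NormalizedExpression
    ratio: pd.Series                  # worst-normalized / best-normalized
    fold_range: float                 # max/min of ratio
    median_fold_offset: float
    group_log_correlation: dict[str, float]


def robustness_compare(
    q: QuantityMatrix, target_region: str, best_set, worst_set
) -> RobustnessComparison:
    """Quantify how much the reference choice distorts a target's profile.

    Reports the per-sample ratio of the two normalizations (its median is
    the systematic fold offset; max/min its spread) and, per group, the
    Pearson correlation of the two log-scale normalized profiles — high
    correlation with a non-unit offset is the scale-shift-without-rank-
    distortion signature.
    """
    best_set, worst_set = list(best_set), list(worst_set)
    if len(best_set) < 2 or len(worst_set) < 2:
        raise ConfigurationError("both reference sets need >=2 regions")
    if target_region in best_set or target_region in worst_set:
        raise ConfigurationError("target region overlaps a reference set")
    best = normalize_target(q, target_region, best_set)
    worst = normalize_target(q, target_region, worst_set)
    ratio = (worst.values / best.values).dropna()
    groups = pd.Series(q.groups)
    corr: dict[str, float] = {}
    for g, members in _groups_of(q).items():
        b = np.log2(best.values[members]).dropna()
        w = np.log2(worst.values[members]).dropna()
        shared = b.index.intersection(w.index)
        if len(shared) >= 3 and b[shared].std() > 0 and w[shared].std() > 0:
            corr[g] = float(np.corrcoef(b[shared], w[shared])[0, 1])
    return RobustnessComparison(
        target_region=target_region,
        best=best,
        worst=worst,
        ratio=ratio,
        fold_range=float(ratio.max() / ratio.min()),
        median_fold_offset=float(ratio.median()),
        group_log_correlation=corr,
    )


def cv_of_normalized(q: QuantityMatrix, reference_set) -> pd.Series:
    """Coefficient of variation of each reference after self-normalization.

    Each reference region's quantities are divided by the NF built from the
    *full* reference set, and CV = SD/mean taken across samples; the index
    additionally carries a ``"mean"`` entry averaging the per-region CVs.
    Per-sample loading cancels exactly, so the CV measures residual
    post-normalization variation of each reference.
    """
    refs = list(reference_set)
    if len(refs) < 2:
        raise ConfigurationError("reference set must have >=2 regions")
    nf_vals = _nf_raw(q, refs)
    out = {}
    for r in refs:
        norm = (q.values[r] / nf_vals).dropna()
        out[r] = float(norm.std(ddof=1) / norm.mean()) if len(norm) > 1 else np.nan
    cv = pd.Series(out, name="cv")
    cv["mean"] = float(cv.mean())
    return cv
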