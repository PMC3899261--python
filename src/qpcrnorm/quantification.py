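"""Standard-curve quantification and the CDS/3'-UTR template-amount ratio.

A dilution series of known relative template quantities (the study design is
five decade steps: 100, 10, 1, 0.1, 0.01) gives the linear calibration

    Ct = intercept + slope * log10(quantity),

from which the per-cycle amplification efficiency is E = 10^(-1/slope) - 1
(E = 1 means perfect doubling, slope -3.3219). Unknown Cts invert the line:
quantity = 10^((Ct - intercept) / slope).

The template-amount ratio between two amplicons of the same gene uses the
exponential-amplification inversion Q0 = T / (1+E)^Ct, with T the fixed
fluorescence threshold (Rn, default 0.3); the ratio Q0_cds / Q0_utr measures
how much more (or less) CDS-region template the reverse-transcription step
produced relative to the 3'-UTR region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CtTable, GeneRegion
from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidCurveError,
)

#: instrument fluorescence threshold used for Q0 computations
DEFAULT_THRESHOLD_RN = 0.3

#: default dilution design: five decade steps
DEFAULT_DILUTIONS = (100.0, 10.0, 1.0, 0.1, 0.01)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution regression for one gene region."""

    region: GeneRegion
    slope: float
    intercept: float
    r_squared: float
    dilution_points: tuple[tuple[float, float], ...]

    @property
    def efficiency(self) -> float:
        """Per-cycle fractional gain E = 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def ct_of(self, quantity) -> np.ndarray | float:
        return self.intercept + self.slope * np.log10(quantity)

    def quantity_of(self, ct) -> np.ndarray | float:
        return 10.0 ** ((np.asarray(ct, dtype=float) - self.intercept) / self.slope)


def fit_standard_curve(series, region: GeneRegion) -> StandardCurve:
    """Least-squares fit of Ct against log10(quantity).

    ``series`` is an iterable of (nominal_quantity, Ct) pairs; replicate Cts
    at a dilution step may simply appear as repeated pairs.
    """
    pts = [(float(q), float(ct)) for q, ct in series]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"standard curve for {region.display_name} needs >=3 points, got {len(pts)}"
        )
    q = np.array([p[0] for p in pts])
    ct = np.array([p[1] for p in pts])
    if (q <= 0).any():
        raise InvalidCurveError("nominal quantities must be strictly positive")
    x = np.log10(q)
    if np.allclose(x, x[0]):
        raise InsufficientDataError("dilution quantities are all equal")
    fit = stats.linregress(x, ct)
    if fit.slope >= 0:
        raise InvalidCurveError(
            f"standard curve for {region.display_name} has non-negative slope "
            f"{fit.slope:.4f}; Ct must decrease with template amount"
        )
    return StandardCurve(
        region=region,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        dilution_points=tuple(pts),
    )


def fit_curves_from_frame(df: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one curve per region from a (region, nominal_quantity, ct) frame."""
    out = {}
    for name, grp in df.groupby("region", sort=False):
        out[name] = fit_standard_curve(
            zip(grp["nominal_quantity"], grp["ct"]),
            GeneRegion.from_display_name(name),
        )
    return out


def curves_to_frame(curves: dict[str, StandardCurve]) -> pd.DataFrame:
    """Export fitted curves as a tidy frame (slope, intercept, efficiency, r2)."""
    return pd.DataFrame(
        [
            {
                "region": name,
                "slope": c.slope,
                "intercept": c.intercept,
                "efficiency": c.efficiency,
                "r_squared": c.r_squared,
            }
            for name, c in curves.items()
        ]
    )


@dataclass
class QuantityMatrix:
    """Relative expression quantities (samples x regions) with mask carried over.

    ``values`` is a float DataFrame (NaN = missing / undetermined);
    ``mask`` a boolean DataFrame of the same shape (True = excluded from
    stability ranking); ``groups`` maps sample_id -> group_id;
    ``provenance`` records per region whether the quantity came from a fitted
    standard curve or an assumed efficiency.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    groups: dict[str, str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise ConfigurationError("values and mask must share index/columns")
        bad = (self.values <= 0) & ~self.mask & self.values.notna()
        if bad.any().any():
            raise ConfigurationError("unmasked quantities must be strictly positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_names(self) -> list[str]:
        return list(self.values.columns)

    def usable(self) -> pd.DataFrame:
        """Values with masked cells set to NaN (stability-analysis view)."""
        return self.values.mask(self.mask)

    def log2(self) -> pd.DataFrame:
        """log2 of the usable quantities."""
        return np.log2(self.usable())

    def subset_samples(self, sample_ids) -> "QuantityMatrix":
        sample_ids = list(sample_ids)
        return QuantityMatrix(
            self.values.loc[sample_ids].copy(),
            self.mask.loc[sample_ids].copy(),
            {s: self.groups[s] for s in sample_ids},
            dict(self.provenance),
        )

    def subset_regions(self, regions) -> "QuantityMatrix":
        regions = list(regions)
        return QuantityMatrix(
            self.values[regions].copy(),
            self.mask[regions].copy(),
            dict(self.groups),
            {r: p for r, p in self.provenance.items() if r in regions},
        )


def quantify(
    table: CtTable,
    curves: dict[str, StandardCurve],
    assumed_efficiencies: dict[str, float] | None = None,
) -> QuantityMatrix:
    """Convert a (collapsed) CtTable to relative quantities.

    Regions with a fitted curve use quantity = 10^((Ct - intercept)/slope).
    A region without a curve may fall back to an assumed efficiency E, using
    quantity = (1+E)^(mean_Ct - Ct) anchored at the region's mean Ct (the
    anchor is irrelevant: every downstream statistic is invariant to a
    per-region scale factor). Undetermined cells become missing.
    """
    assumed_efficiencies = assumed_efficiencies or {}
    ct = table.ct_matrix()
    values = pd.DataFrame(np.nan, index=ct.index, columns=ct.columns)
    provenance: dict[str, str] = {}
    for region in ct.columns:
        col = ct[region]
        if region in curves:
            values[region] = curves[region].quantity_of(col)
            provenance[region] = "from_standard_curve"
        elif region in assumed_efficiencies:
            e = assumed_efficiencies[region]
            anchor = col.mean(skipna=True)
            values[region] = (1.0 + e) ** (anchor - col)
            provenance[region] = "assumed_efficiency"
        else:
            raise ConfigurationError(
                f"region {region!r} has no standard curve and no assumed efficiency"
            )
    groups = {s: table.samples[s].group_id for s in table.sample_ids}
    return QuantityMatrix(values, table.mask_frame(), groups, provenance)


@dataclass
class TemplateRatio:
    """Per-sample CDS/3'-UTR initial-template ratio with group summaries."""

    gene_symbol: str
    cds_region: str
    utr_region: str
    per_sample_ratio: pd.Series
    group_summary: pd.DataFrame  # index group, columns mean/sd/n


def q0(ct, efficiency: float, threshold_rn: float = DEFAULT_THRESHOLD_RN):
    """Initial template amount Q0 = T / (1+E)^Ct."""
    return threshold_rn / (1.0 + efficiency) ** np.asarray(ct, dtype=float)


def template_ratio(
    table: CtTable,
    cds_region: str,
    utr_region: str,
    efficiencies: dict[str, float],
    threshold_rn: float = DEFAULT_THRESHOLD_RN,
) -> TemplateRatio:
    """Ratio of initial template amounts between two amplicons of one gene.

    Per sample: ratio = Q0(Ct_cds, E_cds) / Q0(Ct_utr, E_utr). The threshold
    T cancels when shared, but is carried explicitly in both terms. Group
    means and SDs (n-1) are computed over unmasked samples only.
    """
    for r in (cds_region, utr_region):
        if r not in table.regions:
            raise ConfigurationError(f"region {r!r} not in table")
        if r not in efficiencies:
            raise ConfigurationError(f"no efficiency for region {r!r}")
        if not 0.5 < efficiencies[r] < 1.5:
            raise ConfigurationError(
                f"efficiency for {r!r} must lie in (0.5, 1.5), got {efficiencies[r]}"
            )
    ct = table.ct_matrix()
    shared = ct.index[ct[cds_region].notna() & ct[utr_region].notna()]
    if len(shared) == 0:
        raise InsufficientDataError(
            f"no shared samples between {cds_region} and {utr_region}"
        )
    num = q0(ct.loc[shared, cds_region], efficiencies[cds_region], threshold_rn)
    den = q0(ct.loc[shared, utr_region], efficiencies[utr_region], threshold_rn)
    ratio = pd.Series(num / den, index=shared, name="ratio")

    maskf = table.mask_frame()
    usable = shared[
        ~maskf.loc[shared, cds_region] & ~maskf.loc[shared, utr_region]
    ]
    groups = pd.Series({s: table.group_of(s) for s in usable})
    summary = (
        ratio.loc[usable]
        .groupby(groups)
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
    )
    summary.index.name = "group"
    gene = table.regions[cds_region].gene_symbol
    return TemplateRatio(gene, cds_region, utr_region, ratio, summary)
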