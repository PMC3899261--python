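"""Synthetic Ct-data generator with known ground truth.

Emulates a reference-gene validation study at the Ct level: a panel of gene
regions measured over grouped tissue samples in replicate wells, plus decade
dilution series for standard curves. The generative model is additive on the
cycle scale (hence multiplicative, log-normal, on quantities — the error
structure qPCR statistics assume):

    Ct(sample, region, well) = base_ct
                             + group_shift(region, group)
                             + sample_shift(region, sample)      [optional]
                             + loading(sample)                   ~ N(0, loading_sd)
                             + gene_noise(sample, region)        ~ N(0, noise_sd)
                             + well_noise(well)                  ~ N(0, replicate_sd)
                             + rt_bias(group)  if region is CDS and group biased

``loading`` is the per-sample global pipetting/cDNA-input effect every
stability statistic must cancel; ``rt_bias`` models the oligo-dT
reverse-transcription depletion of CDS-distal template as a fixed extra
cycle count. Dilution series follow each region's true efficiency:
Ct(q) = base_ct - log10(q) / log10(1 + E) + well noise.

All draws derive from the spec's seed; the same spec yields the same tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .data import CtTable, GeneRegion, SampleMeta
from .quantification import DEFAULT_DILUTIONS


class RegionSpec(BaseModel):
    """Generative parameters for one gene region."""

    gene_symbol: str
    region_label: str
    base_ct: float = Field(gt=10, lt=40)
    noise_sd: float = Field(default=0.2, ge=0)
    group_shifts: dict[str, float] = Field(default_factory=dict)
    sample_shifts: tuple[float, ...] | None = None
    efficiency: float = Field(default=1.0, gt=0.5, lt=1.5)

    @property
    def display_name(self) -> str:
        return f"{self.gene_symbol}_{self.region_label}"


class SimSpec(BaseModel):
    """Full design of a synthetic study."""

    groups: dict[str, int]  # group -> number of samples, in order
    regions: list[RegionSpec]
    loading_sd: float = Field(default=0.3, ge=0)
    replicate_sd: float = Field(default=0.15, ge=0)
    n_replicates: int = Field(default=3, ge=1)
    rt_bias: dict[str, float] = Field(default_factory=dict)
    dilutions: tuple[float, ...] = DEFAULT_DILUTIONS
    dilution_replicates: int = Field(default=3, ge=1)
    seed: int = 0

    @field_validator("groups")
    @classmethod
    def _groups_positive(cls, v):
        for g, n in v.items():
            if n < 1:
                raise ValueError(f"groups[{g!r}] must be >= 1, got {n}")
        return v

    @field_validator("dilutions")
    @classmethod
    def _dilutions_positive(cls, v):
        if any(q <= 0 for q in v):
            raise ValueError("dilutions must be strictly positive")
        return v

    @model_validator(mode="after")
    def _check_refs(self):
        names = [r.display_name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("regions: display names must be unique")
        n_samples = sum(self.groups.values())
        for r in self.regions:
            for g in r.group_shifts:
                if g not in self.groups:
                    raise ValueError(
                        f"regions[{r.display_name}].group_shifts references "
                        f"unknown group {g!r}"
                    )
            if r.sample_shifts is not None and len(r.sample_shifts) != n_samples:
                raise ValueError(
                    f"regions[{r.display_name}].sample_shifts must have "
                    f"{n_samples} entries"
                )
        for g in self.rt_bias:
            if g not in self.groups:
                raise ValueError(f"rt_bias references unknown group {g!r}")
        return self

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}{i + 1}" for g, n in self.groups.items() for i in range(n)]

    def cds_mask_pairs(self) -> frozenset[tuple[str, str]]:
        """(group, region) pairs where rt_bias depresses CDS template.

        These are the cells an analysis should mask from stability ranking,
        because the biased RT chemistry makes them non-comparable.
        """
        return frozenset(
            (g, r.display_name)
            for g in self.rt_bias
            for r in self.regions
            if r.region_label == "cds"
        )


@dataclass
class GroundTruth:
    """What the generator actually injected, for parameter-recovery tests."""

    stability_score: pd.Series       # region -> true instability (cycles)
    stability_order: list[str]       # most stable first
    efficiencies: dict[str, float]
    group_shifts: pd.DataFrame       # region x group
    loading: pd.Series               # sample -> latent loading effect


@dataclass
class SimulationResult:
    table: CtTable
    dilution_series: pd.DataFrame    # columns region, nominal_quantity, replicate, ct
    truth: GroundTruth


def _true_stability(spec: SimSpec) -> pd.Series:
    """Instability score: gene noise plus sample-size-weighted shift dispersion.

    Shifts include the RT bias on CDS regions, since a stability statistic
    run without masking would see that bias as group-level variation.
    """
    weights = np.array([n for n in spec.groups.values()], dtype=float)
    weights = weights / weights.sum()
    scores = {}
    for r in spec.regions:
        shifts = np.array(
            [
                r.group_shifts.get(g, 0.0)
                + (spec.rt_bias.get(g, 0.0) if r.region_label == "cds" else 0.0)
                for g in spec.groups
            ]
        )
        mean_shift = float(weights @ shifts)
        shift_var = float(weights @ (shifts - mean_shift) ** 2)
        extra = 0.0
        if r.sample_shifts is not None:
            extra = float(np.var(np.asarray(r.sample_shifts)))
        scores[r.display_name] = float(np.sqrt(r.noise_sd**2 + shift_var + extra))
    return pd.Series(scores, name="true_instability")


def simulate(spec: SimSpec) -> SimulationResult:
    """Draw a full synthetic dataset (Ct table + dilution series) from a spec."""
    rng = np.random.default_rng(spec.seed)
    sample_ids = spec.sample_ids
    group_of = {
        sid: g for g, n in spec.groups.items() for sid in [f"{g}{i + 1}" for i in range(n)]
    }
    loading = pd.Series(
        rng.normal(0.0, spec.loading_sd, size=len(sample_ids)), index=sample_ids
    )

    rows = []
    for r in spec.regions:
        for s_idx, sid in enumerate(sample_ids):
            g = group_of[sid]
            mu = (
                r.base_ct
                + r.group_shifts.get(g, 0.0)
                + (r.sample_shifts[s_idx] if r.sample_shifts is not None else 0.0)
                + loading[sid]
                + rng.normal(0.0, r.noise_sd)
                + (spec.rt_bias.get(g, 0.0) if r.region_label == "cds" else 0.0)
            )
            for w in range(1, spec.n_replicates + 1):
                rows.append(
                    (sid, r.display_name, w, mu + rng.normal(0.0, spec.replicate_sd))
                )
    entries = pd.DataFrame(rows, columns=["sample_id", "region", "replicate", "ct"])
    entries["qc_warning"] = False

    samples = {
        sid: SampleMeta(
            sid,
            group_of[sid],
            "oligo_dT" if group_of[sid] in spec.rt_bias else "random_hexamer",
        )
        for sid in sample_ids
    }
    regions = {
        r.display_name: GeneRegion(r.gene_symbol, r.region_label) for r in spec.regions
    }
    table = CtTable(entries, samples, regions)

    dil_rows = []
    for r in spec.regions:
        slope = -1.0 / np.log10(1.0 + r.efficiency)
        for q in spec.dilutions:
            mu = r.base_ct + slope * np.log10(q)
            for w in range(1, spec.dilution_replicates + 1):
                dil_rows.append(
                    (r.display_name, q, w, mu + rng.normal(0.0, spec.replicate_sd))
                )
    dilution = pd.DataFrame(
        dil_rows, columns=["region", "nominal_quantity", "replicate", "ct"]
    )

    score = _true_stability(spec)
    truth = GroundTruth(
        stability_score=score,
        stability_order=sorted(score.index, key=lambda r: (score[r], r)),
        efficiencies={r.display_name: r.efficiency for r in spec.regions},
        group_shifts=pd.DataFrame(
            {
                g: {r.display_name: r.group_shifts.get(g, 0.0) for r in spec.regions}
                for g in spec.groups
            }
        ),
        loading=loading,
    )
    return SimulationResult(table, dilution, truth)


# -- presets -------------------------------------------------------------------

#: (gene, label, base_ct, noise_sd, group_shifts) for the 17-region panel.
#: Base Cts span ~21-29 cycles (strongest: HIS_cds; weakest: bTUB_utr2);
#: noise and group shifts encode a stable core (SAND/TIP/HIS_cds) and an
#: unstable tail (bTUB_utr2/3, ACT_utr2) with tissue-dependent expression.
_PAPER_LIKE_REGIONS = [
    ("bTUB", "utr1", 23.0, 0.35, {"FO": 0.4}),
    ("bTUB", "utr2", 29.0, 0.60, {"FB": -1.2, "FO": 0.8, "FF": 0.6}),
    ("bTUB", "utr3", 24.0, 0.55, {"FB": -0.9, "FO": 0.7}),
    ("HIS", "cds", 21.0, 0.15, {}),
    ("HIS", "utr1", 22.0, 0.25, {"FO": 0.3}),
    ("HIS", "utr2", 24.0, 0.35, {"FS": 0.6}),
    ("EF1a", "cds", 21.5, 0.25, {"FB": 0.3}),
    ("EF1a", "utr1", 22.0, 0.22, {}),
    ("EF1a", "utr2", 22.5, 0.25, {}),
    ("GAP", "utr1", 23.0, 0.30, {"FF": 0.4}),
    ("GAP", "utr2", 22.0, 0.35, {"FB": 0.5}),
    ("ACT", "utr1", 22.0, 0.30, {"FO": -0.3}),
    ("ACT", "utr2", 23.5, 0.55, {"FB": 0.8, "FF": -0.7}),
    ("ANX", "cds", 23.0, 0.40, {"FF": 0.5}),
    ("ANX", "utr", 23.0, 0.35, {"FF": 0.4}),
    ("SAND", "utr", 25.0, 0.15, {}),
    ("TIP", "utr", 26.0, 0.18, {}),
]

#: amplification-efficiency bounds reported for the study's primer panel
EFFICIENCY_RANGE = (0.91, 1.12)

#: study design: four tissue groups with 4/6/4/2 samples (16 total)
PAPER_LIKE_GROUPS = {"FB": 4, "FO": 6, "FF": 4, "FS": 2}


def preset_paper_like(seed: int = 0) -> SimSpec:
    """The study-like design: 16 samples in 4 groups x 17 gene regions.

    Groups FB (flower bud, 4), FO (flower organs, 6), FF (fruit flesh, 4)
    and FS (fruit skin, 2); three replicate wells; decade dilution series;
    per-region efficiencies drawn uniformly in [0.91, 1.12]; and a +1 cycle
    RT bias on CDS amplicons in FB (oligo-dT primed), which depresses the
    apparent CDS template to roughly half of the 3'-UTR level.
    """
    rng = np.random.default_rng(seed)
    # one efficiency per gene, shared by its amplicons: overlapping amplicons
    # of the same transcript amplify comparably, and a shared value keeps the
    # CDS/UTR template-ratio readout from conflating primer-efficiency
    # differences with the RT-bias effect the design isolates
    genes = sorted({g for g, *_ in _PAPER_LIKE_REGIONS})
    eff_by_gene = dict(
        zip(genes, rng.uniform(*EFFICIENCY_RANGE, size=len(genes)))
    )
    regions = [
        RegionSpec(
            gene_symbol=gene,
            region_label=label,
            base_ct=base,
            noise_sd=noise,
            group_shifts=shifts,
            efficiency=float(eff_by_gene[gene]),
        )
        for gene, label, base, noise, shifts in _PAPER_LIKE_REGIONS
    ]
    return SimSpec(
        groups=dict(PAPER_LIKE_GROUPS),
        regions=regions,
        loading_sd=0.3,
        replicate_sd=0.15,
        rt_bias={"FB": 1.0},
        seed=seed,
    )


#: per-sample log-scale (cycle) shifts for the cold-inducible targets over the
#: 16 preset samples (FB Sep/Nov/Dec/Feb, then FO, FF, FS): expression peaks
#: in December (lowest Ct), is moderate in flower organs and nearly absent in
#: fruit tissues
_TARGET_SEASONAL_SHIFTS = (
    2.0, 0.0, -4.0, 1.0,                 # FB: autumn -> winter peak -> release
    1.0, 0.5, 1.5, 0.5, 1.0, 0.8,        # FO
    5.0, 5.5, 6.0, 5.8,                  # FF: very low expression
    5.5, 6.0,                            # FS
)


def preset_paper_like_with_targets(seed: int = 0) -> SimSpec:
    """Paper-like preset plus two cold-inducible target genes.

    CBF2_utr and CBF4_utr share a seasonal profile peaking in the December
    flower-bud sample, with CBF2 expressed markedly higher (lower base Ct).
    Targets are not reference candidates; exclude them from ranking.
    """
    spec = preset_paper_like(seed=seed)
    targets = [
        RegionSpec(
            gene_symbol=name,
            region_label="utr",
            base_ct=base,
            noise_sd=0.2,
            sample_shifts=_TARGET_SEASONAL_SHIFTS,
            efficiency=1.0,
        )
        for name, base in (("CBF2", 28.0), ("CBF4", 31.0))
    ]
    return spec.model_copy(update={"regions": spec.regions + targets})


def preset_stability_benchmark(
    noisy_region: str = "ACT_utr2",
    noisy_sd: float = 0.5,
    base_sd: float = 0.05,
    seed: int = 0,
) -> SimSpec:
    """Known-ground-truth benchmark: one noisy region among quiet ones.

    Keeps the paper-like panel, groups and efficiencies but removes group
    shifts and RT bias and sets every region's gene noise to ``base_sd``
    except ``noisy_region`` (``noisy_sd``), so noise is the only stability
    difference and the least stable region is known by construction.
    """
    spec = preset_paper_like(seed=seed)
    regions = []
    found = False
    for r in spec.regions:
        sd = base_sd
        if r.display_name == noisy_region:
            sd, found = noisy_sd, True
        regions.append(
            r.model_copy(update={"noise_sd": sd, "group_shifts": {}})
        )
    if not found:
        raise ValueError(f"unknown region {noisy_region!r}")
    return spec.model_copy(
        update={"regions": regions, "rt_bias": {}, "replicate_sd": 0.05, "seed": seed}
    )
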