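"""Core data containers for well-level RT-qPCR threshold-cycle (Ct) data.

The central object is :class:`CtTable`: a long-format table of Ct values
indexed by (sample, gene region, replicate well), together with per-sample
metadata (group membership, reverse-transcription primer) and an optional
mask of (group, region) cells to exclude from stability ranking while keeping
them available for quantification.

Undetermined wells (no amplification within ``max_cycles`` cycles) are kept
as an explicit sentinel — stored as NaN in a row that is present — which is
distinct from a (sample, region) pair that simply has no rows.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import (
    CtParseError,
    DomainError,
    SchemaError,
    UnknownReferenceError,
)

#: closed vocabulary of amplicon region tags
REGION_LABELS = ("cds", "utr", "utr1", "utr2", "utr3")

#: reverse-transcription primer chemistries
RT_PRIMERS = ("oligo_dT", "random_hexamer")

#: sentinel token used in delimited files for wells that never crossed threshold
UNDETERMINED_TOKEN = "Undetermined"


@dataclass(frozen=True, order=True)
class GeneRegion:
    """A primer pair's amplicon, identified by gene symbol and region tag.

    ``display_name`` concatenates the two (e.g. ``HIS_cds``, ``SAND_utr``)
    and is the unique key used throughout the package.
    """

    gene_symbol: str
    region_label: str

    def __post_init__(self):
        if self.region_label not in REGION_LABELS:
            raise DomainError(
                f"region_label {self.region_label!r} not in {REGION_LABELS}"
            )

    @property
    def display_name(self) -> str:
        return f"{self.gene_symbol}_{self.region_label}"

    @classmethod
    def from_display_name(cls, name: str) -> "GeneRegion":
        sym, _, label = name.rpartition("_")
        if not sym:
            raise DomainError(f"cannot split region name {name!r} into gene_region")
        return cls(sym, label)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: group membership and RT primer chemistry."""

    sample_id: str
    group_id: str
    rt_primer: str = "random_hexamer"

    def __post_init__(self):
        if self.rt_primer not in RT_PRIMERS:
            raise DomainError(f"rt_primer {self.rt_primer!r} not in {RT_PRIMERS}")


@dataclass
class CtTable:
    """Long-format Ct table plus sample metadata and stability mask.

    Parameters
    ----------
    entries
        DataFrame with columns ``sample_id, region, replicate, ct, qc_warning``.
        ``ct`` is float; NaN encodes an undetermined well. ``region`` holds
        display names.
    samples
        Mapping sample_id -> :class:`SampleMeta`; every sample_id appearing in
        ``entries`` must be present.
    regions
        Mapping display_name -> :class:`GeneRegion`.
    mask
        Set of (group_id, region display name) pairs excluded from stability
        computations. Masking is flag-only: the Ct values remain stored.
    max_cycles
        Upper bound on valid Ct values (cycling protocol length).
    """

    entries: pd.DataFrame
    samples: dict[str, SampleMeta]
    regions: dict[str, GeneRegion]
    mask: frozenset[tuple[str, str]] = frozenset()
    max_cycles: float = 40.0

    def __post_init__(self):
        required = {"sample_id", "region", "replicate", "ct"}
        missing = required - set(self.entries.columns)
        if missing:
            raise SchemaError(f"entries missing columns: {sorted(missing)}")
        if "qc_warning" not in self.entries.columns:
            self.entries = self.entries.assign(qc_warning=False)
        self.entries = self.entries.reset_index(drop=True)
        unknown_samples = set(self.entries["sample_id"]) - set(self.samples)
        if unknown_samples:
            raise UnknownReferenceError(
                f"entries reference unknown samples: {sorted(unknown_samples)}"
            )
        unknown_regions = set(self.entries["region"]) - set(self.regions)
        if unknown_regions:
            raise UnknownReferenceError(
                f"entries reference unknown regions: {sorted(unknown_regions)}"
            )
        ct = self.entries["ct"]
        bad = ct.notna() & ((ct <= 0) | (ct > self.max_cycles))
        if bad.any():
            raise DomainError(
                f"Ct values outside (0, {self.max_cycles}] at rows "
                f"{self.entries.index[bad].tolist()}"
            )
        if (self.entries["replicate"] < 1).any():
            raise DomainError("replicate_index must be >= 1")
        self.mask = frozenset(self.mask)
        groups = {m.group_id for m in self.samples.values()}
        for g, r in self.mask:
            if g not in groups:
                raise UnknownReferenceError(f"mask references unknown group {g!r}")
            if r not in self.regions:
                raise UnknownReferenceError(f"mask references unknown region {r!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)

    @property
    def region_names(self) -> list[str]:
        return list(self.regions)

    @property
    def groups(self) -> dict[str, list[str]]:
        """group_id -> ordered list of member sample_ids."""
        out: dict[str, list[str]] = {}
        for sid, meta in self.samples.items():
            out.setdefault(meta.group_id, []).append(sid)
        return out

    def group_of(self, sample_id: str) -> str:
        try:
            return self.samples[sample_id].group_id
        except KeyError:
            raise UnknownReferenceError(f"unknown sample {sample_id!r}") from None

    def is_masked(self, sample_id: str, region: str) -> bool:
        return (self.group_of(sample_id), region) in self.mask

    def ct_matrix(self, respect_mask: bool = False) -> pd.DataFrame:
        """Collapsed samples x regions Ct matrix (mean over replicate rows).

        Undetermined wells are excluded from the mean; cells with no finite
        well, or absent entirely, come out NaN. With ``respect_mask=True``
        masked cells are NaN'd as well (for stability statistics).
        """
        wide = (
            self.entries.pivot_table(
                index="sample_id", columns="region", values="ct", aggfunc="mean"
            )
            .reindex(index=self.sample_ids, columns=self.region_names)
        )
        wide.index.name = "sample_id"
        wide.columns.name = "region"
        if respect_mask:
            for g, r in self.mask:
                members = [s for s in self.sample_ids if self.group_of(s) == g]
                wide.loc[members, r] = np.nan
        return wide

    def mask_frame(self) -> pd.DataFrame:
        """Boolean samples x regions frame: True where the cell is masked."""
        m = pd.DataFrame(
            False, index=self.sample_ids, columns=self.region_names
        )
        for g, r in self.mask:
            members = [s for s in self.sample_ids if self.group_of(s) == g]
            m.loc[members, r] = True
        return m


# -- schema-configurable I/O ---------------------------------------------------


@dataclass(frozen=True)
class CtTableSchema:
    """Column-name configuration for delimited Ct files."""

    sample: str = "sample_id"
    group: str = "group_id"
    region: str = "region"
    replicate: str = "replicate"
    ct: str = "ct"
    rt_primer: str = "rt_primer"  # optional in the file
    qc_warning: str = "qc_warning"  # optional in the file
    undetermined: str = UNDETERMINED_TOKEN
    sep: str = ","


def read_ct_table(
    path, schema: CtTableSchema = CtTableSchema(), max_cycles: float = 40.0
) -> CtTable:
    """Read a long-format delimited Ct file into a :class:`CtTable`.

    Lines starting with ``#`` are comments; ``# mask: GROUP,REGION`` lines
    re-install stability masks written by :func:`write_ct_table`.
    """
    mask: set[tuple[str, str]] = set()
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.startswith("mask:"):
                    g, _, r = stripped[len("mask:"):].strip().partition(",")
                    mask.add((g.strip(), r.strip()))
                continue
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("".join(body_lines)), sep=schema.sep, dtype=str)

    for col in (schema.sample, schema.group, schema.region, schema.replicate, schema.ct):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")

    def parse_ct(value: str, row: int) -> float:
        value = value.strip()
        if value == schema.undetermined:
            return np.nan
        try:
            return float(value)
        except ValueError:
            raise CtParseError(
                f"row {row}: cannot parse Ct value {value!r} "
                f"(undetermined token is {schema.undetermined!r})",
                row=row,
            ) from None

    ct = [parse_ct(v, i) for i, v in enumerate(df[schema.ct], start=1)]

    samples: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        sid = row[schema.sample]
        rt = (
            row[schema.rt_primer]
            if schema.rt_primer in df.columns
            else "random_hexamer"
        )
        meta = SampleMeta(sid, row[schema.group], rt)
        if sid in samples and samples[sid] != meta:
            raise SchemaError(f"conflicting metadata for sample {sid!r}")
        samples[sid] = meta

    regions = {
        name: GeneRegion.from_display_name(name)
        for name in pd.unique(df[schema.region])
    }
    qc = (
        df[schema.qc_warning].map({"True": True, "False": False}).fillna(False)
        if schema.qc_warning in df.columns
        else False
    )
    entries = pd.DataFrame(
        {
            "sample_id": df[schema.sample].to_numpy(),
            "region": df[schema.region].to_numpy(),
            "replicate": df[schema.replicate].astype(int).to_numpy(),
            "ct": ct,
            "qc_warning": qc,
        }
    )
    return CtTable(entries, samples, regions, frozenset(mask), max_cycles)


def write_ct_table(table: CtTable, path, schema: CtTableSchema = CtTableSchema()):
    """Write a CtTable as long-format CSV, round-trippable by read_ct_table."""
    from . import __version__

    df = table.entries.copy()
    df["group_id"] = df["sample_id"].map(lambda s: table.samples[s].group_id)
    df["rt_primer"] = df["sample_id"].map(lambda s: table.samples[s].rt_primer)
    out = pd.DataFrame(
        {
            schema.sample: df["sample_id"],
            schema.group: df["group_id"],
            schema.rt_primer: df["rt_primer"],
            schema.region: df["region"],
            schema.replicate: df["replicate"],
            schema.ct: [
                schema.undetermined if pd.isna(v) else repr(float(v))
                for v in df["ct"]
            ],
            schema.qc_warning: df["qc_warning"],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# qpcrnorm {__version__}\n")
        for g, r in sorted(table.mask):
            fh.write(f"# mask: {g},{r}\n")
        out.to_csv(fh, index=False, sep=schema.sep)


# -- operations ----------------------------------------------------------------


def collapse_replicates(
    table: CtTable, policy: str = "mean", max_spread: float = 1.0
) -> CtTable:
    """Collapse replicate wells to one entry per (sample, region).

    Undetermined wells are excluded from the aggregate; if every well of a
    cell is undetermined the collapsed value is undetermined. Cells whose
    finite-well range exceeds ``max_spread`` cycles keep their value but are
    flagged with a QC warning — QC issues are flags, never failures.
    """
    if policy not in ("mean", "median"):
        raise DomainError(f"policy must be 'mean' or 'median', got {policy!r}")
    if max_spread <= 0:
        raise DomainError("max_spread must be > 0")

    rows = []
    for (sid, region), grp in table.entries.groupby(
        ["sample_id", "region"], sort=False
    ):
        finite = grp["ct"].dropna()
        if finite.empty:
            value, warn = np.nan, bool(grp["qc_warning"].any())
        else:
            value = float(finite.mean() if policy == "mean" else finite.median())
            spread = float(finite.max() - finite.min())
            warn = bool(grp["qc_warning"].any()) or spread > max_spread
        rows.append((sid, region, 1, value, warn))
    entries = pd.DataFrame(
        rows, columns=["sample_id", "region", "replicate", "ct", "qc_warning"]
    )
    return CtTable(entries, dict(table.samples), dict(table.regions),
                   table.mask, table.max_cycles)


def apply_mask(table: CtTable, pairs) -> CtTable:
    """Return a copy with (group, region) pairs added to the stability mask.

    Masked cells stay stored and usable for quantification; stability
    statistics skip them. Unknown groups or regions raise
    :class:`UnknownReferenceError`.
    """
    pairs = frozenset(tuple(p) for p in pairs)
    groups = {m.group_id for m in table.samples.values()}
    for g, r in pairs:
        if g not in groups:
            raise UnknownReferenceError(f"unknown group {g!r}")
        if r not in table.regions:
            raise UnknownReferenceError(f"unknown region {r!r}")
    return replace(table, entries=table.entries.copy(), mask=table.mask | pairs)


def subset_samples(table: CtTable, sample_ids) -> CtTable:
    """Restrict a CtTable to the given samples (mask entries pruned to match)."""
    keep = set(sample_ids)
    unknown = keep - set(table.samples)
    if unknown:
        raise UnknownReferenceError(f"unknown samples: {sorted(unknown)}")
    entries = table.entries[table.entries["sample_id"].isin(keep)]
    samples = {s: m for s, m in table.samples.items() if s in keep}
    groups_left = {m.group_id for m in samples.values()}
    mask = frozenset((g, r) for g, r in table.mask if g in groups_left)
    return CtTable(entries.copy(), samples, dict(table.regions), mask, table.max_cycles)


def subset_regions(table: CtTable, regions) -> CtTable:
    """Restrict a CtTable to the given regions, preserving their order."""
    regions = list(regions)
    unknown = set(regions) - set(table.regions)
    if unknown:
        raise UnknownReferenceError(f"unknown regions: {sorted(unknown)}")
    entries = table.entries[table.entries["region"].isin(set(regions))]
    mask = frozenset((g, r) for g, r in table.mask if r in set(regions))
    return CtTable(
        entries.copy(),
        dict(table.samples),
        {r: table.regions[r] for r in regions},
        mask,
        table.max_cycles,
    )


def merge_runs(first: CtTable, second: CtTable, **collapse_kw) -> CtTable:
    """Merge two independent analytical runs by averaging collapsed Cts.

    Both runs are replicate-collapsed, then cell-wise averaged (a cell
    undetermined in one run takes the other run's value). Masks are unioned.
    """
    a = collapse_replicates(first, **collapse_kw)
    b = collapse_replicates(second, **collapse_kw)
    if set(a.samples) != set(b.samples) or set(a.regions) != set(b.regions):
        raise UnknownReferenceError("runs cover different samples or regions")
    ma, mb = a.ct_matrix(), b.ct_matrix()
    merged = pd.concat(
        [ma.stack(future_stack=True), mb.stack(future_stack=True)], axis=1
    ).mean(axis=1, skipna=True)
    qa = a.entries.set_index(["sample_id", "region"])["qc_warning"]
    qb = b.entries.set_index(["sample_id", "region"])["qc_warning"]
    rows = [
        (
            sid,
            region,
            1,
            merged.get((sid, region), np.nan),
            bool(qa.get((sid, region), False)) or bool(qb.get((sid, region), False)),
        )
        for sid in a.sample_ids
        for region in a.region_names
    ]
    entries = pd.DataFrame(
        rows, columns=["sample_id", "region", "replicate", "ct", "qc_warning"]
    )
    return CtTable(entries, dict(a.samples), dict(a.regions),
                   a.mask | b.mask, a.max_cycles)
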