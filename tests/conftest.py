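import numpy as np
import pandas as pd
import pytest

from qpcrnorm import CtTable, GeneRegion, QuantityMatrix, SampleMeta


def make_ct_table(ct_by_region, groups=None, replicates=False, mask=()):
    """Build a CtTable from {region_name: [ct per sample]}.

    ``groups`` maps sample index ranges via a list of group ids, one per
    sample (default: all in group "G1"). With ``replicates=False`` each cell
    is a single well.
    """
    n = len(next(iter(ct_by_region.values())))
    groups = groups or ["G1"] * n
    sample_ids = [f"S{i + 1}" for i in range(n)]
    samples = {s: SampleMeta(s, g) for s, g in zip(sample_ids, groups)}
    regions = {name: GeneRegion.from_display_name(name) for name in ct_by_region}
    rows = []
    for name, values in ct_by_region.items():
        for s, v in zip(sample_ids, values):
            rows.append((s, name, 1, float(v) if v == v else np.nan, False))
    entries = pd.DataFrame(
        rows, columns=["sample_id", "region", "replicate", "ct", "qc_warning"]
    )
    return CtTable(entries, samples, regions, frozenset(mask))


def make_quantities(values_by_region, groups=None, mask=None):
    """Build a QuantityMatrix from {region_name: [quantity per sample]}."""
    values = pd.DataFrame(values_by_region, dtype=float)
    n = len(values)
    values.index = [f"S{i + 1}" for i in range(n)]
    groups = groups or ["G1"] * n
    group_map = dict(zip(values.index, groups))
    mask_df = pd.DataFrame(False, index=values.index, columns=values.columns)
    if mask is not None:
        for s, r in mask:
            mask_df.loc[s, r] = True
    return QuantityMatrix(values, mask_df, group_map)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
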