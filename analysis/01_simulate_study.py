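"""Generate the synthetic validation study.

Emits the well-level Ct table (16 samples in 4 tissue groups x 17 candidate
reference regions + 2 cold-inducible targets x 3 wells), the decade dilution
series for every region, and the generator's ground truth, under
results/study/. Later steps read these files, so the whole analysis is
reproducible from this one seed.
"""

import json
import sys
from pathlib import Path

from qpcrnorm import preset_paper_like_with_targets, simulate, write_ct_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main():
    spec = preset_paper_like_with_targets(seed=SEED)
    res = simulate(spec)
    OUT.mkdir(parents=True, exist_ok=True)
    write_ct_table(res.table, OUT / "ct_table.csv")
    res.dilution_series.to_csv(OUT / "dilution_series.csv", index=False)
    truth = {
        "seed": SEED,
        "stability_order": res.truth.stability_order,
        "stability_score": res.truth.stability_score.round(8).to_dict(),
        "efficiencies": {k: round(v, 8) for k, v in res.truth.efficiencies.items()},
        "loading": res.truth.loading.round(8).to_dict(),
        "mask": sorted(spec.cds_mask_pairs()),
    }
    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))

    ct = res.table.ct_matrix()
    med = ct.median()
    print(f"simulated {ct.shape[0]} samples x {ct.shape[1]} regions (seed {SEED})")
    print(f"median Ct span: {med.min():.1f}-{med.max():.1f} cycles "
          f"(strongest {med.idxmin()}, weakest {med.idxmax()})")
    print(f"wrote study files to {OUT}")


if __name__ == "__main__":
    main()
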