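"""End-to-end pipeline, target normalization, robustness and CV checks."""

import warnings

import numpy as np
import pandas as pd
import pytest

from qpcrnorm import (
    RegionSpec,
    SimSpec,
    StudyConfig,
    cv_of_normalized,
    normalize_target,
    preset_paper_like,
    robustness_compare,
    run_screening_pipeline,
    simulate,
)
from qpcrnorm.errors import ConfigurationError

from conftest import make_quantities


@pytest.fixture(scope="module")
def paper_like_run():
    spec = preset_paper_like(seed=11)
    res = simulate(spec)
    config = StudyConfig(mask=sorted(spec.cds_mask_pairs()), seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_screening_pipeline(res.table, res.dilution_series, config)
    return spec, res, report


class TestScreeningPipeline:
    def test_report_contains_every_stage(self, paper_like_run):
        _, _, report = paper_like_run
        assert len(report.kept_regions) == 6
        assert len(report.genorm_overall.final_trio) == 3
        assert report.normfinder_overall is not None
        assert report.normfinder_best_pair is not None
        assert report.v_3_4 is not None
        d = report.to_json_dict()
        assert d["genorm"]["final_trio"] == sorted(report.genorm_overall.final_trio)
        assert d["normalization"]["verdict"] == report.verdict

    def test_per_group_rankings_present(self, paper_like_run):
        _, _, report = paper_like_run
        assert set(report.deltact_per_group) == {"FB", "FO", "FF", "FS"}
        # per-group NormFinder runs in single-group (intra-group) mode
        assert all(
            r.mode == "single_group" for r in report.normfinder_per_group.values()
        )

    def test_keep_none_bypasses_screen(self):
        spec = preset_paper_like(seed=11)
        res = simulate(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = run_screening_pipeline(
                res.table, res.dilution_series, StudyConfig(keep=None, seed=11)
            )
        assert set(report.kept_regions) == set(res.table.region_names)

    def test_sufficiency_verdict_when_v34_below_cutoff(self, paper_like_run):
        _, _, report = paper_like_run
        if report.v_3_4 < report.config.v_cutoff:
            assert report.verdict == "3 genes sufficient"
        else:
            assert "cutoff" in report.verdict

    def test_determinism_byte_identical_outputs(self, tmp_path):
        spec = preset_paper_like(seed=4)
        config = StudyConfig(mask=sorted(spec.cds_mask_pairs()), seed=4)
        outs = []
        for name in ("a", "b"):
            res = simulate(spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = run_screening_pipeline(res.table, res.dilution_series, config)
            out = tmp_path / name
            report.write(out)
            outs.append(out)
        for fname in (
            "report.json",
            "report.md",
            "deltact_ranking.csv",
            "genorm_ranking.csv",
            "genorm_v_curve.csv",
            "normfinder_ranking.csv",
            "standard_curves.csv",
        ):
            assert (outs[0] / fname).read_bytes() == (outs[1] / fname).read_bytes()

    def test_ranking_concordance_on_clean_data(self):
        # strict noise ordering, no group structure: all three methods
        # should agree on the top-3 set nearly always
        agree = 0
        n_seeds = 30
        for seed in range(n_seeds):
            spec = SimSpec(
                groups={"A": 4, "B": 4},
                regions=[
                    RegionSpec(
                        gene_symbol=f"G{i}",
                        region_label="utr",
                        base_ct=22.0 + 0.3 * i,
                        noise_sd=[0.03, 0.05, 0.08, 0.45, 0.6, 0.75, 0.9, 1.1][i],
                    )
                    for i in range(8)
                ],
                loading_sd=0.4,
                replicate_sd=0.02,
                seed=seed,
            )
            res = simulate(spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = run_screening_pipeline(
                    res.table, res.dilution_series, StudyConfig(keep=None, seed=seed)
                )
            top3 = {"G0_utr", "G1_utr", "G2_utr"}
            sets = [
                set(report.deltact_overall.ranking[:3]),
                set(report.genorm_overall.ranking[:3]),
                set(report.normfinder_overall.ranking[:3]),
            ]
            agree += all(s == top3 for s in sets)
        assert agree >= int(0.9 * n_seeds)


class TestNormalizeTarget:
    def quantities(self, rng):
        cols = {f"R{i}_utr": rng.lognormal(0, 0.5, 8).tolist() for i in range(3)}
        cols["CBF2_utr"] = rng.lognormal(1, 1.0, 8).tolist()
        return make_quantities(cols, groups=["A"] * 4 + ["B"] * 4)

    def test_self_normalization_gives_ones(self, rng):
        q = self.quantities(rng)
        refs = ["R0_utr", "R1_utr", "R2_utr"]
        nf = np.exp(np.log(q.values[refs]).mean(axis=1))
        q.values["CBF2_utr"] = nf  # target equals the geometric mean of refs
        res = normalize_target(q, "CBF2_utr", refs)
        assert np.allclose(res.values, 1.0)

    def test_per_sample_scaling_cancels(self, rng):
        q1 = self.quantities(rng)
        scale = rng.lognormal(0, 1, 8)
        q2 = make_quantities(
            {c: (q1.values[c] * scale).tolist() for c in q1.values.columns},
            groups=["A"] * 4 + ["B"] * 4,
        )
        r1 = normalize_target(q1, "CBF2_utr", ["R0_utr", "R1_utr", "R2_utr"])
        r2 = normalize_target(q2, "CBF2_utr", ["R0_utr", "R1_utr", "R2_utr"])
        assert np.allclose(r1.values, r2.values)

    def test_target_in_reference_set_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            normalize_target(self.quantities(rng), "R0_utr", ["R0_utr", "R1_utr"])

    def test_seasonal_peak_survives_reference_choice(self):
        # the injected December flower-bud peak (sample FB3) must be the
        # argmax of the normalized profile under best and worst references
        from qpcrnorm import (
            collapse_replicates,
            preset_paper_like_with_targets,
            simulate,
        )
        from qpcrnorm.quantification import fit_curves_from_frame, quantify

        sim = simulate(preset_paper_like_with_targets(seed=2))
        table = collapse_replicates(sim.table)
        q = quantify(table, fit_curves_from_frame(sim.dilution_series))
        refs = [r for r in sim.truth.stability_order if not r.startswith("CBF")]
        best3, worst3 = refs[:3], refs[-3:]
        fb = [s for s in q.sample_ids if q.groups[s] == "FB"]
        for ref_set in (best3, worst3):
            res = normalize_target(q, "CBF2_utr", ref_set)
            assert res.values[fb].idxmax() == "FB3"

    def test_group_means_indexed_by_group(self, rng):
        res = normalize_target(
            self.quantities(rng), "CBF2_utr", ["R0_utr", "R1_utr", "R2_utr"]
        )
        assert set(res.group_means.index) == {"A", "B"}


class TestRobustnessCompare:
    def test_identical_sets_give_unit_ratio(self, rng):
        cols = {f"R{i}_utr": rng.lognormal(0, 0.5, 9).tolist() for i in range(4)}
        cols["T_utr"] = rng.lognormal(0, 1.5, 9).tolist()
        q = make_quantities(cols, groups=["A"] * 5 + ["B"] * 4)
        cmp = robustness_compare(
            q, "T_utr", ["R0_utr", "R1_utr"], ["R0_utr", "R1_utr"]
        )
        assert np.allclose(cmp.ratio, 1.0)
        assert cmp.fold_range == pytest.approx(1.0)
        assert all(c == pytest.approx(1.0) for c in cmp.group_log_correlation.values())

    def test_scale_only_difference_keeps_correlation_one(self, rng):
        cols = {f"R{i}_utr": rng.lognormal(0, 0.5, 9).tolist() for i in range(2)}
        cols["R0s_utr"] = (np.array(cols["R0_utr"]) * 5.0).tolist()
        cols["R1s_utr"] = (np.array(cols["R1_utr"]) * 0.3).tolist()
        cols["T_utr"] = rng.lognormal(0, 1.5, 9).tolist()
        q = make_quantities(cols, groups=["A"] * 5 + ["B"] * 4)
        cmp = robustness_compare(
            q, "T_utr", ["R0_utr", "R1_utr"], ["R0s_utr", "R1s_utr"]
        )
        assert np.allclose(cmp.ratio, cmp.ratio.iloc[0])   # constant offset
        assert cmp.fold_range == pytest.approx(1.0)
        assert all(
            c == pytest.approx(1.0, abs=1e-9)
            for c in cmp.group_log_correlation.values()
        )

    def test_target_overlapping_a_reference_set_rejected(self, rng):
        cols = {f"R{i}_utr": rng.lognormal(0, 0.5, 6).tolist() for i in range(3)}
        cols["T_utr"] = rng.lognormal(0, 1, 6).tolist()
        q = make_quantities(cols)
        with pytest.raises(ConfigurationError):
            robustness_compare(
                q, "T_utr", ["R0_utr", "R1_utr"], ["T_utr", "R2_utr"]
            )


class TestCvOfNormalized:
    def test_constant_regions_have_zero_cv(self):
        q = make_quantities({f"R{i}_utr": [2.0, 2.0, 2.0, 2.0] for i in range(3)})
        cv = cv_of_normalized(q, q.region_names)
        assert np.allclose(cv, 0.0, atol=1e-14)

    def test_invariant_to_global_per_sample_scaling(self, rng):
        cols = {f"R{i}_utr": rng.lognormal(0, 0.5, 7) for i in range(3)}
        q1 = make_quantities({k: v.tolist() for k, v in cols.items()})
        scale = rng.lognormal(0, 2, 7)
        q2 = make_quantities({k: (v * scale).tolist() for k, v in cols.items()})
        assert np.allclose(
            cv_of_normalized(q1, q1.region_names),
            cv_of_normalized(q2, q2.region_names),
            atol=1e-12,
        )

    def test_matches_direct_recomputation(self, rng):
        cols = {f"R{i}_utr": rng.lognormal(0, 0.5, 10).tolist() for i in range(4)}
        q = make_quantities(cols)
        cv = cv_of_normalized(q, q.region_names)
        for r in cols:
            nf = [
                np.prod([cols[c][s] for c in cols]) ** (1 / 4) for s in range(10)
            ]
            norm = np.array([cols[r][s] / nf[s] for s in range(10)])
            expected = norm.std(ddof=1) / norm.mean()
            assert cv[r] == pytest.approx(expected, abs=1e-12)
        assert cv["mean"] == pytest.approx(cv.drop("mean").mean(), abs=1e-12)
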