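"""Generator structure: cohorts, determinism, replication, days, rescue."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from crbflow.errors import ConfigurationError, InputError
from crbflow.fva_quantify import quantify_sample_pair, replicate_cv
from crbflow.performance import pearson_r2
from crbflow.synthetic_data import (
    ASSAYS,
    AssayParams,
    GeneratorConfig,
    RescueExperiment,
    SampleSpec,
    Subject,
    generate_cohort,
    generate_control_cohort,
    read_event_table,
    simulate_fva_events,
    simulate_replicate_pairs,
    simulate_rescue_experiment,
    simulate_sample_pair,
    subject_latents,
    write_event_table,
)

from conftest import TEST_EVENTS, subject_features


def _subject(sid="s1", phenotype="defective", gene="BRCA1"):
    group = 1 if phenotype == "defective" else 3
    if phenotype == "intact":
        return Subject(sid, "t", 3, "none", "none", "intact", "unaffected")
    return Subject(sid, "t", 1, gene, "P", "defective", "breast")


class TestCohortGeneration:
    def test_deterministic_for_fixed_seed(self, gen_config):
        a = generate_cohort(gen_config, 30, "det")
        b = generate_cohort(gen_config, 30, "det")
        assert a == b

    def test_different_seed_differs(self, gen_config):
        a = generate_cohort(gen_config, 30, "det")
        b = generate_cohort(replace(gen_config, rng_seed=8), 30, "det")
        assert a != b

    def test_group_invariants_hold(self, gen_config):
        for s in generate_cohort(gen_config, 200, "inv"):
            s.validate()
            if s.group == 1:
                assert s.variant_class in ("P", "LP") and s.gene != "none"
            if s.group == 3:
                assert s.variant_class == "none" and s.true_phenotype == "intact"

    def test_prevalences_in_expectation(self):
        cfg = GeneratorConfig(
            events_per_sample=TEST_EVENTS, plp_prevalence=0.20, rng_seed=5
        )
        subs = generate_cohort(cfg, 59, "northwell-like")
        n1 = sum(s.group == 1 for s in subs)
        # binomial(59, 0.2): ~12 expected, 3 sigma ~ 9
        assert abs(n1 - 59 * 0.20) < 3 * np.sqrt(59 * 0.2 * 0.8)

    def test_forced_single_carrier(self):
        cfg = GeneratorConfig(
            events_per_sample=TEST_EVENTS,
            plp_prevalence=1.0,
            vus_prevalence=0.0,
            relative_prevalence=0.0,
            plp_intact_leak_rate=0.0,
        )
        (s,) = generate_cohort(cfg, 1, "one")
        assert s.group == 1 and s.true_phenotype == "defective"

    def test_zero_subjects_rejected(self, gen_config):
        with pytest.raises(InputError):
            generate_cohort(gen_config, 0, "empty")

    @pytest.mark.parametrize(
        "field,value",
        [("plp_prevalence", 1.2), ("vus_prevalence", -0.1), ("measurement_cv", -1.0)],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = GeneratorConfig(events_per_sample=TEST_EVENTS, **{field: value})
        with pytest.raises(ConfigurationError, match=field):
            cfg.validate()

    def test_prevalences_summing_above_one_rejected(self):
        cfg = GeneratorConfig(
            events_per_sample=TEST_EVENTS,
            plp_prevalence=0.5,
            vus_prevalence=0.4,
            relative_prevalence=0.2,
        )
        with pytest.raises(ConfigurationError, match="prevalence"):
            cfg.validate()

    def test_leak_rate_zero_means_all_carriers_defective(self):
        cfg = GeneratorConfig(events_per_sample=TEST_EVENTS, plp_intact_leak_rate=0.0)
        subs = generate_control_cohort(cfg, 40, 0, "leak0")
        assert all(s.true_phenotype == "defective" for s in subs)


class TestEventSimulation:
    def test_intact_positive_fraction_near_configured_mean(self):
        # near-degenerate latent SD isolates the gating recovery of the mean
        params = {a: AssayParams(0.75, 0.35, 1e-4, 1e-4) for a in ("brca1_nl", "brca2_nl")}
        params["p53_ratio"] = AssayParams(2.5, 1.2, 1e-4, 1e-4)
        cfg = GeneratorConfig(
            assay_params=params,
            events_per_sample=8000,
            measurement_cv=0.0,
            rng_seed=3,
        )
        s = Subject("s1", "t", 2, "none", "none", "intact", "unaffected")
        ch, un = simulate_sample_pair(s, SampleSpec("s1"), cfg)
        r = quantify_sample_pair(ch, un, subject_id="s1")
        # 3 binomial SEs at ~7200 gated nuclei is ~1.5 points
        assert abs(r.brca1_nl - 75.0) < 2.0
        assert abs(r.p53_ratio - 2.5) < 0.15

    def test_untreated_positive_fraction_is_gating_false_positive_rate(self, gen_config):
        s = _subject()
        un1 = simulate_fva_events(s, SampleSpec("s1", treatment="untreated"), gen_config)
        un2 = simulate_fva_events(
            s, SampleSpec("s1", treatment="untreated", replicate_index=2), gen_config
        )
        r = quantify_sample_pair(un2, un1, subject_id="s1")
        assert r.brca1_nl < 3.0 and r.brca2_nl < 3.0
        assert abs(r.p53_ratio - 1.0) < 0.1

    def test_unknown_cell_type_or_treatment_rejected(self, gen_config):
        with pytest.raises(InputError):
            simulate_fva_events(_subject(), SampleSpec("s1", cell_type="whole-blood"), gen_config)
        with pytest.raises(InputError):
            simulate_fva_events(_subject(), SampleSpec("s1", treatment="mock"), gen_config)

    def test_event_table_roundtrip(self, gen_config, tmp_path):
        events = simulate_fva_events(_subject(), SampleSpec("s1"), gen_config)
        path = tmp_path / "events.csv"
        write_event_table(events, path)
        back = read_event_table(path)
        pd.testing.assert_frame_equal(events, back)


class TestReplication:
    def test_zero_measurement_cv_shares_exact_latents(self, gen_config):
        cfg = replace(gen_config, measurement_cv=0.0)
        s = _subject()
        from crbflow.synthetic_data import effective_values

        vals = [
            effective_values(s, SampleSpec("s1", replicate_index=i + 1), cfg)
            for i in range(3)
        ]
        for a in ASSAYS:
            assert vals[0][a] == vals[1][a] == vals[2][a]

    def test_replicate_cv_tracks_configured_value_large_k(self):
        cfg = GeneratorConfig(
            events_per_sample=4000, measurement_cv=0.05, rng_seed=11
        )
        cvs = []
        for i in range(15):
            s = _subject(f"s{i}", phenotype="intact" if i % 2 else "defective")
            pairs = simulate_replicate_pairs(s, SampleSpec(s.subject_id), 10, cfg)
            reps = [
                quantify_sample_pair(c, u, subject_id=s.subject_id, replicate_index=j + 1)
                for j, (c, u) in enumerate(pairs)
            ]
            cvs.append(replicate_cv(reps).cv_percent["p53_ratio"])
        assert 3.5 < np.mean(cvs) < 6.5

    def test_triplicate_cv_below_three_percent_at_defaults(self):
        cfg = GeneratorConfig(rng_seed=7)  # production defaults: 10k events, cv 1.5%
        subs = generate_control_cohort(cfg, 10, 10, "cv")
        all_cvs = []
        for s in subs:
            pairs = simulate_replicate_pairs(s, SampleSpec(s.subject_id), 3, cfg)
            reps = [
                quantify_sample_pair(c, u, subject_id=s.subject_id, replicate_index=j + 1)
                for j, (c, u) in enumerate(pairs)
            ]
            st = replicate_cv(reps)
            all_cvs.extend(st.cv_percent.values())
        assert np.mean(all_cvs) < 3.0

    def test_single_replicate_rejected(self, gen_config):
        with pytest.raises(InputError):
            simulate_replicate_pairs(_subject(), SampleSpec("s1"), 1, gen_config)


class TestDayAndCellTypeStructure:
    def _day_values(self, cfg, subjects, day):
        out = {a: [] for a in ASSAYS}
        for s in subjects:
            ch, un = simulate_sample_pair(s, SampleSpec(s.subject_id, day=day), cfg)
            r = quantify_sample_pair(ch, un, subject_id=s.subject_id, day=day)
            for a in ASSAYS:
                out[a].append(getattr(r, a))
        return out

    def test_day_storage_correlation_structure(self, gen_config):
        subs = generate_control_cohort(gen_config, 15, 15, "days")
        by_day = {d: self._day_values(gen_config, subs, d) for d in (1, 2, 3, 4)}
        for a in ASSAYS:
            for d in (2, 3):
                assert pearson_r2(by_day[1][a], by_day[d][a])["r2"] > 0.9
            assert pearson_r2(by_day[1][a], by_day[4][a])["r2"] < 0.9

    def test_matched_pbmc_lcl_correlation(self, gen_config):
        subs = generate_control_cohort(gen_config, 10, 10, "matched")
        pbmc = subject_features(subs, gen_config, cell_type="PBMC")
        lcl = subject_features(subs, gen_config, cell_type="LCL")
        for a in ASSAYS:
            assert pearson_r2(pbmc[a], lcl[a])["r2"] > 0.9


class TestPhenotypeSeparation:
    def test_interquartile_ranges_do_not_overlap(self, gen_config):
        intact = [
            subject_latents(_subject(f"i{k}", "intact"), gen_config) for k in range(60)
        ]
        defective = [
            subject_latents(_subject(f"d{k}", "defective"), gen_config)
            for k in range(60)
        ]
        for a in ASSAYS:
            iv = np.array([v[a] for v in intact])
            dv = np.array([v[a] for v in defective])
            assert np.percentile(dv, 75) < np.percentile(iv, 25)


class TestRescue:
    def test_transfection_efficiency_bounds(self):
        exp = RescueExperiment(_subject(), "BRCA1", transfection_efficiency=1.2)
        with pytest.raises(ConfigurationError):
            exp.validate()
        with pytest.raises(InputError):
            RescueExperiment(_subject(), "GFP").validate()

    def test_sham_never_changes_phenotype_distribution(self, gen_config):
        # paired pre/post summaries over independent experiments: no shift
        pre_vals, post_vals = [], []
        for i in range(6):
            cfg = replace(gen_config, rng_seed=100 + i)
            exp = simulate_rescue_experiment(
                RescueExperiment(_subject(f"lcl{i}"), "sham"), cfg
            )
            pre = quantify_sample_pair(exp.pre_events, exp.pre_control, subject_id="x")
            post = quantify_sample_pair(exp.post_events, exp.post_control, subject_id="x")
            pre_vals.append(pre.brca1_nl)
            post_vals.append(post.brca1_nl)
        from crbflow.performance import two_sample_t_test

        assert two_sample_t_test(pre_vals, post_vals)["p_two_sided"] > 0.05

    def test_matched_gene_rescue_raises_all_assays(self, gen_config):
        exp = simulate_rescue_experiment(
            RescueExperiment(_subject("lclA"), "BRCA1"), gen_config
        )
        pre = quantify_sample_pair(exp.pre_events, exp.pre_control, subject_id="x")
        post = quantify_sample_pair(exp.post_events, exp.post_control, subject_id="x")
        assert post.brca1_nl > pre.brca1_nl + 20
        assert post.p53_ratio > pre.p53_ratio + 0.5

    def test_mismatched_gene_rescue_has_no_effect(self, gen_config):
        s = Subject("lclN", "t", 1, "NBN", "P", "defective", "breast")
        exp = simulate_rescue_experiment(RescueExperiment(s, "BRCA1"), gen_config)
        pre = quantify_sample_pair(exp.pre_events, exp.pre_control, subject_id="x")
        post = quantify_sample_pair(exp.post_events, exp.post_control, subject_id="x")
        assert abs(post.brca1_nl - pre.brca1_nl) < 5.0
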