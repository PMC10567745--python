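"""Rarity, region and in silico filters; tool calling; concordance tallies."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardiosplice.anatomy import analyse_variant, classify_region
from cardiosplice.models import (
    ConfigError,
    DataError,
    Disease,
    ExclusionList,
    SpliceScores,
    VariantObservation,
)
from cardiosplice.prioritise import (
    FilterName,
    Mode,
    Thresholds,
    Tool,
    concordance_tally,
    frequency_filter,
    prioritise,
    region_filter,
    tool_calls,
)


def obs(**kwargs) -> VariantObservation:
    base = dict(
        participant_id="P1",
        disease=Disease.HCM,
        gene="MYBPC3",
        transcript="NM_000256.3",
        hgvs_c="c.100G>A",
    )
    base.update(kwargs)
    return VariantObservation(**base)


class TestFrequencyFilter:
    def test_absent_everywhere_passes(self):
        assert frequency_filter(obs(af_overall=0.0, af_subpops={p: 0.0 for p in
                                                               ("afr", "eas", "amr", "nfe", "sas")}))

    def test_subpopulation_excess_fails(self):
        # overall AF is rare but one sub-population is not
        assert not frequency_filter(obs(af_overall=5e-5, af_subpops={"amr": 2e-4}))

    def test_allele_count_boundary(self):
        assert frequency_filter(obs(af_overall=5e-5, allele_count_controls=15))
        assert not frequency_filter(obs(af_overall=5e-5, allele_count_controls=16))

    def test_threshold_is_strict(self):
        assert not frequency_filter(obs(af_overall=1e-4))
        assert frequency_filter(obs(af_overall=9.9e-5))

    def test_missing_frequency_passes(self):
        assert frequency_filter(obs())

    def test_negative_frequency_is_data_error(self):
        record = obs()
        object.__setattr__(record, "af_overall", -0.1)  # bypass constructor guard
        with pytest.raises(DataError):
            frequency_filter(record)


class TestRegionFilter:
    @pytest.mark.parametrize(
        "offset,mode,expected",
        [
            (-52, Mode.burden_75bp, True),
            (-75, Mode.burden_75bp, True),
            (-76, Mode.burden_75bp, False),
            (-80, Mode.burden_75bp, False),
            (-80, Mode.discovery, True),
            (0, Mode.burden_75bp, True),
            (0, Mode.discovery, True),
        ],
    )
    def test_boundaries(self, offset, mode, expected):
        assert region_filter(classify_region(offset), mode) is expected


class TestToolCalls:
    def test_published_rows(self, demo_variants):
        expected = {
            "014": {Tool.MES, Tool.ADA, Tool.RF},
            "015": {Tool.ADA, Tool.RF, Tool.SpliceAI},
            "051": {Tool.MES, Tool.SpliceAI},
            "054": {Tool.ADA, Tool.SpliceAI},
            "102": {Tool.MES, Tool.ADA, Tool.RF, Tool.SpliceAI},
            "125": {Tool.MES, Tool.ADA, Tool.RF, Tool.SpliceAI},
        }
        for dv in demo_variants:
            o = dv.observation
            anatomy = analyse_variant(o.hgvs_c, o.scores, o.exon_boundary_distance)
            assert tool_calls(o.scores, anatomy) == expected[dv.family], dv.family

    def test_all_missing_scores_flag_nothing(self):
        anatomy = classify_region(1)
        assert tool_calls(SpliceScores(), anatomy) == frozenset()

    def test_boundary_values_fail(self):
        anatomy = classify_region(5)  # canonical donor, site loss
        assert tool_calls(SpliceScores(ada=0.6, rf=0.6, spliceai=0.5), anatomy) == frozenset()
        assert tool_calls(SpliceScores(mes_ref=8.0, mes_alt=4.0), anatomy) == frozenset()
        assert Tool.MES in tool_calls(SpliceScores(mes_ref=8.0, mes_alt=3.99), anatomy)

    def test_ada_rf_not_evaluable_outside_canonical_sites(self):
        deep = analyse_variant("c.1224-80G>A", SpliceScores(ada=0.99, rf=0.99))
        assert tool_calls(SpliceScores(ada=0.99, rf=0.99), deep) == frozenset()

    def test_de_novo_gain_uses_zero_reference(self):
        deep = analyse_variant("c.1224-80G>A", SpliceScores(mes_delta=7.96))
        assert Tool.MES in tool_calls(SpliceScores(mes_delta=7.96), deep)

    @given(
        ada=st.floats(0, 1),
        rf=st.floats(0, 1),
        spliceai=st.floats(0, 1),
        drop=st.floats(0, 12),
        bump=st.floats(0, 3),
    )
    def test_raising_thresholds_never_adds_tools(self, ada, rf, spliceai, drop, bump):
        scores = SpliceScores(mes_ref=9.0, mes_alt=9.0 - drop, ada=ada, rf=rf,
                              spliceai=spliceai)
        anatomy = classify_region(3)
        loose = tool_calls(scores, anatomy, Thresholds())
        strict = tool_calls(
            scores,
            anatomy,
            Thresholds(ada=0.6 + bump / 10, rf=0.6 + bump / 10,
                       spliceai=0.5 + bump / 10, mes_loss_delta=4 + bump),
        )
        assert strict <= loose


class TestPrioritise:
    def test_oceanian_polymorphism_excluded(self, gene_meta):
        record = obs(
            disease=Disease.HCM,
            gene="TNNT2",
            transcript="NM_001276345.2",
            hgvs_c="c.601-1G>A",
            scores=SpliceScores(spliceai=0.9),
            af_overall=0.0,
        )
        verdict = prioritise(record, gene_meta)
        assert not verdict.candidate
        assert FilterName.exclusion_list in verdict.failed_filters

    def test_phenotype_concordance_required(self, gene_meta):
        record = obs(disease=Disease.BrS, scores=SpliceScores(spliceai=0.9))
        verdict = prioritise(record, gene_meta)  # MYBPC3 is not a BrS gene
        assert not verdict.candidate
        assert FilterName.panel in verdict.failed_filters

    def test_sud_uses_all_definitive_genes(self, gene_meta):
        record = obs(disease=Disease.SUD, scores=SpliceScores(spliceai=0.9),
                     af_overall=0.0)
        assert prioritise(record, gene_meta).candidate

    def test_passing_variant_is_candidate(self, gene_meta):
        record = obs(scores=SpliceScores(spliceai=0.9), af_overall=0.0)
        verdict = prioritise(record, gene_meta)
        assert verdict.candidate
        assert verdict.tools_flagging == frozenset({Tool.SpliceAI})
        assert verdict.failed_filters == ()

    def test_unknown_gene_is_config_error(self, gene_meta):
        with pytest.raises(ConfigError, match="NOTAGENE"):
            prioritise(obs(gene="NOTAGENE"), gene_meta)

    def test_no_tool_recorded_as_failed_filter(self, gene_meta):
        verdict = prioritise(obs(), gene_meta)
        assert not verdict.candidate
        assert FilterName.no_tool in verdict.failed_filters


class TestConcordance:
    def test_published_rows_histogram(self, demo_variants, gene_meta):
        exclusion = ExclusionList.empty()
        verdicts = [
            prioritise(dv.observation, gene_meta, exclusion=exclusion)
            for dv in demo_variants
        ]
        tally = concordance_tally(verdicts).as_dict()
        assert tally["canonical_by_n_tools"] == {1: 0, 2: 1, 3: 2, 4: 2}
        assert tally["noncanonical"] == {"MES_only": 0, "both": 1, "SpliceAI_only": 0}

    def test_single_four_tool_variant(self, gene_meta):
        record = obs(
            hgvs_c="c.848+1G>A",
            scores=SpliceScores(mes_ref=9.0, mes_alt=0.0, ada=0.9, rf=0.9, spliceai=0.9),
            af_overall=0.0,
        )
        verdict = prioritise(record, gene_meta)
        tally = concordance_tally([verdict]).as_dict()
        assert tally["canonical_by_n_tools"][4] == 1

    def test_empty_input_all_zero(self):
        tally = concordance_tally([]).as_dict()
        assert all(v == 0 for v in tally["canonical_by_n_tools"].values())
        assert all(v == 0 for v in tally["noncanonical"].values())


def test_unique_variant_counts_never_exceed_carrier_counts(small_cohort):
    from cardiosplice.prioritise import dedupe_observations

    per_gene_carriers = {}
    for o in small_cohort.observations:
        per_gene_carriers.setdefault(o.gene, set()).add(o.participant_id)
    unique = dedupe_observations(small_cohort.observations)
    per_gene_unique = {}
    for o in unique:
        per_gene_unique[o.gene] = per_gene_unique.get(o.gene, 0) + 1
    for gene, n_unique in per_gene_unique.items():
        assert n_unique <= len(per_gene_carriers[gene])
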