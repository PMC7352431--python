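import itertools

import pytest

from famprio.cascade import (
    DEFAULT_STAGES,
    FilterConfig,
    cadd_filter,
    conservation_filter,
    deleteriousness_vote,
    quality_filter,
    rarity_filter,
    rescue_check,
    run_cascade,
)
from famprio.simulate import SimulationConfig, simulate_dataset
from famprio.variants import AnnotatedVariant, PredictorCalls

CFG = FilterConfig()


def make_variant(**kwargs):
    base = dict(
        chrom="1",
        pos=1000,
        ref="A",
        alt="G",
        qual=50.0,
        genotypes={"II-2": 1},
        depth={"II-2": 30},
        cadd_phred=23.1,
        gerp=4.1,
        phastcons=0.9,
        phylop=5.2,
        gene="GENEX",
        consequence="missense",
    )
    base.update(kwargs)
    return AnnotatedVariant(**base)


class TestQualityFilter:
    def test_good_variant_passes(self):
        assert quality_filter(make_variant(), CFG)

    def test_qual_boundary_is_strict(self):
        assert not quality_filter(make_variant(qual=20.0), CFG)
        assert quality_filter(make_variant(qual=20.0001), CFG)

    def test_caller_fail_overrides_scores(self):
        assert not quality_filter(make_variant(caller_filter_pass=False), CFG)

    def test_depth_boundary_is_strict(self):
        assert not quality_filter(make_variant(depth={"II-2": 5}), CFG)
        assert quality_filter(make_variant(depth={"II-2": 6}), CFG)

    def test_depth_of_ungenotyped_member_ignored(self):
        v = make_variant(genotypes={"II-2": 1, "II-3": None},
                         depth={"II-2": 30, "II-3": 2})
        assert quality_filter(v, CFG)

    def test_missing_qual_fails(self):
        assert not quality_filter(make_variant(qual=None), CFG)


class TestRarityFilter:
    def test_rare_in_both_sources(self):
        v = make_variant(maf_sources={"thousand_genomes": 0.0005, "exac_nontcga": 0.0005})
        assert rarity_filter(v, CFG)

    def test_common_in_one_source_fails(self):
        v = make_variant(maf_sources={"thousand_genomes": None, "exac_nontcga": 0.002})
        assert not rarity_filter(v, CFG)

    def test_novel_variant_survives(self):
        v = make_variant(maf_sources={"thousand_genomes": None, "exac_nontcga": None})
        assert rarity_filter(v, CFG)

    def test_boundary_exactly_at_ceiling_is_retained(self):
        v = make_variant(maf_sources={"thousand_genomes": 0.001, "exac_nontcga": 0.001})
        assert rarity_filter(v, CFG)


class TestCaddFilter:
    def test_high_score_passes(self):
        assert cadd_filter(make_variant(cadd_phred=23.1), CFG)

    def test_boundary_is_strict(self):
        assert not cadd_filter(make_variant(cadd_phred=10.0), CFG)

    def test_missing_fails_by_default(self):
        assert not cadd_filter(make_variant(cadd_phred=None), CFG)

    def test_missing_configurable(self):
        cfg = FilterConfig(missing_cadd_fails=False)
        assert cadd_filter(make_variant(cadd_phred=None), cfg)


class TestConservationFilter:
    def test_all_passing(self):
        assert conservation_filter(make_variant(gerp=4.1, phastcons=0.9, phylop=5.2), CFG)

    def test_phylop_boundary_inclusive(self):
        assert conservation_filter(make_variant(phylop=3.0), CFG)

    def test_gerp_boundary_strict(self):
        assert not conservation_filter(make_variant(gerp=2.0), CFG)

    def test_phastcons_boundary_strict(self):
        assert not conservation_filter(make_variant(phastcons=0.3), CFG)

    def test_missing_score_skipped(self):
        assert conservation_filter(make_variant(gerp=None, phastcons=None, phylop=3.5), CFG)

    def test_all_missing_fails_by_default(self):
        v = make_variant(gerp=None, phastcons=None, phylop=None)
        assert not conservation_filter(v, CFG)
        assert conservation_filter(v, FilterConfig(require_conservation_score=False))


class TestDeleteriousnessVote:
    @pytest.mark.parametrize(
        "letters, expected",
        [
            ("DDDDDDTTTT", True),   # 6/10 = 60% meets "at least 60%"
            ("DDDDDTTTTT", False),  # 5/10
            ("DDD..TT...", True),   # 3/5 over the non-missing calls
            ("DD..TT....", False),  # only 4 calls available
            ("DDDDDDDDDD", True),
            ("TTTTTTTTTT", False),
        ],
    )
    def test_vote_outcomes(self, letters, expected):
        result = deleteriousness_vote(PredictorCalls.from_letters(letters), CFG)
        assert result.passed is expected

    def test_counts_reported(self):
        result = deleteriousness_vote(PredictorCalls.from_letters("DDD..TT..."), CFG)
        assert (result.n_deleterious, result.n_available) == (3, 5)

    def test_effective_threshold_is_60_percent(self):
        passing = [
            k
            for k in range(11)
            if deleteriousness_vote(
                PredictorCalls.from_letters("D" * k + "T" * (10 - k)), CFG
            ).passed
        ]
        assert min(passing) == 6


class TestRescue:
    RESCUE_CFG = FilterConfig(rescue_genes=frozenset({"RET"}))

    def test_rescue_gene_coding_variant(self):
        assert rescue_check(make_variant(gene="RET"), self.RESCUE_CFG)

    def test_non_rescue_gene(self):
        assert not rescue_check(make_variant(gene="GENEX"), self.RESCUE_CFG)

    def test_synonymous_never_rescued(self):
        assert not rescue_check(
            make_variant(gene="RET", consequence="synonymous"), self.RESCUE_CFG
        )

    def test_rescued_variant_bypasses_cadd_and_vote(self, family5):
        v = make_variant(
            gene="RET",
            cadd_phred=2.0,  # fails the CADD gate
            predictor_calls=PredictorCalls.from_letters("TTTTTTTTTT"),
            genotypes={"II-2": 1, "II-3": 1, "II-5": 1, "II-8": 1, "II-7": 0},
        )
        report = run_cascade([v], family5, self.RESCUE_CFG)
        assert report.candidate_keys == [v.key]
        assert v.key in report.rescued
        assert report.trail[v.key]["cadd"] == "rescued"

    def test_rescue_never_bypasses_segregation(self, family5):
        v = make_variant(
            gene="RET",
            genotypes={"II-2": 0, "II-3": 1, "II-5": 1, "II-8": 1, "II-7": 0},
        )
        report = run_cascade([v], family5, self.RESCUE_CFG)
        assert report.candidate_keys == []
        assert report.trail[v.key]["segregation"] == "fail"


SEGREGATING = {"II-2": 1, "II-3": 1, "II-5": 1, "II-8": 1, "II-7": 0, "II-1": 0,
               "I-1": 0, "II-4": 0, "II-6": 1}


class TestRunCascade:
    def test_planted_variant_recovered(self, family5):
        ped, variants = simulate_dataset(SimulationConfig(seed=11, n_background_variants=1000))
        report = run_cascade(variants, ped)
        assert "7:124503601:C>A" in report.candidate_keys

    def test_all_common_variants_yield_zero_candidates(self, family5):
        variants = [
            make_variant(pos=i, genotypes=dict(SEGREGATING),
                         maf_sources={"thousand_genomes": 0.05, "exac_nontcga": 0.05})
            for i in range(1, 20)
        ]
        report = run_cascade(variants, family5)
        assert report.candidates == []
        assert dict(report.stage_counts)["rarity"] == 0

    def test_empty_input_is_valid(self, family5):
        report = run_cascade([], family5)
        assert report.n_input == 0
        assert all(count == 0 for _, count in report.stage_counts)

    def test_counts_non_increasing(self, family5):
        ped, variants = simulate_dataset(SimulationConfig(seed=5, n_background_variants=300))
        report = run_cascade(variants, ped)
        counts = [report.n_input] + [c for _, c in report.stage_counts]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_uninformative_variant_dropped_not_fatal(self, family5):
        v = make_variant(genotypes={"I-1": 1})  # no case genotyped
        report = run_cascade([v], family5)
        assert report.trail[v.key]["segregation"] == "fail"

    def test_trail_marks_stages_after_death_not_applicable(self, family5):
        v = make_variant(qual=5.0, genotypes=dict(SEGREGATING))
        report = run_cascade([v], family5)
        assert report.trail[v.key]["quality"] == "fail"
        assert report.trail[v.key]["vote"] == "not-applicable"


def _independent_survivors(variants, ped, cfg):
    """Brute-force oracle: re-derive the final set predicate-by-predicate
    with literal comparisons, independent of the cascade code."""
    survivors = []
    for v in variants:
        rescued = v.gene in cfg.rescue_genes and v.consequence in (
            "missense", "nonsense", "splice", "frameshift", "inframe_indel")
        depths = [d for m, d in v.depth.items() if v.genotypes.get(m) is not None]
        ok = v.caller_filter_pass and v.qual is not None and v.qual > 20
        ok = ok and (not depths or min(depths) > 5)
        for f in v.maf_sources.values():
            ok = ok and (f is None or f <= 0.001)
        seg = True
        informative = False
        for m in ped:
            d = v.genotypes.get(m.id)
            if d is None:
                continue
            if m.role == "case":
                informative = True
                seg = seg and d >= 1
            elif m.role == "control":
                seg = seg and d == 0
        ok = ok and seg and informative
        if not rescued:
            ok = ok and v.cadd_phred is not None and v.cadd_phred > 10
            cons = [s for s in (
                None if v.gerp is None else v.gerp > 2.0,
                None if v.phastcons is None else v.phastcons > 0.3,
                None if v.phylop is None else v.phylop >= 3.0,
            ) if s is not None]
            ok = ok and bool(cons) and all(cons)
            n_del = v.predictor_calls.n_deleterious
            n_av = v.predictor_calls.n_available
            ok = ok and v.consequence in ("missense", "nonsense", "splice")
            ok = ok and n_av >= 5 and n_del / n_av >= 0.6
        if ok:
            survivors.append(v.key)
    return sorted(survivors)


class TestCascadeProperties:
    def test_oracle_equivalence(self):
        ped, variants = simulate_dataset(SimulationConfig(seed=23, n_background_variants=99))
        report = run_cascade(variants, ped)
        assert sorted(report.candidate_keys) == _independent_survivors(
            variants, ped, FilterConfig()
        )

    def test_stage_order_does_not_change_final_set(self):
        ped, variants = simulate_dataset(SimulationConfig(seed=31, n_background_variants=80))
        baseline = sorted(run_cascade(variants, ped).candidate_keys)
        for order in itertools.islice(itertools.permutations(DEFAULT_STAGES), 0, 720, 71):
            cfg = FilterConfig(stage_order=order)
            assert sorted(run_cascade(variants, ped, cfg).candidate_keys) == baseline


class TestFilterConfig:
    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        cfg = FilterConfig(rescue_genes=frozenset({"TP53", "RET"}), cadd_min=15.0)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert FilterConfig.from_yaml(path) == cfg

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("frobnicate: 1\n")
        with pytest.raises(ValueError, match="frobnicate"):
            FilterConfig.from_yaml(path)

    def test_consensus_fraction_validated(self):
        with pytest.raises(ValueError, match="consensus_fraction"):
            FilterConfig(consensus_fraction=0.0)

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="stage"):
            FilterConfig(stage_order=("quality", "phase_of_moon"))
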