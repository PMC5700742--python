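import dataclasses
import io
import math

import numpy as np
import pytest

from tfrep.errors import ConfigurationError
from tfrep.rule_engine import classify_set
from tfrep.sequence_prep import six_frame_translate, write_fasta
from tfrep.synthetic_data import (
    GroundTruth,
    GroundTruthRecord,
    SyntheticSpec,
    exact_match_scan,
    generate_domain_hits,
    generate_pipeline_outputs,
    generate_proteome,
    generate_rule_set,
    motif_for_domain,
    planted_evalue,
    serialize_rule_set,
)


class TestSpecValidation:
    def test_proportions_bounded(self):
        with pytest.raises(ConfigurationError):
            SyntheticSpec(decoy_rate=1.5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticSpec(n_families=-1)

    def test_domains_per_family_range(self):
        with pytest.raises(ConfigurationError):
            SyntheticSpec(domains_per_family=(0, 2))


class TestGenerateRuleSet:
    def test_lang_scale_rule_set(self):
        rules = generate_rule_set(SyntheticSpec(n_families=111, n_domains=250))
        assert rules.n_families == 111

    def test_zero_families_valid(self):
        rules = generate_rule_set(SyntheticSpec(n_families=0))
        assert rules.n_families == 0

    def test_deterministic_serialization(self):
        spec = SyntheticSpec(n_families=5, seed=1)
        assert serialize_rule_set(generate_rule_set(spec)) == serialize_rule_set(
            generate_rule_set(spec)
        )

    def test_every_family_has_mandatory_disjoint_from_forbidden(self):
        rules = generate_rule_set(SyntheticSpec(n_families=30, seed=3))
        for rule in rules.families.values():
            assert rule.mandatory
            assert not rule.mandatory & rule.forbidden

    def test_synonym_alias_pair_included(self):
        rules = generate_rule_set(SyntheticSpec(n_families=5))
        assert rules.synonyms
        assert all(v in rules.families for v in rules.synonyms.values())

    def test_vocabulary_too_small_rejected(self):
        with pytest.raises(ConfigurationError, match="pool"):
            generate_rule_set(SyntheticSpec(n_families=100, n_domains=50))


class TestGenerateProteome:
    @pytest.fixture
    def spec(self):
        return SyntheticSpec(n_families=5, family_size_distribution=3,
                             models_per_gene=1, seed=2, n_background_genes=3)

    def test_members_classifiable_by_rule_engine(self, spec):
        rules = generate_rule_set(spec)
        proteins, _, truth = generate_proteome(rules, spec)
        hits = exact_match_scan(proteins, rules.all_domains())
        _, counts = classify_set(hits, rules)
        assert dict(counts) == {
            fam: c[1] for fam, c in truth.expected_family_counts().items()
        }

    def test_full_decoy_rate_yields_no_strict_assignments(self):
        spec = SyntheticSpec(n_families=3, family_size_distribution=4,
                             models_per_gene=1, decoy_rate=1.0, seed=4,
                             n_background_genes=0)
        rules = generate_rule_set(spec)
        proteins, _, truth = generate_proteome(rules, spec)
        assert all(r.is_decoy for r in truth.records)
        hits = exact_match_scan(proteins, rules.all_domains())
        assignments, counts = classify_set(hits, rules)
        assert not counts
        assert {a.reason for a in assignments} == {"forbidden-domain-present"}

    def test_two_models_per_gene(self):
        spec = SyntheticSpec(n_families=2, family_size_distribution=5,
                             models_per_gene=2, seed=5, n_background_genes=0)
        rules = generate_rule_set(spec)
        _, _, truth = generate_proteome(rules, spec)
        assert len(truth.records) == 20
        assert len(truth.gene_ids()) == 10

    def test_gene_model_conservation(self, spec):
        rules = generate_rule_set(spec)
        _, _, truth = generate_proteome(rules, spec)
        assert len(truth.gene_ids()) <= len(truth.records)
        assert all(
            r.model_id.startswith(r.gene_id) for r in truth.records
        )

    def test_recorded_frame_decodes_the_protein(self, spec):
        rules = generate_rule_set(spec)
        proteins, transcripts, truth = generate_proteome(rules, spec)
        by_id = {p.id: p.residues for p in proteins}
        for rec, transcript in zip(truth.records[:10], transcripts[:10]):
            frames = {f.frame: f.peptide for f in six_frame_translate(transcript)}
            assert by_id[rec.model_id] in frames[rec.frame]

    def test_background_sequences_carry_no_planted_domains(self, spec):
        rules = generate_rule_set(spec)
        proteins, _, truth = generate_proteome(rules, spec)
        background_ids = {r.model_id for r in truth.records if r.family is None}
        assert len(background_ids) == 3
        hits = exact_match_scan(
            [p for p in proteins if p.id in background_ids], rules.all_domains()
        )
        assert hits == []

    def test_byte_identical_fasta_for_same_seed(self, spec, tmp_path):
        rules = generate_rule_set(spec)
        outputs = []
        for run in ("a", "b"):
            proteins, transcripts, _ = generate_proteome(rules, spec)
            pp, tp = tmp_path / f"p_{run}.fa", tmp_path / f"t_{run}.fa"
            write_fasta(proteins, pp)
            write_fasta(transcripts, tp)
            outputs.append((pp.read_bytes(), tp.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_unknown_family_in_size_spec_rejected(self, spec):
        rules = generate_rule_set(spec)
        bad = dataclasses.replace(spec, family_size_distribution={"NOPE": 3})
        with pytest.raises(ConfigurationError, match="NOPE"):
            generate_proteome(rules, bad)


class TestGenerateDomainHits:
    @pytest.fixture
    def truth_and_spec(self):
        spec = SyntheticSpec(n_families=4, family_size_distribution=4,
                             models_per_gene=1, seed=6, n_background_genes=0)
        rules = generate_rule_set(spec)
        _, _, truth = generate_proteome(rules, spec)
        return truth, spec

    def test_zero_noise_equals_planted_architecture(self, truth_and_spec):
        truth, spec = truth_and_spec
        hits = generate_domain_hits(truth, spec)
        planted = {
            (r.model_id, d, s, e) for r in truth.records
            for d, s, e in r.architecture
        }
        assert {(h.seq_id, h.domain, h.start, h.end) for h in hits} == planted

    def test_evalue_monotone_in_match_length(self):
        assert planted_evalue(30) < planted_evalue(15) < planted_evalue(8)
        assert planted_evalue(10_000) == 1e-300

    def test_noisy_table_reproducible(self, truth_and_spec):
        truth, spec = truth_and_spec
        noisy = dataclasses.replace(spec, hit_noise=0.5)
        assert generate_domain_hits(truth, noisy) == generate_domain_hits(
            truth, noisy
        )

    def test_drop_only_noise_matches_binomial_expectation(self):
        # 100 planted hits, drop rate 0.1, 1000 seeds: mean retained ~ 90
        truth = GroundTruth(
            records=[
                GroundTruthRecord(f"G{i}", f"G{i}.1", "F", (("D0", 1, 15),), 1)
                for i in range(100)
            ],
            vocabulary=("D0",),
        )
        retained = []
        for seed in range(1000):
            spec = SyntheticSpec(n_families=1, seed=seed)
            hits = generate_domain_hits(truth, spec, add_rate=0.0, drop_rate=0.1)
            retained.append(len(hits))
        mean = np.mean(retained)
        se = math.sqrt(100 * 0.1 * 0.9) / math.sqrt(len(retained))
        assert abs(mean - 90.0) <= 3 * se


class TestGeneratePipelineOutputs:
    @pytest.fixture
    def truth(self):
        spec = SyntheticSpec(n_families=4, family_size_distribution=5,
                             models_per_gene=1, seed=8, n_background_genes=0)
        rules = generate_rule_set(spec)
        _, _, truth = generate_proteome(rules, spec)
        return truth

    def test_zero_disagreement_tables_match_truth(self, truth):
        tfcat, itak, rule = generate_pipeline_outputs(truth)
        expected = {(r.model_id, r.frame, r.family) for r in truth.classifiable()}
        for table in (tfcat, itak):
            assert {(r.seq_id, r.frame, r.family) for r in table} == expected
        assert {(r.seq_id, r.frame, r.family) for r in rule
                if r.kind == "transcript"} == expected

    def test_rule_table_emits_both_record_kinds(self, truth):
        _, _, rule = generate_pipeline_outputs(truth)
        kinds = {(r.source, r.kind) for r in rule}
        assert kinds == {("ruleP", "protein"), ("ruleT", "transcript")}

    def test_disagreement_rate_perturbs_only_that_source(self, truth):
        tfcat, itak, _ = generate_pipeline_outputs(truth, (0.5, 0.0, 0.0))
        expected = {(r.seq_id, r.frame, r.family) for r in itak}
        got = {(r.seq_id, r.frame, r.family) for r in tfcat}
        assert got != expected  # perturbed
        assert len(expected) == len(truth.classifiable())  # untouched

    def test_family_dropped_by_one_source_recovered_in_merge(self, truth):
        from tfrep.consensus_merge import merge

        victim = truth.classifiable()[0].family
        tfcat, itak, rule = generate_pipeline_outputs(truth)
        tfcat = [r for r in tfcat if r.family != victim]
        merged = merge([], tfcat, itak, [r for r in rule if r.kind == "transcript"])
        assert victim in merged.families()


class TestMotifs:
    def test_motif_deterministic_and_distinct(self):
        assert motif_for_domain("DOM0001") == motif_for_domain("DOM0001")
        motifs = {motif_for_domain(f"DOM{i:04d}") for i in range(200)}
        assert len(motifs) == 200

    def test_ground_truth_tsv_written(self, tmp_path):
        spec = SyntheticSpec(n_families=2, family_size_distribution=2,
                             models_per_gene=1, seed=1)
        rules = generate_rule_set(spec)
        _, _, truth = generate_proteome(rules, spec)
        out = tmp_path / "truth.tsv"
        truth.write_tsv(out)
        lines = out.read_text().splitlines()
        assert len(lines) == 1 + len(truth.records)
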