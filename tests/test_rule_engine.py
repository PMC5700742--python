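import itertools

import numpy as np
import pytest

from tfrep.errors import ConfigurationError, InputError
from tfrep.rule_engine import (
    DomainHit,
    FamilyRule,
    FamilyRuleSet,
    classify_sequence,
    classify_set,
    load_rules,
    read_domtblout,
    read_hits_tsv,
    resolve_synonym,
    write_hits_tsv,
)

from conftest import hit

# ---------------------------------------------------------------------------
# independent oracle: plain enumeration of the rule semantics


def oracle_classify(present, rules, mode, evalues, bitscores):
    """Brute-force family choice from a set of present domains."""
    satisfied = {}
    for name, rule in rules.families.items():
        if all(d in present for d in rule.mandatory) and not any(
            d in present for d in rule.forbidden
        ):
            satisfied[name] = rule
    if not satisfied:
        return None
    if mode == "strict":
        return next(iter(satisfied)) if len(satisfied) == 1 else None
    keyed = [
        min((evalues[d], -bitscores[d]) for d in rule.mandatory) + (name,)
        for name, rule in satisfied.items()
    ]
    return min(keyed)[2]


def random_small_ruleset(rng, domains):
    families = {}
    for i in range(int(rng.integers(1, 5))):
        k = int(rng.integers(1, 4))
        mand = frozenset(rng.choice(domains, size=k, replace=False))
        rest = [d for d in domains if d not in mand]
        n_forb = int(rng.integers(0, 3))
        forb = frozenset(rng.choice(rest, size=min(n_forb, len(rest)), replace=False))
        families[f"F{i}"] = FamilyRule(mand, forb)
    return FamilyRuleSet(families=families, provenance="random")


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["strict", "best-domain"])
    def test_agrees_with_enumeration_over_all_hit_subsets(self, mode):
        rng = np.random.default_rng(42)
        domains = [f"D{i}" for i in range(6)]
        for _ in range(40):
            rules = random_small_ruleset(rng, domains)
            evalues = {d: 10.0 ** -float(rng.integers(4, 50)) for d in domains}
            bitscores = {d: float(rng.integers(20, 200)) for d in domains}
            for r in range(len(domains) + 1):
                for subset in itertools.combinations(domains, r):
                    hits = [
                        hit(domain=d, evalue=evalues[d], bitscore=bitscores[d])
                        for d in subset
                    ]
                    got = classify_sequence(hits, rules, mode=mode)
                    want = oracle_classify(set(subset), rules, mode, evalues, bitscores)
                    assert got.family == want, (subset, rules.families, mode)


class TestLoadRules:
    def test_bundled_rule_file_totals(self, lang_rules):
        assert lang_rules.n_families == 111
        assert lang_rules.n_mandatory == 134
        assert lang_rules.n_forbidden == 89

    def test_empty_file_gives_empty_valid_set(self, tmp_path):
        p = tmp_path / "empty.yaml"
        p.write_text("")
        rules = load_rules(p)
        assert rules.n_families == 0

    def test_overlapping_mandatory_forbidden_rejected(self):
        rules = FamilyRuleSet(
            families={"F": FamilyRule(frozenset({"D1"}), frozenset({"D1"}))}
        )
        with pytest.raises(ConfigurationError, match="mandatory"):
            rules.validate()

    def test_unresolved_synonym_target_rejected(self):
        rules = FamilyRuleSet(
            families={"F": FamilyRule(frozenset({"D1"}))},
            synonyms={"G": "NOPE"},
        )
        with pytest.raises(ConfigurationError, match="synonym"):
            rules.validate()


class TestResolveSynonym:
    @pytest.mark.parametrize(
        "label,canonical",
        [
            ("NF-YC", "CCAAT-HAP5"),
            ("CCAAT-HAP5", "CCAAT-HAP5"),
            ("ABI3/VP1", "B3"),
        ],
    )
    def test_known_aliases(self, lang_rules, label, canonical):
        assert resolve_synonym(label, lang_rules) == canonical

    def test_unknown_label_returned_unchanged(self, lang_rules):
        assert resolve_synonym("made-up", lang_rules) == "made-up"

    def test_idempotent(self, lang_rules):
        for label in ["NF-YC", "C2H2", "made-up"]:
            once = resolve_synonym(label, lang_rules)
            assert resolve_synonym(once, lang_rules) == once


class TestClassifySequence:
    def test_single_satisfied_family_assigned(self, toy_rules):
        a = classify_sequence([hit(domain="NF-YB")], toy_rules)
        assert a.family == "CCAAT-HAP3" and a.reason == "assigned"

    def test_two_satisfied_families_conflict_in_strict_mode(self, toy_rules):
        hits = [hit(domain="NF-YB", evalue=1e-40), hit(domain="NF-YC", evalue=1e-10)]
        a = classify_sequence(hits, toy_rules)
        assert a.family is None and a.reason == "multi-family-conflict"

    def test_best_domain_mode_takes_lowest_evalue(self, toy_rules):
        hits = [hit(domain="NF-YB", evalue=1e-40), hit(domain="NF-YC", evalue=1e-10)]
        a = classify_sequence(hits, toy_rules, mode="best-domain")
        assert a.family == "CCAAT-HAP3"

    def test_forbidden_domain_blocks_assignment(self, toy_rules):
        hits = [hit(domain="D1"), hit(domain="D2")]
        a = classify_sequence(hits, toy_rules)
        assert a.family is None and a.reason == "forbidden-domain-present"

    def test_hits_above_threshold_ignored(self, toy_rules):
        a = classify_sequence([hit(domain="NF-YB", evalue=0.1)], toy_rules)
        assert a.reason == "no-rule-satisfied"

    def test_mixed_sequence_ids_rejected(self, toy_rules):
        hits = [hit(seq="a", domain="D1"), hit(seq="b", domain="D1")]
        with pytest.raises(InputError, match="multiple"):
            classify_sequence(hits, toy_rules)

    def test_adding_forbidden_hit_never_rescues(self, toy_rules):
        # monotonicity: a forbidden-domain hit cannot flip UNASSIGNED->assigned
        base = [hit(domain="D1")]
        assert classify_sequence(base, toy_rules).family == "FAM-A"
        blocked = classify_sequence(base + [hit(domain="D2")], toy_rules)
        assert blocked.family is None

    def test_best_domain_assigns_superset_of_strict(self):
        rng = np.random.default_rng(3)
        domains = [f"D{i}" for i in range(5)]
        for _ in range(50):
            rules = random_small_ruleset(rng, domains)
            subset = [d for d in domains if rng.random() < 0.5]
            hits = [hit(domain=d, evalue=10.0 ** -float(rng.integers(4, 30)))
                    for d in subset]
            strict = classify_sequence(hits, rules, mode="strict")
            best = classify_sequence(hits, rules, mode="best-domain")
            if strict.is_assigned:
                assert best.family == strict.family


class TestClassifySet:
    def test_empty_hit_table(self, toy_rules):
        assignments, counts = classify_set([], toy_rules)
        assert assignments == [] and not counts

    def test_conflict_excluded_strict_included_best_domain(self, toy_rules):
        hits = [
            hit(seq="ok", domain="NF-YB"),
            hit(seq="both", domain="NF-YB", evalue=1e-30),
            hit(seq="both", domain="NF-YC", evalue=1e-10),
        ]
        _, strict_counts = classify_set(hits, toy_rules, mode="strict")
        _, best_counts = classify_set(hits, toy_rules, mode="best-domain")
        assert strict_counts["CCAAT-HAP3"] == 1
        assert best_counts["CCAAT-HAP3"] == 2

    def test_frames_classified_independently(self, toy_rules):
        hits = [hit(seq="t", frame=1, domain="NF-YB"),
                hit(seq="t", frame=-2, domain="NF-YC")]
        assignments, counts = classify_set(hits, toy_rules)
        assert len(assignments) == 2
        assert counts["CCAAT-HAP3"] == 1 and counts["CCAAT-HAP5"] == 1


class TestHitIO:
    def test_hits_tsv_roundtrip(self, tmp_path):
        hits = [hit(seq="a", frame=2, domain="D1"), hit(seq="b", domain="D9")]
        p = tmp_path / "hits.tsv"
        write_hits_tsv(hits, p)
        back = read_hits_tsv(p)
        assert [(h.seq_id, h.frame, h.domain) for h in back] == [
            ("a", 2, "D1"), ("b", None, "D9")
        ]

    def test_domtblout_parsing(self, tmp_path):
        line = (
            "NF-YB PF02045.1 90 seq1_frame+2 - 300 1.2e-40 140.1 0.1 1 1 "
            "2e-42 1.1e-40 130.0 0.1 5 88 10 95 8 99 0.95 description here"
        )
        p = tmp_path / "scan.domtblout"
        p.write_text("# comment\n" + " ".join(line.split()) + "\n")
        (h,) = read_domtblout(p, frame_from_id=True)
        assert h.seq_id == "seq1" and h.frame == 2
        assert h.domain == "NF-YB"
        assert h.evalue == pytest.approx(1.1e-40)
        assert (h.start, h.end) == (8, 99)  # envelope coordinates
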