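import numpy as np
import pytest

from tfrep.msa_curation import Alignment
from tfrep.rule_engine import DomainHit, FamilyRule, FamilyRuleSet, bundled_rules


@pytest.fixture(scope="session")
def lang_rules():
    """The bundled synthetic reconstruction of the plant TF/TAP rule set."""
    return bundled_rules()


@pytest.fixture
def toy_rules():
    """Two CCAAT subfamilies plus a two-domain family with a forbidden
    domain: enough to exercise every classification outcome."""
    rules = FamilyRuleSet(
        families={
            "CCAAT-HAP3": FamilyRule(frozenset({"NF-YB"})),
            "CCAAT-HAP5": FamilyRule(frozenset({"NF-YC"})),
            "FAM-A": FamilyRule(frozenset({"D1"}), frozenset({"D2"})),
        },
        synonyms={"NF-YC": "CCAAT-HAP5", "NF-YB": "CCAAT-HAP3"},
        provenance="toy",
    )
    rules.validate()
    return rules


def hit(seq="s1", frame=None, domain="D1", evalue=1e-10, bitscore=50.0,
        start=1, end=15):
    return DomainHit(seq, frame, domain, evalue, bitscore, start, end)


@pytest.fixture
def make_hit():
    return hit


def pad_aligner(seqs):
    """Deterministic stub aligner: left-justify ungapped sequences with
    trailing gaps to a rectangle."""
    ids = [s for s, _ in seqs]
    rows = [r for _, r in seqs]
    width = max((len(r) for r in rows), default=0)
    return Alignment(ids, [r.ljust(width, "-") for r in rows])


@pytest.fixture
def stub_aligner():
    return pad_aligner


def random_alignment(rng, n_rows=None, n_cols=None):
    n_rows = n_rows or int(rng.integers(2, 12))
    n_cols = n_cols or int(rng.integers(5, 40))
    alphabet = list("ACDEFGHIKLMNPQRSTVWY-")
    probs = np.full(len(alphabet), 0.7 / 20)
    probs[-1] = 0.3
    rows = [
        "".join(rng.choice(alphabet, size=n_cols, p=probs)) for _ in range(n_rows)
    ]
    return Alignment([f"s{i}" for i in range(n_rows)], rows)
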