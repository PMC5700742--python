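"""Mandatory/forbidden domain-rule classification of TF/TAP families.

A family rule names the protein domains a sequence must carry (mandatory)
and those it must not (forbidden). A family is *satisfied* by a set of
domain hits iff every mandatory domain is present and no forbidden domain
is. Classification per (sequence, frame) then runs in one of two modes:

* ``strict`` — exactly one satisfied family is assigned; zero or two-plus
  satisfied families leave the sequence unassigned (with a reason).
* ``best-domain`` — among satisfied families, the one whose mandatory-domain
  hit has the strongest similarity (lowest e-value, bit score then family
  name as tie-breaks) wins. This resolves the multi-family conflicts that
  leave sequences unassigned in strict mode.

Family names are canonicalised through a synonym map before counting, so
the same family reported under different database aliases is counted once.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .errors import ConfigurationError, InputError

logger = logging.getLogger("tfrep")

UNASSIGNED = "UNASSIGNED"

DEFAULT_E_THRESHOLD = 1e-3


@dataclass(frozen=True)
class DomainHit:
    """One domain match on one sequence (and frame, for translated
    transcripts): the classifier's unit of evidence."""

    seq_id: str
    frame: Optional[int]
    domain: str
    evalue: float
    bitscore: float
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(
                f"hit {self.seq_id}/{self.domain}: start {self.start} > end {self.end}"
            )
        if self.evalue <= 0:
            raise InputError(
                f"hit {self.seq_id}/{self.domain}: e-value must be positive"
            )


@dataclass(frozen=True)
class FamilyRule:
    mandatory: frozenset[str]
    forbidden: frozenset[str] = frozenset()


@dataclass
class FamilyRuleSet:
    """Per-family mandatory/forbidden domain sets plus a synonym map."""

    families: dict[str, FamilyRule] = field(default_factory=dict)
    synonyms: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def validate(self) -> None:
        for name, rule in self.families.items():
            if not rule.mandatory:
                raise ConfigurationError(f"family {name!r}: empty mandatory set")
            overlap = rule.mandatory & rule.forbidden
            if overlap:
                raise ConfigurationError(
                    f"family {name!r}: domains {sorted(overlap)} both mandatory "
                    "and forbidden"
                )
        for alias, target in self.synonyms.items():
            if target not in self.families:
                raise ConfigurationError(
                    f"synonym {alias!r} -> {target!r}: target is not a known family"
                )

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_mandatory(self) -> int:
        return sum(len(r.mandatory) for r in self.families.values())

    @property
    def n_forbidden(self) -> int:
        return sum(len(r.forbidden) for r in self.families.values())

    def all_domains(self) -> frozenset[str]:
        out: set[str] = set()
        for rule in self.families.values():
            out |= rule.mandatory | rule.forbidden
        return frozenset(out)


@dataclass(frozen=True)
class Assignment:
    """Classification outcome for one (sequence, frame)."""

    seq_id: str
    frame: Optional[int]
    family: Optional[str]  # canonical name, or None when unassigned
    reason: str  # assigned | no-rule-satisfied | forbidden-domain-present |
    #              multi-family-conflict
    supporting_hits: tuple[DomainHit, ...] = ()

    def __post_init__(self) -> None:
        if (self.reason == "assigned") != (self.family is not None):
            raise InputError("reason 'assigned' iff a family is set")

    @property
    def is_assigned(self) -> bool:
        return self.family is not None


def load_rules(path: str | Path) -> FamilyRuleSet:
    """Load a family rule set from a YAML config.

    Expected layout::

        provenance: <label>
        families:
          <name>: {mandatory: [dom, ...], forbidden: [dom, ...]}
        synonyms:
          <alias>: <canonical name>
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        logger.warning("rule file %s is empty; loading an empty rule set", path)
        return FamilyRuleSet(provenance=str(path))
    families = {}
    for name, spec in (data.get("families") or {}).items():
        families[str(name)] = FamilyRule(
            mandatory=frozenset(spec.get("mandatory") or ()),
            forbidden=frozenset(spec.get("forbidden") or ()),
        )
    rules = FamilyRuleSet(
        families=families,
        synonyms={str(k): str(v) for k, v in (data.get("synonyms") or {}).items()},
        provenance=str(data.get("provenance", path)),
    )
    rules.validate()
    logger.info(
        "loaded %d families (%d mandatory + %d forbidden rules) from %s",
        rules.n_families, rules.n_mandatory, rules.n_forbidden, path,
    )
    return rules


def bundled_rules() -> FamilyRuleSet:
    """The rule set shipped with the package: a synthetic reconstruction in
    the shape of the Lang et al.-style plant TF/TAP rule system (111
    families, 134 mandatory + 89 forbidden rules, with synonym aliases)."""
    path = Path(__file__).parent / "data" / "rules_synthetic_lang_style.yaml"
    return load_rules(path)


def resolve_synonym(label: str, rules: FamilyRuleSet) -> str:
    """Map a family alias to its canonical name.

    Canonical names map to themselves; unknown labels are returned
    unchanged with a warning.
    """
    if label in rules.families:
        return label
    if label in rules.synonyms:
        return rules.synonyms[label]
    logger.warning("unknown family label %r: returned unchanged", label)
    return label


def _satisfied_families(
    present: frozenset[str], rules: FamilyRuleSet
) -> tuple[dict[str, FamilyRule], bool]:
    """Canonical families satisfied by the present domains, plus a flag for
    whether any family failed *only* because of a forbidden domain."""
    satisfied: dict[str, FamilyRule] = {}
    forbidden_blocked = False
    for name, rule in rules.families.items():
        if rule.mandatory <= present:
            if rule.forbidden & present:
                forbidden_blocked = True
            else:
                satisfied[resolve_synonym(name, rules)] = rule
    return satisfied, forbidden_blocked


def classify_sequence(
    hits: Sequence[DomainHit],
    rules: FamilyRuleSet,
    e_threshold: float = DEFAULT_E_THRESHOLD,
    mode: str = "strict",
) -> Assignment:
    """Classify one (sequence, frame) from its domain hits.

    Hits with e-value above ``e_threshold`` are ignored. See module
    docstring for the strict / best-domain contracts.
    """
    if mode not in ("strict", "best-domain"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if e_threshold <= 0:
        raise ConfigurationError("e_threshold must be positive")
    keys = {(h.seq_id, h.frame) for h in hits}
    if len(keys) > 1:
        raise InputError(f"hits span multiple (sequence, frame) keys: {sorted(keys)}")
    seq_id, frame = next(iter(keys)) if keys else ("", None)

    passing = [h for h in hits if h.evalue <= e_threshold]
    present = frozenset(h.domain for h in passing)
    satisfied, forbidden_blocked = _satisfied_families(present, rules)

    def _support(rule: FamilyRule) -> tuple[DomainHit, ...]:
        return tuple(h for h in passing if h.domain in rule.mandatory)

    if not satisfied:
        reason = "forbidden-domain-present" if forbidden_blocked else "no-rule-satisfied"
        return Assignment(seq_id, frame, None, reason, tuple(passing))
    if len(satisfied) == 1:
        family, rule = next(iter(satisfied.items()))
        return Assignment(seq_id, frame, family, "assigned", _support(rule))
    if mode == "strict":
        return Assignment(seq_id, frame, None, "multi-family-conflict", tuple(passing))

    # best-domain: strongest mandatory-domain hit wins (lowest e-value, then
    # highest bit score, then lexicographically smallest family name).
    def strength(item: tuple[str, FamilyRule]) -> tuple[float, float, str]:
        family, rule = item
        best = min((h.evalue, -h.bitscore) for h in _support(rule))
        return (best[0], best[1], family)

    ranked = sorted(satisfied.items(), key=strength)
    if len(ranked) > 1 and strength(ranked[0])[:2] == strength(ranked[1])[:2]:
        logger.info(
            "best-domain tie on %s between %s and %s: chose %s (lexicographic)",
            seq_id, ranked[0][0], ranked[1][0], ranked[0][0],
        )
    family, rule = ranked[0]
    return Assignment(seq_id, frame, family, "assigned", _support(rule))


def classify_set(
    hits: Iterable[DomainHit],
    rules: FamilyRuleSet,
    e_threshold: float = DEFAULT_E_THRESHOLD,
    mode: str = "strict",
) -> tuple[list[Assignment], Counter]:
    """Classify every (sequence, frame) with at least one passing hit.

    Returns the assignment list and per-canonical-family counts of
    assigned sequences.
    """
    grouped: dict[tuple[str, Optional[int]], list[DomainHit]] = defaultdict(list)
    for h in hits:
        grouped[(h.seq_id, h.frame)].append(h)
    assignments = []
    counts: Counter = Counter()
    for key in sorted(grouped, key=lambda k: (k[0], k[1] if k[1] is not None else 0)):
        group = grouped[key]
        if not any(h.evalue <= e_threshold for h in group):
            continue
        asn = classify_sequence(group, rules, e_threshold, mode)
        assignments.append(asn)
        if asn.is_assigned:
            counts[asn.family] += 1
    return assignments, counts


# ---------------------------------------------------------------------------
# I/O: HMMER3 per-domain tabular output, generic hit TSV, assignment TSV

_FRAME_PATTERN = re.compile(r"_frame([+-][123])$")


def _split_frame(seq_id: str) -> tuple[str, Optional[int]]:
    m = _FRAME_PATTERN.search(seq_id)
    if m:
        return seq_id[: m.start()], int(m.group(1))
    return seq_id, None


def read_domtblout(path: str | Path, frame_from_id: bool = False) -> list[DomainHit]:
    """Parse HMMER3 ``--domtblout`` per-domain output (hmmscan layout:
    target = domain model, query = sequence). Uses the independent
    e-value, the domain bit score and the envelope coordinates.

    With ``frame_from_id``, a trailing ``_frame±k`` tag on the query name
    is split off into the hit's frame field.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 23:
                raise InputError(f"{path}: malformed domtblout line: {line[:60]!r}")
            seq_id, frame = _split_frame(f[3]) if frame_from_id else (f[3], None)
            hits.append(
                DomainHit(
                    seq_id=seq_id,
                    frame=frame,
                    domain=f[0],
                    evalue=float(f[12]),
                    bitscore=float(f[13]),
                    start=int(f[19]),
                    end=int(f[20]),
                )
            )
    return hits


def read_hits_tsv(path: str | Path) -> list[DomainHit]:
    """Read the generic 7-column hit TSV:
    seq_id, frame ('.' for proteins), domain, e-value, bit score, start, end.
    """
    hits = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 7:
                raise InputError(f"{path}:{ln}: expected 7 columns, got {len(f)}")
            frame = None if f[1] in (".", "") else int(f[1])
            hits.append(
                DomainHit(f[0], frame, f[2], float(f[3]), float(f[4]),
                          int(f[5]), int(f[6]))
            )
    return hits


def write_hits_tsv(hits: Sequence[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            frame = "." if h.frame is None else f"{h.frame:+d}"
            fh.write(
                f"{h.seq_id}\t{frame}\t{h.domain}\t{h.evalue:.3g}\t"
                f"{h.bitscore:.1f}\t{h.start}\t{h.end}\n"
            )


def write_assignments_tsv(assignments: Sequence[Assignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tframe\tfamily\treason\n")
        for a in assignments:
            frame = "." if a.frame is None else f"{a.frame:+d}"
            fam = a.family if a.family is not None else UNASSIGNED
            fh.write(f"{a.seq_id}\t{frame}\t{fam}\t{a.reason}\n")
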