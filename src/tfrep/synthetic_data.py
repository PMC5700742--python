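"""Synthetic genomes with planted TF-family domain architectures.

Everything the classification pipeline consumes can be generated here
with known ground truth: family rule sets (mandatory/forbidden domain
sets over a domain vocabulary), proteomes whose family members carry
their mandatory domains as planted motifs (decoys additionally carry a
forbidden domain), transcripts encoding each protein in a recorded
reading frame with short UTRs, domain-hit tables with controllable noise,
discordant outputs from three pseudo-pipelines, and a reference
transcript atlas with a tissue x transcript FPKM matrix.

Planted domains are realized as fixed high-information motif strings
(15 residues, derived deterministically from the domain id) embedded in
random background residues, so a trivial exact-match scanner can stand in
for an HMM-based domain caller. All randomness flows from the spec seed;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .consensus_merge import PipelineRecord
from .errors import ConfigurationError
from .rule_engine import DomainHit, FamilyRule, FamilyRuleSet
from .sequence_prep import SeqRecordT, reverse_complement, six_frame_translate

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MOTIF_LENGTH = 15
EVALUE_CAP = 1e-300

#: one representative codon per amino acid (plus a stop), for
#: reverse-translating planted proteins into transcripts
_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

CountLike = Union[int, tuple[int, int], dict]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration; all randomness derives from ``seed``."""

    n_families: int = 25
    domains_per_family: tuple[int, int] = (1, 2)
    #: mandatory/forbidden shares of the domain vocabulary, mirroring the
    #: roughly 60/40 mandatory-to-forbidden rule mix of plant TF rule sets
    mandatory_fraction: float = 0.6
    forbidden_fraction: float = 0.4
    family_size_distribution: CountLike = (2, 8)
    models_per_gene: CountLike = (1, 2)
    decoy_rate: float = 0.0
    hit_noise: float = 0.0
    seed: int = 0
    n_domains: int = 80
    n_background_genes: int = 10

    def __post_init__(self) -> None:
        for name in ("mandatory_fraction", "forbidden_fraction", "decoy_rate",
                     "hit_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.mandatory_fraction + self.forbidden_fraction > 1.0 + 1e-9:
            raise ConfigurationError("mandatory + forbidden fractions exceed 1")
        for name in ("n_families", "n_domains", "n_background_genes"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        lo, hi = self.domains_per_family
        if lo < 1 or hi < lo:
            raise ConfigurationError("domains_per_family must be a range with lo >= 1")


@dataclass(frozen=True)
class GroundTruthRecord:
    """Planted truth for one gene model."""

    gene_id: str
    model_id: str
    family: Optional[str]
    architecture: tuple[tuple[str, int, int], ...]  # (domain, start, end)
    frame: int
    is_decoy: bool = False


@dataclass
class GroundTruth:
    records: list[GroundTruthRecord] = field(default_factory=list)
    vocabulary: tuple[str, ...] = ()
    seed: int = 0
    #: model id -> generated transcript residues (used by the expression
    #: generator to plant reference transcripts)
    transcript_seqs: dict[str, str] = field(default_factory=dict)

    def gene_ids(self) -> set[str]:
        return {r.gene_id for r in self.records}

    def classifiable(self) -> list[GroundTruthRecord]:
        """Models a strict mandatory/forbidden classifier should assign:
        family members that are not decoys."""
        return [r for r in self.records if r.family is not None and not r.is_decoy]

    def expected_family_counts(self) -> dict[str, tuple[int, int, int]]:
        """Per family: (domain records, sequences, genes) a noise-free
        pipeline should recover (one family claim per member model)."""
        out: dict[str, tuple[set, set]] = {}
        for r in self.classifiable():
            seqs, genes = out.setdefault(r.family, (set(), set()))
            seqs.add(r.model_id)
            genes.add(r.gene_id)
        return {
            fam: (len(seqs), len(seqs), len(genes))
            for fam, (seqs, genes) in sorted(out.items())
        }

    def expected_totals(self) -> tuple[int, int, int]:
        members = self.classifiable()
        return (
            len(members),
            len({r.model_id for r in members}),
            len({r.gene_id for r in members}),
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tmodel_id\tfamily\tframe\tis_decoy\tarchitecture\n")
            for r in self.records:
                arch = ";".join(f"{d}:{s}-{e}" for d, s, e in r.architecture)
                fam = r.family if r.family is not None else "."
                fh.write(
                    f"{r.gene_id}\t{r.model_id}\t{fam}\t{r.frame:+d}\t"
                    f"{int(r.is_decoy)}\t{arch}\n"
                )


def motif_for_domain(domain: str, length: int = MOTIF_LENGTH) -> str:
    """Deterministic high-information motif string for a domain id."""
    rng = np.random.default_rng(zlib.crc32(domain.encode()))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def planted_evalue(match_length: int) -> float:
    """Synthetic hit e-value: monotone decreasing in match length,
    10^-(length/2) capped at 1e-300."""
    return max(10.0 ** (-match_length / 2.0), EVALUE_CAP)


def _draw_count(rng: np.random.Generator, dist: CountLike, key=None) -> int:
    if isinstance(dist, dict):
        return int(dist[key])
    if isinstance(dist, tuple):
        lo, hi = dist
        return int(rng.integers(lo, hi + 1))
    return int(dist)


# ---------------------------------------------------------------------------
# rule-set generation


def generate_rule_set(spec: SyntheticSpec) -> FamilyRuleSet:
    """Generate a family rule set over a synthetic domain vocabulary.

    Each family receives a unique 'primary' mandatory domain (so no
    family's mandatory set is a subset of another family's planted
    architecture), optional shared mandatory domains, and at least one
    forbidden domain when the forbidden pool is non-empty.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = [f"DOM{i:04d}" for i in range(spec.n_domains)]
    n_mand = int(round(spec.mandatory_fraction * spec.n_domains))
    n_forb = int(round(spec.forbidden_fraction * spec.n_domains))
    if spec.n_families > 0 and n_mand < spec.n_families:
        raise ConfigurationError(
            f"mandatory pool ({n_mand} domains) smaller than n_families "
            f"({spec.n_families}); enlarge n_domains or mandatory_fraction"
        )
    primary = vocab[: spec.n_families]
    shared = vocab[spec.n_families : n_mand]
    forbidden_pool = vocab[n_mand : n_mand + n_forb]

    families: dict[str, FamilyRule] = {}
    for i in range(spec.n_families):
        name = f"FAM{i + 1:03d}"
        k = _draw_count(rng, spec.domains_per_family)
        extras = (
            list(rng.choice(shared, size=min(k - 1, len(shared)), replace=False))
            if k > 1 and shared
            else []
        )
        forb = (
            frozenset(
                rng.choice(
                    forbidden_pool,
                    size=min(int(rng.integers(1, 3)), len(forbidden_pool)),
                    replace=False,
                )
            )
            if forbidden_pool
            else frozenset()
        )
        families[name] = FamilyRule(frozenset([primary[i]] + extras), forb)

    synonyms = {
        f"{name}-ALIAS": name for name in list(families)[: min(2, len(families))]
    }
    rules = FamilyRuleSet(families, synonyms, provenance=f"synthetic(seed={spec.seed})")
    rules.validate()
    return rules


def serialize_rule_set(rules: FamilyRuleSet) -> str:
    """Stable YAML-compatible text serialization (for determinism checks
    and for writing swappable rule configs)."""
    lines = [f"provenance: {rules.provenance}", "families:"]
    for name in sorted(rules.families):
        r = rules.families[name]
        lines.append(f"  {name}:")
        lines.append(f"    mandatory: [{', '.join(sorted(r.mandatory))}]")
        lines.append(f"    forbidden: [{', '.join(sorted(r.forbidden))}]")
    lines.append("synonyms:")
    for alias in sorted(rules.synonyms):
        lines.append(f"  {alias}: {rules.synonyms[alias]}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# proteome generation


def _random_residues(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _build_protein(
    rng: np.random.Generator, motifs: Sequence[str], domains: Sequence[str]
) -> tuple[str, tuple[tuple[str, int, int], ...]]:
    """Embed motifs into background residues; returns the protein and the
    planted (domain, start, end) architecture with 1-based coordinates."""
    parts = [_random_residues(rng, int(rng.integers(10, 40)))]
    arch = []
    pos = len(parts[0])
    for domain, motif in zip(domains, motifs):
        arch.append((domain, pos + 1, pos + len(motif)))
        parts.append(motif)
        pos += len(motif)
        spacer = _random_residues(rng, int(rng.integers(5, 30)))
        parts.append(spacer)
        pos += len(spacer)
    return "".join(parts), tuple(arch)


def _encode_transcript(
    rng: np.random.Generator, protein: str
) -> tuple[str, int]:
    """Reverse-translate a protein into a transcript with random UTRs
    (uniform 0-30 nt) on a random strand; returns (sequence, frame)."""
    cds = "".join(_CODON_OF[aa] for aa in protein) + "TAA"
    utr5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 31))))
    utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 31))))
    forward = utr5 + cds + utr3
    frame = (len(utr5) % 3) + 1
    if rng.random() < 0.5:
        return forward, frame
    return reverse_complement(forward), -frame


def generate_proteome(
    rules: FamilyRuleSet, spec: SyntheticSpec
) -> tuple[list[SeqRecordT], list[SeqRecordT], GroundTruth]:
    """Generate (protein records, transcript records, ground truth).

    Family members carry all their mandatory domains as planted motifs;
    decoys (at ``decoy_rate``) additionally carry one of the family's
    forbidden domains; background genes carry no planted domains.
    """
    if not rules.families:
        raise ConfigurationError("generate_proteome requires a non-empty rule set")
    if isinstance(spec.family_size_distribution, dict):
        unknown = set(spec.family_size_distribution) - set(rules.families)
        if unknown:
            raise ConfigurationError(
                f"family sizes given for families absent from rules: {sorted(unknown)}"
            )
    rng = np.random.default_rng(spec.seed + 1)
    proteins: list[SeqRecordT] = []
    transcripts: list[SeqRecordT] = []
    truth = GroundTruth(vocabulary=tuple(sorted(rules.all_domains())), seed=spec.seed)

    gene_counter = 0

    def _emit(family: Optional[str], domains: Sequence[str], is_decoy: bool,
              gene_id: str, model_id: str) -> None:
        motifs = [motif_for_domain(d) for d in domains]
        protein, arch = _build_protein(rng, motifs, domains)
        transcript, frame = _encode_transcript(rng, protein)
        proteins.append(SeqRecordT(model_id, "protein", protein, "v1"))
        transcripts.append(SeqRecordT(model_id, "nucleotide", transcript, "v1"))
        truth.records.append(
            GroundTruthRecord(gene_id, model_id, family, arch, frame, is_decoy)
        )
        truth.transcript_seqs[model_id] = transcript

    for family in sorted(rules.families):
        rule = rules.families[family]
        size = _draw_count(rng, spec.family_size_distribution, family)
        for _ in range(size):
            gene_counter += 1
            gene_id = f"SYNG{gene_counter:05d}"
            n_models = max(1, _draw_count(rng, spec.models_per_gene))
            for m in range(n_models):
                domains = sorted(rule.mandatory)
                is_decoy = bool(rule.forbidden) and rng.random() < spec.decoy_rate
                if is_decoy:
                    domains = domains + [
                        str(rng.choice(sorted(rule.forbidden)))
                    ]
                _emit(family, domains, is_decoy, gene_id, f"{gene_id}.{m + 1}")

    for _ in range(spec.n_background_genes):
        gene_counter += 1
        gene_id = f"SYNG{gene_counter:05d}"
        _emit(None, [], False, gene_id, f"{gene_id}.1")

    return proteins, transcripts, truth


# ---------------------------------------------------------------------------
# domain hits


def generate_domain_hits(
    truth: GroundTruth,
    spec: SyntheticSpec,
    add_rate: Optional[float] = None,
    drop_rate: Optional[float] = None,
) -> list[DomainHit]:
    """Emulate an HMM-scanner hit table from the planted architectures.

    With zero noise the hits equal the planted architectures exactly.
    Noise drops each planted hit with probability ``drop_rate`` and adds a
    spurious hit per sequence with probability ``add_rate`` (both default
    to ``spec.hit_noise``). E-values are monotone decreasing in planted
    match length.
    """
    add_rate = spec.hit_noise if add_rate is None else add_rate
    drop_rate = spec.hit_noise if drop_rate is None else drop_rate
    rng = np.random.default_rng(spec.seed + 2)
    hits: list[DomainHit] = []
    vocab = list(truth.vocabulary)
    for rec in truth.records:
        for domain, start, end in rec.architecture:
            if drop_rate > 0 and rng.random() < drop_rate:
                continue
            length = end - start + 1
            hits.append(
                DomainHit(rec.model_id, None, domain, planted_evalue(length),
                          2.0 * length, start, end)
            )
        if vocab and add_rate > 0 and rng.random() < add_rate:
            domain = str(rng.choice(vocab))
            start = int(rng.integers(1, 50))
            hits.append(
                DomainHit(rec.model_id, None, domain, planted_evalue(10),
                          20.0, start, start + 9)
            )
    return hits


def exact_match_scan(
    records: Iterable[SeqRecordT], domains: Iterable[str]
) -> list[DomainHit]:
    """Stand-in domain caller: exact motif matching on protein records."""
    out = []
    motifs = {d: motif_for_domain(d) for d in domains}
    for rec in records:
        for domain, motif in motifs.items():
            pos = rec.residues.find(motif)
            while pos != -1:
                out.append(
                    DomainHit(rec.id, None, domain, planted_evalue(len(motif)),
                              2.0 * len(motif), pos + 1, pos + len(motif))
                )
                pos = rec.residues.find(motif, pos + 1)
    return out


def scan_six_frames(
    transcripts: Iterable[SeqRecordT], domains: Iterable[str]
) -> list[DomainHit]:
    """Six-frame translate transcripts and exact-match scan every frame;
    hits carry the frame they were found on."""
    out = []
    motifs = {d: motif_for_domain(d) for d in domains}
    for rec in transcripts:
        for ft in six_frame_translate(rec):
            for domain, motif in motifs.items():
                pos = ft.peptide.find(motif)
                while pos != -1:
                    out.append(
                        DomainHit(rec.id, ft.frame, domain,
                                  planted_evalue(len(motif)), 2.0 * len(motif),
                                  pos + 1, pos + len(motif))
                    )
                    pos = ft.peptide.find(motif, pos + 1)
    return out


# ---------------------------------------------------------------------------
# pseudo-pipeline outputs


def generate_pipeline_outputs(
    truth: GroundTruth,
    disagreement: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: Optional[int] = None,
) -> tuple[list[PipelineRecord], list[PipelineRecord], list[PipelineRecord]]:
    """Emulate three classifier outputs entering the consensus merge.

    Returns (PlantTFcat-style transcripts, iTAK-style transcripts,
    rule-pipeline records). The rule-pipeline table carries both
    protein-kind (source ``ruleP``) and transcript-kind (``ruleT``)
    records. Each source perturbs the truth independently at its
    disagreement rate: half the perturbations drop the claim, half
    relabel it to a random other family.
    """
    rng = np.random.default_rng((truth.seed if seed is None else seed) + 3)
    families = sorted({r.family for r in truth.classifiable()})

    def perturb(family: str, rate: float) -> Optional[str]:
        if rate > 0 and rng.random() < rate:
            others = [f for f in families if f != family]
            if rng.random() < 0.5 or not others:
                return None  # dropped
            return str(rng.choice(others))
        return family

    def transcript_table(source: str, rate: float) -> list[PipelineRecord]:
        out = []
        for rec in truth.classifiable():
            fam = perturb(rec.family, rate)
            if fam is not None:
                out.append(
                    PipelineRecord(source, "transcript", rec.model_id, rec.frame, fam)
                )
        return out

    tfcat = transcript_table("TFcatT", disagreement[0])
    itak = transcript_table("iTAKT", disagreement[1])
    rule_table = []
    for rec in truth.classifiable():
        fam = perturb(rec.family, disagreement[2])
        if fam is not None:
            rule_table.append(PipelineRecord("ruleP", "protein", rec.model_id, None, fam))
    rule_table.extend(transcript_table("ruleT", disagreement[2]))
    return tfcat, itak, rule_table


# ---------------------------------------------------------------------------
# expression atlas


@dataclass
class ExpressionTruth:
    """Reference atlas with the planted query -> reference links."""

    reference: list[SeqRecordT]
    fpkm: pd.DataFrame
    links: dict[str, str]  # query model id -> reference transcript id


def _mutate(rng: np.random.Generator, seq: str, fraction: float) -> str:
    chars = list(seq)
    n = max(1, int(len(chars) * fraction))
    idx = rng.choice(len(chars), size=min(n, len(chars)), replace=False)
    for i in idx:
        alternatives = [c for c in "ACGT" if c != chars[i]]
        chars[i] = str(rng.choice(alternatives))
    return "".join(chars)


def generate_expression(
    truth: GroundTruth,
    tissues: Sequence[str],
    seed: Optional[int] = None,
    zero_row_rate: float = 0.05,
) -> ExpressionTruth:
    """Emulate a reference transcript atlas plus FPKM matrix.

    Every truth transcript gets exactly one identical reference transcript
    (its planted best hit); every fifth query also gets a distractor
    mutated to <= 80% identity. FPKM values are non-negative lognormal
    draws, with a few all-zero rows (silent transcripts) preserved.
    """
    rng = np.random.default_rng((truth.seed if seed is None else seed) + 4)
    reference: list[SeqRecordT] = []
    links: dict[str, str] = {}
    for i, (model_id, seq) in enumerate(sorted(truth.transcript_seqs.items())):
        ref_id = f"VuREF{i + 1:05d}"
        reference.append(SeqRecordT(ref_id, "nucleotide", seq, "atlas"))
        links[model_id] = ref_id
        if i % 5 == 0:
            dec_id = f"VuDEC{i + 1:05d}"
            reference.append(
                SeqRecordT(dec_id, "nucleotide", _mutate(rng, seq, 0.25), "atlas")
            )
    fpkm = pd.DataFrame(
        np.round(rng.lognormal(mean=1.0, sigma=1.0,
                               size=(len(reference), len(tissues))), 2),
        index=[r.id for r in reference],
        columns=list(tissues),
    )
    zero_rows = rng.random(len(reference)) < zero_row_rate
    fpkm.loc[zero_rows, :] = 0.0
    fpkm.index.name = "transcript"
    return ExpressionTruth(reference, fpkm, links)
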