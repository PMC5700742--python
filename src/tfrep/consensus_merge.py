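"""Priority merge of classifications from multiple pipelines.

Several family-identification pipelines are run over both the protein set
and six-frame-translated transcripts; their claims are merged into one
non-redundant repertoire by a fixed priority rule: protein-level records
are accepted first, and for transcript records the higher-priority
pipeline's claim for the same (sequence, frame, family) survives while the
lower-priority duplicate is eliminated (and logged). A protein record
additionally suppresses transcript records for the same (sequence, family)
on any frame — the locus is already represented by its protein.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from .errors import ConfigurationError, InputError
from .sequence_prep import gene_id_of

#: Priority order: rule-pipeline proteins, then PlantTFcat-style,
#: iTAK-style and rule-pipeline transcripts.
DEFAULT_PRIORITY = ("ruleP", "TFcatT", "iTAKT", "ruleT")


@dataclass(frozen=True)
class PipelineRecord:
    """One (source pipeline, sequence, frame, family) claim."""

    source: str
    kind: str  # protein | transcript
    seq_id: str
    frame: Optional[int]
    family: str

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "transcript"):
            raise InputError(f"record {self.seq_id!r}: unknown kind {self.kind!r}")
        if (self.kind == "transcript") != (self.frame is not None):
            raise InputError(
                f"record {self.seq_id!r}: frame must be present iff kind=transcript"
            )


@dataclass
class MergedRepertoire:
    """Accepted records plus a log of every eliminated duplicate."""

    accepted: list[PipelineRecord] = field(default_factory=list)
    #: (eliminated record, source of the surviving record)
    dedup_log: list[tuple[PipelineRecord, str]] = field(default_factory=list)

    def families(self) -> set[str]:
        return {r.family for r in self.accepted}


def merge(
    protein_records: Iterable[PipelineRecord],
    tfcat_records: Iterable[PipelineRecord],
    itak_records: Iterable[PipelineRecord],
    rule_records: Iterable[PipelineRecord],
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> MergedRepertoire:
    """Merge four pipeline outputs under the stated priority rule.

    Family labels must already be canonical. Records whose source is not
    in ``priority`` raise a configuration error.
    """
    by_source: dict[str, list[PipelineRecord]] = defaultdict(list)
    for group in (protein_records, tfcat_records, itak_records, rule_records):
        for rec in group:
            if rec.source not in priority:
                raise ConfigurationError(
                    f"record {rec.seq_id!r}: source {rec.source!r} not in "
                    f"priority order {tuple(priority)}"
                )
            by_source[rec.source].append(rec)

    out = MergedRepertoire()
    accepted_keys: dict[tuple[str, Optional[int], str], str] = {}
    protein_keys: dict[tuple[str, str], str] = {}

    # Proteins first (regardless of their position in the priority order):
    # protein presence suppresses same-(sequence, family) transcripts.
    for pass_kind in ("protein", "transcript"):
        for source in priority:
            for rec in by_source.get(source, ()):
                if rec.kind != pass_kind:
                    continue
                if (
                    rec.kind == "transcript"
                    and (rec.seq_id, rec.family) in protein_keys
                ):
                    out.dedup_log.append(
                        (rec, protein_keys[(rec.seq_id, rec.family)])
                    )
                    continue
                key = (rec.seq_id, rec.frame, rec.family)
                if key in accepted_keys:
                    out.dedup_log.append((rec, accepted_keys[key]))
                    continue
                accepted_keys[key] = rec.source
                if rec.kind == "protein":
                    protein_keys[(rec.seq_id, rec.family)] = rec.source
                out.accepted.append(rec)
    return out


def domains_sequences_genes(
    merged: MergedRepertoire,
    gene_map: Callable[[str], str] | dict[str, str] = gene_id_of,
) -> tuple[tuple[int, int, int], dict[str, tuple[int, int, int]]]:
    """Count the repertoire at domain, sequence and gene granularity.

    * domain count — accepted (sequence, frame, family) records;
    * sequence count — distinct (sequence, frame) pairs;
    * gene count — distinct gene ids under ``gene_map``.

    Returns ``((domains, sequences, genes), per_family)`` with the same
    triple per family. Totals always satisfy domains >= sequences >= genes.
    """
    if isinstance(gene_map, dict):
        mapper = gene_map.__getitem__
    else:
        mapper = gene_map
    seqs: set[tuple[str, Optional[int]]] = set()
    genes: set[str] = set()
    fam_records: dict[str, list[PipelineRecord]] = defaultdict(list)
    for rec in merged.accepted:
        seqs.add((rec.seq_id, rec.frame))
        genes.add(mapper(rec.seq_id))
        fam_records[rec.family].append(rec)
    per_family = {}
    for fam, recs in sorted(fam_records.items()):
        per_family[fam] = (
            len(recs),
            len({(r.seq_id, r.frame) for r in recs}),
            len({mapper(r.seq_id) for r in recs}),
        )
    return (len(merged.accepted), len(seqs), len(genes)), per_family


# ---------------------------------------------------------------------------
# TSV I/O


def read_records_tsv(path: str | Path) -> list[PipelineRecord]:
    """Read a 5-column record table: source, kind, seq_id, frame, family."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("source\t"):
                continue
            f = line.split("\t")
            if len(f) != 5:
                raise InputError(f"{path}:{ln}: expected 5 columns, got {len(f)}")
            frame = None if f[3] in (".", "") else int(f[3])
            out.append(PipelineRecord(f[0], f[1], f[2], frame, f[4]))
    return out


def write_records_tsv(records: Sequence[PipelineRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\tkind\tseq_id\tframe\tfamily\n")
        for r in records:
            frame = "." if r.frame is None else f"{r.frame:+d}"
            fh.write(f"{r.source}\t{r.kind}\t{r.seq_id}\t{frame}\t{r.family}\n")


def write_dedup_log(merged: MergedRepertoire, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("eliminated_source\tkind\tseq_id\tframe\tfamily\tsurviving_source\n")
        for rec, survivor in merged.dedup_log:
            frame = "." if rec.frame is None else f"{rec.frame:+d}"
            fh.write(
                f"{rec.source}\t{rec.kind}\t{rec.seq_id}\t{frame}\t"
                f"{rec.family}\t{survivor}\n"
            )
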