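"""Sequence preparation: non-redundant merging of annotation versions,
six-frame translation, and gene-id derivation from gene-model ids.

Gene annotations often ship several protein/transcript versions of the same
locus; downstream family classification wants (a) one record per distinct
amino-acid composition, (b) all six translation frames of every nucleotide
sequence (classification runs per frame), and (c) a mapping from gene-model
ids (``Gene.1``, ``Gene.2``) to gene ids so repertoires can be counted at
either granularity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import InputError

FRAMES = (1, 2, 3, -1, -2, -3)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_MAP[_stop] = "*"

_NUC_CHARS = frozenset("ACGTN")
# IUPAC ambiguity codes other than N; rejected unless allow_ambiguity is set.
_AMBIG_CHARS = frozenset("RYSWKMBDHV")


@dataclass(frozen=True)
class SeqRecordT:
    """One sequence with its provenance label.

    kind is ``protein`` or ``nucleotide``; residues are upper-case.
    """

    id: str
    kind: str
    residues: str
    source_version: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError(f"record {self.id!r}: empty residue string")
        if self.kind not in ("protein", "nucleotide"):
            raise InputError(f"record {self.id!r}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class FrameTranslation:
    """Translation of one reading frame of a nucleotide sequence.

    Frames +1/+2/+3 read the forward strand at offsets 0/1/2; frames
    -1/-2/-3 read the reverse complement at the same offsets. Stop codons
    are rendered '*' and retained.
    """

    parent_id: str
    frame: int
    peptide: str

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise InputError(f"illegal frame {self.frame}")


def merge_annotation_versions(
    set_a: Iterable[SeqRecordT], set_b: Iterable[SeqRecordT]
) -> list[SeqRecordT]:
    """Combine two protein sets into one non-redundant set.

    Exactly one record is kept per distinct residue string; the first-seen
    id is retained and input order is otherwise preserved (set_a before
    set_b). Nucleotide records are rejected.
    """
    seen: dict[str, SeqRecordT] = {}
    out: list[SeqRecordT] = []
    for rec in list(set_a) + list(set_b):
        if rec.kind != "protein":
            raise InputError(
                f"merge_annotation_versions: record {rec.id!r} is {rec.kind}, "
                "expected protein"
            )
        if rec.residues not in seen:
            seen[rec.residues] = rec
            out.append(rec)
    return out


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate_frame(seq: str, offset: int) -> str:
    """Translate one frame; any codon containing N (or another ambiguity
    code admitted upstream) becomes 'X'."""
    n_codons = max(0, (len(seq) - offset) // 3)
    out = []
    for i in range(n_codons):
        codon = seq[offset + 3 * i : offset + 3 * i + 3]
        out.append(_CODON_MAP.get(codon, "X"))
    return "".join(out)


def six_frame_translate(
    rec: SeqRecordT, allow_ambiguity: bool = False
) -> list[FrameTranslation]:
    """Translate a nucleotide record in all six reading frames.

    The standard genetic code (translation table 1) is used; N translates
    to 'X'. Other IUPAC ambiguity codes raise unless ``allow_ambiguity``
    is set, in which case they also render as 'X'. Frames shorter than one
    codon are emitted as empty peptides.
    """
    if rec.kind != "nucleotide":
        raise InputError(f"six_frame_translate: record {rec.id!r} is not nucleotide")
    seq = rec.residues.upper()
    allowed = _NUC_CHARS | _AMBIG_CHARS if allow_ambiguity else _NUC_CHARS
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise InputError(
                f"record {rec.id!r}: illegal character {ch!r} at position {pos + 1}"
            )
    rc = reverse_complement(seq)
    out = []
    for frame in FRAMES:
        strand_seq = seq if frame > 0 else rc
        out.append(
            FrameTranslation(rec.id, frame, _translate_frame(strand_seq, abs(frame) - 1))
        )
    return out


DEFAULT_MODEL_SUFFIX = r"\.\d+$"


def gene_id_of(model_id: str, pattern: str = DEFAULT_MODEL_SUFFIX) -> str:
    """Derive a gene id from a gene-model id.

    Strips a trailing gene-model suffix (default a Phytozome-style
    ``.<integer>``) when present; ids without the suffix are returned
    unchanged.
    """
    return re.sub(pattern, "", model_id)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, kind: str, source_version: str = "") -> list[SeqRecordT]:
    return [
        SeqRecordT(r.id, kind, str(r.seq).upper(), source_version)
        for r in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Sequence[SeqRecordT], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")
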