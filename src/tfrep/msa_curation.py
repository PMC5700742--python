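"""Iterative multiple-sequence-alignment curation.

Family alignments are cleaned by a three-filter cycle run around an
external aligner until the alignment stabilises:

1. drop duplicate rows and rows covering < 30% of the alignment columns;
2. drop columns that are >= 90% gaps;
3. drop near-duplicate sequences (pairwise identity >= 95%, greedy
   keep-first);
4. re-align the survivors and repeat until neither the sequence count nor
   the column count changes.

The aligner is any callable mapping an ungapped sequence list to an
Alignment (MAFFT in production, a deterministic stub in tests). Curated
sequences can also be rebuilt from motif tables (e.g. MEME output) by
concatenating each sequence's motifs in start order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from .errors import InputError

logger = logging.getLogger("tfrep")

GAP = "-"


@dataclass
class Alignment:
    """A rectangular alignment: parallel id and row lists, gap '-'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise InputError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self) -> list[tuple[str, str]]:
        return [(i, r.replace(GAP, "")) for i, r in zip(self.ids, self.rows)]


@dataclass(frozen=True)
class CurationParams:
    min_seq_coverage: float = 0.30
    max_col_gap_frac: float = 0.90
    max_pairwise_identity: float = 0.95
    max_cycles: int = 20


#: Motif-discovery defaults used when running the external finder.
MOTIF_DISCOVERY_DEFAULTS = {
    "e_value_threshold": 0.001,
    "min_width": 8,
    "max_width": 200,
    "mode": "anr",  # any number of repeats
    "max_motifs": 100,
}


@dataclass(frozen=True)
class MotifAnnotation:
    """One discovered motif occurrence on one sequence."""

    seq_id: str
    motif_id: str
    start: int  # 1-based inclusive
    end: int
    motif: str
    evalue: float = float("nan")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(
                f"motif {self.motif_id} on {self.seq_id}: start > end"
            )


def drop_low_coverage(aln: Alignment, min_seq_coverage: float = 0.30) -> Alignment:
    """Remove duplicate rows (first kept) and rows whose non-gap fraction
    is strictly below the threshold."""
    seen: set[str] = set()
    ids, rows = [], []
    ncols = aln.n_cols
    for sid, row in zip(aln.ids, aln.rows):
        if row in seen:
            continue
        cov = (len(row) - row.count(GAP)) / ncols if ncols else 0.0
        if ncols and cov < min_seq_coverage:
            continue
        seen.add(row)
        ids.append(sid)
        rows.append(row)
    return Alignment(ids, rows)


def drop_gappy_columns(aln: Alignment, max_col_gap_frac: float = 0.90) -> Alignment:
    """Remove columns whose gap fraction is >= the threshold (inclusive,
    'at least 90% gaps')."""
    if not aln.rows:
        return Alignment([], [])
    nrows = aln.n_rows
    keep = [
        c
        for c in range(aln.n_cols)
        if sum(r[c] == GAP for r in aln.rows) / nrows < max_col_gap_frac
    ]
    return Alignment(list(aln.ids), ["".join(r[c] for c in keep) for r in aln.rows])


def pairwise_identity(a: str, b: str) -> float:
    """Identity of two aligned rows: matching non-gap positions over the
    aligned length excluding dual-gap columns."""
    matches = 0
    comparable = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        comparable += 1
        if x == y and x != GAP:
            matches += 1
    return matches / comparable if comparable else 0.0


def drop_near_duplicates(
    aln: Alignment, max_pairwise_identity: float = 0.95
) -> Alignment:
    """Greedy scan in input order: a row is dropped when its identity to
    any already-kept row is >= the threshold."""
    ids, rows = [], []
    for sid, row in zip(aln.ids, aln.rows):
        if any(pairwise_identity(row, kept) >= max_pairwise_identity for kept in rows):
            continue
        ids.append(sid)
        rows.append(row)
    return Alignment(ids, rows)


def apply_filters(aln: Alignment, params: CurationParams) -> Alignment:
    aln = drop_low_coverage(aln, params.min_seq_coverage)
    aln = drop_gappy_columns(aln, params.max_col_gap_frac)
    return drop_near_duplicates(aln, params.max_pairwise_identity)


def curation_cycle(
    seqs: Sequence[tuple[str, str]],
    aligner: Callable[[Sequence[tuple[str, str]]], Alignment],
    params: CurationParams = CurationParams(),
) -> tuple[Alignment, list[dict]]:
    """Run the align-filter loop to a fixed point.

    Terminates when a cycle's filters change neither the sequence count
    nor the column count, or at ``params.max_cycles`` with a warning.
    Returns the final alignment and a per-cycle log of counts.
    """
    log: list[dict] = []
    current = list(seqs)
    aln = Alignment([], [])
    for cycle in range(1, params.max_cycles + 1):
        try:
            aln = aligner(current)
        except Exception as exc:
            raise InputError(f"aligner failed at cycle {cycle}: {exc}") from exc
        before = (aln.n_rows, aln.n_cols)
        aln = apply_filters(aln, params)
        after = (aln.n_rows, aln.n_cols)
        log.append(
            {"cycle": cycle, "n_seq_in": before[0], "n_col_in": before[1],
             "n_seq": after[0], "n_col": after[1]}
        )
        if after == before:
            return aln, log
        current = aln.degapped()
    logger.warning(
        "curation did not stabilise within %d cycles", params.max_cycles
    )
    return aln, log


def build_curated_sequence(motifs: Iterable[MotifAnnotation]) -> str:
    """Concatenate one sequence's motifs in order of start coordinate
    (ties by end, then motif id); overlaps are concatenated literally."""
    motifs = list(motifs)
    if len({m.seq_id for m in motifs}) > 1:
        raise InputError("motifs span multiple sequences")
    ordered = sorted(motifs, key=lambda m: (m.start, m.end, m.motif_id))
    return "".join(m.motif for m in ordered)


# ---------------------------------------------------------------------------
# I/O: aligned FASTA, motif tables


def read_aligned_fasta(path: str | Path) -> Alignment:
    ids, rows = [], []
    sid, buf = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if sid is not None:
                    ids.append(sid)
                    rows.append("".join(buf))
                sid, buf = line[1:].split()[0], []
            elif line:
                buf.append(line)
    if sid is not None:
        ids.append(sid)
        rows.append("".join(buf))
    return Alignment(ids, rows)


def write_aligned_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


def read_motifs_tsv(path: str | Path) -> list[MotifAnnotation]:
    """Read a motif table: seq_id, motif_id, start, end, motif
    [, e-value]."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) not in (5, 6):
                raise InputError(f"{path}:{ln}: expected 5-6 columns, got {len(f)}")
            ev = float(f[5]) if len(f) == 6 else float("nan")
            out.append(MotifAnnotation(f[0], f[1], int(f[2]), int(f[3]), f[4], ev))
    return out


_MEME_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)")
_MEME_SITES_RE = re.compile(r"sites sorted by position p-value")
_MEME_EVALUE_RE = re.compile(r"E-value\s*=\s*(\S+)")
_MEME_WIDTH_RE = re.compile(r"width\s*=\s*(\d+)")


def parse_meme_text(path: str | Path) -> list[MotifAnnotation]:
    """Lenient parser for MEME plain-text output: collects, for each MOTIF
    block, the 'sites sorted by position p-value' table (sequence name,
    start, site string)."""
    out: list[MotifAnnotation] = []
    motif_id: Optional[str] = None
    evalue = float("nan")
    width: Optional[int] = None
    in_sites = False
    with open(path) as fh:
        for line in fh:
            m = _MEME_MOTIF_RE.match(line)
            if m:
                motif_id = m.group(1)
                em = _MEME_EVALUE_RE.search(line)
                evalue = float(em.group(1)) if em else float("nan")
                wm = _MEME_WIDTH_RE.search(line)
                width = int(wm.group(1)) if wm else None
                in_sites = False
                continue
            if motif_id and _MEME_SITES_RE.search(line):
                in_sites = True
                continue
            if in_sites:
                s = line.strip()
                if not s or s.startswith(("-", "Sequence name")):
                    if s.startswith("--") and out and out[-1].motif_id == motif_id:
                        in_sites = False  # closing rule of the table
                    continue
                f = s.split()
                # layout: name [strand] start p-value [flank] site [flank]
                try:
                    start_idx = next(
                        i for i, tok in enumerate(f[1:], 1) if tok.isdigit()
                    )
                    start = int(f[start_idx])
                    candidates = [
                        tok
                        for tok in f[start_idx + 2 :]
                        if re.fullmatch(r"[A-Za-z]+", tok)
                    ]
                    if width is not None:
                        site = next(t for t in candidates if len(t) == width)
                    else:
                        site = max(candidates, key=len)
                except (StopIteration, ValueError):
                    continue
                out.append(
                    MotifAnnotation(
                        f[0], motif_id, start, start + len(site) - 1, site, evalue
                    )
                )
    return out
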