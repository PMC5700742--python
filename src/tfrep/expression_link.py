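"""Linking repertoire sequences to reference-transcript expression.

Each classified TF/TAP sequence is searched against a reference transcript
atlas; the best hit under an E-value cutoff (default 1e-5, inclusive)
defines its transcript, whose FPKM row over the tissue panel is joined to
the sequence. Families with no repertoire member at all can be probed by
homolog rescue: a similarity search of related-species family members
against the raw assembly, counting distinct subjects under a looser
cutoff (default strictly below 1e-3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger("tfrep")

LINK_E_THRESHOLD = 1e-5
RESCUE_E_THRESHOLD = 1e-3

#: Standard 12-column tabular search output (BLAST outfmt 6 dialect).
OUTFMT6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HitRecord:
    """One local alignment between a query and a reference subject."""

    query: str
    subject: str
    pident: float
    length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise InputError(f"hit {self.query}->{self.subject}: negative e-value")


def read_outfmt6(path: str | Path) -> list[HitRecord]:
    df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    return [
        HitRecord(str(r.query), str(r.subject), float(r.pident), int(r.length),
                  float(r.evalue), float(r.bitscore))
        for r in df.itertuples()
    ]


def best_hit(
    hits: Iterable[HitRecord], e_threshold: float = LINK_E_THRESHOLD
) -> dict[str, HitRecord]:
    """Per query, the subject with the minimal e-value among hits passing
    the (inclusive) threshold; ties broken by higher bit score, then
    lexicographically smaller subject id. Invariant under row order."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.evalue > e_threshold:
            continue
        cur = best.get(h.query)
        if cur is None or (h.evalue, -h.bitscore, h.subject) < (
            cur.evalue, -cur.bitscore, cur.subject
        ):
            best[h.query] = h
    return best


@dataclass
class LinkTable:
    """Per-query link plus joined expression.

    ``table`` is indexed by query id with columns: subject, evalue, family,
    then one column per tissue (NaN for queries whose subject is missing
    from the expression matrix, or that have no link at all).
    """

    table: pd.DataFrame
    tissues: list[str]


def join_expression(
    links: dict[str, HitRecord],
    fpkm: pd.DataFrame,
    families: Optional[dict[str, str]] = None,
    queries: Optional[Sequence[str]] = None,
) -> LinkTable:
    """Join each linked query to its subject's FPKM row.

    ``fpkm`` is transcripts x tissues. Queries whose subject is absent
    from the matrix get an all-missing vector with a warning; ``queries``
    may extend the row universe to unlinked queries (also all-missing).
    """
    if (fpkm.to_numpy() < 0).any():
        raise InputError("FPKM values must be non-negative")
    tissues = list(fpkm.columns)
    families = families or {}
    all_queries = list(dict.fromkeys(list(queries or []) + list(links)))
    rows = []
    for q in all_queries:
        hit = links.get(q)
        if hit is None:
            rows.append([None, math.nan, families.get(q)] + [math.nan] * len(tissues))
            continue
        if hit.subject in fpkm.index:
            expr = list(fpkm.loc[hit.subject])
        else:
            logger.warning(
                "query %s: subject %s absent from expression matrix", q, hit.subject
            )
            expr = [math.nan] * len(tissues)
        rows.append([hit.subject, hit.evalue, families.get(q)] + expr)
    table = pd.DataFrame(
        rows, index=pd.Index(all_queries, name="query"),
        columns=["subject", "evalue", "family"] + tissues,
    )
    return LinkTable(table, tissues)


def homolog_rescue(
    family: str,
    query_seqs: Sequence[tuple[str, str]],
    target_db: Sequence[tuple[str, str]],
    search: Callable[[Sequence[tuple[str, str]], Sequence[tuple[str, str]]],
                     Iterable[HitRecord]],
    e_threshold: float = RESCUE_E_THRESHOLD,
) -> tuple[int, list[HitRecord]]:
    """Search family members from a related species against a raw assembly
    and count distinct subjects with at least one hit strictly below the
    cutoff. ``search`` is any procedure emitting HitRecord rows (a real
    similarity-search tool in production, a stub in tests)."""
    hits = [h for h in search(query_seqs, target_db) if h.evalue < e_threshold]
    subjects = sorted({h.subject for h in hits})
    logger.info("family %s: rescued %d subjects", family, len(subjects))
    return len(subjects), hits


def heatmap_table(
    link_table: LinkTable,
    ordering: Optional[Sequence[str]] = None,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Expression matrix for rendering next to a tree.

    Rows follow ``ordering`` (e.g. tree leaf order) when given, else input
    order; unlinked queries keep their all-missing rows so heatmap rows
    stay aligned with tree tips. ``log_transform`` applies log10(x + 1).
    """
    mat = link_table.table[link_table.tissues]
    if ordering is not None:
        mat = mat.reindex(list(ordering))
    if log_transform:
        mat = np.log10(mat + 1.0)
    return mat


def plot_heatmap(matrix: pd.DataFrame, path: str | Path, **imshow_kwargs):
    """Thin optional rendering layer (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * matrix.shape[1]), max(4, 0.25 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", **imshow_kwargs)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="FPKM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_link_tsv(link_table: LinkTable, path: str | Path) -> None:
    link_table.table.to_csv(path, sep="\t", na_rep="NA")


def read_fpkm_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
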