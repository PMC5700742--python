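"""Comparative family-representation statistics between species.

A species' TF/TAP repertoire is tabulated per family at three
granularities (domains, sequences i.e. gene models, genes). Two species
are then compared family by family on one of three bases:

* ``repertoire_share`` — the family's fraction of its species' repertoire;
* ``raw_count`` — absolute counts (optionally with the comparator divided
  by a ploidy factor, e.g. halving a tetraploid before comparison with a
  diploid);
* ``protein_gene_share`` — the family's gene count over the species'
  protein-coding gene total.

The query/comparator ratio is banded: within [0.9, 1.1] (inclusive) the
family is similarly represented; above 1.1 over-represented; below 0.9
under-represented. The band is deliberately not reciprocal-symmetric — the
query species is always the numerator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .errors import ConfigurationError, InputError

COLUMNS = ("domains", "sequences", "genes")
_GRANULARITY = {"domains": "domains", "gene_models": "sequences", "genes": "genes"}
BASES = ("repertoire_share", "raw_count", "protein_gene_share")


def _half_away_from_zero(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class RepertoireTable:
    """Per-family repertoire counts for one species.

    ``counts`` is a DataFrame indexed by family with columns
    domains/sequences/genes; totals are column sums unless the table was
    built totals-only. ``protein_coding_total`` is the species' number of
    protein-coding genes (denominator of the protein_gene_share basis).
    """

    species: str
    counts: Optional[pd.DataFrame] = None
    totals_override: Optional[dict[str, float]] = None
    protein_coding_total: Optional[int] = None

    def __post_init__(self) -> None:
        if self.counts is None and self.totals_override is None:
            raise InputError("a RepertoireTable needs counts or totals")
        if self.counts is not None:
            self.counts = self.counts.reindex(columns=list(COLUMNS)).fillna(0)
            if (self.counts.to_numpy() < 0).any():
                raise InputError(f"{self.species}: negative counts")

    @classmethod
    def from_per_family(
        cls,
        species: str,
        per_family: Mapping[str, tuple[int, int, int]],
        protein_coding_total: Optional[int] = None,
    ) -> "RepertoireTable":
        """Build from a {family: (domains, sequences, genes)} mapping, e.g.
        the per-family output of consensus_merge.domains_sequences_genes."""
        df = pd.DataFrame.from_dict(per_family, orient="index", columns=list(COLUMNS))
        return cls(species, df.sort_index(), protein_coding_total=protein_coding_total)

    def families(self) -> list[str]:
        return [] if self.counts is None else list(self.counts.index)

    def count(self, family: str, granularity: str = "gene_models") -> float:
        col = _GRANULARITY[granularity]
        if self.counts is None or family not in self.counts.index:
            return 0.0
        return float(self.counts.loc[family, col])

    def total(self, granularity: str = "gene_models") -> float:
        col = _GRANULARITY[granularity]
        if self.totals_override is not None:
            return float(self.totals_override[col])
        return float(self.counts[col].sum())


@dataclass(frozen=True)
class ComparisonThresholds:
    lower: float = 0.9
    upper: float = 1.1

    def __post_init__(self) -> None:
        if not (0 < self.lower < 1 < self.upper):
            raise ConfigurationError(
                f"thresholds must satisfy 0 < lower < 1 < upper, "
                f"got ({self.lower}, {self.upper})"
            )


@dataclass
class RepresentationReport:
    """Per-family over/similar/under calls for a two-species comparison."""

    basis: str
    granularity: str
    ploidy_divisor: float
    per_family: pd.DataFrame  # index family; columns ratio, call
    summary: tuple[int, int, int]  # (n_under, n_similar, n_over)


def family_share(
    table: RepertoireTable,
    family: str,
    basis: str = "repertoire_share",
    granularity: str = "gene_models",
) -> float:
    """One family's measure under a basis, as a proportion for the share
    bases (multiply by 100 for display) or a count for raw_count.

    A zero denominator yields NaN (undefined share).
    """
    if basis not in BASES:
        raise ConfigurationError(f"unknown basis {basis!r}")
    count = table.count(family, granularity)
    if basis == "raw_count":
        return count
    if basis == "repertoire_share":
        denom = table.total(granularity)
    else:  # protein_gene_share: always at gene granularity per definition
        if table.protein_coding_total is None:
            raise InputError(
                f"{table.species}: protein_gene_share needs protein_coding_total"
            )
        count = table.count(family, "genes")
        denom = float(table.protein_coding_total)
    return count / denom if denom > 0 else math.nan


def compare(
    query: RepertoireTable,
    comparator: RepertoireTable,
    basis: str = "repertoire_share",
    granularity: str = "gene_models",
    thresholds: ComparisonThresholds = ComparisonThresholds(),
    ploidy_divisor: float = 1.0,
) -> RepresentationReport:
    """Call each family over-/similarly-/under-represented in the query.

    The family universe is the union of both tables; families present in
    exactly one species are flagged absent-query / absent-comparator and
    excluded from the summary triple. ``ploidy_divisor`` scales the
    comparator's counts before ratio formation on the raw_count basis
    (shares are scale-invariant, so it is a no-op there).
    """
    rows = []
    universe = sorted(set(query.families()) | set(comparator.families()))
    for fam in universe:
        q = family_share(query, fam, basis, granularity)
        c = family_share(comparator, fam, basis, granularity)
        if basis == "raw_count":
            c = c / ploidy_divisor
        q_present = q > 0
        c_present = c > 0
        if not q_present and not c_present:
            continue
        if not c_present:
            rows.append((fam, math.nan, "absent-comparator"))
            continue
        if not q_present:
            rows.append((fam, math.nan, "absent-query"))
            continue
        ratio = q / c
        if ratio < thresholds.lower:
            call = "under"
        elif ratio > thresholds.upper:
            call = "over"
        else:
            call = "similar"
        rows.append((fam, ratio, call))
    df = pd.DataFrame(rows, columns=["family", "ratio", "call"]).set_index("family")
    calls = df["call"]
    summary = (
        int((calls == "under").sum()),
        int((calls == "similar").sum()),
        int((calls == "over").sum()),
    )
    return RepresentationReport(basis, granularity, ploidy_divisor, df, summary)


def percent_difference(query_total: float, comparator_total: float, mode: str) -> float:
    """Headline percentage comparing two repertoire totals.

    ``fewer`` = (1 - q/c) * 100 (how much smaller the query is);
    ``of``    = (q/c) * 100 (the query as a percentage of the comparator).
    Full precision is returned; round to one decimal for display.
    """
    if mode not in ("fewer", "of"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if comparator_total == 0:
        return math.nan
    frac = query_total / comparator_total
    return (1.0 - frac) * 100.0 if mode == "fewer" else frac * 100.0


def halve_counts(
    table: RepertoireTable, divisor: float = 2.0
) -> RepertoireTable:
    """Divide every count by ``divisor`` with half-away-from-zero rounding
    (ploidy correction, e.g. halving a tetraploid comparator).

    Totals are recomputed from the divided per-family counts when
    per-family data exist, otherwise divided directly.
    """
    if divisor <= 0:
        raise ConfigurationError("divisor must be positive")
    if table.counts is not None:
        counts = table.counts.map(lambda x: _half_away_from_zero(x / divisor))
        return RepertoireTable(
            table.species, counts, protein_coding_total=table.protein_coding_total
        )
    totals = {
        k: _half_away_from_zero(v / divisor) for k, v in table.totals_override.items()
    }
    return RepertoireTable(
        table.species, None, totals, protein_coding_total=table.protein_coding_total
    )


# ---------------------------------------------------------------------------
# TSV I/O


def read_repertoire_tsv(
    path: str | Path, species: str, protein_coding_total: Optional[int] = None
) -> RepertoireTable:
    """Read a per-family table: family, domains, sequences, genes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RepertoireTable(species, df, protein_coding_total=protein_coding_total)


def write_repertoire_tsv(table: RepertoireTable, path: str | Path) -> None:
    if table.counts is None:
        raise InputError("totals-only table has no per-family rows to write")
    df = table.counts.copy()
    df.index.name = "family"
    df.to_csv(path, sep="\t")


def write_report_tsv(report: RepresentationReport, path: str | Path) -> None:
    df = report.per_family.copy()
    df["ratio"] = df["ratio"].round(4)
    df.to_csv(path, sep="\t")
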