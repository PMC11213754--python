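"""Taxon count-table summaries: relative abundance at a chosen rank, the
strict >threshold display filter, and kingdom-level proportions.

Profiles are computed against each sample's reads classified at least at
kingdom level; fully unclassified reads are excluded from the denominator
(the exclusion is logged per table). Taxa unassigned at the requested rank
aggregate under their deepest assigned rank, labeled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "RANKS",
    "UNASSIGNED",
    "TaxonTableError",
    "TaxonTable",
    "AbundanceProfile",
    "read_taxon_table",
    "relative_abundance",
    "filter_threshold",
    "domain_split",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
UNASSIGNED = "unassigned"
RESIDUAL_LABEL = "other/below-threshold"


class TaxonTableError(ValueError):
    pass


@dataclass
class TaxonTable:
    """Counts per (sample, taxon) with a rank lineage per taxon.

    ``lineage`` is indexed by taxon id with one column per rank in
    :data:`RANKS`; unassigned ranks hold the explicit :data:`UNASSIGNED`
    placeholder, never empty strings. ``counts`` shares the taxon index and
    has one integer column per sample.
    """

    lineage: pd.DataFrame
    counts: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.lineage.columns) != list(RANKS):
            raise TaxonTableError(f"lineage columns must be {RANKS}")
        if not self.lineage.index.equals(self.counts.index):
            raise TaxonTableError("lineage and counts must share the taxon index")
        if (self.counts.values < 0).any():
            raise TaxonTableError("negative counts")
        if (self.lineage.values == "").any():
            raise TaxonTableError("empty-string ranks; use the unassigned placeholder")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class AbundanceProfile:
    """Per-sample taxon percentages with a residual bucket.

    ``table`` maps each sample to ``{taxon_label: percent}``; ``residual``
    maps each sample to the pooled below-threshold/other percentage. Within
    every sample, retained percentages plus residual sum to 100.
    """

    rank: str
    table: dict[str, dict[str, float]]
    residual: dict[str, float]
    threshold: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        """Taxa x samples percentage matrix with a residual row appended."""
        df = pd.DataFrame(self.table).fillna(0.0)
        df.loc[RESIDUAL_LABEL] = pd.Series(self.residual)
        df.index.name = self.rank
        return df


def _parse_lineage(text: object) -> list[str]:
    if not isinstance(text, str) or not text.strip():
        return [UNASSIGNED] * len(RANKS)
    parts = [p.strip() for p in text.split(";")]
    parts = parts[: len(RANKS)]
    parts += [""] * (len(RANKS) - len(parts))
    return [p if p else UNASSIGNED for p in parts]


def read_taxon_table(path: str | Path, lineage_column: str | None = None) -> TaxonTable:
    """Read a TSV of taxon counts: one lineage column (semicolon-delimited
    ranks, kingdom first) plus one count column per sample.

    Malformed lineages are normalized to placeholders, duplicate lineages
    merged, and all-zero sample columns dropped — each with a logged warning.
    """
    df = pd.read_csv(path, sep="\t")
    if lineage_column is None:
        for cand in ("lineage", "taxonomy", "taxon"):
            if cand in df.columns:
                lineage_column = cand
                break
        else:
            raise TaxonTableError(
                "no lineage column found (expected one of lineage/taxonomy/taxon)"
            )
    warnings: list[str] = []
    lineage_rows = [_parse_lineage(v) for v in df[lineage_column]]
    n_malformed = sum(
        1 for v in df[lineage_column] if not isinstance(v, str) or not v.strip()
    )
    if n_malformed:
        warnings.append(f"{n_malformed} malformed lineages normalized to placeholders")
    counts = df.drop(columns=[lineage_column])
    try:
        counts = counts.astype(float)
    except ValueError as exc:
        raise TaxonTableError(f"non-numeric count column: {exc}") from exc
    if (counts.values < 0).any():
        raise TaxonTableError("negative counts in table")
    if (counts.values != counts.values.round()).any():
        raise TaxonTableError("non-integer counts in table")
    counts = counts.astype(int)
    lineage = pd.DataFrame(lineage_rows, columns=list(RANKS))
    key = lineage.apply(lambda r: ";".join(r), axis=1)
    if key.duplicated().any():
        dup = int(key.duplicated().sum())
        warnings.append(f"{dup} duplicate taxon rows merged")
        counts = counts.groupby(key).sum()
        lineage = lineage.assign(_key=key).drop_duplicates("_key").set_index("_key")
        lineage = lineage.loc[counts.index]
        index = pd.Index(counts.index, name="taxon_id")
        lineage.index = index
        counts.index = index
    empty = [s for s in counts.columns if counts[s].sum() == 0]
    if empty:
        warnings.append(f"dropped empty sample columns: {empty}")
        counts = counts.drop(columns=empty)
    return TaxonTable(lineage=lineage, counts=counts, warnings=warnings)


def _aggregation_labels(lineage: pd.DataFrame, rank: str) -> pd.Series:
    """Label each taxon at ``rank``, falling back to its deepest assigned rank."""
    idx = RANKS.index(rank)
    labels = []
    for _, row in lineage.iterrows():
        if row[rank] != UNASSIGNED:
            labels.append(row[rank])
            continue
        # fall back to the deepest rank assigned above the requested one
        for shallower in reversed(RANKS[:idx]):
            if row[shallower] != UNASSIGNED:
                labels.append(f"{row[shallower]} ({shallower})")
                break
        else:
            labels.append(UNASSIGNED)
    return pd.Series(labels, index=lineage.index)


def relative_abundance(t: TaxonTable, rank: str = "genus") -> AbundanceProfile:
    """Relative abundance (%) per sample at ``rank``, unfiltered.

    The denominator per sample is the total of reads classified at least at
    kingdom level; zero-total samples are excluded with a warning.
    """
    if rank not in RANKS:
        raise TaxonTableError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = _aggregation_labels(t.lineage, rank)
    classified = t.lineage["kingdom"] != UNASSIGNED
    n_excluded = int(t.counts.loc[~classified].values.sum())
    if n_excluded:
        t.warnings.append(
            f"{n_excluded} fully unclassified reads excluded from denominators"
        )
    counts = t.counts.loc[classified]
    grouped = counts.groupby(labels.loc[classified]).sum()
    table: dict[str, dict[str, float]] = {}
    for sample in grouped.columns:
        total = grouped[sample].sum()
        if total == 0:
            t.warnings.append(f"sample {sample!r} has no classified reads; excluded")
            continue
        pct = 100.0 * grouped[sample] / total
        table[sample] = {taxon: float(v) for taxon, v in pct.items() if v > 0}
    return AbundanceProfile(
        rank=rank, table=table, residual={s: 0.0 for s in table}, threshold=0.0
    )


def filter_threshold(p: AbundanceProfile, threshold: float = 1.0) -> AbundanceProfile:
    """Retain taxa strictly above ``threshold`` percent; pool the rest.

    Taxa at exactly the threshold are pooled (strict inequality). The
    per-sample normalization to 100% (retained + residual) is preserved.
    """
    if threshold < 0:
        raise TaxonTableError("threshold must be >= 0")
    table: dict[str, dict[str, float]] = {}
    residual: dict[str, float] = {}
    for sample, taxa in p.table.items():
        kept = {k: v for k, v in taxa.items() if v > threshold}
        residual[sample] = p.residual.get(sample, 0.0) + sum(
            v for k, v in taxa.items() if v <= threshold
        )
        table[sample] = kept
    return AbundanceProfile(
        rank=p.rank, table=table, residual=residual, threshold=threshold
    )


def domain_split(t: TaxonTable) -> pd.DataFrame:
    """Kingdom-level percentages per sample over all reads.

    Reads with a placeholder kingdom are bucketed under ``"other"``. Returns
    a kingdoms x samples DataFrame of percentages summing to 100 per sample.
    """
    kingdom = t.lineage["kingdom"].where(t.lineage["kingdom"] != UNASSIGNED, "other")
    grouped = t.counts.groupby(kingdom).sum()
    totals = grouped.sum(axis=0)
    nonzero = totals[totals > 0].index
    return 100.0 * grouped[nonzero] / totals[nonzero]
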