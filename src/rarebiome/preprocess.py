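"""Table hygiene and abundance transforms applied ahead of every screen.

The order of operations mirrors the study workflow: remove non-target OTUs
(mitochondria, chloroplast, plant/protist ribosomal sequences), drop global
singletons, sum replicate jars of each host x tissue x substrate treatment,
convert summed counts to relative percentages, and binarise at a detection
threshold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import OtuCountTable, SampleMetadata, TaxonomyTable

#: Case-insensitive substrings marking amplicons that are not bacteria/fungi.
DEFAULT_NONTARGET_RULES = (
    "mitochondri",
    "chloroplast",
    "plant",
    "protist",
    "viridiplantae",
    "streptophyta",
)

#: Row index names of a replicate-collapsed table.
GROUP_LEVELS = ("host", "tissue", "substrate")


def flag_nontarget(
    tax: TaxonomyTable,
    rules: tuple[str, ...] = DEFAULT_NONTARGET_RULES,
) -> set[str]:
    """OTU ids whose taxonomy matches any non-target keyword at any rank.

    Matching is case-insensitive substring search across all rank strings.
    Deterministic given the rule list; OTUs with empty taxonomy never match.
    """
    if not rules:
        raise ValueError("rules must be non-empty")
    patterns = [re.compile(re.escape(r), re.IGNORECASE) for r in rules]
    flagged: set[str] = set()
    joined = tax.frame.agg(" ".join, axis=1)
    for otu_id, text in joined.items():
        if any(p.search(text) for p in patterns):
            flagged.add(str(otu_id))
    return flagged


def drop_nontarget(counts: OtuCountTable, flagged: set[str]) -> OtuCountTable:
    keep = [o for o in counts.otu_ids if o not in flagged]
    return counts.select_otus(keep)


def drop_singletons(counts: OtuCountTable, min_total_reads: int = 2) -> OtuCountTable:
    """Remove OTUs whose total read count across all samples is below
    ``min_total_reads`` (default 2, i.e. global singletons go).

    The screen works on table-wide totals; the sample axis is untouched.
    """
    totals = counts.counts.sum(axis=0)
    keep = [o for o in counts.otu_ids if totals[o] >= min_total_reads]
    return counts.select_otus(keep)


def collapse_replicates(
    counts: OtuCountTable,
    meta: SampleMetadata,
    include_controls: bool = False,
) -> pd.DataFrame:
    """Sum replicate samples of each (host, tissue, substrate) treatment.

    Returns an integer DataFrame with a (host, tissue, substrate) MultiIndex.
    Total reads are conserved exactly (integer arithmetic). Unplanted control
    samples are excluded unless ``include_controls``.
    """
    missing = [s for s in counts.sample_ids if s not in set(meta.sample_ids)]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    sub = meta.frame.loc[counts.sample_ids]
    if not include_controls:
        keep = sub.index[sub["tissue"] != "control"]
        sub = sub.loc[keep]
    df = counts.counts.loc[sub.index]
    grouped = df.groupby(
        [sub["host"], sub["tissue"], sub["substrate"]], observed=True
    ).sum()
    grouped.index.names = list(GROUP_LEVELS)
    return grouped.astype(np.int64)


@dataclass(frozen=True)
class GroupedAbundanceTable:
    """Replicate-collapsed relative abundances in percent, per treatment group.

    ``values`` rows sum to 100 (tolerance 1e-6) except groups that had zero
    reads, which stay all-zero and are listed in ``zero_groups``.
    """

    marker: str
    values: pd.DataFrame  # MultiIndex (host, tissue, substrate) x OTUs, percent
    zero_groups: tuple[tuple[str, str, str], ...] = ()

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.columns)

    def compartment(self, tissue: str, substrate: str) -> pd.DataFrame:
        """Rows of one (tissue, substrate) compartment, indexed by host."""
        mask = (self.values.index.get_level_values("tissue") == tissue) & (
            self.values.index.get_level_values("substrate") == substrate
        )
        sub = self.values[mask]
        return sub.droplevel(["tissue", "substrate"])


def relative_abundance(grouped: pd.DataFrame, marker: str) -> GroupedAbundanceTable:
    """Scale each collapsed group row to percentages summing to 100.

    All-zero rows are left at zero and flagged rather than dropped, so the
    group axis stays aligned with the design.
    """
    totals = grouped.sum(axis=1)
    vals = grouped.astype(float)
    nonzero = totals > 0
    vals.loc[nonzero] = vals.loc[nonzero].div(totals[nonzero], axis=0) * 100.0
    zero_groups = tuple(tuple(ix) for ix in grouped.index[~nonzero])
    return GroupedAbundanceTable(marker=marker, values=vals, zero_groups=zero_groups)


@dataclass(frozen=True)
class PresenceMatrix:
    """Boolean detection matrix derived from a GroupedAbundanceTable.

    ``threshold_percent`` is recorded as provenance: a cell is True iff its
    relative abundance strictly exceeds the threshold. At threshold 0 this
    means >= 1 read in the collapsed group.
    """

    marker: str
    values: pd.DataFrame  # boolean, same axes as source
    threshold_percent: float

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.columns)

    def compartment(self, tissue: str, substrate: str) -> pd.DataFrame:
        mask = (self.values.index.get_level_values("tissue") == tissue) & (
            self.values.index.get_level_values("substrate") == substrate
        )
        return self.values[mask].droplevel(["tissue", "substrate"])

    def detected(self, host: str, tissue: str, substrate: str, otu_id: str) -> bool:
        key = (host, tissue, substrate)
        if key not in self.values.index:
            return False
        return bool(self.values.at[key, otu_id])


def presence(table: GroupedAbundanceTable, threshold_percent: float = 0.0) -> PresenceMatrix:
    """Binarise abundances: present iff strictly above ``threshold_percent``.

    Strict inequality makes the screen monotone: raising the threshold can
    only turn cells absent, never present.
    """
    if threshold_percent < 0:
        raise ValueError("threshold_percent must be >= 0")
    vals = table.values > threshold_percent
    return PresenceMatrix(
        marker=table.marker, values=vals, threshold_percent=float(threshold_percent)
    )
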