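"""End-to-end conveniences chaining the individual analysis stages.

These helpers wire counts -> hygiene -> collapsed abundances -> presence ->
screens -> transmission calls, exactly as the per-module functions would be
called by hand; they add no behaviour of their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from . import preprocess, rarity, transmission
from .preprocess import GroupedAbundanceTable, PresenceMatrix
from .rarity import DEFAULT_MAX_HOSTS, UncommonSet
from .tables_io import OtuCountTable, SampleMetadata, TaxonomyTable
from .transmission import ClassifierParams, SorensenTable, TransmissionCall

PLANT_COMPARTMENTS = tuple(
    (t, s) for t in ("shoot", "root", "rhizosphere") for s in ("sand", "soil")
)


@dataclass
class PipelineResult:
    """Everything the screens and the classifier derive from one marker."""

    marker: str
    grouped_counts: pd.DataFrame
    rel: GroupedAbundanceTable
    pres: PresenceMatrix
    uncommon: dict[tuple[str, str], UncommonSet]
    sorensen: SorensenTable
    calls: list[TransmissionCall]


def run_marker(
    counts: OtuCountTable,
    meta: SampleMetadata,
    tax: TaxonomyTable | None = None,
    drop_nontarget: bool = True,
    min_total_reads: int = 2,
    threshold_percent: float = 0.0,
    max_hosts: int = DEFAULT_MAX_HOSTS,
    params: ClassifierParams = ClassifierParams(),
    classify_tissues: tuple[str, ...] = ("shoot", "root", "rhizosphere"),
) -> PipelineResult:
    """Run the whole screening/transmission pipeline for one marker.

    Steps: non-target removal (if taxonomy given), singleton removal,
    replicate collapsing, percent normalisation, presence at
    ``threshold_percent``, per-compartment uncommon screens at
    ``max_hosts``, the substrate Sorensen table, and source classification
    of every soil-grown detection in ``classify_tissues``.
    """
    table = counts
    if drop_nontarget and tax is not None:
        flagged = preprocess.flag_nontarget(tax)
        table = preprocess.drop_nontarget(table, flagged)
    table = preprocess.drop_singletons(table, min_total_reads=min_total_reads)
    grouped = preprocess.collapse_replicates(table, meta)
    rel = preprocess.relative_abundance(grouped, marker=table.marker)
    pres = preprocess.presence(rel, threshold_percent)

    uncommon: dict[tuple[str, str], UncommonSet] = {}
    for tissue, substrate in PLANT_COMPARTMENTS:
        try:
            occ = rarity.species_occupancy(pres, tissue, substrate)
        except ValueError:
            continue
        uncommon[(tissue, substrate)] = rarity.screen_uncommon(occ, max_hosts=max_hosts)

    sor = transmission.substrate_similarity_table(pres, uncommon)
    calls: list[TransmissionCall] = []
    for tissue in classify_tissues:
        unc = uncommon.get((tissue, "soil"))
        if unc is None:
            continue
        calls.extend(transmission.classify_compartment(pres, unc, params))
    return PipelineResult(
        marker=table.marker,
        grouped_counts=grouped,
        rel=rel,
        pres=pres,
        uncommon=uncommon,
        sorensen=sor,
        calls=calls,
    )


def load_reference_similarity() -> pd.DataFrame:
    """The package's bundled per-host substrate-similarity reference table.

    17 hosts x 6 columns (fungal/bacterial x rhizosphere/root/shoot) of
    Sorensen similarities between soil- and sand-grown uncommon communities
    from the 17-species sealed-jar experiment.
    """
    with resources.files("rarebiome.data").joinpath("sorensen_reference.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def reference_similarity_means(ndigits: int = 2) -> dict[str, float]:
    """Column means of the bundled similarity table, rounded for reporting."""
    df = load_reference_similarity()
    return {col: round(float(df[col].mean()), ndigits) for col in df.columns}
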