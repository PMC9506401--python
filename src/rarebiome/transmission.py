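"""Seed-vs-soil transmission inference for uncommon OTUs.

Two complementary views:

* ``substrate_similarity_table`` quantifies, per host and tissue, how much of
  the uncommon community detected on field soil was also detected on sterile
  sand (Dice-Sorensen index on presence sets). Sand-grown plants can only
  have been inoculated by their seeds, so shared membership is evidence of
  vertical (seed) transmission.
* ``classify_source`` + ``annotate_flags`` reconstruct, per (OTU, host,
  tissue), the most plausible inoculum source of a soil-grown detection
  (seed / soil / unknown), with flags for one-off stochastic propagules and
  for biotic filtering (high rhizosphere occupancy, low root occupancy).

The classification rules are parameterised reconstructions of expert calls;
every numeric default lives in ``ClassifierParams`` and is surfaced on the
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .preprocess import PresenceMatrix
from .rarity import UncommonSet

PLANT_TISSUES = ("shoot", "root", "rhizosphere")


def sorensen(a: Iterable[str], b: Iterable[str]) -> float:
    """Dice-Sorensen similarity 2|A∩B| / (|A|+|B|) on presence sets.

    Defined as 0.0 when both sets are empty (no community observed on either
    substrate means no evidence of shared membership).
    """
    sa, sb = set(a), set(b)
    denom = len(sa) + len(sb)
    if denom == 0:
        return 0.0
    return 2.0 * len(sa & sb) / denom


@dataclass(frozen=True)
class SorensenEntry:
    host: str
    tissue: str
    marker: str
    similarity: float
    n_sand: int
    n_soil: int
    n_shared: int


@dataclass(frozen=True)
class SorensenTable:
    """Per-host substrate-similarity entries plus per-tissue column means."""

    marker: str
    entries: tuple[SorensenEntry, ...]
    omitted: tuple[tuple[str, str], ...] = ()  # (host, tissue) lacking one substrate

    def column_means(self, ndigits: int = 2) -> dict[str, float]:
        """Arithmetic mean of the per-host similarities for each tissue."""
        out: dict[str, float] = {}
        for tissue in sorted({e.tissue for e in self.entries}):
            vals = [e.similarity for e in self.entries if e.tissue == tissue]
            out[tissue] = round(sum(vals) / len(vals), ndigits)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                (e.host, e.tissue, e.similarity, e.n_sand, e.n_soil, e.n_shared)
                for e in self.entries
            ],
            columns=["host", "tissue", "similarity", "n_sand", "n_soil", "n_shared"],
        )
        return df


def substrate_similarity_table(
    pres: PresenceMatrix,
    uncommon_by_compartment: Mapping[tuple[str, str], UncommonSet],
    tissues: Sequence[str] = PLANT_TISSUES,
) -> SorensenTable:
    """One Sorensen entry per host x tissue comparing sand vs soil detections.

    For each host and tissue, A is the set of uncommon OTUs detected in that
    host's sand-grown group and B the soil-grown set; an OTU counts as
    uncommon if the screen flagged it in either substrate's compartment.
    Hosts missing one substrate's group are omitted (and reported).
    """
    entries: list[SorensenEntry] = []
    omitted: list[tuple[str, str]] = []
    for tissue in tissues:
        unc_sand = uncommon_by_compartment.get((tissue, "sand"))
        unc_soil = uncommon_by_compartment.get((tissue, "soil"))
        pool: set[str] = set()
        if unc_sand:
            pool |= set(unc_sand.otu_ids)
        if unc_soil:
            pool |= set(unc_soil.otu_ids)
        sand = pres.compartment(tissue, "sand")
        soil = pres.compartment(tissue, "soil")
        hosts = sorted(set(sand.index) | set(soil.index))
        for host in hosts:
            if host not in sand.index or host not in soil.index:
                omitted.append((host, tissue))
                continue
            a = {o for o in pool if o in sand.columns and sand.at[host, o]}
            b = {o for o in pool if o in soil.columns and soil.at[host, o]}
            entries.append(
                SorensenEntry(
                    host=host,
                    tissue=tissue,
                    marker=pres.marker,
                    similarity=sorensen(a, b),
                    n_sand=len(a),
                    n_soil=len(b),
                    n_shared=len(a & b),
                )
            )
    return SorensenTable(marker=pres.marker, entries=tuple(entries), omitted=tuple(omitted))


@dataclass(frozen=True)
class ClassifierParams:
    """Numeric knobs of the source classifier and its flags.

    cross_tissue:
        Seed evidence is tied to the host, not the tissue: a detection in any
        of the host's sand-grown tissues counts as seed transmission for all
        of that host's tissues. Set False for a strict same-tissue reading.
    soil_support:
        Minimum number of soil-grown rhizosphere hosts carrying the OTU for a
        soil call (widely distributed soil inoculum).
    stochastic_max_groups:
        An OTU seen in at most this many collapsed groups dataset-wide is
        flagged as a stochastic one-off propagule.
    filter_rhizo_min / filter_root_max:
        Biotic filtering = abundant around roots but excluded from them:
        soil-rhizosphere host occupancy >= filter_rhizo_min while soil-root
        host occupancy <= filter_root_max.
    """

    cross_tissue: bool = True
    soil_support: int = 2
    stochastic_max_groups: int = 2
    filter_rhizo_min: int = 10
    filter_root_max: int = 4


@dataclass(frozen=True)
class TransmissionCall:
    otu_id: str
    host: str
    tissue: str
    source: str  # "seed" | "soil" | "unknown"
    stochastic: bool = False
    biotic_filtered: bool = False
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in ("seed", "soil", "unknown"):
            raise ValueError(f"bad source {self.source!r}")
        ev = self.evidence
        if self.source == "seed" and ev.get("sand_detections", 1) < 1:
            raise ValueError("seed call requires at least one sand detection")
        if self.source == "soil" and ev.get("sand_detections", 0) != 0:
            raise ValueError("soil call forbids sand detections for the host")


def _sand_detections(pres: PresenceMatrix, otu_id: str, host: str, tissue: str, cross_tissue: bool) -> int:
    tissues = PLANT_TISSUES if cross_tissue else (tissue,)
    return sum(pres.detected(host, t, "sand", otu_id) for t in tissues)


def _host_occupancy(pres: PresenceMatrix, otu_id: str, tissue: str, substrate: str) -> int:
    comp = pres.compartment(tissue, substrate)
    if otu_id not in comp.columns:
        return 0
    return int(comp[otu_id].sum())


def _group_occurrences(pres: PresenceMatrix, otu_id: str) -> int:
    if otu_id not in pres.values.columns:
        return 0
    return int(pres.values[otu_id].sum())


def classify_source(
    otu_id: str,
    host: str,
    tissue: str,
    pres: PresenceMatrix,
    params: ClassifierParams = ClassifierParams(),
) -> TransmissionCall:
    """Infer the inoculum source of one (OTU, host, tissue) detection.

    * seed: the OTU was detected in the host's sterile sand-grown plants —
      only the seed could have put it there.
    * soil: no sand detection for the host anywhere, the focal soil group
      carries it, and it shows up in at least ``soil_support`` soil-grown
      rhizospheres dataset-wide (evidence the soil actually supplies it).
    * unknown: anything else — typically a one-off soil-side detection whose
      propagule could have ridden in on either seed or soil.
    """
    sand_n = _sand_detections(pres, otu_id, host, tissue, params.cross_tissue)
    # soil calls require zero sand evidence across every tissue of the host
    sand_any = _sand_detections(pres, otu_id, host, tissue, cross_tissue=True)
    soil_here = pres.detected(host, tissue, "soil", otu_id)
    rhizo_occ = _host_occupancy(pres, otu_id, "rhizosphere", "soil")
    root_occ = _host_occupancy(pres, otu_id, "root", "soil")
    evidence = {
        "sand_detections": sand_n,
        "soil_detection": int(soil_here),
        "soil_rhizosphere_hosts": rhizo_occ,
        "soil_root_hosts": root_occ,
        "group_occurrences": _group_occurrences(pres, otu_id),
    }
    if sand_n >= 1:
        source = "seed"
    elif sand_any == 0 and soil_here and rhizo_occ >= params.soil_support:
        source = "soil"
    else:
        source = "unknown"
    return TransmissionCall(
        otu_id=otu_id, host=host, tissue=tissue, source=source, evidence=evidence
    )


def annotate_flags(
    calls: Sequence[TransmissionCall],
    pres: PresenceMatrix,
    params: ClassifierParams = ClassifierParams(),
) -> list[TransmissionCall]:
    """Attach stochastic-inoculum and biotic-filtering flags to calls."""
    out: list[TransmissionCall] = []
    for call in calls:
        groups = _group_occurrences(pres, call.otu_id)
        rhizo_occ = _host_occupancy(pres, call.otu_id, "rhizosphere", "soil")
        root_occ = _host_occupancy(pres, call.otu_id, "root", "soil")
        stochastic = groups <= params.stochastic_max_groups
        filtered = rhizo_occ >= params.filter_rhizo_min and root_occ <= params.filter_root_max
        out.append(replace(call, stochastic=stochastic, biotic_filtered=filtered))
    return out


def classify_compartment(
    pres: PresenceMatrix,
    uncommon: UncommonSet,
    params: ClassifierParams = ClassifierParams(),
    whitelist: Iterable[str] = (),
) -> list[TransmissionCall]:
    """Classify every soil-grown detection of an uncommon OTU in one tissue.

    Emits one call per (OTU, host) where the OTU — uncommon in the tissue's
    soil compartment or explicitly whitelisted — is detected in that host's
    soil-grown group, then annotates flags.
    """
    tissue, _ = uncommon.compartment
    comp = pres.compartment(tissue, "soil")
    eligible = sorted(set(uncommon.otu_ids) | set(whitelist))
    calls = []
    for otu in eligible:
        if otu not in comp.columns:
            continue
        for host in comp.index[comp[otu]]:
            calls.append(classify_source(otu, str(host), tissue, pres, params))
    return annotate_flags(calls, pres, params)


def calls_to_frame(calls: Sequence[TransmissionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "otu_id": c.otu_id,
            "host": c.host,
            "tissue": c.tissue,
            "source": c.source,
            "stochastic": c.stochastic,
            "biotic_filtered": c.biotic_filtered,
        }
        row.update({f"ev_{k}": v for k, v in c.evidence.items()})
        rows.append(row)
    return pd.DataFrame(rows)
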