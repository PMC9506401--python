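"""Reading, validating and writing OTU count tables, sample metadata and taxonomy.

All downstream analysis consumes the three containers defined here:

``OtuCountTable``
    Integer read counts, samples (rows) x OTUs (columns), for one marker
    (bacterial 16S or fungal ITS).  The two markers are analysed separately
    throughout and are never merged.
``SampleMetadata``
    One row per sample mapping it to (host, tissue, substrate, replicate).
``TaxonomyTable``
    One row per OTU carrying kingdom..genus rank strings.

The canonical on-disk layout is tab-separated UTF-8 text with samples as rows
and OTUs as columns (spreadsheet-shaped); BIOM 2.x files can optionally be
ingested onto the same in-memory table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MARKERS = ("16S", "ITS")
#: Plant-associated compartments sampled in the jar experiment.
TISSUES = ("shoot", "root", "rhizosphere", "seed", "spermosphere", "control")
#: Tissues growing in (and therefore tied to) a substrate treatment.
SUBSTRATE_TISSUES = ("shoot", "root", "rhizosphere", "control")
SUBSTRATES = ("sand", "soil", "none")
#: Tissues sampled before/independently of planting: no substrate applies.
SEEDLIKE_TISSUES = ("seed", "spermosphere")

#: The 17-species host panel of the jar experiment (configurable everywhere).
DEFAULT_HOSTS = (
    "arabidopsis", "barley", "brachiaria", "brachypodium", "cassava",
    "coffee", "maize", "panicum", "pea", "phaseolus", "rice", "sorghum",
    "soy", "sugarcane", "sunflower", "tomato", "wheat",
)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


class ValidationError(ValueError):
    """Base class for dataset validation failures."""


class MissingFileError(ValidationError):
    """Input path does not exist."""


class DuplicateIdError(ValidationError):
    """Duplicate sample or OTU identifiers."""


class BadCountError(ValidationError):
    """Negative, NaN or non-integer count cell."""


class MetadataError(ValidationError):
    """Metadata row violates the schema."""


@dataclass(frozen=True)
class OtuCountTable:
    """Validated integer OTU read counts for a single marker.

    ``counts`` is a samples x OTUs DataFrame with a string index of sample
    ids and string columns of OTU ids; every cell is a non-negative integer.
    """

    marker: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValidationError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        if self.counts.shape[0] < 1 or self.counts.shape[1] < 1:
            raise ValidationError("count table needs at least 1 sample and 1 OTU")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate sample ids: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate OTU ids: {dups}")
        _check_integral_nonnegative(self.counts)
        # normalise dtype and axis names so round-trips are bit-exact
        fixed = self.counts.astype(np.int64)
        fixed.index.name = None
        fixed.columns.name = None
        object.__setattr__(self, "counts", fixed)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuCountTable":
        return OtuCountTable(self.marker, self.counts.loc[list(sample_ids)])

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuCountTable":
        return OtuCountTable(self.marker, self.counts.loc[:, list(otu_ids)])


def _check_integral_nonnegative(df: pd.DataFrame) -> None:
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        raise BadCountError("count table contains non-numeric cells")
    bad = ~np.isfinite(arr.astype(float)) | (arr.astype(float) < 0) | (arr.astype(float) % 1 != 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise BadCountError(
            f"invalid count {arr[i, j]!r} at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
        )


def load_counts(path: str | Path, marker: str, dialect: str = "tsv") -> OtuCountTable:
    """Load an OTU count table from ``path``.

    Parameters
    ----------
    path:
        TSV file (header row of OTU ids, first column sample ids) or a BIOM
        2.x HDF5 file when ``dialect="biom"``.
    marker:
        ``"16S"`` or ``"ITS"``; carried on the returned table.
    dialect:
        ``"tsv"`` (default) or ``"biom"``.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"count table not found: {path}")
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif dialect == "biom":
        import biom  # optional dependency; only the biom dialect needs it

        tbl = biom.load_table(str(path))
        # biom convention: observations are OTUs, samples are columns
        df = pd.DataFrame(
            tbl.matrix_data.toarray().T,
            index=[str(s) for s in tbl.ids("sample")],
            columns=[str(o) for o in tbl.ids("observation")],
        )
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    return OtuCountTable(marker=marker, counts=df)


def write_counts(table: OtuCountTable, path: str | Path) -> None:
    """Write a count table in the canonical TSV layout (round-trip safe)."""
    df = table.counts.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample experimental design: host, tissue, substrate, replicate.

    ``frame`` is indexed by sample_id with columns host/tissue/substrate/
    replicate. Seed and spermosphere samples have no substrate (``"none"``);
    substrate-grown tissues must name sand or soil.
    """

    frame: pd.DataFrame
    hosts: tuple[str, ...] = DEFAULT_HOSTS

    def __post_init__(self) -> None:
        required = {"host", "tissue", "substrate", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise MetadataError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.duplicated().any():
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate sample ids in metadata: {dups}")
        for sid, row in self.frame.iterrows():
            if row["tissue"] not in TISSUES:
                raise MetadataError(f"{sid}: unknown tissue {row['tissue']!r}")
            if row["substrate"] not in SUBSTRATES:
                raise MetadataError(f"{sid}: unknown substrate {row['substrate']!r}")
            seedlike = row["tissue"] in SEEDLIKE_TISSUES
            if seedlike and row["substrate"] != "none":
                raise MetadataError(
                    f"{sid}: substrate must be 'none' for {row['tissue']} samples"
                )
            if not seedlike and row["substrate"] == "none":
                raise MetadataError(
                    f"{sid}: {row['tissue']} samples require a substrate"
                )
            if self.hosts and row["host"] not in self.hosts and row["tissue"] != "control":
                raise MetadataError(f"{sid}: unknown host {row['host']!r}")
            rep = row["replicate"]
            if not (float(rep).is_integer() and int(rep) >= 1):
                raise MetadataError(f"{sid}: replicate must be a positive integer, got {rep!r}")
        object.__setattr__(self, "frame", self.frame.assign(replicate=self.frame["replicate"].astype(int)))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def samples_for(
        self,
        host: str | None = None,
        tissue: str | None = None,
        substrate: str | None = None,
    ) -> list[str]:
        """Sample ids matching every given (non-None) design coordinate."""
        mask = pd.Series(True, index=self.frame.index)
        if host is not None:
            mask &= self.frame["host"] == host
        if tissue is not None:
            mask &= self.frame["tissue"] == tissue
        if substrate is not None:
            mask &= self.frame["substrate"] == substrate
        return list(self.frame.index[mask])


def load_metadata(path: str | Path, hosts: Iterable[str] | None = DEFAULT_HOSTS) -> SampleMetadata:
    """Load sample metadata TSV (columns sample_id, host, tissue, substrate, replicate).

    ``hosts`` is the expected host panel; pass an empty list for permissive
    mode where any host name is accepted.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"metadata not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise MetadataError("metadata must have a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(frame=df, hosts=tuple(hosts) if hosts else ())


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class TaxonomyTable:
    """Per-OTU rank annotations (kingdom..genus; missing ranks are empty)."""

    frame: pd.DataFrame
    marker: str = "16S"

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            raise DuplicateIdError("duplicate OTU ids in taxonomy")
        fixed = self.frame.reindex(columns=list(RANKS)).fillna("").astype(str)
        object.__setattr__(self, "frame", fixed)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.frame.index)

    def rank(self, otu_id: str, rank: str) -> str:
        return str(self.frame.at[otu_id, rank])

    def phylum(self, otu_id: str) -> str:
        p = self.rank(otu_id, "phylum")
        return p if p else "unclassified"


def load_taxonomy(path: str | Path, marker: str = "16S") -> TaxonomyTable:
    """Load taxonomy TSV (columns otu_id + the six ranks, missing allowed)."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"taxonomy not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "otu_id" not in df.columns:
        raise MetadataError("taxonomy must have an otu_id column")
    return TaxonomyTable(frame=df.set_index("otu_id"), marker=marker)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    df = tax.frame.copy()
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


@dataclass
class ValidationReport:
    """Consistency findings for a (counts, metadata, taxonomy) triple.

    An empty report (``ok`` True) means the dataset is fully consistent.
    Reporting, never raising: callers decide severity.
    """

    samples_without_metadata: list[str] = field(default_factory=list)
    otus_without_taxonomy: list[str] = field(default_factory=list)
    empty_samples: list[str] = field(default_factory=list)
    underreplicated_groups: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.samples_without_metadata
            or self.otus_without_taxonomy
            or self.empty_samples
            or self.underreplicated_groups
        )

    def summary(self) -> str:
        if self.ok:
            return "dataset consistent"
        lines = []
        if self.samples_without_metadata:
            lines.append(f"samples without metadata: {self.samples_without_metadata}")
        if self.otus_without_taxonomy:
            lines.append(f"OTUs without taxonomy: {self.otus_without_taxonomy}")
        if self.empty_samples:
            lines.append(f"empty samples (zero reads): {self.empty_samples}")
        if self.underreplicated_groups:
            lines.append(f"under-replicated groups: {self.underreplicated_groups}")
        return "\n".join(lines)


def validate_dataset(
    counts: OtuCountTable,
    meta: SampleMetadata,
    tax: TaxonomyTable | None = None,
    expected_replicates: int = 1,
) -> ValidationReport:
    """Cross-check a dataset; side-effect free and idempotent.

    ``expected_replicates`` flags host x tissue x substrate groups observed
    with fewer member samples than the design intends (default 1: only
    impossible groups are flagged).
    """
    report = ValidationReport()
    meta_ids = set(meta.sample_ids)
    report.samples_without_metadata = [s for s in counts.sample_ids if s not in meta_ids]
    if tax is not None:
        tax_ids = set(tax.otu_ids)
        report.otus_without_taxonomy = [o for o in counts.otu_ids if o not in tax_ids]
    sums = counts.counts.sum(axis=1)
    report.empty_samples = list(sums.index[sums == 0])
    with_meta = [s for s in counts.sample_ids if s in meta_ids]
    if with_meta:
        sub = meta.frame.loc[with_meta]
        sizes = sub.groupby(["host", "tissue", "substrate"], observed=True).size()
        report.underreplicated_groups = [
            tuple(k) for k, n in sizes.items() if n < expected_replicates
        ]
    return report
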