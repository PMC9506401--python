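import hypothesis
import numpy as np
import pandas as pd
import pytest

from rarebiome.preprocess import GroupedAbundanceTable, PresenceMatrix
from rarebiome.tables_io import OtuCountTable, SampleMetadata, TaxonomyTable

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("default")

PLANT_TISSUES = ("shoot", "root", "rhizosphere")


def make_counts(rows, samples, otus, marker="ITS"):
    return OtuCountTable(
        marker=marker,
        counts=pd.DataFrame(np.asarray(rows), index=list(samples), columns=list(otus)),
    )


def make_metadata(rows, hosts=()):
    """rows: list of (sample_id, host, tissue, substrate, replicate)."""
    df = pd.DataFrame(
        rows, columns=["sample_id", "host", "tissue", "substrate", "replicate"]
    ).set_index("sample_id")
    return SampleMetadata(frame=df, hosts=tuple(hosts))


def make_taxonomy(mapping, marker="ITS"):
    """mapping: otu_id -> dict of rank strings."""
    df = pd.DataFrame.from_dict(mapping, orient="index")
    df.index.name = "otu_id"
    return TaxonomyTable(frame=df, marker=marker)


def make_presence(present, hosts, otus, marker="ITS", threshold=0.0):
    """Full plant-compartment presence matrix from a set of
    (host, tissue, substrate, otu) detections."""
    index = pd.MultiIndex.from_tuples(
        [(h, t, s) for h in hosts for t in PLANT_TISSUES for s in ("sand", "soil")],
        names=["host", "tissue", "substrate"],
    )
    vals = pd.DataFrame(False, index=index, columns=list(otus))
    for h, t, s, o in present:
        vals.at[(h, t, s), o] = True
    return PresenceMatrix(marker=marker, values=vals, threshold_percent=threshold)


def make_grouped_abundance(value_rows, groups, otus, marker="ITS"):
    """GroupedAbundanceTable from explicit percent rows.

    groups: list of (host, tissue, substrate) tuples.
    """
    index = pd.MultiIndex.from_tuples(groups, names=["host", "tissue", "substrate"])
    vals = pd.DataFrame(np.asarray(value_rows, dtype=float), index=index, columns=list(otus))
    return GroupedAbundanceTable(marker=marker, values=vals)


@pytest.fixture
def toy_dataset():
    """2 hosts x root tissue x 2 substrates x 2 reps, 3 OTUs; consistent."""
    samples = []
    rows = []
    rng = np.random.default_rng(0)
    for host in ("maize", "rice"):
        for substrate in ("sand", "soil"):
            for rep in (1, 2):
                sid = f"{host}_root_{substrate}_{rep}"
                samples.append((sid, host, "root", substrate, rep))
                rows.append(rng.integers(0, 50, size=3))
    counts = make_counts(rows, [s[0] for s in samples], ["otu1", "otu2", "otu3"])
    meta = make_metadata(samples, hosts=("maize", "rice"))
    tax = make_taxonomy(
        {
            "otu1": {"kingdom": "Fungi", "phylum": "Ascomycota", "genus": "Fusarium"},
            "otu2": {"kingdom": "Fungi", "phylum": "Basidiomycota"},
            "otu3": {"kingdom": "Fungi", "phylum": "Ascomycota"},
        }
    )
    return counts, meta, tax
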