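"""Host-occupancy accounting and the uncommon/abundant screens.

"Uncommon" here means low occupancy across host species, irrespective of
abundance: with the default panel of 17 hosts an OTU is uncommon in a
compartment when detected in 9 or fewer species (9/17 = 52.9% < 53%).
Seed and spermosphere samples, which have no substrate treatment, use a
sample-level majority rule instead (uncommon = present in at most half the
samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .preprocess import GroupedAbundanceTable, PresenceMatrix

#: Default occupancy ceiling for the uncommon screen (hosts, not samples).
DEFAULT_MAX_HOSTS = 9


@dataclass(frozen=True)
class OccupancyRecord:
    otu_id: str
    marker: str
    compartment: tuple[str, str]  # (tissue, substrate) or (tissue, "none")
    n_hosts_present: int
    n_hosts_total: int

    @property
    def occupancy_fraction(self) -> float:
        return self.n_hosts_present / self.n_hosts_total


@dataclass(frozen=True)
class UncommonSet:
    """OTUs flagged uncommon in one compartment plus the screen parameters."""

    compartment: tuple[str, str]
    otu_ids: frozenset[str]
    max_hosts: int | None = None
    threshold_percent: float | None = None


def species_occupancy(
    pres: PresenceMatrix, tissue: str, substrate: str
) -> list[OccupancyRecord]:
    """Count, per OTU, the distinct hosts detected in one compartment."""
    comp = pres.compartment(tissue, substrate)
    if comp.shape[0] == 0:
        raise ValueError(f"no hosts observed in compartment ({tissue}, {substrate})")
    n_hosts = comp.shape[0]
    counts = comp.sum(axis=0)
    return [
        OccupancyRecord(
            otu_id=str(otu),
            marker=pres.marker,
            compartment=(tissue, substrate),
            n_hosts_present=int(counts[otu]),
            n_hosts_total=n_hosts,
        )
        for otu in comp.columns
    ]


def screen_uncommon(
    occ: list[OccupancyRecord], max_hosts: int = DEFAULT_MAX_HOSTS
) -> UncommonSet:
    """Uncommon = detected in at most ``max_hosts`` host species."""
    if not occ:
        raise ValueError("empty occupancy collection")
    h = occ[0].n_hosts_total
    if not 0 <= max_hosts <= h:
        raise ValueError(f"max_hosts must be in [0, {h}]")
    flagged = frozenset(r.otu_id for r in occ if r.n_hosts_present <= max_hosts)
    return UncommonSet(compartment=occ[0].compartment, otu_ids=flagged, max_hosts=max_hosts)


def occupancy_cutoff_fraction(n_hosts: int = 17, max_hosts: int = DEFAULT_MAX_HOSTS) -> float:
    """The occupancy fraction at the screen boundary (9/17 ~ 0.529)."""
    return max_hosts / n_hosts


def screen_uncommon_seedlike(sample_presence: pd.DataFrame, tissue: str) -> UncommonSet:
    """Majority screen over seed or spermosphere samples.

    ``sample_presence`` is a boolean samples x OTUs frame restricted to one
    seed-like tissue. Uncommon = present in at most floor(N/2) of N samples.
    """
    n = sample_presence.shape[0]
    if n == 0:
        raise ValueError("no samples to screen")
    counts = sample_presence.sum(axis=0)
    flagged = frozenset(str(o) for o in counts.index[counts <= n // 2])
    return UncommonSet(compartment=(tissue, "none"), otu_ids=flagged)


def screen_abundant(
    rel: GroupedAbundanceTable,
    uncommon: UncommonSet,
    min_peak_percent: float = 5.0,
) -> list[str]:
    """Uncommon OTUs whose peak abundance in the compartment exceeds the bar.

    The peak is the maximum over the compartment's collapsed host groups;
    the comparison is strict, so a peak exactly at ``min_peak_percent`` is
    dropped.
    """
    if min_peak_percent < 0:
        raise ValueError("min_peak_percent must be >= 0")
    tissue, substrate = uncommon.compartment
    comp = rel.compartment(tissue, substrate)
    keep = [o for o in sorted(uncommon.otu_ids) if o in comp.columns]
    peaks = comp[keep].max(axis=0) if keep else pd.Series(dtype=float)
    return [o for o in keep if peaks[o] > min_peak_percent]


def top_uncommon(
    rel: GroupedAbundanceTable, uncommon: UncommonSet, n: int = 40
) -> list[str]:
    """The ``n`` uncommon OTUs with the largest summed relative abundance.

    Totals are summed across the compartment's groups; ties break on
    lexicographic OTU id so the ranking is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tissue, substrate = uncommon.compartment
    comp = rel.compartment(tissue, substrate)
    keep = [o for o in uncommon.otu_ids if o in comp.columns]
    totals = comp[keep].sum(axis=0)
    ranked = sorted(keep, key=lambda o: (-totals[o], o))
    return ranked[:n]
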