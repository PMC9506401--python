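"""Synthetic multi-host microbiome generator with known transmission truth.

The generator emulates the sealed-jar experiment: a panel of host species
(default 17), each grown in replicate jars on sterile sand and on field
soil, sampled as shoot, root and rhizosphere, plus seed and spermosphere
samples taken from each seed lot. Two markers (bacterial 16S, fungal ITS)
are simulated independently with distinct OTU pools.

OTU classes and their generative channels:

``core_seed``
    carried by every host's seed lot; the common backbone.
``rare_seed_deterministic``
    carried, with certainty, by a fixed small subset of hosts.
``rare_seed_stochastic``
    carriage is an independent Bernoulli(p_seed_carriage) draw per seed lot,
    so expected host occupancy is H * p.
``host_specialist``
    carried by exactly one host at high abundance (hyperabundant symbionts).
``soil_common``
    present in every soil-filled jar (saturating propagule density); a
    subset is designated root-filtered (hosts mostly exclude it from roots).
``soil_rare``
    propagules arrive per soil jar as Poisson(lambda_soil); a jar is
    inoculated when at least one propagule lands, so per-jar presence
    probability is 1 - exp(-lambda_soil).
``contaminant``
    injected into a handful of random samples; no biological source.

Seed-class OTUs colonise both substrates of carrying hosts (only the seed
can reach a sterile sand jar); soil-class OTUs colonise soil jars only,
always appearing in the rhizosphere, entering roots with a per-(OTU, host)
passage probability and shoots rarely. Reads are drawn multinomially per
sample at a log-normal depth clipped to the observed range [10, 80000];
setting ``multinomial_reads=False`` switches to proportional allocation
that guarantees every established OTU at least one read (the fully
deterministic regime).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .tables_io import (
    DEFAULT_HOSTS,
    OtuCountTable,
    SampleMetadata,
    TaxonomyTable,
)

SEED_CLASSES = frozenset(
    {"core_seed", "rare_seed_deterministic", "rare_seed_stochastic", "host_specialist"}
)
SOIL_CLASSES = frozenset({"soil_common", "soil_rare"})

_FUNGAL_PHYLA = (
    ("Ascomycota", 0.60),
    ("Basidiomycota", 0.25),
    ("Mortierellomycota", 0.05),
    ("Glomeromycota", 0.05),
    ("Chytridiomycota", 0.05),
)
_BACTERIAL_PHYLA = (
    ("Proteobacteria", 0.45),
    ("Firmicutes", 0.20),
    ("Actinobacteria", 0.15),
    ("Bacteroidetes", 0.10),
    ("Cyanobacteria", 0.10),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped generator settings; defaults are the simulated baseline.

    Class sizes are per marker. ``p_seed_carriage`` and ``lambda_soil`` are
    the two stochastic inoculum channels; read depths are log-normal with
    parameters on the log scale, clipped to [depth_min, depth_max].
    """

    n_hosts: int = 17
    hosts: tuple[str, ...] = DEFAULT_HOSTS
    replicates: int = 3
    seed_replicates: int = 2
    # OTU class sizes (per marker)
    n_core_seed: int = 8
    n_rare_seed_deterministic: int = 25
    n_rare_seed_stochastic: int = 25
    n_soil_common: int = 15
    n_soil_rare: int = 35
    n_host_specialist: int = 17
    n_contaminant: int = 5
    # transmission channels
    p_seed_carriage: float = 0.3
    lambda_soil: float = 0.5
    det_carriers_max: int = 4  # deterministic seed OTUs ride in <= this many lots
    # establishment / filtering
    tissue_establish_prob: float = 0.9
    root_pass_prob: float = 0.8
    root_pass_prob_filtered: float = 0.15
    n_soil_common_filtered: int = 5
    shoot_pass_prob: float = 0.05
    # abundance & sequencing
    log_abundance_sigma: float = 1.5
    core_boost: float = 5.0
    specialist_boost: float = 50.0
    depth_log_mean: float = float(np.log(3000.0))
    depth_log_sigma: float = 1.3
    depth_min: int = 10
    depth_max: int = 80000
    multinomial_reads: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_seed_carriage <= 1.0:
            raise ValueError("p_seed_carriage must be in [0, 1]")
        if self.lambda_soil < 0:
            raise ValueError("lambda_soil must be >= 0")
        for name in (
            "n_core_seed", "n_rare_seed_deterministic", "n_rare_seed_stochastic",
            "n_soil_common", "n_soil_rare", "n_host_specialist", "n_contaminant",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tissue_establish_prob", "root_pass_prob",
                     "root_pass_prob_filtered", "shoot_pass_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_hosts != len(self.hosts):
            object.__setattr__(self, "hosts", tuple(f"host{i + 1:02d}" for i in range(self.n_hosts)))
        if not self.depth_min >= 1 or self.depth_max < self.depth_min:
            raise ValueError("depth bounds must satisfy 1 <= depth_min <= depth_max")


def deterministic_regime(config: SimulationConfig | None = None) -> SimulationConfig:
    """A copy of ``config`` with every stochastic channel switched off.

    Seed carriage is certain, soil inoculum saturates every jar, roots and
    shoots never filter, no contaminants, and reads are allocated
    proportionally so established OTUs are always detected.
    """
    base = config or SimulationConfig()
    return replace(
        base,
        p_seed_carriage=1.0,
        lambda_soil=50.0,
        tissue_establish_prob=1.0,
        root_pass_prob=1.0,
        root_pass_prob_filtered=1.0,
        shoot_pass_prob=1.0,
        n_contaminant=0,
        multinomial_reads=False,
    )


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the simulated tables.

    ``classes`` maps OTU id to generative class; ``carriage`` records which
    seed lots carry each seed-class OTU; ``soil_jars`` records which
    (host, replicate) soil jars received propagules of each soil-class OTU;
    ``root_blocked`` records hosts whose roots excluded the OTU;
    ``events`` is one row per inoculation event.
    """

    classes: dict[str, str] = field(default_factory=dict)
    carriage: dict[str, frozenset[str]] = field(default_factory=dict)
    soil_jars: dict[str, frozenset[tuple[str, int]]] = field(default_factory=dict)
    root_blocked: dict[str, frozenset[str]] = field(default_factory=dict)
    events: pd.DataFrame = field(default_factory=pd.DataFrame)

    def expected_source(self, otu_id: str, host: str) -> str:
        """The inoculum source a perfect classifier should report for a
        soil-grown detection of ``otu_id`` in ``host``."""
        cls = self.classes[otu_id]
        if cls in SEED_CLASSES and host in self.carriage.get(otu_id, frozenset()):
            return "seed"
        if cls in SOIL_CLASSES and any(h == host for h, _ in self.soil_jars.get(otu_id, frozenset())):
            return "soil"
        return "unknown"

    def otus_of_class(self, cls: str) -> list[str]:
        return sorted(o for o, c in self.classes.items() if c == cls)


@dataclass
class SimulationResult:
    counts: dict[str, OtuCountTable]  # marker -> table
    metadata: SampleMetadata
    taxonomy: dict[str, TaxonomyTable]
    truth: SyntheticTruth
    config: SimulationConfig


def _class_layout(cfg: SimulationConfig, prefix: str) -> list[tuple[str, str]]:
    """(otu_id, class) pairs in a stable order."""
    out: list[tuple[str, str]] = []
    i = 1
    for cls, n in (
        ("core_seed", cfg.n_core_seed),
        ("rare_seed_deterministic", cfg.n_rare_seed_deterministic),
        ("rare_seed_stochastic", cfg.n_rare_seed_stochastic),
        ("host_specialist", cfg.n_host_specialist),
        ("soil_common", cfg.n_soil_common),
        ("soil_rare", cfg.n_soil_rare),
        ("contaminant", cfg.n_contaminant),
    ):
        for _ in range(n):
            out.append((f"{prefix}{i}", cls))
            i += 1
    return out


def _sample_frame(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for host in cfg.hosts:
        for substrate in ("sand", "soil"):
            for tissue in ("shoot", "root", "rhizosphere"):
                for rep in range(1, cfg.replicates + 1):
                    rows.append((f"{host}_{tissue}_{substrate}_{rep}", host, tissue, substrate, rep))
        for tissue in ("seed", "spermosphere"):
            for rep in range(1, cfg.seed_replicates + 1):
                rows.append((f"{host}_{tissue}_{rep}", host, tissue, "none", rep))
    df = pd.DataFrame(rows, columns=["sample_id", "host", "tissue", "substrate", "replicate"])
    return df.set_index("sample_id")


def _simulate_marker(
    cfg: SimulationConfig, marker: str, prefix: str, rng: np.random.Generator
) -> tuple[OtuCountTable, TaxonomyTable, SyntheticTruth, pd.DataFrame]:
    layout = _class_layout(cfg, prefix)
    otu_ids = [o for o, _ in layout]
    classes = dict(layout)
    hosts = list(cfg.hosts)
    meta = _sample_frame(cfg)

    truth = SyntheticTruth(classes=dict(classes))
    events: list[tuple[str, str, str, int, str]] = []

    # --- carriage / inoculation draws -------------------------------------
    carriage: dict[str, set[str]] = {}
    specialist_iter = iter(hosts * ((cfg.n_host_specialist // len(hosts)) + 1))
    for otu, cls in layout:
        if cls == "core_seed":
            carriage[otu] = set(hosts)
        elif cls == "rare_seed_deterministic":
            k = int(rng.integers(1, cfg.det_carriers_max + 1))
            carriage[otu] = {str(h) for h in rng.choice(hosts, size=k, replace=False)}
        elif cls == "rare_seed_stochastic":
            carriage[otu] = {h for h in hosts if rng.random() < cfg.p_seed_carriage}
        elif cls == "host_specialist":
            carriage[otu] = {next(specialist_iter)}

    soil_jars: dict[str, set[tuple[str, int]]] = {}
    for otu, cls in layout:
        if cls == "soil_common":
            soil_jars[otu] = {(h, r) for h in hosts for r in range(1, cfg.replicates + 1)}
        elif cls == "soil_rare":
            soil_jars[otu] = {
                (h, r)
                for h in hosts
                for r in range(1, cfg.replicates + 1)
                if rng.poisson(cfg.lambda_soil) >= 1
            }

    # per-(OTU, host) root passage; a "filtered" subset of soil_common is
    # mostly blocked, emulating biotic filtering
    soil_common_ids = [o for o, c in layout if c == "soil_common"]
    filtered_ids = set(soil_common_ids[: cfg.n_soil_common_filtered])
    root_pass: dict[tuple[str, str], bool] = {}
    root_blocked: dict[str, set[str]] = {o: set() for o in otu_ids}
    for otu, cls in layout:
        if cls not in SOIL_CLASSES:
            continue
        p = cfg.root_pass_prob_filtered if otu in filtered_ids else cfg.root_pass_prob
        for h in hosts:
            ok = rng.random() < p
            root_pass[(otu, h)] = ok
            if not ok:
                root_blocked[otu].add(h)
    # seed-class establishment per (otu, host, substrate, tissue)
    establish: dict[tuple[str, str, str, str], bool] = {}
    for otu, cls in layout:
        if cls not in SEED_CLASSES:
            continue
        for h in sorted(carriage.get(otu, set())):
            for sub in ("sand", "soil"):
                for tis in ("shoot", "root", "rhizosphere"):
                    establish[(otu, h, sub, tis)] = rng.random() < cfg.tissue_establish_prob
    # soil-class shoot passage per (otu, host)
    shoot_pass: dict[tuple[str, str], bool] = {
        (otu, h): rng.random() < cfg.shoot_pass_prob
        for otu, cls in layout if cls in SOIL_CLASSES for h in hosts
    }

    # --- abundance weights ------------------------------------------------
    base = np.exp(rng.normal(0.0, cfg.log_abundance_sigma, size=len(otu_ids)))
    for i, (otu, cls) in enumerate(layout):
        if cls == "core_seed":
            base[i] *= cfg.core_boost
        elif cls == "host_specialist":
            base[i] *= cfg.specialist_boost
    base_w = dict(zip(otu_ids, base))

    # --- assemble per-sample membership ------------------------------------
    otu_index = {o: j for j, o in enumerate(otu_ids)}
    weights = np.zeros((len(meta), len(otu_ids)))
    sample_pos = {s: i for i, s in enumerate(meta.index)}

    def put(sample_id: str, otu: str, w: float) -> None:
        weights[sample_pos[sample_id], otu_index[otu]] = w

    for otu, cls in layout:
        if cls in SEED_CLASSES:
            for h in sorted(carriage.get(otu, set())):
                for rep in range(1, cfg.seed_replicates + 1):
                    put(f"{h}_seed_{rep}", otu, base_w[otu])
                    put(f"{h}_spermosphere_{rep}", otu, base_w[otu])
                for sub in ("sand", "soil"):
                    for rep in range(1, cfg.replicates + 1):
                        events.append((otu, h, sub, rep, "seed"))
                    for tis in ("shoot", "root", "rhizosphere"):
                        if establish[(otu, h, sub, tis)]:
                            for rep in range(1, cfg.replicates + 1):
                                put(f"{h}_{tis}_{sub}_{rep}", otu, base_w[otu])
        elif cls in SOIL_CLASSES:
            for (h, rep) in sorted(soil_jars.get(otu, set())):
                events.append((otu, h, "soil", rep, "soil"))
                put(f"{h}_rhizosphere_soil_{rep}", otu, base_w[otu])
                if root_pass[(otu, h)]:
                    put(f"{h}_root_soil_{rep}", otu, base_w[otu])
                    if shoot_pass[(otu, h)]:
                        put(f"{h}_shoot_soil_{rep}", otu, base_w[otu])

    contaminant_ids = [o for o, c in layout if c == "contaminant"]
    all_samples = list(meta.index)
    for otu in contaminant_ids:
        s = all_samples[int(rng.integers(len(all_samples)))]
        row = meta.loc[s]
        events.append((otu, str(row["host"]), str(row["substrate"]), int(row["replicate"]), "contaminant"))
        put(s, otu, base_w[otu])

    # multiplicative noise on established weights
    jitter = np.exp(rng.normal(0.0, 0.5, size=weights.shape))
    weights = weights * jitter

    # --- read sampling ------------------------------------------------------
    depths = np.exp(rng.normal(cfg.depth_log_mean, cfg.depth_log_sigma, size=len(meta)))
    depths = np.clip(np.round(depths), cfg.depth_min, cfg.depth_max).astype(int)
    counts = np.zeros_like(weights, dtype=np.int64)
    for i in range(len(meta)):
        w = weights[i]
        total = w.sum()
        if total == 0:
            continue
        p = w / total
        n_present = int((w > 0).sum())
        depth = max(int(depths[i]), n_present) if not cfg.multinomial_reads else int(depths[i])
        if cfg.multinomial_reads:
            counts[i] = rng.multinomial(depth, p)
        else:
            # proportional allocation, >=1 read per present OTU, exact depth
            alloc = np.floor(p * (depth - n_present)).astype(np.int64)
            alloc[w > 0] += 1
            short = depth - alloc.sum()
            if short > 0:
                order = np.argsort(-p)
                alloc[order[:short]] += 1
            counts[i] = alloc

    table = OtuCountTable(
        marker=marker,
        counts=pd.DataFrame(counts, index=meta.index, columns=otu_ids),
    )

    # --- taxonomy -----------------------------------------------------------
    phyla_pool = _BACTERIAL_PHYLA if marker == "16S" else _FUNGAL_PHYLA
    kingdom = "Bacteria" if marker == "16S" else "Fungi"
    names, probs = zip(*phyla_pool)
    assigned = rng.choice(names, size=len(otu_ids), p=np.array(probs))
    tax = TaxonomyTable(
        frame=pd.DataFrame(
            {"kingdom": kingdom, "phylum": assigned},
            index=pd.Index(otu_ids, name="otu_id"),
        ),
        marker=marker,
    )

    truth.carriage = {o: frozenset(s) for o, s in carriage.items()}
    truth.soil_jars = {o: frozenset(s) for o, s in soil_jars.items()}
    truth.root_blocked = {o: frozenset(s) for o, s in root_blocked.items() if s}
    truth.events = pd.DataFrame(
        events, columns=["otu_id", "host", "substrate", "replicate", "channel"]
    )
    return table, tax, truth, meta


def simulate(config: SimulationConfig | None = None) -> SimulationResult:
    """Run the generator for both markers; deterministic given rng_seed."""
    cfg = config or SimulationConfig()
    root_seq = np.random.SeedSequence(cfg.rng_seed)
    rng_16s, rng_its = (np.random.default_rng(s) for s in root_seq.spawn(2))

    t16, tax16, truth16, meta_frame = _simulate_marker(cfg, "16S", "BactOTU", rng_16s)
    tits, taxits, truthits, _ = _simulate_marker(cfg, "ITS", "FungOTU", rng_its)

    truth = SyntheticTruth(
        classes={**truth16.classes, **truthits.classes},
        carriage={**truth16.carriage, **truthits.carriage},
        soil_jars={**truth16.soil_jars, **truthits.soil_jars},
        root_blocked={**truth16.root_blocked, **truthits.root_blocked},
        events=pd.concat([truth16.events, truthits.events], ignore_index=True),
    )
    metadata = SampleMetadata(frame=meta_frame, hosts=cfg.hosts)
    return SimulationResult(
        counts={"16S": t16, "ITS": tits},
        metadata=metadata,
        taxonomy={"16S": tax16, "ITS": taxits},
        truth=truth,
        config=cfg,
    )


def expected_occupancy(cls: str, config: SimulationConfig) -> float:
    """Closed-form occupancy expectations for the stochastic classes.

    * ``rare_seed_stochastic``: expected number of carrying seed lots,
      H * p_seed_carriage.
    * ``soil_rare``: per-jar presence probability, 1 - exp(-lambda_soil).
    * ``soil_common``: every host, H.
    * ``core_seed``: every host, H.
    """
    h = config.n_hosts
    if cls == "rare_seed_stochastic":
        return h * config.p_seed_carriage
    if cls == "soil_rare":
        return 1.0 - float(np.exp(-config.lambda_soil))
    if cls in ("soil_common", "core_seed"):
        return float(h)
    raise ValueError(f"no closed form for class {cls!r}")


@dataclass
class EvaluationResult:
    """Confusion accounting of transmission calls against synthetic truth."""

    confusion: pd.DataFrame  # rows = true source, columns = predicted
    per_class: pd.DataFrame  # precision/recall/F1 per source class
    n_calls: int
    unscreened: list[str]  # truth OTUs that never produced a call

    def f1(self, cls: str) -> float:
        return float(self.per_class.at[cls, "f1"])

    @property
    def accuracy(self) -> float:
        total = self.confusion.to_numpy().sum()
        if total == 0:
            return float("nan")
        return float(np.trace(self.confusion.to_numpy()) / total)


def evaluate_calls(calls: Sequence, truth: SyntheticTruth) -> EvaluationResult:
    """Score per-(OTU, host, tissue) source calls against the ground truth.

    Calls must reference OTUs in the truth universe (mismatches raise).
    Precision/recall/F1 use the standard one-vs-rest accounting on the three
    source labels; OTUs the screens never surfaced are listed separately.
    """
    labels = ("seed", "soil", "unknown")
    known = set(truth.classes)
    bad = sorted({c.otu_id for c in calls} - known)
    if bad:
        raise ValueError(f"calls reference OTUs outside the truth universe: {bad[:5]}")
    conf = pd.DataFrame(0, index=list(labels), columns=list(labels), dtype=int)
    for c in calls:
        true = truth.expected_source(c.otu_id, c.host)
        conf.at[true, c.source] += 1
    rows = {}
    for lab in labels:
        tp = int(conf.at[lab, lab])
        fp = int(conf[lab].sum()) - tp
        fn = int(conf.loc[lab].sum()) - tp
        prec = tp / (tp + fp) if tp + fp else float("nan")
        rec = tp / (tp + fn) if tp + fn else float("nan")
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        rows[lab] = {"precision": prec, "recall": rec, "f1": f1,
                     "support": tp + fn}
    called = {c.otu_id for c in calls}
    unscreened = sorted(known - called)
    return EvaluationResult(
        confusion=conf,
        per_class=pd.DataFrame(rows).T,
        n_calls=len(list(calls)),
        unscreened=unscreened,
    )
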