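"""Synthetic gene universes with the statistical structure the ranker assumes.

Real driver-gene feature tables are compiled from many public resources and
cannot be redistributed here, so every downstream stage is exercised on
generated universes instead.  A universe consists of:

* a mixed-type feature table (continuous, binary, one categorical
  essentiality column) in which a subset of features carries class-conditional
  shifts for planted TSGs and OGs;
* a log-normal protein-size column in which planted TSGs annotated for
  chromosome organization are inflated by a configurable factor — the
  structure behind the large-protein/chromatin enrichment analysis;
* deliberately sparse and deliberately duplicated columns that the cleaning
  filters must remove, plus completely-at-random missingness;
* gene coordinates on a single synthetic chromosome, a preferential-attachment
  protein-interaction graph, and a gene × tissue expression matrix;
* a noisy multi-source evidence matrix emulating the published multi-study
  driver compendia that label assembly consumes.

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "Universe",
    "generate_universe",
    "generate_source_membership",
    "generate_ppi_graph",
]


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a simulated study.

    ``effect_size`` is the standardized mean shift applied to each informative
    continuous feature in the driver classes; ``binary_enrichment`` gives the
    class-conditional Bernoulli rate of informative binary flags;
    ``size_inflation`` multiplies the CDS length of planted TSGs annotated for
    chromosome organization.  Evidence sources mark true drivers with
    probability ``source_sensitivity`` and background genes with probability
    ``source_fpr``; a marked driver's per-source role call is flipped with
    probability ``role_flip``.
    """

    n_genes: int = 2000
    n_tsg: int = 40
    n_og: int = 40
    n_continuous: int = 24
    n_binary: int = 12
    effect_size: float = 1.5
    binary_enrichment: dict[str, float] = field(
        default_factory=lambda: {"TSG": 0.45, "OG": 0.35, "BG": 0.10}
    )
    missing_rate: float = 0.05
    n_sparse_features: int = 2
    n_duplicate_features: int = 2
    size_inflation: float = 3.8
    chromatin_rate: dict[str, float] = field(
        default_factory=lambda: {"TSG": 0.5, "OG": 0.12, "BG": 0.08}
    )
    n_sources: int = 15
    source_sensitivity: float = 0.9
    source_fpr: float = 0.005
    role_flip: float = 0.05
    n_tissues: int = 27
    informative_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tsg + self.n_og >= self.n_genes:
            raise ValueError("n_tsg + n_og must be smaller than n_genes")
        rates = [
            self.missing_rate, self.source_sensitivity, self.source_fpr,
            self.role_flip, self.informative_fraction,
            *self.binary_enrichment.values(), *self.chromatin_rate.values(),
        ]
        if any(not 0 <= r <= 1 for r in rates) or self.missing_rate >= 1:
            raise ValueError("all rates must lie in [0, 1] (missing_rate < 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if min(self.n_genes, self.n_continuous, self.n_binary,
               self.n_sources, self.n_tissues) < 1:
            raise ValueError("counts must be positive")


@dataclass
class SimTruth:
    """Planted ground truth: class per gene, chromatin flag, informative columns.

    Field names are deliberately disjoint from feature-table column names so
    that truth can never silently leak into the classifier's input.
    """

    true_class: pd.Series
    chromatin_flag: pd.Series
    informative_features: list[str]
    tsg_informative: list[str]
    og_informative: list[str]


@dataclass
class Universe:
    """One generated study: features, truth, and the side tables."""

    features: "FeatureTable"
    truth: SimTruth
    coords: pd.DataFrame
    ppi_edges: pd.DataFrame
    expression: pd.DataFrame
    config: SimConfig


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def generate_ppi_graph(n_genes: int, m_attach: int = 2, seed: int = 0) -> pd.DataFrame:
    """Connected preferential-attachment interaction graph as an edge list.

    Barabási–Albert growth yields the heavy-tailed degree distribution typical
    of protein-interaction networks.  Node names are gene identifiers.
    """
    if m_attach < 1:
        raise ValueError("m_attach must be >= 1")
    if n_genes < m_attach + 1:
        raise ValueError("need n_genes >= m_attach + 1")
    g = nx.barabasi_albert_graph(n_genes, m_attach, seed=int(seed))
    ids = _gene_ids(n_genes)
    edges = [(ids[u], ids[v]) for u, v in sorted(g.edges())]
    return pd.DataFrame(edges, columns=["gene_a", "gene_b"])


def generate_universe(config: SimConfig) -> Universe:
    """Draw a complete synthetic study deterministically from ``config``.

    Continuous features are Gaussian except size-like and expression-like
    columns, which are log-normal; informative columns receive a mean shift of
    ``effect_size`` standard deviations in the appropriate driver class(es).
    Planted sparse columns satisfy both sparse-removal criteria by
    construction and are exempt from the missingness mask so the criteria
    survive; duplicate columns are exact copies of existing continuous columns.
    """
    from .feature_pipeline import FeatureTable  # local import: avoid cycle

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ids = _gene_ids(cfg.n_genes)
    classes = np.array(["BG"] * cfg.n_genes, dtype=object)
    driver_idx = rng.choice(cfg.n_genes, size=cfg.n_tsg + cfg.n_og, replace=False)
    classes[driver_idx[: cfg.n_tsg]] = "TSG"
    classes[driver_idx[cfg.n_tsg:]] = "OG"
    true_class = pd.Series(classes, index=ids, name="true_class")

    # chromatin annotation, enriched in TSGs
    p_chrom = true_class.map(cfg.chromatin_rate).to_numpy(dtype=float)
    chromatin = rng.random(cfg.n_genes) < p_chrom
    chromatin_flag = pd.Series(chromatin, index=ids, name="chromatin_flag")

    data: dict[str, np.ndarray] = {}
    types: dict[str, str] = {}
    categories: dict[str, str] = {}

    # protein size: log-normal around ~500 aa, inflated for TSG∩chromatin
    cds = np.exp(rng.normal(np.log(480.0), 0.55, cfg.n_genes))
    inflate = (true_class == "TSG").to_numpy() & chromatin
    cds = np.where(inflate, cds * cfg.size_inflation, cds)
    data["cds_length_aa"] = np.round(cds).clip(min=30)
    types["cds_length_aa"] = "continuous"
    categories["cds_length_aa"] = "protein_size"

    # informative continuous features: half driver-generic, rest class-specific
    n_info = max(2, int(round(cfg.informative_fraction * cfg.n_continuous)))
    info_names: list[str] = []
    tsg_info: list[str] = []
    og_info: list[str] = []
    is_tsg = (true_class == "TSG").to_numpy()
    is_og = (true_class == "OG").to_numpy()
    for j in range(cfg.n_continuous):
        name = f"cont_{j:02d}"
        lognormal = j % 3 == 0  # a third of columns long-tailed
        base = rng.normal(0.0, 1.0, cfg.n_genes)
        shift = np.zeros(cfg.n_genes)
        if j < n_info:
            target = j % 3
            if target == 0:  # driver-generic
                shift[is_tsg | is_og] = cfg.effect_size
                info_names.append(name)
            elif target == 1:  # TSG-specific
                shift[is_tsg] = cfg.effect_size
                info_names.append(name)
                tsg_info.append(name)
            else:  # OG-specific
                shift[is_og] = cfg.effect_size
                info_names.append(name)
                og_info.append(name)
            categories[name] = "tumor_genomics" if target == 0 else "non_tumor"
        else:
            categories[name] = "non_tumor"
        values = base + shift
        data[name] = np.exp(values * 0.5) if lognormal else values
        types[name] = "continuous"

    # binary features: first half informative via class-conditional rates
    n_info_bin = max(1, cfg.n_binary // 2)
    p_bg = cfg.binary_enrichment["BG"]
    for j in range(cfg.n_binary):
        name = f"bin_{j:02d}"
        if j < n_info_bin:
            p = true_class.map(cfg.binary_enrichment).to_numpy(dtype=float)
            info_names.append(name)
        else:
            p = np.full(cfg.n_genes, p_bg)
        data[name] = (rng.random(cfg.n_genes) < p).astype(float)
        types[name] = "binary"
        categories[name] = "non_tumor"

    # the chromatin GO flag is itself an observed feature column
    data["go_chromosome_organization"] = chromatin.astype(float)
    types["go_chromosome_organization"] = "binary"
    categories["go_chromosome_organization"] = "non_tumor"
    info_names.append("go_chromosome_organization")
    tsg_info.append("go_chromosome_organization")

    # three-level essentiality, mildly enriched in drivers (only when the
    # universe carries any planted signal at all)
    driver_shift = (is_tsg | is_og) & (cfg.effect_size > 0)
    p_ess = np.where(driver_shift, 0.30, 0.10)
    p_phe = np.where(driver_shift, 0.30, 0.20)
    u = rng.random(cfg.n_genes)
    ess = np.where(u < p_ess, "essential", np.where(u < p_ess + p_phe,
                                                    "phenotype", "other"))
    data["essentiality"] = ess
    types["essentiality"] = "categorical"
    categories["essentiality"] = "non_tumor"

    df = pd.DataFrame(data, index=pd.Index(ids, name="gene_id"))

    # planted sparse columns: near-constant and low-cardinality by construction
    for j in range(cfg.n_sparse_features):
        name = f"sparse_{j:02d}"
        col = np.zeros(cfg.n_genes)
        n_rare = max(1, int(cfg.n_genes * 0.005))
        col[rng.choice(cfg.n_genes, size=n_rare, replace=False)] = 1.0
        df[name] = col
        types[name] = "binary"
        categories[name] = "non_tumor"

    # planted duplicates: exact copies of the first continuous columns
    for j in range(cfg.n_duplicate_features):
        src = f"cont_{j % cfg.n_continuous:02d}"
        name = f"dup_of_{src}"
        df[name] = df[src].to_numpy().copy()
        types[name] = "continuous"
        categories[name] = categories[src]

    # MCAR missingness; planted sparse columns exempt so their removal
    # criteria survive the mask
    if cfg.missing_rate > 0:
        maskable = [c for c in df.columns if not c.startswith("sparse_")]
        mask = rng.random((cfg.n_genes, len(maskable))) < cfg.missing_rate
        block = df[maskable].copy()
        block = block.mask(pd.DataFrame(mask, index=df.index, columns=maskable))
        df[maskable] = block

    features = FeatureTable(data=df, types=types, categories=categories)

    coords = pd.DataFrame(
        {
            "chrom": "chrS",
            "center_bp": rng.uniform(0, 250e6, cfg.n_genes).round(),
        },
        index=pd.Index(ids, name="gene_id"),
    )

    graph_seed = int(rng.integers(0, 2**31 - 1))
    ppi_edges = generate_ppi_graph(cfg.n_genes, m_attach=2, seed=graph_seed)

    expr = np.exp(rng.normal(2.0, 1.0, (cfg.n_genes, cfg.n_tissues)))
    expression = pd.DataFrame(
        expr,
        index=pd.Index(ids, name="gene_id"),
        columns=[f"tissue_{t:02d}" for t in range(cfg.n_tissues)],
    )

    truth = SimTruth(
        true_class=true_class,
        chromatin_flag=chromatin_flag,
        informative_features=info_names,
        tsg_informative=tsg_info,
        og_informative=og_info,
    )
    return Universe(
        features=features, truth=truth, coords=coords,
        ppi_edges=ppi_edges, expression=expression, config=cfg,
    )


def generate_source_membership(truth: SimTruth, config: SimConfig):
    """Noisy multi-source evidence matrix over the simulated universe.

    Each of ``n_sources`` sources marks a true driver with probability
    ``source_sensitivity`` and a background gene with probability
    ``source_fpr``; where a driver is marked, the source's TSG/OG role call is
    correct except with probability ``role_flip``.  Sources are tagged with
    alternating alteration evidence (mutation / cna) so that downstream label
    rules exercising alteration modes have something to read.
    """
    from .label_assembly import SourceMembership  # local import: avoid cycle

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)))
    genes = truth.true_class.index
    is_driver = truth.true_class.isin(["TSG", "OG"]).to_numpy()
    n = len(genes)
    names = [f"source_{s:02d}" for s in range(config.n_sources)]
    member = {}
    roles = {}
    for s, name in enumerate(names):
        p = np.where(is_driver, config.source_sensitivity, config.source_fpr)
        hit = rng.random(n) < p
        member[name] = hit
        call = truth.true_class.copy().astype(object)
        flip = rng.random(n) < config.role_flip
        flipped = call.map({"TSG": "OG", "OG": "TSG"}).fillna("unknown")
        call = call.where(~flip, flipped)
        call[~is_driver] = "unknown"
        call[~hit] = None
        roles[name] = call
    membership = pd.DataFrame(member, index=genes)
    role_df = pd.DataFrame(roles, index=genes)
    meta = pd.DataFrame(
        {
            "category": ["mutation_method" if s % 2 == 0 else "db"
                         for s in range(config.n_sources)],
            "alteration": ["mutation" if s % 2 == 0 else "cna"
                           for s in range(config.n_sources)],
        },
        index=names,
    )
    return SourceMembership(membership=membership, roles=role_df, sources=meta)


def holdout_label_set(truth: SimTruth, holdout_fraction: float, seed: int = 0):
    """LabelSet that hides a fraction of planted drivers from training.

    Held-out drivers are placed in the medium tier (excluded from training
    but still scored out-of-bag by every tree), the remaining drivers become
    the high-confidence set with their true roles, and all background genes
    are training negatives.  This is the harness for planted-signal recovery
    experiments: a ranker that works must score the held-out drivers above
    the background.
    """
    from .label_assembly import LabelSet  # local import: avoid cycle

    if not 0 <= holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    tiers = pd.Series("background", index=truth.true_class.index, dtype=object)
    drivers = truth.true_class.index[truth.true_class.isin(["TSG", "OG"])]
    n_hold = int(round(holdout_fraction * len(drivers)))
    held = set(rng.choice(drivers, size=n_hold, replace=False)) if n_hold else set()
    for g in drivers:
        if g in held:
            tiers[g] = "medium"
        else:
            tiers[g] = "high_TSG" if truth.true_class[g] == "TSG" else "high_OG"
    prov = pd.DataFrame(
        {"role": truth.true_class[tiers.isin(["high_TSG", "high_OG"])],
         "rule": "planted", "mode": "unknown"}
    )
    return LabelSet(tiers=tiers, provenance=prov)


def write_universe(universe: Universe, outdir: str | Path) -> dict[str, Path]:
    """Write every table of a universe as TSV; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": outdir / "features.tsv",
        "truth": outdir / "truth.tsv",
        "coords": outdir / "coords.tsv",
        "ppi_edges": outdir / "ppi_edges.tsv",
        "expression": outdir / "expression.tsv",
    }
    universe.features.write_tsv(paths["features"])
    truth_df = pd.DataFrame(
        {
            "true_class": universe.truth.true_class,
            "chromatin_flag": universe.truth.chromatin_flag.astype(int),
        }
    )
    truth_df.to_csv(paths["truth"], sep="\t", index_label="gene_id")
    universe.coords.to_csv(paths["coords"], sep="\t", index_label="gene_id")
    universe.ppi_edges.to_csv(paths["ppi_edges"], sep="\t", index=False)
    universe.expression.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    return paths


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=int(seed))
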