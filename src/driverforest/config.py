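"""Run configuration and the end-to-end pipeline orchestrator.

A ``RunConfig`` bundles the per-stage configurations (simulation, feature
filtering, forest, evaluation, enrichment) under one master seed; every
stochastic stage derives its own seed from the master via a counter-based
scheme, so a full run is bit-reproducible regardless of which stages are
re-executed or how work is parallelized.  ``run_pipeline`` executes the
stages simulate → labels → features → train → rank → evaluate → enrich,
writing TSV artifacts plus a manifest (config hash, derived seeds, and
row/column counts and checksums per stage).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import evaluation as ev
from . import feature_pipeline as fp
from . import label_assembly as la
from . import pu_forest as pf
from . import synthetic_data as sd

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "labels", "features", "train", "rank", "evaluate", "enrich")


@dataclass
class RunConfig:
    """Everything a full pipeline run needs.

    ``seed`` is the master seed; per-stage seeds are derived from it and any
    seed fields inside the sub-configs are overwritten at run time.
    """

    outdir: str = "runs/default"
    seed: int = 0
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    filter: fp.FilterConfig = field(default_factory=fp.FilterConfig)
    forest: pf.ForestConfig = field(default_factory=pf.ForestConfig)
    label_min_sources: int = 3
    eval_n_max: int = 200
    enrich_q: float = 0.05
    enrich_top_k: int = 40

    def stage_seed(self, stage: str) -> int:
        """Derived seed for one stage, stable under the master seed."""
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=int(self.seed), spawn_key=(idx,))
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))

    # --- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = sd.SimConfig(**d["sim"])
        if "filter" in d:
            d["filter"] = fp.FilterConfig(**d["filter"])
        if "forest" in d:
            d["forest"] = pf.ForestConfig(**d["forest"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(outdir: Path, stage: str, *files: str) -> None:
    missing = [f for f in files if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"stage depends on missing artifacts {missing}; run {stage!r} first"
        )


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested pipeline stages and return the manifest.

    Stage dependencies are checked by artifact presence; a missing upstream
    artifact raises an error naming the stage to run first.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest.setdefault("stages", {})
    manifest["config_hash"] = config.config_hash()
    manifest["master_seed"] = config.seed

    def record(stage: str, files: list[str], **extra) -> None:
        manifest["stages"][stage] = {
            "seed": config.stage_seed(stage),
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "artifacts": {
                f: {"checksum": _checksum(outdir / f)} for f in files
            },
            **extra,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if "simulate" in stages:
        sim_cfg = sd.with_seed(config.sim, config.stage_seed("simulate"))
        universe = sd.generate_universe(sim_cfg)
        sd.write_universe(universe, outdir)
        membership = sd.generate_source_membership(universe.truth, sim_cfg)
        membership.write_tsv(outdir / "membership.tsv")
        record(
            "simulate",
            ["features.tsv", "truth.tsv", "coords.tsv", "ppi_edges.tsv",
             "expression.tsv", "membership.tsv"],
            n_genes=len(universe.features.data),
            n_features=universe.features.data.shape[1],
        )

    if "labels" in stages:
        _require(outdir, "simulate", "membership.tsv", "truth.tsv")
        membership = _read_membership(outdir / "membership.tsv")
        sources = list(membership.membership.columns)
        half = len(sources) // 2
        rules = [
            la.Rule(
                name="consensus_vote",
                type="consensus",
                sources=tuple(sources),
                min_count=config.label_min_sources,
            )
        ]
        tier_cfg = {
            "medium_sources": sources[:half],
            "low_sources": sources[half:],
        }
        high = la.assemble_high_confidence(membership, rules, {})
        labels = la.assign_tiers(membership, high, tier_cfg)
        labels.write_tsv(outdir / "labels.tsv")
        record(
            "labels", ["labels.tsv"],
            tier_counts=labels.tier_counts().to_dict(),
        )

    if "features" in stages:
        _require(outdir, "simulate", "features.tsv", "coords.tsv",
                 "ppi_edges.tsv", "expression.tsv")
        table = fp.FeatureTable.read_tsv(outdir / "features.tsv")
        coords = pd.read_csv(outdir / "coords.tsv", sep="\t", index_col="gene_id")
        edges = pd.read_csv(outdir / "ppi_edges.tsv", sep="\t")
        expr = pd.read_csv(outdir / "expression.tsv", sep="\t",
                           index_col="gene_id")

        density = fp.genomic_density(coords)
        bc = fp.betweenness(edges).reindex(table.data.index).fillna(0.0)
        degree = (
            pd.concat([edges["gene_a"], edges["gene_b"]])
            .value_counts()
            .reindex(table.data.index)
            .fillna(0.0)
        )
        tsum = fp.tissue_summary(expr)
        extra = pd.DataFrame(
            {
                "genomic_density": density,
                "betweenness": bc,
                "n_ppi": degree,
                "expression_median": tsum["expression_median"],
                "expression_variation": tsum["expression_variation"],
            }
        )
        data = pd.concat([table.data, extra], axis=1)
        types = dict(table.types)
        cats = dict(table.categories)
        for c in extra.columns:
            types[c] = "continuous"
            cats[c] = "non_tumor"
        full = fp.FeatureTable(data=data, types=types, categories=cats)
        matrix, column_map, report = fp.prepare_features(full, config.filter)
        matrix.to_csv(outdir / "matrix.tsv", sep="\t", index_label="gene_id")
        column_map.to_csv(outdir / "column_map.tsv", sep="\t", na_rep="")
        report.to_csv(outdir / "removed_features.tsv", sep="\t", index=False)
        record(
            "features",
            ["matrix.tsv", "column_map.tsv", "removed_features.tsv"],
            n_encoded_columns=matrix.shape[1],
            n_removed=len(report),
        )

    if "train" in stages:
        _require(outdir, "features", "matrix.tsv")
        _require(outdir, "labels", "labels.tsv")
        matrix = pd.read_csv(outdir / "matrix.tsv", sep="\t", index_col="gene_id")
        labels = _read_labels(outdir / "labels.tsv")
        training = la.build_training_labels(labels)
        forest_cfg = dataclasses.replace(
            config.forest, seed=config.stage_seed("train")
        )
        model = pf.fit_forest(matrix, training, forest_cfg)
        model.save(outdir / "model.pkl")
        record(
            "train", [],
            n_trees=model.n_trees,
            n_training_genes=len(training),
        )

    if "rank" in stages:
        _require(outdir, "features", "matrix.tsv")
        if not (outdir / "model.pkl").exists():
            raise FileNotFoundError("model.pkl missing; run 'train' first")
        matrix = pd.read_csv(outdir / "matrix.tsv", sep="\t", index_col="gene_id")
        model = pf.ForestModel.load(outdir / "model.pkl")
        post = pf.oob_posteriors(model, matrix)
        post.table.to_csv(outdir / "predictions.tsv", sep="\t",
                          index_label="gene_id", na_rep="")
        pf.feature_importance(model).to_csv(
            outdir / "importance.tsv", sep="\t", index_label="feature"
        )
        record("rank", ["predictions.tsv", "importance.tsv"])

    if "evaluate" in stages:
        _require(outdir, "rank", "predictions.tsv")
        _require(outdir, "labels", "labels.tsv")
        post = _read_predictions(outdir / "predictions.tsv")
        labels = _read_labels(outdir / "labels.tsv")
        ranking = pf.rank_genes(post, mode="driver")
        rows = []
        for tier in ("high", "medium", "low"):
            curve = ev.precision_at_n(ranking, labels, tier,
                                      n_max=config.eval_n_max)
            for n, p, h in zip(curve.n_grid, curve.precision, curve.hits):
                rows.append({"tier": tier, "N": int(n), "hits": int(h),
                             "precision": float(p)})
        pd.DataFrame(rows).to_csv(outdir / "precision_curves.tsv", sep="\t",
                                  index=False)
        auc = ev.tsg_og_auc(post, labels.high_confidence)
        pd.DataFrame([{"metric": "tsg_og_auc", "value": auc}]).to_csv(
            outdir / "auc.tsv", sep="\t", index=False
        )
        record("evaluate", ["precision_curves.tsv", "auc.tsv"], tsg_og_auc=auc)

    if "enrich" in stages:
        _require(outdir, "rank", "predictions.tsv")
        _require(outdir, "labels", "labels.tsv")
        _require(outdir, "simulate", "features.tsv")
        table = fp.FeatureTable.read_tsv(outdir / "features.tsv")
        labels = _read_labels(outdir / "labels.tsv")
        post = _read_predictions(outdir / "predictions.tsv")
        cds = table.data["cds_length_aa"].astype(float)
        flags = pd.DataFrame(
            {
                "chromosome_organization": table.data[
                    "go_chromosome_organization"
                ].fillna(0).astype(bool)
            }
        )
        hc = labels.high_confidence
        tsg_rank = pf.rank_genes(post, mode="TSG")
        predicted = [g for g in tsg_rank if g not in set(hc.index)][
            : config.enrich_top_k
        ]
        profile = enr.intersect_and_profile(
            cds, flags, hc, "chromosome_organization",
            q=config.enrich_q, predicted_tsg=predicted,
        )
        profile.composition.to_csv(outdir / "enrichment_composition.tsv",
                                   sep="\t", index_label="class")
        e = profile.enrichment
        pd.DataFrame(
            [{"N": e.N, "K": e.K, "n": e.n, "k": e.k,
              "fold": e.fold, "p_upper": e.p_upper}]
        ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        record(
            "enrich", ["enrichment.tsv", "enrichment_composition.tsv"],
            set_size=e.n, p_upper=e.p_upper,
        )

    return manifest


# --- artifact readers ------------------------------------------------------


def _read_membership(path: Path) -> la.SourceMembership:
    path = Path(path)
    membership = pd.read_csv(path, sep="\t", index_col="gene_id").astype(bool)
    roles = pd.read_csv(path.with_suffix(".roles.tsv"), sep="\t",
                        index_col="gene_id", dtype=object)
    roles = roles.where(roles.notna() & (roles != ""), None)
    sources = pd.read_csv(path.with_suffix(".sources.tsv"), sep="\t",
                          index_col="source")
    return la.SourceMembership(membership=membership, roles=roles,
                               sources=sources)


def _read_labels(path: Path) -> la.LabelSet:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    prov_cols = [c for c in df.columns if c not in ("tier", "class")]
    prov = df.loc[df["tier"].isin(["high_TSG", "high_OG"]), prov_cols]
    return la.LabelSet(tiers=df["tier"], provenance=prov)


def _read_predictions(path: Path) -> pf.PosteriorTable:
    return pf.PosteriorTable(
        table=pd.read_csv(path, sep="\t", index_col="gene_id")
    )
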