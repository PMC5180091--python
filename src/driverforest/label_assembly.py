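"""Assemble disjoint gene tiers from a multi-source evidence table.

Published driver-gene compendia disagree with each other, so training labels
are built in tiers: a high-confidence positive set admitted by an ordered
list of declarative rules over the evidence sources, medium/low/other
excluded sets built from designated source unions, and the remaining genes as
background negatives.  The rules are data, not code — a curation that
includes manual literature judgments ships as a rule file rather than being
recomputed.

Tier precedence is high > medium > low > other > background; the tiers
partition the universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

__all__ = [
    "SourceMembership",
    "LabelSet",
    "Rule",
    "assemble_high_confidence",
    "assign_tiers",
    "build_training_labels",
]

TIERS = ("high_TSG", "high_OG", "medium", "low", "other", "background")
ROLES = ("TSG", "OG")


@dataclass
class SourceMembership:
    """Genes × evidence sources with optional per-source role calls.

    ``membership`` is boolean genes × sources; ``roles`` holds per-source
    TSG/OG/unknown calls where membership is true (None/NaN elsewhere);
    ``sources`` is per-source metadata with at least a ``category`` column
    and an optional ``alteration`` tag (mutation / cna) used for
    mode-of-alteration bookkeeping.
    """

    membership: pd.DataFrame
    roles: pd.DataFrame
    sources: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.roles.columns) != list(self.membership.columns):
            raise ValueError("roles and membership must share source columns")
        if set(self.sources.index) != set(self.membership.columns):
            raise ValueError("source metadata must cover every source column")
        leaked = self.roles.notna() & ~self.membership.astype(bool)
        if leaked.to_numpy().any():
            raise ValueError("role calls present where membership is false")

    @property
    def genes(self) -> pd.Index:
        return self.membership.index

    def members(self, source: str) -> pd.Index:
        return self.membership.index[self.membership[source].astype(bool)]

    def any_member(self) -> pd.Index:
        return self.membership.index[self.membership.any(axis=1)]

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.membership.astype(int).to_csv(path, sep="\t", index_label="gene_id")
        self.roles.to_csv(path.with_suffix(".roles.tsv"), sep="\t",
                          index_label="gene_id", na_rep="")
        self.sources.to_csv(path.with_suffix(".sources.tsv"), sep="\t",
                            index_label="source", na_rep="")


@dataclass
class LabelSet:
    """Disjoint tier per gene, plus provenance for high-confidence admissions.

    ``tiers`` maps every gene in the universe to one tier; ``provenance``
    records, per high-confidence gene, the admitting rule, the role and the
    alteration mode.
    """

    tiers: pd.Series
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.tiers.unique()) - set(TIERS)
        if bad:
            raise ValueError(f"unknown tiers: {bad}")

    def genes_in(self, tier: str) -> list[str]:
        return list(self.tiers.index[self.tiers == tier])

    @property
    def high_confidence(self) -> pd.Series:
        """Role (TSG/OG) of every high-confidence gene."""
        mask = self.tiers.isin(["high_TSG", "high_OG"])
        return self.tiers[mask].map({"high_TSG": "TSG", "high_OG": "OG"})

    def tier_counts(self) -> pd.Series:
        return self.tiers.value_counts().reindex(TIERS, fill_value=0)

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"tier": self.tiers})
        df["class"] = self.tiers.map(
            {"high_TSG": "TSG", "high_OG": "OG", "background": "BG"}
        )
        prov = self.provenance.reindex(df.index)
        for col in prov.columns:
            df[col] = prov[col]
        df.to_csv(Path(path), sep="\t", index_label="gene_id", na_rep="")


@dataclass(frozen=True)
class Rule:
    """One declarative admission rule.

    type ∈ {base, and_k_of_m, intersection, vote}:

    * ``base`` — admit every member of ``sources[0]``; role from ``role`` if
      set, else from the source's own role call.
    * ``and_k_of_m`` — admit members of the anchor (``sources[0]``) that are
      also in at least ``min_count`` of the supporting sources
      (``sources[1:]``); fixed ``role``.
    * ``intersection`` — admit genes in all listed sources; fixed ``role``.
    * ``vote`` — genes in at least ``min_count`` of the listed sources, but
      only those with an explicit manual role in ``roles`` (manual curation
      cannot be computed).
    * ``consensus`` — genes in at least ``min_count`` of the listed sources,
      role by strict majority of the sources' own role calls (genes with a
      tied or entirely unknown role are skipped); suited to simulated
      evidence where no manual curation exists.
    """

    name: str
    type: str
    sources: tuple[str, ...]
    min_count: int = 0
    role: str | None = None
    roles: dict[str, str] = field(default_factory=dict)
    mode: str | None = None  # alteration mode stamped on admissions

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Rule":
        return cls(
            name=d["name"],
            type=d["type"],
            sources=tuple(d["sources"]),
            min_count=int(d.get("min_count", 0)),
            role=d.get("role"),
            roles=dict(d.get("roles", {})),
            mode=d.get("mode"),
        )


def load_rules(path: str | Path) -> tuple[list[Rule], dict[str, str], dict]:
    """Read an ordered rule file (YAML): rules, overrides, tier config."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rules = [Rule.from_dict(d) for d in doc.get("rules", [])]
    overrides = dict(doc.get("overrides", {}))
    tier_config = dict(doc.get("tiers", {}))
    return rules, overrides, tier_config


def _rule_admissions(rule: Rule, membership: SourceMembership) -> dict[str, str]:
    """Gene → role admitted by one rule (before precedence/overrides)."""
    m = membership.membership.astype(bool)
    if rule.type == "base":
        (src,) = rule.sources
        out = {}
        for g in membership.members(src):
            role = rule.role or membership.roles.loc[g, src]
            if role not in ROLES:
                raise ValueError(
                    f"rule {rule.name!r}: gene {g} in base source {src} has no "
                    f"usable role call ({role!r})"
                )
            out[g] = role
        return out
    if rule.type == "and_k_of_m":
        anchor, *support = rule.sources
        hits = m[list(support)].sum(axis=1)
        sel = m[anchor] & (hits >= rule.min_count)
        return {g: rule.role for g in membership.genes[sel]}
    if rule.type == "intersection":
        sel = m[list(rule.sources)].all(axis=1)
        return {g: rule.role for g in membership.genes[sel]}
    if rule.type == "vote":
        hits = m[list(rule.sources)].sum(axis=1)
        qualifying = set(membership.genes[hits >= rule.min_count])
        return {g: r for g, r in rule.roles.items() if g in qualifying}
    if rule.type == "consensus":
        hits = m[list(rule.sources)].sum(axis=1)
        out = {}
        calls = membership.roles[list(rule.sources)]
        for g in membership.genes[hits >= rule.min_count]:
            votes = calls.loc[g].value_counts()
            votes = votes[votes.index.isin(ROLES)]
            if len(votes) == 0:
                continue
            if len(votes) > 1 and votes.iloc[0] == votes.iloc[1]:
                continue  # tied role call: leave to lower tiers
            out[g] = votes.index[0]
        return out
    raise ValueError(f"unknown rule type {rule.type!r}")


def _alteration_mode(
    gene: str, role: str, rule_mode: str | None, membership: SourceMembership
) -> str:
    """mutation / cna / both, from source tags plus the admitting rule's mode."""
    tags = set()
    if rule_mode:
        tags.add(rule_mode)
    alt = membership.sources.get("alteration")
    if alt is not None:
        row = membership.membership.loc[gene].astype(bool)
        for src in membership.membership.columns[row]:
            tag = alt.get(src)
            if isinstance(tag, str) and tag in ("mutation", "cna"):
                tags.add(tag)
    if {"mutation", "cna"} <= tags:
        return "both"
    if tags:
        return tags.pop()
    return "unknown"


def assemble_high_confidence(
    membership: SourceMembership,
    rules: list[Rule],
    overrides: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Apply ordered admission rules, then final overrides.

    Returns a DataFrame indexed by gene with columns role / rule / mode.
    Earlier rules take precedence: a gene already admitted is skipped by later
    rules unless the later rule assigns a *conflicting* role, which is an
    error unless an override (``remove`` or an explicit role) resolves it.
    Overrides apply last: ``remove`` deletes a gene, ``TSG``/``OG`` forces its
    role.
    """
    overrides = overrides or {}
    unknown_src = {
        s for r in rules for s in r.sources
        if s not in membership.membership.columns
    }
    if unknown_src:
        raise KeyError(f"rules reference unknown sources: {sorted(unknown_src)}")
    unknown_genes = set(overrides) - set(membership.genes)
    if unknown_genes:
        raise KeyError(f"overrides reference unknown genes: {sorted(unknown_genes)}")

    admitted: dict[str, dict[str, str]] = {}
    conflicts = []
    for rule in rules:
        for gene, role in _rule_admissions(rule, membership).items():
            if gene in admitted:
                if admitted[gene]["role"] != role and gene not in overrides:
                    conflicts.append((gene, admitted[gene]["role"], role))
                continue
            admitted[gene] = {
                "role": role,
                "rule": rule.name,
                "mode": _alteration_mode(gene, role, rule.mode, membership),
            }
    if conflicts:
        listing = ", ".join(f"{g} ({a} vs {b})" for g, a, b in conflicts)
        raise ValueError(f"conflicting roles without override: {listing}")

    for gene, action in overrides.items():
        if gene not in admitted:
            continue
        if action == "remove":
            del admitted[gene]
        elif action in ROLES:
            admitted[gene]["role"] = action
        else:
            raise ValueError(f"unknown override action {action!r} for {gene}")

    if not admitted:
        return pd.DataFrame(columns=["role", "rule", "mode"])
    return pd.DataFrame.from_dict(admitted, orient="index").sort_index()


def assign_tiers(
    membership: SourceMembership,
    high_set: pd.DataFrame,
    tier_config: dict,
) -> LabelSet:
    """Partition the universe into tiers around the high-confidence set.

    ``tier_config`` holds ``medium_sources`` and ``low_sources`` lists.
    medium = union of the designated genomics sources minus high; low = union
    of the designated secondary sources minus medium and high; other = any
    remaining source-positive gene; background = everything else.
    """
    for key in ("medium_sources", "low_sources"):
        unknown = set(tier_config.get(key, [])) - set(membership.membership.columns)
        if unknown:
            raise KeyError(f"{key} references unknown sources: {sorted(unknown)}")

    genes = membership.genes
    tiers = pd.Series("background", index=genes, dtype=object)

    source_positive = set(membership.any_member())
    tiers[tiers.index.isin(source_positive)] = "other"

    low_sources = list(tier_config.get("low_sources", []))
    if low_sources:
        low_union = set(
            membership.genes[
                membership.membership[low_sources].astype(bool).any(axis=1)
            ]
        )
        tiers[tiers.index.isin(low_union)] = "low"

    medium_sources = list(tier_config.get("medium_sources", []))
    if medium_sources:
        med_union = set(
            membership.genes[
                membership.membership[medium_sources].astype(bool).any(axis=1)
            ]
        )
        tiers[tiers.index.isin(med_union)] = "medium"

    high_genes = set(high_set.index)
    missing = high_genes - set(genes)
    if missing:
        raise KeyError(f"high-confidence genes outside the universe: {sorted(missing)}")
    for gene in high_genes:
        tiers[gene] = "high_TSG" if high_set.loc[gene, "role"] == "TSG" else "high_OG"

    return LabelSet(tiers=tiers, provenance=high_set)


def build_training_labels(labels: LabelSet) -> pd.Series:
    """Training classes: high_TSG → TSG, high_OG → OG, background → BG.

    Medium, low and other tiers are excluded — they are expected to carry
    high false-positive rates and cannot be functionally assigned.
    """
    mapping = {"high_TSG": "TSG", "high_OG": "OG", "background": "BG"}
    kept = labels.tiers[labels.tiers.isin(mapping)]
    return kept.map(mapping).rename("class")
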