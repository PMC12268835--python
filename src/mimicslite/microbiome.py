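"""Copiotroph:oligotroph ratios from taxonomy-labelled ASV count tables.

The workflow: rarefy each sample to a common read depth (2447 reads by
default, subsampling without replacement), classify every ASV lineage as
copiotroph, oligotroph or unassigned using a multi-rank rule table with
finest-rank precedence, and compute the per-sample ratio of copiotroph to
oligotroph read counts.  Unassigned taxa are excluded from the main ratio
but swept through an allocation sensitivity analysis (100% to copiotrophs,
90/10, ... , 0/100).

ASV tables are TSV with a ``taxon_id`` column, a semicolon-delimited
``lineage`` column of ``rank:name`` entries (ranks phylum through genus),
and one count column per sample — the layout common amplicon pipelines
export.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "RAREFACTION_DEPTH",
    "ClassificationRuleSet",
    "load_rules",
    "read_asv_table",
    "rarefy",
    "rarefy_table",
    "parse_lineage",
    "classify_taxa",
    "classify_table",
    "copiotroph_oligotroph_ratio",
    "unassigned_sensitivity",
    "sample_ratios",
    "UndefinedRatioError",
]

#: Taxonomic ranks from coarsest to finest.
RANKS = ("phylum", "class", "order", "family", "genus")
RAREFACTION_DEPTH = 2447

GROUPS = ("copiotroph", "oligotroph")


class UndefinedRatioError(ValueError):
    """Raised when a sample has no oligotroph reads."""


@dataclasses.dataclass
class ClassificationRuleSet:
    """(rank, taxon name) -> group rules with finest-rank precedence."""

    rules: dict[tuple[str, str], str]

    def __post_init__(self):
        for (rank, name), group in self.rules.items():
            if rank not in RANKS:
                raise ValueError(f"unknown rank {rank!r} for taxon {name!r}")
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r} for taxon {name!r}")

    def counts_by_rank(self) -> dict[str, int]:
        out = {r: 0 for r in RANKS}
        for rank, _ in self.rules:
            out[rank] += 1
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ClassificationRuleSet":
        rules: dict[tuple[str, str], str] = {}
        conflicts = set()
        for _, row in frame.iterrows():
            key = (str(row["rank"]), str(row["name"]))
            group = str(row["group"])
            if key in rules and rules[key] != group:
                conflicts.add(key)
            rules[key] = group
        for key in conflicts:
            del rules[key]  # conflicting same-rank rules are dropped -> unassigned
        if conflicts:
            import warnings

            warnings.warn(f"conflicting rules dropped for {sorted(conflicts)}")
        return cls(rules)


def load_rules(path: str | Path | None = None) -> ClassificationRuleSet:
    """Load a rank/name/group rule table (packaged demo set by default)."""
    if path is None:
        src = resources.files("mimicslite.data").joinpath("copiotroph_rules.tsv").open("r")
    else:
        src = open(path)
    with src as fh:
        frame = pd.read_csv(
            fh, sep="\t", comment="#", names=["rank", "name", "group"], header=None
        )
    return ClassificationRuleSet.from_frame(frame)


def read_asv_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"taxon_id", "lineage"}
    if not required <= set(table.columns):
        raise ValueError(f"ASV table must have columns {sorted(required)}")
    return table


def rarefy(
    sample_counts: np.ndarray, depth: int = RAREFACTION_DEPTH, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    Exact multivariate hypergeometric draw; the result sums to ``depth``
    and never exceeds the input counts.  Raises ``ValueError`` when the
    sample is shallower than ``depth`` (callers flag and drop it).
    """
    counts = np.asarray(sample_counts)
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative integers")
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"sample has {total} reads, fewer than depth {depth}")
    if total == depth:
        return counts.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def rarefy_table(
    table: pd.DataFrame, depth: int = RAREFACTION_DEPTH, seed: int = 0
) -> tuple[pd.DataFrame, list[str]]:
    """Rarefy every sample column; shallow samples are dropped and reported."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    dropped = []
    for col in _sample_columns(table):
        counts = table[col].to_numpy()
        if counts.sum() < depth:
            dropped.append(col)
            out = out.drop(columns=[col])
        else:
            out[col] = rarefy(counts, depth, rng)
    return out, dropped


def _sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("taxon_id", "lineage", "group")]


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse ``rank:name;rank:name;...`` into a dict; ranks must be known."""
    if not isinstance(lineage, str) or not lineage.strip():
        raise ValueError(f"malformed lineage: {lineage!r}")
    out = {}
    for part in lineage.split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise ValueError(f"malformed lineage entry {part!r} in {lineage!r}")
        rank, name = part.split(":", 1)
        rank = rank.strip().lower()
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r} in lineage {lineage!r}")
        out[rank] = name.strip()
    return out


def classify_taxa(lineage: str, rules: ClassificationRuleSet) -> str:
    """Classify one lineage; the matching rule at the finest rank wins."""
    parsed = parse_lineage(lineage)
    for rank in reversed(RANKS):  # genus first
        name = parsed.get(rank)
        if name is not None and (rank, name) in rules.rules:
            return rules.rules[(rank, name)]
    return "unassigned"


def classify_table(table: pd.DataFrame, rules: ClassificationRuleSet) -> pd.DataFrame:
    out = table.copy()
    out["group"] = [classify_taxa(l, rules) for l in table["lineage"]]
    return out


def _group_sums(classified: pd.DataFrame, col: str) -> tuple[float, float, float]:
    counts = classified[col]
    by = classified["group"]
    c = float(counts[by == "copiotroph"].sum())
    o = float(counts[by == "oligotroph"].sum())
    u = float(counts[by == "unassigned"].sum())
    return c, o, u


def copiotroph_oligotroph_ratio(classified: pd.DataFrame, sample: str) -> float:
    """Sum of copiotroph counts over sum of oligotroph counts for one
    sample; unassigned reads excluded."""
    c, o, _ = _group_sums(classified, sample)
    if o <= 0:
        raise UndefinedRatioError(f"sample {sample!r} has no oligotroph reads")
    return c / o


def unassigned_sensitivity(
    classified: pd.DataFrame,
    sample: str,
    fractions: np.ndarray | None = None,
) -> pd.Series:
    """Ratio when a fraction f of unassigned reads counts as copiotroph and
    (1-f) as oligotroph, for f from 1.0 down to 0.0."""
    if fractions is None:
        fractions = np.round(np.arange(1.0, -0.01, -0.1), 1)
    c, o, u = _group_sums(classified, sample)
    out = {}
    for f in fractions:
        denom = o + (1.0 - f) * u
        if denom <= 0:
            raise UndefinedRatioError(
                f"sample {sample!r} has no oligotroph reads at allocation {f}"
            )
        out[float(f)] = (c + f * u) / denom
    return pd.Series(out, name=sample)


def sample_ratios(
    table: pd.DataFrame,
    rules: ClassificationRuleSet,
    *,
    depth: int = RAREFACTION_DEPTH,
    seed: int = 0,
    sensitivity: bool = True,
) -> pd.DataFrame:
    """Full per-sample pipeline: rarefy, classify, ratio (+ sensitivity).

    Samples shallower than ``depth`` or with zero oligotroph reads are
    flagged in the ``status`` column rather than silently dropped.
    """
    rarefied, dropped = rarefy_table(table, depth, seed)
    classified = classify_table(rarefied, rules)
    rows = []
    for col in _sample_columns(table):
        if col in dropped:
            rows.append({"sample": col, "status": "too_shallow", "co_ratio": np.nan})
            continue
        try:
            ratio = copiotroph_oligotroph_ratio(classified, col)
        except UndefinedRatioError:
            rows.append({"sample": col, "status": "no_oligotrophs", "co_ratio": np.nan})
            continue
        row = {"sample": col, "status": "ok", "co_ratio": ratio}
        if sensitivity:
            sweep = unassigned_sensitivity(classified, col)
            row.update({f"ratio_f{f:.1f}": v for f, v in sweep.items()})
        rows.append(row)
    return pd.DataFrame(rows)
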