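"""Rarefaction, Shannon diversity and the abundant-active-taxon census.

Shannon diversity is reported in bits (log base 2) on rarefied tables so
that samples are compared at equal sequencing effort. Rarefaction is exact
subsampling without replacement (multivariate hypergeometric draws), and
the mean over independent restarts smooths subsampling noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from saltmarsh.dormancy import activity_ratio, classify_activity, ACTIVE
from saltmarsh.tables import CountTable, PairedCommunityTable


@dataclass
class RarefactionPlan:
    """How to rarefy: target depth, number of independent restarts, and the
    depth increment used when tracing a rarefaction curve."""

    depth: int = 32_501
    restarts: int = 100
    step: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


def rarefy(table: CountTable, depth: int, seed: int | np.random.Generator = 0) -> CountTable:
    """Subsample every sample (column) to exactly ``depth`` reads without
    replacement. Samples with fewer than ``depth`` total reads are dropped
    with a warning."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(f"dropping samples below depth {depth}: {dropped}")
    cols = []
    for j in np.flatnonzero(keep):
        cols.append(rng.multivariate_hypergeometric(table.counts[:, j], depth))
    counts = np.column_stack(cols) if cols else np.zeros((table.shape[0], 0), dtype=np.int64)
    sample_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return CountTable(list(table.taxon_ids), sample_ids, counts)


def shannon(counts: np.ndarray, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log p_i over positive counts."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("Shannon diversity undefined for an all-zero vector")
    p = counts / counts.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def mean_rarefied_shannon(table: CountTable, plan: RarefactionPlan,
                          base: float = 2.0) -> pd.DataFrame:
    """Shannon diversity averaged over ``plan.restarts`` independent
    rarefactions at ``plan.depth``.

    Returns a DataFrame indexed by sample id with columns ``shannon``
    (mean H, bits by default), ``sd`` (across restarts) and
    ``observed_taxa`` (mean rarefied richness). Deterministic for a fixed
    plan seed.
    """
    rng = np.random.default_rng(plan.seed)
    totals = table.sample_totals()
    keep = totals >= plan.depth
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(f"dropping samples below depth {plan.depth}: {dropped}")
    records = {}
    for j in np.flatnonzero(keep):
        hs = np.empty(plan.restarts)
        obs = np.empty(plan.restarts)
        col = table.counts[:, j]
        for r in range(plan.restarts):
            sub = rng.multivariate_hypergeometric(col, plan.depth)
            hs[r] = shannon(sub, base=base)
            obs[r] = int((sub > 0).sum())
        records[table.sample_ids[j]] = {
            "shannon": hs.mean(),
            "sd": hs.std(ddof=1) if plan.restarts > 1 else 0.0,
            "observed_taxa": obs.mean(),
        }
    return pd.DataFrame.from_dict(records, orient="index")


def rarefaction_curve(table: CountTable, plan: RarefactionPlan,
                      base: float = 2.0) -> pd.DataFrame:
    """Mean Shannon diversity along a depth grid (step ... depth by
    ``plan.step``), one restart per grid point per sample."""
    rng = np.random.default_rng(plan.seed)
    depths = list(range(plan.step, plan.depth + 1, plan.step))
    rows = []
    totals = table.sample_totals()
    for j, sample in enumerate(table.sample_ids):
        for d in depths:
            if totals[j] < d:
                continue
            sub = rng.multivariate_hypergeometric(table.counts[:, j], d)
            rows.append({"sample_id": sample, "depth": d,
                         "shannon": shannon(sub, base=base)})
    return pd.DataFrame(rows)


def abundant_active_taxa(paired: PairedCommunityTable, theta: float = 1.0,
                         min_count: int = 100, group_col: str = "treatment",
                         scope: Literal["group", "sample", "dataset"] = "group",
                         normalize: bool = True) -> dict[str, set[str]]:
    """The most abundant active taxa per treatment group.

    A taxon qualifies in a group when its RNA reads total at least
    ``min_count`` (summed within the group by default; ``scope`` switches
    to per-sample or whole-dataset totals for the ambiguous readings of
    "present at least 100 times") and its mean activity ratio across the
    group's samples exceeds ``theta``.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if paired.metadata is None or group_col not in paired.metadata.columns:
        raise ValueError(f"paired table needs metadata with a {group_col!r} column")
    groups = paired.metadata.loc[list(paired.sample_ids), group_col].to_numpy()
    out: dict[str, set[str]] = {}
    for g in pd.unique(groups):
        cols = np.flatnonzero(groups == g)
        rna_g = paired.rna[:, cols]
        if scope == "group":
            abundant = rna_g.sum(axis=1) >= min_count
        elif scope == "sample":
            abundant = (rna_g >= min_count).any(axis=1)
        elif scope == "dataset":
            abundant = paired.rna.sum(axis=1) >= min_count
        else:
            raise ValueError(f"unknown scope: {scope!r}")
        ratios = np.vstack([
            activity_ratio(paired, paired.sample_ids[j], normalize=normalize)[0]
            for j in cols
        ])
        active = classify_activity(ratios.mean(axis=0), theta) == ACTIVE
        out[str(g)] = {t for t, a, b in zip(paired.taxon_ids, abundant, active) if a and b}
    return out
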