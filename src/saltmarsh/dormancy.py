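"""Activity ratios, dormancy classification and the threshold sweep.

The operational definition of dormancy: for each taxon in each sample the
ratio of 16S rRNA reads (activity proxy) to 16S rRNA-gene reads (presence
proxy) is computed as ``r = rna / (dna + 1)``; a detected taxon with
``r <= theta`` (default theta = 1) is dormant, one with ``r > theta`` is
potentially active. The +1 on the gene count encodes the assumption that a
taxon observed in the rRNA pool must be present in the community even when
its gene dropped below the sequencing depth, and keeps the ratio finite.

Because raw DNA and RNA library depths differ for reasons unrelated to
activity, ratios are computed on depth-normalized counts by default (each
library scaled to the mean library size of the paired table); the raw-count
mode is retained for exact reproduction of pipelines that skip this step.

The threshold sweep re-runs the classification over a grid of thresholds
(1..50 by default) to show that dormancy contrasts are not an artefact of
the threshold choice; per-sample dormant proportions are non-decreasing in
the threshold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from saltmarsh.tables import PairedCommunityTable, TaxonomyMap

ACTIVE, DORMANT, UNDETECTED = "active", "dormant", "undetected"


@dataclass
class ActivityProfile:
    """Per-taxon activity ratios and labels for one sample."""

    sample_id: str
    taxon_ids: list[str]
    ratios: np.ndarray          # r_i = rna/(dna+1), 0 for undetected taxa
    detected: np.ndarray        # bool; False where rna = dna = 0
    labels: np.ndarray          # {active, dormant, undetected}
    threshold: float
    dormant_proportion: float


def _normalized_counts(paired: PairedCommunityTable, normalize: bool
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Scale every library (column) to the mean library size across both
    molecules, so a count of c in a shallow library outweighs c in a deep
    one. Returns float matrices."""
    dna = paired.dna.astype(float)
    rna = paired.rna.astype(float)
    if not normalize:
        return dna, rna
    totals = np.concatenate([dna.sum(axis=0), rna.sum(axis=0)])
    if not (totals > 0).any():
        return dna, rna  # empty table; downstream detection check will object
    target = totals[totals > 0].mean()
    for m in (dna, rna):
        t = m.sum(axis=0)
        nz = t > 0
        m[:, nz] *= target / t[nz]
    return dna, rna


def activity_ratio(paired: PairedCommunityTable, sample: str,
                   normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Per-taxon rRNA:rRNA-gene ratio for one sample.

    Returns ``(ratios, detected)`` where ``ratios[i] = rna_i / (dna_i + 1)``
    and ``detected[i]`` is False for taxa with zero reads in both libraries
    (their ratio is reported as 0 but carries no information).
    """
    j = paired.sample_index(sample)
    dna, rna = _normalized_counts(paired, normalize)
    d, r = dna[:, j], rna[:, j]
    detected = (paired.dna[:, j] + paired.rna[:, j]) > 0
    return r / (d + 1.0), detected


def classify_activity(ratios: np.ndarray, theta: float = 1.0,
                      detected: np.ndarray | None = None) -> np.ndarray:
    """Label each taxon active (ratio > theta), dormant (ratio <= theta)
    or undetected. The boundary ratio == theta is dormant."""
    if theta < 0:
        raise ValueError("threshold must be >= 0")
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios < 0):
        raise ValueError("ratios must be non-negative")
    labels = np.where(ratios > theta, ACTIVE, DORMANT).astype(object)
    if detected is not None:
        labels[~np.asarray(detected, dtype=bool)] = UNDETECTED
    return labels


def dormant_proportion(paired: PairedCommunityTable, sample: str,
                       theta: float = 1.0, normalize: bool = True,
                       abundance_weighted: bool = False) -> float:
    """Fraction of detected taxa classified dormant in one sample.

    Richness-based by default (each detected taxon counts once, matching
    'per cent of dormant taxa'); ``abundance_weighted=True`` weights taxa
    by their DNA read share instead.
    """
    ratios, detected = activity_ratio(paired, sample, normalize=normalize)
    if not detected.any():
        raise ValueError(f"sample {sample!r} has no detected taxa")
    labels = classify_activity(ratios, theta, detected)
    dormant = labels == DORMANT
    if abundance_weighted:
        w = paired.dna[:, paired.sample_index(sample)].astype(float)
        w = np.where(detected, np.maximum(w, 1.0), 0.0)  # RNA-only taxa get the presumed 1 gene copy
        return float(w[dormant].sum() / w.sum())
    return float(dormant.sum() / detected.sum())


def activity_profile(paired: PairedCommunityTable, sample: str,
                     theta: float = 1.0, normalize: bool = True) -> ActivityProfile:
    ratios, detected = activity_ratio(paired, sample, normalize=normalize)
    labels = classify_activity(ratios, theta, detected)
    prop = float((labels == DORMANT).sum() / detected.sum())
    return ActivityProfile(sample, list(paired.taxon_ids), ratios, detected,
                           labels, theta, prop)


def threshold_sweep(paired: PairedCommunityTable,
                    thetas: Sequence[float] = tuple(range(1, 51)),
                    normalize: bool = True) -> pd.DataFrame:
    """Dormant proportion of every sample at every threshold.

    Returns a samples-by-thresholds DataFrame; each row is non-decreasing
    left to right because raising the threshold can only move taxa from
    active to dormant.
    """
    thetas = list(thetas)
    if not thetas:
        raise ValueError("empty threshold list")
    if any(b < a for a, b in zip(thetas, thetas[1:])):
        raise ValueError("thresholds must be sorted ascending")
    out = np.empty((paired.n_samples, len(thetas)))
    for i, sample in enumerate(paired.sample_ids):
        ratios, detected = activity_ratio(paired, sample, normalize=normalize)
        r = ratios[detected]
        for k, theta in enumerate(thetas):
            out[i, k] = np.mean(r <= theta)
    return pd.DataFrame(out, index=list(paired.sample_ids), columns=thetas)


def order_activity(paired: PairedCommunityTable, taxonomy: TaxonomyMap,
                   coverage: float = 0.9, group_col: str = "treatment",
                   normalize: bool = True, strict: bool = False) -> pd.DataFrame:
    """Order-level log10 display ratios per treatment group.

    OTU counts are summed to taxonomic orders; the display ratio per order
    per sample is ``(sum_rna + 1) / (sum_dna + 1)`` (the +1 on both sides is
    a visualization convention keeping log10 finite; classification uses the
    asymmetric ratio). Orders are ranked by total reads and kept until they
    jointly cover ``coverage`` of all reads. Returns a tidy frame with
    columns order, group, mean_log10_ratio, sem, total_reads.
    """
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    if paired.metadata is None or group_col not in paired.metadata.columns:
        raise ValueError(f"paired table needs metadata with a {group_col!r} column")
    orders = np.array([taxonomy.order(t) for t in paired.taxon_ids])
    unresolved_reads = paired.dna[orders == "unclassified"].sum() + \
        paired.rna[orders == "unclassified"].sum()
    total_reads = paired.dna.sum() + paired.rna.sum()
    if strict and unresolved_reads > 0.5 * total_reads:
        raise ValueError("taxonomy unresolved for >50% of reads")

    dna, rna = _normalized_counts(paired, normalize)
    uniq = pd.unique(orders)
    order_dna = np.vstack([dna[orders == o].sum(axis=0) for o in uniq])
    order_rna = np.vstack([rna[orders == o].sum(axis=0) for o in uniq])
    raw_totals = np.array([(paired.dna[orders == o].sum() + paired.rna[orders == o].sum())
                           for o in uniq])
    rank = np.argsort(-raw_totals)
    cum = np.cumsum(raw_totals[rank]) / raw_totals.sum()
    n_keep = int(np.searchsorted(cum, coverage) + 1)
    keep = rank[:n_keep]

    log_ratio = np.log10((order_rna + 1.0) / (order_dna + 1.0))
    groups = paired.metadata.loc[list(paired.sample_ids), group_col].to_numpy()
    rows = []
    for i in keep:
        for g in pd.unique(groups):
            vals = log_ratio[i, groups == g]
            sem = float(stats.sem(vals)) if len(vals) > 1 else 0.0
            rows.append({"order": uniq[i], "group": g,
                         "mean_log10_ratio": float(vals.mean()),
                         "sem": sem, "total_reads": int(raw_totals[i])})
    return pd.DataFrame(rows)


def dormancy_anova(proportions: Sequence[float] | np.ndarray,
                   groups: Sequence) -> tuple[float, float]:
    """Classical one-way ANOVA of dormant proportions across groups.

    Returns ``(F, p)``. Degenerate input where every observation is equal
    returns ``(0.0, 1.0)`` by convention.
    """
    proportions = np.asarray(proportions, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [proportions[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 values per group")
    if np.ptp(proportions) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)
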