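"""Between-plant-family comparisons of family sizes and domain content.

Family-size differences between species groups (Brassicaceae-like vs
Poaceae-like) are tested per family with a two-sided Wilcoxon rank-sum
test; accessory protein-protein-interaction domain counts are compared per
(family, domain) with a pooled-variance Student's t-test; and the species ×
family count profiles are co-clustered hierarchically with Manhattan
distances and Ward linkage, mirroring the heatmap analysis convention.
Nominal significance thresholds are used by default (0.05 for sizes, 0.01
for domains); Benjamini–Hochberg correction is available but off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .family_annotation import FamilyAssignment


@dataclass
class CountProfile:
    """Species × category count matrix with a group label per species."""

    counts: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [sp for sp in self.counts.index if sp not in self.groups]
        if missing:
            raise ValueError(f"species without a group label: {missing}")

    def group_labels(self) -> tuple[str, str]:
        labels = sorted(set(self.groups[sp] for sp in self.counts.index))
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {labels}")
        return labels[0], labels[1]

    def split(self, category) -> tuple[np.ndarray, np.ndarray, str, str]:
        g1, g2 = self.group_labels()
        col = self.counts[category]
        a = col[[sp for sp in col.index if self.groups[sp] == g1]].to_numpy(dtype=float)
        b = col[[sp for sp in col.index if self.groups[sp] == g2]].to_numpy(dtype=float)
        return a, b, g1, g2


@dataclass(frozen=True)
class EnrichmentResult:
    category: object
    mean_group1: float
    mean_group2: float
    statistic: float
    p_value: float
    enriched_in: str | None

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def _bh_adjust(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    n = len(pvals)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, pvals[idx] * n / rank)
        adj[idx] = running
    return adj.tolist()


def family_size_compare(
    profile: CountProfile, alpha: float = 0.05, bh_correct: bool = False
) -> list[EnrichmentResult]:
    """Per-family two-sided rank-sum comparison between the two species
    groups; significant families are labeled with the larger-mean group."""
    g1, g2 = profile.group_labels()
    for label in (g1, g2):
        if sum(1 for sp in profile.counts.index if profile.groups[sp] == label) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 species")
    results = []
    pvals = []
    for category in profile.counts.columns:
        a, b, _, _ = profile.split(category)
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        results.append((category, float(a.mean()), float(b.mean()), float(stat), float(p)))
        pvals.append(float(p))
    if bh_correct:
        pvals = _bh_adjust(pvals)
    out = []
    for (category, m1, m2, stat, _), p in zip(results, pvals):
        enriched = None
        if p < alpha and m1 != m2:
            enriched = g1 if m1 > m2 else g2
        out.append(EnrichmentResult(category, m1, m2, stat, p, enriched))
    return out


def domain_enrichment(
    profile: CountProfile, alpha: float = 0.01, bh_correct: bool = False
) -> list[EnrichmentResult]:
    """Per (family, domain) pooled-variance two-sample t-test on per-genome
    accessory-domain counts; domains absent everywhere are skipped, and
    zero-variance ties are not significant."""
    g1, g2 = profile.group_labels()
    results = []
    pvals = []
    for category in profile.counts.columns:
        a, b, _, _ = profile.split(category)
        if a.sum() == 0 and b.sum() == 0:
            continue
        if a.std() == 0 and b.std() == 0:
            if a.mean() == b.mean():
                stat, p = 0.0, 1.0
            else:
                stat, p = np.inf if a.mean() > b.mean() else -np.inf, 0.0
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=True)
        results.append((category, float(a.mean()), float(b.mean()), float(stat), float(p)))
        pvals.append(float(p))
    if bh_correct:
        pvals = _bh_adjust(pvals)
    out = []
    for (category, m1, m2, stat, _), p in zip(results, pvals):
        enriched = None
        if p < alpha and m1 != m2:
            enriched = g1 if m1 > m2 else g2
        out.append(EnrichmentResult(category, m1, m2, stat, p, enriched))
    return out


def domain_count_profile(
    assignments: Iterable[FamilyAssignment],
    species_of_locus: Mapping[str, str],
    groups: Mapping[str, str],
) -> CountProfile:
    """Per-genome counts of loci carrying each accessory domain, keyed by
    (family, domain)."""
    species = sorted(set(species_of_locus.values()))
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for a in assignments:
        sp = species_of_locus[a.locus_id]
        for domain in a.subfamily_signature:
            key = (a.family_name, domain)
            counts.setdefault(key, {s: 0 for s in species})[sp] += 1
    frame = pd.DataFrame(
        {key: [col[s] for s in species] for key, col in sorted(counts.items())}, index=species
    )
    return CountProfile(counts=frame, groups=groups)


def cluster_profiles(profile: CountProfile) -> dict:
    """Hierarchical co-clustering of species and categories.

    Classical Ward linkage applied to Manhattan distances on both axes
    (implemented by feeding sqrt distances to scipy's Ward update and
    squaring the merge heights, which reproduces R's hclust "ward.D" on the
    original dissimilarities).  Returns linkage matrices and deterministic
    leaf orders; a constant matrix has no structure and raises.
    """
    X = profile.counts.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 species")
    if np.all(X == X.flat[0]):
        raise ValueError("constant count matrix cannot be clustered")

    def ward_d(mat: np.ndarray) -> np.ndarray:
        d = pdist(mat, metric="cityblock")
        Z = linkage(np.sqrt(d), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
        return Z

    species_linkage = ward_d(X)
    if X.shape[1] >= 2:
        category_linkage = ward_d(X.T)
        category_order = [profile.counts.columns[i] for i in leaves_list(category_linkage)]
    else:  # a single category yields the species tree only
        category_linkage = None
        category_order = list(profile.counts.columns)
    return {
        "species_linkage": species_linkage,
        "category_linkage": category_linkage,
        "species_order": [profile.counts.index[i] for i in leaves_list(species_linkage)],
        "category_order": category_order,
    }


def cut_into_groups(linkage_matrix: np.ndarray, labels: Sequence, k: int) -> dict:
    """Cut a dendrogram into k flat clusters (label -> cluster id)."""
    from scipy.cluster.hierarchy import fcluster

    assignments = fcluster(linkage_matrix, t=k, criterion="maxclust")
    return {label: int(c) for label, c in zip(labels, assignments)}
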