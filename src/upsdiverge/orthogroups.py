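"""Orthologous groups by Markov clustering and ladder age ranks.

The all-vs-all protein similarity table is turned into a weighted undirected
graph (default edge weight: −log10 E-value, capped; reciprocal rows
averaged) and clustered with a native implementation of the Markov Cluster
algorithm (expansion/inflation iteration on a column-stochastic matrix,
inflation 1.5 by default).  Each group containing a focal-species gene is
then placed on the speciation ladder: rank 0 when the group is private to
the focal species, ranks 6..10 as the group's presence exactly matches
successively larger nested sets of within-family species, and rank A when
the group extends to the outgroup or the other plant family.  Groups whose
presence pattern fits none of these are "non_ranked".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import LadderConfig

logger = logging.getLogger(__name__)

RANK_PRIVATE = "0"
RANK_ANCIENT = "A"
RANK_NON_RANKED = "non_ranked"
RANK_NOT_APPLICABLE = "not_applicable"

SIMILARITY_COLUMNS = ["qseqid", "sseqid", "pident", "length", "score", "evalue"]


@dataclass
class SimilarityGraph:
    """Weighted undirected similarity graph; node attribute ``species``."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def species_of(self, node: str) -> str:
        return self.graph.nodes[node]["species"]


@dataclass(frozen=True)
class MCLConfig:
    inflation: float = 1.5
    expansion_power: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tol: float = 1e-6

    def __post_init__(self):
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.expansion_power < 2:
            raise ValueError("expansion power must be at least 2")


@dataclass(frozen=True)
class Orthogroup:
    group_id: str
    members: tuple[str, ...]
    species_presence: frozenset[str]
    age_rank: str | None = None

    def __post_init__(self):
        if not self.members:
            raise ValueError("orthogroup must have members")


def _default_species(locus_id: str) -> str:
    return locus_id.split("|", 1)[0]


def build_graph(
    similarity_rows: pd.DataFrame | Iterable[Mapping],
    score_transform: str = "evalue",
    weight_cap: float = 200.0,
    species_of_locus: Mapping[str, str] | None = None,
) -> SimilarityGraph:
    """Similarity rows → weighted undirected graph.

    Default transform is −log10(E-value) capped at ``weight_cap`` (an
    E-value of exactly 0 is capped); ``score_transform="score"`` uses the
    raw score column.  Asymmetric reciprocal rows are averaged into one
    edge; rows whose transformed weight is non-positive are dropped with a
    warning.  Species labels default to the prefix before "|" in locus ids.
    """
    if not isinstance(similarity_rows, pd.DataFrame):
        similarity_rows = pd.DataFrame(list(similarity_rows))
    directed: dict[tuple[str, str], list[float]] = {}
    dropped = 0
    for row in similarity_rows.itertuples(index=False):
        q, s = str(row.qseqid), str(row.sseqid)
        if q == s:
            continue
        if score_transform == "evalue":
            e = float(row.evalue)
            w = weight_cap if e <= 0 else min(-np.log10(e), weight_cap)
        elif score_transform == "score":
            w = float(row.score)
        else:
            raise ValueError(f"unknown score transform {score_transform!r}")
        if w <= 0:
            dropped += 1
            continue
        directed.setdefault((min(q, s), max(q, s)), []).append(w)
    if dropped:
        logger.warning("dropped %d similarity rows with non-positive weight", dropped)
    g = nx.Graph()
    for (a, b), ws in directed.items():
        g.add_edge(a, b, weight=float(np.mean(ws)))
    for node in g.nodes:
        g.nodes[node]["species"] = (
            species_of_locus[node] if species_of_locus is not None else _default_species(node)
        )
    return SimilarityGraph(g)


def _normalize_columns(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=0)
    dead = sums <= 0
    if np.any(dead):
        M[np.where(dead)[0], np.where(dead)[0]] = 1.0
        sums = M.sum(axis=0)
    return M / sums


def mcl_cluster(graph: SimilarityGraph, config: MCLConfig = MCLConfig()) -> list[Orthogroup]:
    """Markov clustering of the similarity graph into orthogroups.

    Self-loops (weight = the node's maximum incident edge weight, 1 for
    isolated nodes) are added, columns are normalized to a stochastic
    matrix, and expansion (matrix power) alternates with inflation
    (entrywise power + renormalization) and pruning until the matrix stops
    changing.  Clusters are the connected components of the converged
    matrix's non-zero structure and partition all nodes.
    """
    nodes = graph.nodes
    if not nodes:
        raise ValueError("empty similarity graph")
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for a, b, data in graph.graph.edges(data=True):
        A[index[a], index[b]] = A[index[b], index[a]] = data["weight"]
    loops = A.max(axis=0)
    loops[loops <= 0] = 1.0
    A[np.diag_indices(n)] = loops

    M = _normalize_columns(A)
    for _ in range(config.max_iterations):
        expanded = np.linalg.matrix_power(M, config.expansion_power)
        inflated = expanded**config.inflation
        inflated[inflated < config.prune_threshold] = 0.0
        inflated = _normalize_columns(inflated)
        residual = np.abs(inflated - M).max()
        M = inflated
        if residual < config.convergence_tol:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {config.max_iterations} iterations (residual {residual:.3g})"
        )

    structure = csr_matrix((M + M.T) > 0)
    n_comp, labels = connected_components(structure, directed=False)
    clusters: dict[int, list[str]] = {}
    for node, lab in zip(nodes, labels):
        clusters.setdefault(int(lab), []).append(node)
    ordered = sorted(clusters.values(), key=lambda ms: (-len(ms), ms[0]))
    return [
        Orthogroup(
            group_id=f"OG{i:05d}",
            members=tuple(sorted(ms)),
            species_presence=frozenset(graph.species_of(m) for m in ms),
        )
        for i, ms in enumerate(ordered)
    ]


def assign_age_rank(group: Orthogroup, ladder: "LadderConfig", strict: bool = True) -> str:
    """Ladder age label for one orthogroup.

    Strict mode requires the non-focal within-family presence to equal a
    nested species set exactly (with no outgroup/other-family members) for
    ranks 6..10; lenient mode ranks by the deepest split represented.  A
    group lacking the focal species is "not_applicable" rather than an
    error.
    """
    presence = set(group.species_presence)
    if ladder.focal_species not in presence:
        return RANK_NOT_APPLICABLE
    within_other = presence & set(ladder.nested_sets[-1])
    outside = presence - {ladder.focal_species} - set(ladder.nested_sets[-1])
    has_outside = bool(outside)  # outgroup or other plant family
    if presence == {ladder.focal_species}:
        return RANK_PRIVATE
    full_family = set(ladder.nested_sets[-1])
    if within_other == full_family and has_outside:
        return RANK_ANCIENT
    if strict:
        if not has_outside:
            for label, nested in zip(ladder.rank_labels, ladder.nested_sets):
                if within_other == set(nested):
                    return label
        return RANK_NON_RANKED
    # lenient: rank by the most deeply diverged within-family species present
    if has_outside:
        return RANK_ANCIENT
    deepest = -1
    for sp in within_other:
        first = next(i for i, nested in enumerate(ladder.nested_sets) if sp in nested)
        deepest = max(deepest, first)
    return ladder.rank_labels[deepest] if deepest >= 0 else RANK_PRIVATE


def rank_groups(groups: Iterable[Orthogroup], ladder: "LadderConfig", strict: bool = True) -> list[Orthogroup]:
    return [replace(g, age_rank=assign_age_rank(g, ladder, strict)) for g in groups]


def age_count_matrix(
    groups: Iterable[Orthogroup],
    family_of_locus: Mapping[str, str],
    ladder: "LadderConfig",
) -> pd.DataFrame:
    """Family × age-rank matrix of focal-species orthologous locus counts.

    Ranks are assigned on the fly when a group carries none; "non_ranked"
    is tallied as its own column and groups without a focal locus are
    skipped.
    """
    columns = [RANK_PRIVATE, *ladder.rank_labels, RANK_ANCIENT, RANK_NON_RANKED]
    families = sorted({f for f in family_of_locus.values()})
    table = pd.DataFrame(0, index=families, columns=columns)
    for group in groups:
        rank = group.age_rank or assign_age_rank(group, ladder)
        if rank == RANK_NOT_APPLICABLE:
            continue
        for member in group.members:
            species = member.split("|", 1)[0]
            if species != ladder.focal_species:
                continue
            fam = family_of_locus.get(member)
            if fam is None:
                continue
            table.loc[fam, rank] += 1
    return table


def groups_to_frame(groups: Iterable[Orthogroup], species_of_locus: Mapping[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for g in groups:
        for m in g.members:
            sp = species_of_locus[m] if species_of_locus else _default_species(m)
            rows.append({"group_id": g.group_id, "locus": m, "species": sp, "age_rank": g.age_rank})
    return pd.DataFrame(rows, columns=["group_id", "locus", "species", "age_rank"])
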