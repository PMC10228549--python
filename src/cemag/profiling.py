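"""Per-genome pathway-completeness profiles and hierarchical clustering.

A profile records, for each pathway, the percentage of its enzyme roster
detected by the translated homology search, plus per-enzyme presence bits.
These are the quantities hierarchically clustered into the heatmap that
drives rule-based functional assignment, and the feature vector consumed
by the multiclass classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .homology import HomologHit
from .records import PathwayCatalog


@dataclass
class PathwayProfile:
    genome_id: str
    per_pathway_percent: dict[str, float]
    per_enzyme_present: dict[str, int]
    unique_enzyme_percent: dict[str, float]


def build_profile(
    hits: list[HomologHit], catalog: PathwayCatalog, genome_id: str
) -> PathwayProfile:
    """Profile one genome from its (already filtered) hit list.

    An enzyme is present iff it has at least one retained hit; pathway
    percentages are computed over the full roster and over the subset of
    enzymes unique to that pathway.
    """
    roster_names = set(catalog.enzyme_names)
    detected: set[str] = set()
    for h in hits:
        if h.genome_id != genome_id:
            continue
        if h.query_id not in roster_names and h.query_id not in catalog.extras:
            raise ValueError(f"hit references unknown query {h.query_id!r}")
        detected.add(h.query_id)
    per_pathway: dict[str, float] = {}
    unique_pct: dict[str, float] = {}
    present: dict[str, int] = {}
    for pw in catalog.pathway_names:
        roster = catalog.roster(pw)
        found = sum(1 for e in roster if e.enzyme in detected)
        per_pathway[pw] = 100.0 * found / len(roster)
        uniq = [e for e in roster if e.is_unique]
        if uniq:
            unique_pct[pw] = 100.0 * sum(1 for e in uniq if e.enzyme in detected) / len(uniq)
        else:
            unique_pct[pw] = 0.0
        for e in roster:
            present[e.enzyme] = int(e.enzyme in detected)
    return PathwayProfile(genome_id, per_pathway, present, unique_pct)


def profile_matrix(profiles: list[PathwayProfile], catalog: PathwayCatalog) -> pd.DataFrame:
    """Genomes x (pathway percentages, then enzyme bits), rows sorted by id.

    Column order is fixed: pathway percentages in catalog order first,
    then per-enzyme presence bits in catalog order.
    """
    ids = [p.genome_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate genome ids: {dupes}")
    cols = list(catalog.pathway_names) + list(catalog.enzyme_names)
    rows = {}
    for p in sorted(profiles, key=lambda x: x.genome_id):
        rows[p.genome_id] = [p.per_pathway_percent[pw] for pw in catalog.pathway_names] + [
            p.per_enzyme_present[e] for e in catalog.enzyme_names
        ]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    out.index.name = "genome_id"
    return out


def hierarchical_cluster(
    matrix: pd.DataFrame, linkage: str = "complete", distance: str = "euclidean"
):
    """Agglomerative clustering over rows (heatmap.2 defaults: Euclidean
    distance, complete linkage).  Returns (linkage matrix, leaf order as
    row labels, Newick string)."""
    values = matrix.values.astype(float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite values")
    z = hierarchy.linkage(values, method=linkage, metric=distance)
    leaves = hierarchy.leaves_list(z)
    labels = [str(matrix.index[i]) for i in leaves]
    tree = hierarchy.to_tree(z)
    newick = _to_newick(tree, [str(i) for i in matrix.index])
    return z, labels, newick


def _to_newick(node, labels: list[str]) -> str:
    def rec(n) -> str:
        if n.is_leaf():
            return labels[n.id]
        left = rec(n.get_left())
        right = rec(n.get_right())
        dl = n.dist - n.get_left().dist
        dr = n.dist - n.get_right().dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(node) + ";"
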