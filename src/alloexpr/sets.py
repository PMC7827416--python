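"""Cross-individual set algebra of gene lists and trait clustering.

The twelve roman categories combine into six named gene families per
individual (bias toward A = IV + IX, bias toward C = II + XI, above both
parents = II + IV, below both parents = IX + XI, transgressive up =
V + VI + VIII, transgressive down = III + VII + X). For each family this
module reports, across individuals, the union, the global intersection,
pairwise intersections and each individual's *specific* genes (present in
that individual only).

Trait grades are clustered hierarchically (average linkage on standardized
Euclidean distance) to relate expression divergence to phenotypic
divergence among the polyploid individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .io import ConfigError, TraitMatrix

COMBINED_SETS: dict[str, tuple[str, ...]] = {
    "BIA_A": ("IV", "IX"),
    "BIA_C": ("II", "XI"),
    "high_parents": ("II", "IV"),
    "down_parents": ("IX", "XI"),
    "TRANS_UP": ("V", "VI", "VIII"),
    "TRANS_DOWN": ("III", "VII", "X"),
}

_KNOWN_ROMANS = {
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII",
    "CONSERVED", "AMBIGUOUS",
}


@dataclass
class GeneSetFamily:
    """One labelled gene-id set per polyploid individual."""

    label: str
    sets: dict[str, set[str]]  # individual -> gene ids

    @property
    def individuals(self) -> list[str]:
        return sorted(self.sets)


def derive_pattern_sets(assignments: dict[str, pd.DataFrame]) -> dict[str, GeneSetFamily]:
    """Build the six combined families from per-individual category tables.

    ``assignments`` maps individual -> classification table with columns
    pair_id and roman.
    """
    for individual, table in assignments.items():
        unknown = set(table["roman"]) - _KNOWN_ROMANS
        if unknown:
            raise ConfigError(f"{individual}: unknown roman labels {sorted(unknown)}")
    families = {}
    for label, romans in COMBINED_SETS.items():
        sets = {}
        for individual, table in assignments.items():
            mask = table["roman"].isin(romans)
            sets[individual] = set(table.loc[mask, "pair_id"])
        families[label] = GeneSetFamily(label=label, sets=sets)
    return families


def family_from_lists(label: str, lists: dict[str, set[str] | list[str]]) -> GeneSetFamily:
    return GeneSetFamily(label=label, sets={k: set(v) for k, v in lists.items()})


def set_report(family: GeneSetFamily) -> pd.DataFrame:
    """Union, global intersection, per-individual sizes/specific counts and
    pairwise intersections for one family."""
    inds = family.individuals
    if not inds:
        raise ConfigError("set report needs at least one individual")
    sets = family.sets
    union = set().union(*sets.values())
    inter = set(sets[inds[0]])
    for i in inds[1:]:
        inter &= sets[i]
    rows = [
        {"label": family.label, "statistic": "union", "individual": "", "other": "",
         "count": len(union)},
        {"label": family.label, "statistic": "intersection", "individual": "", "other": "",
         "count": len(inter)},
    ]
    for i in inds:
        others = set().union(*(sets[j] for j in inds if j != i)) if len(inds) > 1 else set()
        rows.append({"label": family.label, "statistic": "size", "individual": i,
                     "other": "", "count": len(sets[i])})
        rows.append({"label": family.label, "statistic": "specific", "individual": i,
                     "other": "", "count": len(sets[i] - others)})
    for i, j in combinations(inds, 2):
        rows.append({"label": family.label, "statistic": "pairwise_intersection",
                     "individual": i, "other": j, "count": len(sets[i] & sets[j])})
    return pd.DataFrame(rows)


def membership_table(family: GeneSetFamily) -> pd.DataFrame:
    """Long-form gene membership export (gene lists are the GO hand-off)."""
    rows = [
        {"label": family.label, "individual": ind, "gene_id": g}
        for ind in family.individuals
        for g in sorted(family.sets[ind])
    ]
    return pd.DataFrame(rows, columns=["label", "individual", "gene_id"])


def trait_cluster(traits: TraitMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Average-linkage hierarchical clustering of standardized trait grades.

    Grades are standardized per trait (zero mean, unit variance; constant
    traits dropped); individuals are sorted by label before clustering so
    the result is independent of input row order. Returns the merge table
    (children + height + cluster size) and the leaf order.
    """
    df = traits.frame.sort_index()
    if len(df) < 2:
        raise ConfigError("trait clustering needs at least 2 individuals")
    values = df.to_numpy(dtype=float)
    std = values.std(axis=0, ddof=0)
    keep = std > 0
    if keep.any():
        z = (values[:, keep] - values[:, keep].mean(axis=0)) / std[keep]
    else:  # all traits constant: all individuals coincide
        z = np.zeros((len(df), 1))
    linkage = average(pdist(z, metric="euclidean"))
    labels = list(df.index)
    merges = pd.DataFrame(
        {
            "child1": linkage[:, 0].astype(int),
            "child2": linkage[:, 1].astype(int),
            "height": linkage[:, 2],
            "size": linkage[:, 3].astype(int),
        }
    )
    leaf_order = [labels[i] for i in leaves_list(linkage)]
    return merges, leaf_order
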