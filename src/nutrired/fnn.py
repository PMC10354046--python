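"""The food-nutrient network (FNN) and its nutritional-distance geometry.

The FNN is a weighted bipartite graph linking N foods to the M nutrients they
contain, represented by a non-negative N x M incidence matrix G (grams
contributed by food i to nutrient a) and its binarisation B = [G > 0].  A diet
record's nutrient profile is the simplex-normalised projection n = c f G of
its food profile f through the network.  Pairwise nutritional distances
between foods are unweighted Jaccard distances on nutrient sets — the
magnitudes in G span several orders of magnitude and would otherwise dominate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .io_units import FoodCompositionTable

logger = logging.getLogger(__name__)

__all__ = [
    "FoodNutrientNetwork",
    "NutrientProfile",
    "DistanceMatrix",
    "build_fnn",
    "degrees",
    "nutrient_profile",
    "jaccard_distance_matrix",
    "jaccard_from_incidence",
    "food_similarity_network",
    "personal_similarity_subnetwork",
    "write_bipartite_edgelist",
]


@dataclass
class FoodNutrientNetwork:
    """Bipartite food-nutrient network with weighted and binary incidence."""

    foods: list[str]
    nutrients: list[str]
    G: np.ndarray
    food_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.shape != (len(self.foods), len(self.nutrients)):
            raise ValueError(
                f"G shape {self.G.shape} does not match "
                f"{len(self.foods)} foods x {len(self.nutrients)} nutrients"
            )
        if len(self.foods) < 1 or len(self.nutrients) < 1:
            raise ValueError("network needs at least one food and one nutrient")
        if (self.G < 0).any():
            raise ValueError("incidence weights must be non-negative")
        if len(set(self.foods)) != len(self.foods):
            raise ValueError("duplicate food ids")
        if len(set(self.nutrients)) != len(self.nutrients):
            raise ValueError("duplicate nutrient ids")
        self._food_index = {f: i for i, f in enumerate(self.foods)}

    @property
    def B(self) -> np.ndarray:
        """Binary incidence: B_ia = 1 iff food i contributes nutrient a."""
        return (self.G > 0).astype(int)

    @property
    def n_foods(self) -> int:
        return len(self.foods)

    @property
    def n_nutrients(self) -> int:
        return len(self.nutrients)

    @property
    def zero_degree_foods(self) -> list[str]:
        """Foods with no nutrient links (retained but flagged)."""
        empty = ~(self.G > 0).any(axis=1)
        return [f for f, e in zip(self.foods, empty) if e]

    def food_vector(self, amounts: dict[str, float]) -> np.ndarray:
        """Relative-abundance vector over this network's food ordering."""
        f = np.zeros(self.n_foods)
        for food, g in amounts.items():
            if food not in self._food_index:
                raise KeyError(f"unknown food id {food!r}")
            f[self._food_index[food]] = g
        total = f.sum()
        if total <= 0:
            raise ValueError("food amounts sum to zero")
        return f / total


@dataclass
class NutrientProfile:
    """Nutrient relative-abundance vector n = c f G with normalisation c."""

    nutrients: list[str]
    values: np.ndarray
    c: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isclose(self.values.sum(), 1.0, atol=1e-9):
            raise ValueError("nutrient profile must sum to 1")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise nutritional distances d_ij in [0, 1], zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("distances must lie in [0, 1]")
        self.values = v

    @property
    def similarity(self) -> np.ndarray:
        """s_ij = 1 - d_ij (diagonal is 1)."""
        return 1.0 - self.values

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])


def build_fnn(table: FoodCompositionTable) -> FoodNutrientNetwork:
    """Pivot a composition table into an FNN (missing pairs become zeros)."""
    wide = table.data.pivot_table(
        index="food_id", columns="nutrient_id", values="amount", fill_value=0.0
    ).sort_index(axis=0).sort_index(axis=1)
    net = FoodNutrientNetwork(
        foods=list(wide.index),
        nutrients=list(wide.columns),
        G=wide.to_numpy(dtype=float),
        food_groups=table.food_groups(),
    )
    if net.zero_degree_foods:
        logger.warning(
            "%d food(s) have no nutrient links: %s",
            len(net.zero_degree_foods),
            net.zero_degree_foods[:5],
        )
    return net


def degrees(net: FoodNutrientNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted degrees: (k_food = row sums of B, k_nutrient = column sums)."""
    B = net.B
    return B.sum(axis=1), B.sum(axis=0)


def nutrient_profile(
    f: np.ndarray, net: FoodNutrientNetwork
) -> NutrientProfile:
    """Project a food profile through the FNN: n = c f G, with Σ_a n_a = 1."""
    f = np.asarray(f, dtype=float)
    if f.shape != (net.n_foods,):
        raise ValueError(f"food profile length {f.shape} != {net.n_foods}")
    if (f < 0).any() or not np.isclose(f.sum(), 1.0, atol=1e-9):
        raise ValueError("food profile must be on the simplex")
    raw = f @ net.G
    total = raw.sum()
    if total <= 0:
        raise ValueError(
            "projected nutrient mass is zero (all consumed foods lack nutrients)"
        )
    c = 1.0 / total
    return NutrientProfile(list(net.nutrients), c * raw, c)


def jaccard_from_incidence(B: np.ndarray) -> np.ndarray:
    """Pairwise unweighted Jaccard distance matrix from a binary incidence.

    Empty-vs-empty nutrient sets get distance 0 (logged); empty-vs-nonempty
    get 1, which the union/intersection formula already yields.
    """
    B = np.asarray(B)
    Bf = (B > 0).astype(float)
    inter = Bf @ Bf.T
    k = Bf.sum(axis=1)
    union = k[:, None] + k[None, :] - inter
    if (k == 0).sum() >= 2:
        logger.warning(
            "distance between foods with empty nutrient sets set to 0"
        )
    # union == 0 only when both nutrient sets are empty -> d = 0 by convention
    d = np.where(union > 0, 1.0 - inter / np.maximum(union, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 1.0)


def jaccard_distance_matrix(net: FoodNutrientNetwork) -> DistanceMatrix:
    """Nutritional distance d_ij = 1 - |G_i ∩ G_j| / |G_i ∪ G_j| over nutrient sets."""
    return DistanceMatrix(list(net.foods), jaccard_from_incidence(net.B))


def food_similarity_network(
    net: FoodNutrientNetwork,
    threshold: float = 0.85,
    distances: Optional[DistanceMatrix] = None,
) -> nx.Graph:
    """Project the FNN into food space: edges where s_ij = 1 - d_ij >= threshold.

    The threshold comparison is inclusive.  Nodes carry their food group; edges
    carry the similarity weight.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if distances is None:
        distances = jaccard_distance_matrix(net)
    s = distances.similarity
    g = nx.Graph()
    for food in net.foods:
        g.add_node(food, food_group=net.food_groups.get(food, ""))
    ii, jj = np.where(np.triu(s >= threshold, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(net.foods[i], net.foods[j], similarity=float(s[i, j]))
    return g


def personal_similarity_subnetwork(
    amounts: dict[str, float],
    net: FoodNutrientNetwork,
    threshold: float = 0.85,
    reference: Optional[nx.Graph] = None,
) -> nx.Graph:
    """Food-similarity subgraph induced by one record's consumed foods.

    Node attribute ``abundance`` carries the record's relative abundances; the
    edge set is a subset of the reference network's at the same threshold.
    """
    if not amounts or sum(amounts.values()) <= 0:
        raise ValueError("record is empty")
    f = net.food_vector(amounts)
    if reference is None:
        reference = food_similarity_network(net, threshold=threshold)
    consumed = [food for food, v in zip(net.foods, f) if v > 0]
    sub = reference.subgraph(consumed).copy()
    for food in consumed:
        sub.nodes[food]["abundance"] = float(f[net.foods.index(food)])
    return sub


def write_bipartite_edgelist(
    net: FoodNutrientNetwork, path: Union[str, Path]
) -> None:
    """Export the weighted bipartite incidence as TSV (food, nutrient, grams)."""
    rows = []
    ii, aa = np.nonzero(net.G)
    for i, a in zip(ii, aa):
        rows.append((net.foods[i], net.nutrients[a], net.G[i, a]))
    pd.DataFrame(rows, columns=["food_id", "nutrient_id", "grams"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
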