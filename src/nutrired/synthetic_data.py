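"""Synthetic food-composition tables and longitudinal dietary cohorts.

Restricted cohort data (FFQ/ASA24 exports) cannot ship with the package, so
this module generates inputs with the statistical structure the analysis
assumes: a nested food-nutrient incidence (tunable from random to perfectly
triangular), nutrient amounts spanning three orders of magnitude, sparse
overdispersed per-record food profiles, and per-subject food signatures whose
stability over time is controlled by a personalization weight.

The generator is deterministic given a :class:`SyntheticSpec` and its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .fnn import FoodNutrientNetwork
from .io_units import DietRecordSet, FoodCompositionTable

__all__ = ["SyntheticSpec", "synth_fnn", "synth_cohort", "nested_incidence"]


@dataclass
class SyntheticSpec:
    """Study-condition parameters for the synthetic generator.

    ``nestedness`` in [0, 1] tunes the incidence from fully rewired (0) to the
    perfect triangle (1).  ``personalization`` in [0, 1] is the weight of each
    subject's stable food-preference vector in every record.  Richness (foods
    per record) follows a truncated negative binomial with the given mean and
    dispersion (size) parameters; ``concentration`` is the symmetric Dirichlet
    parameter for abundance noise (``math.inf`` switches the noiseless,
    fully deterministic limit).
    """

    n_foods: int = 200
    n_nutrients: int = 40
    nestedness: float = 0.9
    n_subjects: int = 50
    n_timepoints: int = 4
    personalization: float = 0.8
    richness_mean: float = 15.0
    richness_dispersion: float = 5.0
    concentration: float = 1.0
    weight_orders: float = 3.0  # log10 span of nutrient amounts
    meal_grams: float = 2000.0
    n_food_groups: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_foods, self.n_nutrients, self.n_subjects,
               self.n_timepoints, self.n_food_groups) < 1:
            raise ValueError("all counts must be >= 1")
        for name in ("nestedness", "personalization"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.richness_mean < 1 or self.richness_mean > self.n_foods:
            raise ValueError("richness_mean must be in [1, n_foods]")
        if self.richness_dispersion < 0:
            raise ValueError("richness_dispersion must be >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")


def nested_incidence(n_foods: int, n_nutrients: int) -> np.ndarray:
    """Perfectly nested ("triangular") binary incidence.

    Row i gets the first ceil(M (N - i) / N) columns, giving decreasing row
    fills and strictly decreasing column fills; when N == M the row degrees
    are strictly distinct too and NODF is exactly 1.
    """
    n, m = n_foods, n_nutrients
    B = np.zeros((n, m), dtype=int)
    for i in range(n):
        deg = max(1, math.ceil(m * (n - i) / n))
        B[i, :deg] = 1
    return B


def _rewire(B: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Move a fraction of links to uniformly random empty cells.

    Links that are the last in their row or column are never removed, so the
    generated table keeps every requested food and nutrient after pivoting.
    """
    B = B.copy()
    n_move = int(round(fraction * B.sum()))
    if n_move == 0:
        return B
    links = np.argwhere(B == 1)
    order = rng.permutation(len(links))
    removed = 0
    for idx in order:
        if removed == n_move:
            break
        i, a = links[idx]
        if B[i].sum() > 1 and B[:, a].sum() > 1:
            B[i, a] = 0
            removed += 1
    empties = np.argwhere(B == 0)
    chosen = rng.choice(len(empties), size=removed, replace=False)
    for i, a in empties[chosen]:
        B[i, a] = 1
    return B


def _food_id(i: int) -> str:
    return f"food{i + 1:04d}"


def _nutrient_id(a: int) -> str:
    return f"nutr{a + 1:03d}"


def synth_fnn(spec: SyntheticSpec) -> FoodCompositionTable:
    """Generate a food-composition table with tunable nestedness.

    Starts from the perfect triangle, rewires a (1 - nestedness) fraction of
    links uniformly, and assigns positive weights log-uniform over
    ``weight_orders`` decades (default 1 mg - 1 g).  Foods are split into
    ``n_food_groups`` contiguous groups.
    """
    rng = np.random.default_rng(spec.seed)
    B = nested_incidence(spec.n_foods, spec.n_nutrients)
    B = _rewire(B, 1.0 - spec.nestedness, rng)
    ii, aa = np.nonzero(B)
    amounts = 10.0 ** rng.uniform(-spec.weight_orders, 0.0, size=len(ii))
    groups = [
        f"group{(i * spec.n_food_groups) // spec.n_foods + 1}"
        for i in range(spec.n_foods)
    ]
    table = pd.DataFrame(
        {
            "food_id": [_food_id(i) for i in ii],
            "food_group": [groups[i] for i in ii],
            "nutrient_id": [_nutrient_id(a) for a in aa],
            "amount": amounts,
        }
    )
    return FoodCompositionTable(table)


def _draw_richness(spec: SyntheticSpec, rng: np.random.Generator) -> int:
    """Truncated negative binomial on [2, n_foods] (fixed if dispersion is 0)."""
    lo, hi = 2, spec.n_foods
    if spec.richness_dispersion == 0:
        return int(np.clip(round(spec.richness_mean), lo, hi))
    r = spec.richness_dispersion
    p = r / (r + spec.richness_mean)
    for _ in range(1000):
        k = rng.negative_binomial(r, p)
        if lo <= k <= hi:
            return int(k)
    return int(np.clip(round(spec.richness_mean), lo, hi))


def synth_cohort(
    spec: SyntheticSpec, net: FoodNutrientNetwork
) -> DietRecordSet:
    """Generate longitudinal dietary records with personal food signatures.

    Each subject has a Dirichlet preference vector over the network's foods;
    each record mixes it (weight ``personalization``) with a fresh random
    vector, draws a richness, samples that many foods weighted by the mix,
    and assigns abundances from a symmetric Dirichlet scaled by the mix.  In
    the noiseless limit (``concentration == math.inf``) the top-richness foods
    are taken deterministically with abundances proportional to preference.
    """
    foods = list(net.foods)
    n = len(foods)
    if spec.richness_mean > n:
        raise ValueError("richness exceeds the number of foods in the network")
    rng = np.random.default_rng(spec.seed + 1)
    w = spec.personalization
    rows = []
    for s in range(spec.n_subjects):
        subject = f"subj{s + 1:03d}"
        pref = rng.dirichlet(np.full(n, 0.3))
        for t in range(spec.n_timepoints):
            fresh = rng.dirichlet(np.full(n, 0.3))
            mix = w * pref + (1.0 - w) * fresh
            k = _draw_richness(spec, rng)
            if math.isinf(spec.concentration):
                chosen = np.argsort(-mix, kind="stable")[:k]
                weights = mix[chosen]
            else:
                chosen = rng.choice(n, size=k, replace=False, p=mix)
                noise = rng.dirichlet(np.full(k, spec.concentration))
                weights = noise * mix[chosen]
                if weights.sum() <= 0:  # extreme Dirichlet underflow
                    weights = mix[chosen]
            grams = spec.meal_grams * weights / weights.sum()
            for food_idx, g in zip(chosen, grams):
                rows.append((subject, t + 1, foods[food_idx], float(g)))
    return DietRecordSet(
        pd.DataFrame(rows, columns=["subject_id", "timepoint", "food_id", "grams"])
    )
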