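"""Null models for the food-nutrient network and for dietary records.

Four network randomizations probe which topological features of the FNN drive
redundancy:

* ``fnn1`` — complete rewiring keeping N, M and the total link count L;
* ``fnn2`` — each food keeps its degree, its nutrients are redrawn;
* ``fnn3`` — each nutrient keeps its degree, its foods are redrawn;
* ``fnn4`` — both degree sequences preserved exactly via checkerboard
  (2x2 swap) MCMC.

Three composition randomizations probe the role of the dietary records
themselves:

* ``comp1`` — each record's abundances reassigned to a random food subset of
  the pool with the same richness;
* ``comp2`` — non-zero abundances permuted within each record (across its own
  consumed foods by default, across the whole pool behind a flag);
* ``comp3`` — each food's non-zero abundances permuted across the records
  consuming it (across all records behind a flag).

``nr_null_comparison`` recomputes per-record redundancy under replicate
randomizations and summarises the observed-versus-null contrast with a paired
sign-flip permutation test on the median difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .diversity import record_nr
from .fnn import DistanceMatrix, FoodNutrientNetwork, jaccard_from_incidence
from .io_units import DietRecordSet

logger = logging.getLogger(__name__)

__all__ = [
    "FNN_SCHEMES",
    "COMP_SCHEMES",
    "NullScheme",
    "NullComparison",
    "randomize_fnn",
    "randomize_composition",
    "nr_null_comparison",
    "paired_permutation_test",
]

FNN_SCHEMES = ("fnn1", "fnn2", "fnn3", "fnn4")
COMP_SCHEMES = ("comp1", "comp2", "comp3")


@dataclass
class NullScheme:
    """A named randomization scheme with its replicate count and seed."""

    name: str
    replicates: int = 100
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        name = self.name.lower().replace("-", "").replace("_", "")
        name = name.replace("null", "")
        if name not in FNN_SCHEMES + COMP_SCHEMES:
            raise ValueError(
                f"unknown scheme {self.name!r}; expected one of "
                f"{FNN_SCHEMES + COMP_SCHEMES}"
            )
        self.name = name
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def is_network_scheme(self) -> bool:
        return self.name in FNN_SCHEMES


def randomize_fnn(
    B: np.ndarray, scheme: int, rng_or_seed: Union[int, np.random.Generator, None]
) -> np.ndarray:
    """Randomize a binary incidence matrix under Null-FNN scheme 1-4.

    1: uniform placement of the same number of links; 2: row degrees
    preserved; 3: column degrees preserved; 4: both margins preserved by
    checkerboard swaps (10 x L attempts).  Scheme 4 warns and returns a copy
    of the input if no swap is ever possible.
    """
    B = np.asarray(B)
    if not np.isin(B, (0, 1)).all():
        raise ValueError("incidence matrix must be binary")
    rng = np.random.default_rng(rng_or_seed) if not isinstance(
        rng_or_seed, np.random.Generator
    ) else rng_or_seed
    n, m = B.shape
    out = np.zeros_like(B)
    if scheme == 1:
        L = int(B.sum())
        cells = rng.choice(n * m, size=L, replace=False)
        out.flat[cells] = 1
    elif scheme == 2:
        for i in range(n):
            k = int(B[i].sum())
            out[i, rng.choice(m, size=k, replace=False)] = 1
    elif scheme == 3:
        for a in range(m):
            k = int(B[:, a].sum())
            out[rng.choice(n, size=k, replace=False), a] = 1
    elif scheme == 4:
        out = B.copy()
        L = int(B.sum())
        attempts = 10 * L
        rows = rng.integers(0, n, size=2 * attempts).reshape(attempts, 2)
        cols = rng.integers(0, m, size=2 * attempts).reshape(attempts, 2)
        swapped = 0
        for (i, j), (a, b) in zip(rows, cols):
            if i == j or a == b:
                continue
            # checkerboard: 1 0 / 0 1 (or its mirror) across rows i,j cols a,b
            if out[i, a] == out[j, b] and out[i, b] == out[j, a] and out[i, a] != out[i, b]:
                out[i, a], out[i, b] = out[i, b], out[i, a]
                out[j, a], out[j, b] = out[j, b], out[j, a]
                swapped += 1
        if swapped == 0:
            logger.warning(
                "no swappable checkerboard found in %d attempts; "
                "matrix returned unchanged",
                attempts,
            )
    else:
        raise ValueError(f"scheme must be 1-4, got {scheme}")
    return out


def randomize_composition(
    records: DietRecordSet,
    scheme: int,
    pool: Sequence[str],
    rng_or_seed: Union[int, np.random.Generator, None],
    whole_pool: bool = False,
) -> DietRecordSet:
    """Randomize dietary records under Null-comp scheme 1-3.

    1: each record's abundance values land on a uniformly drawn food subset
    of the pool with the same richness; 2: non-zero abundances permuted
    within each record (``whole_pool=True`` scatters them over the whole pool
    instead, which changes which foods are consumed but not the values);
    3: each food's non-zero abundances permuted across the records consuming
    it (``whole_pool=True`` permutes across all records).
    """
    rng = np.random.default_rng(rng_or_seed) if not isinstance(
        rng_or_seed, np.random.Generator
    ) else rng_or_seed
    pool = list(pool)
    df = records.data
    consumed = set(df.loc[df["grams"] > 0, "food_id"])
    if not consumed.issubset(pool):
        raise ValueError("pool does not cover all consumed foods")

    if scheme in (1, 2):
        parts = []
        for key, rec in df[df["grams"] > 0].groupby(
            ["subject_id", "timepoint"], sort=True
        ):
            grams = rec["grams"].to_numpy()
            k = len(grams)
            if scheme == 1 or (scheme == 2 and whole_pool):
                if k > len(pool):
                    raise ValueError(
                        f"record {key} richness {k} exceeds pool size {len(pool)}"
                    )
                foods = list(np.asarray(pool)[rng.choice(len(pool), k, replace=False)])
                values = grams if scheme == 1 else rng.permutation(grams)
            else:  # comp-2, within the record's own consumed foods
                foods = list(rec["food_id"])
                values = rng.permutation(grams)
            parts.append(
                pd.DataFrame(
                    {
                        "subject_id": key[0],
                        "timepoint": key[1],
                        "food_id": foods,
                        "grams": values,
                    }
                )
            )
        return DietRecordSet(pd.concat(parts, ignore_index=True))

    if scheme == 3:
        out = df[df["grams"] > 0].copy().reset_index(drop=True)
        if whole_pool:
            out["grams"] = rng.permutation(out["grams"].to_numpy())
        else:
            for _, idx in out.groupby("food_id").groups.items():
                vals = out.loc[idx, "grams"].to_numpy()
                out.loc[idx, "grams"] = rng.permutation(vals)
        return DietRecordSet(out)

    raise ValueError(f"scheme must be 1-3, got {scheme}")


def paired_permutation_test(
    observed: np.ndarray,
    null: np.ndarray,
    n_permutations: int = 10000,
    seed: Optional[int] = None,
) -> float:
    """One-sided sign-flip permutation p for median(observed - null) > 0."""
    diffs = np.asarray(observed, dtype=float) - np.asarray(null, dtype=float)
    stat = np.median(diffs)
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_permutations, diffs.size))
    perm_stats = np.median(signs * diffs, axis=1)
    return float((1 + np.sum(perm_stats >= stat)) / (n_permutations + 1))


@dataclass
class NullComparison:
    """Observed per-record NR against replicate null distributions."""

    scheme: NullScheme
    record_ids: list[tuple]
    observed: np.ndarray  # per record
    null: np.ndarray  # replicates x records
    p_value: float = float("nan")
    seed: Optional[int] = None
    mode: Union[str, float] = "GSI"

    @property
    def observed_median(self) -> float:
        return float(np.median(self.observed))

    @property
    def null_medians(self) -> np.ndarray:
        """Per-replicate medians over records."""
        return np.median(self.null, axis=1)

    @property
    def null_median(self) -> float:
        return float(np.median(self.null))


def nr_null_comparison(
    records: DietRecordSet,
    net: FoodNutrientNetwork,
    scheme: Union[str, NullScheme],
    replicates: Optional[int] = None,
    seed: Optional[int] = None,
    mode: Union[str, float] = "GSI",
    n_permutations: int = 10000,
) -> NullComparison:
    """Observed vs null per-record NR for one randomization scheme.

    Network schemes rebuild the Jaccard distance matrix from each randomized
    incidence; composition schemes randomize the records against the fixed
    network.  The summary p-value is a paired sign-flip permutation test of
    the median observed-minus-null difference (null per record averaged over
    replicates), one-sided for observed > null.
    """
    if not isinstance(scheme, NullScheme):
        scheme = NullScheme(scheme, replicates=replicates or 100, seed=seed)
    if replicates is not None:
        scheme.replicates = replicates
    if seed is not None:
        scheme.seed = seed
    if (records.data["grams"] <= 0).all():
        raise ValueError("all records are empty")
    rng = np.random.default_rng(scheme.seed)

    obs = record_nr(records, net, mode=mode)
    record_ids = list(zip(obs["subject_id"], obs["timepoint"]))
    observed = obs["NR"].to_numpy()

    null = np.empty((scheme.replicates, len(observed)))
    scheme_no = int(scheme.name[-1])
    for r in range(scheme.replicates):
        if scheme.is_network_scheme:
            Bnull = randomize_fnn(net.B, scheme_no, rng)
            dist = DistanceMatrix(list(net.foods), jaccard_from_incidence(Bnull))
            res = record_nr(records, net, mode=mode, distances=dist)
        else:
            shuffled = randomize_composition(records, scheme_no, net.foods, rng)
            res = record_nr(shuffled, net, mode=mode)
        res = res.sort_values(["subject_id", "timepoint"]).reset_index(drop=True)
        null[r] = res["NR"].to_numpy()

    p = paired_permutation_test(
        observed,
        null.mean(axis=0),
        n_permutations=n_permutations,
        seed=rng.integers(2**31),
    )
    return NullComparison(
        scheme=scheme,
        record_ids=record_ids,
        observed=observed,
        null=null,
        p_value=p,
        seed=scheme.seed,
        mode=mode,
    )
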