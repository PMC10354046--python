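"""Food diversity, nutritional diversity, and nutritional redundancy.

For a diet record with food profile f (relative abundances on the simplex)
and pairwise nutritional distances d_ij in [0, 1]:

* Gini-Simpson form — food diversity FD = GSI = 1 - Σ f_i², nutritional
  diversity ND = Rao's quadratic entropy Q = Σ_{i≠j} d_ij f_i f_j, and
  nutritional redundancy NR = FD - ND = Σ_{i≠j} (1 - d_ij) f_i f_j: the
  expected nutrient overlap of two randomly drawn food units.

* Hill-number form of order q — FD_q is the effective number of foods
  (Σ f_i^q)^{1/(1-q)}; ND_q(Q') is the attribute-diversity generalisation
  built on the modified distance matrix Δ' whose diagonal λ_i is food i's
  mean distance to all other foods; NR_q = FD_q - ND_q(Q').

Both families degenerate gracefully: a single-food record or an all-zero
distance matrix gives ND = 0 and hence NR = FD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .fnn import DistanceMatrix, FoodNutrientNetwork, jaccard_distance_matrix
from .io_units import DietRecordSet

__all__ = [
    "ModifiedDistanceMatrix",
    "RedundancyResult",
    "gini_simpson",
    "rao_q",
    "nr_gsi",
    "hill_fd",
    "modified_distance",
    "hill_nd",
    "hill_nr",
    "record_nr",
]

_SIMPLEX_ATOL = 1e-6


def _check_simplex(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 1:
        raise ValueError("profile must be a 1-D vector")
    if (f < 0).any() or not np.isclose(f.sum(), 1.0, atol=_SIMPLEX_ATOL):
        raise ValueError("profile must be non-negative and sum to 1")
    return f


def _distance_values(delta: Union[DistanceMatrix, np.ndarray]) -> np.ndarray:
    if isinstance(delta, DistanceMatrix):
        return delta.values
    return np.asarray(delta, dtype=float)


@dataclass
class ModifiedDistanceMatrix:
    """Δ': off-diagonal distances plus diagonal λ_i = mean distance to others.

    When all pairwise distances equal a constant c, every λ_i = c.  ``Q_prime``
    evaluates Rao's quadratic entropy under Δ' (diagonal terms included) for a
    given profile.
    """

    values: np.ndarray
    degenerate: bool = False  # N = 1: no off-diagonal entries to average

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def Q_prime(self, f: np.ndarray) -> float:
        f = np.asarray(f, dtype=float)
        return float(f @ self.values @ f)


@dataclass
class RedundancyResult:
    """FD, ND and NR for one record at a given order (or the GSI form)."""

    q: Union[str, float]  # "GSI" or the Hill order
    fd: float
    nd: float
    nr: float
    record_id: Optional[tuple] = None


def gini_simpson(f: np.ndarray) -> float:
    """Gini-Simpson index 1 - Σ f_i²: probability two random units differ."""
    f = _check_simplex(f)
    return float(1.0 - np.dot(f, f))


def rao_q(f: np.ndarray, delta: Union[DistanceMatrix, np.ndarray]) -> float:
    """Rao's quadratic entropy Q = Σ_{i≠j} d_ij f_i f_j (zero diagonal assumed)."""
    f = _check_simplex(f)
    d = _distance_values(delta)
    if d.shape != (f.size, f.size):
        raise ValueError(f"distance matrix {d.shape} does not match profile {f.size}")
    return float(f @ d @ f)


def nr_gsi(
    f: np.ndarray,
    delta: Union[DistanceMatrix, np.ndarray],
    record_id: Optional[tuple] = None,
) -> RedundancyResult:
    """Gini-Simpson-form redundancy: NR = GSI - Q = Σ_{i≠j} (1 - d_ij) f_i f_j."""
    fd = gini_simpson(f)
    nd = rao_q(f, delta)
    return RedundancyResult(q="GSI", fd=fd, nd=nd, nr=fd - nd, record_id=record_id)


def hill_fd(f: np.ndarray, q: float) -> float:
    """Hill number of order q: the effective number of equally abundant foods.

    FD_q = (Σ f_i^q)^{1/(1-q)} for q != 1 and exp(-Σ f_i log f_i) at q = 1;
    zero abundances are excluded (relevant at q <= 1).
    """
    if q < 0:
        raise ValueError(f"Hill order must be non-negative, got {q}")
    f = _check_simplex(f)
    fs = f[f > 0]
    if q == 1:
        return float(np.exp(-np.sum(fs * np.log(fs))))
    return float(np.sum(fs**q) ** (1.0 / (1.0 - q)))


def modified_distance(
    delta: Union[DistanceMatrix, np.ndarray]
) -> ModifiedDistanceMatrix:
    """Build Δ' from Δ: copy off-diagonals, set diagonal to row means λ_i."""
    d = _distance_values(delta).copy()
    n = d.shape[0]
    if n == 1:
        return ModifiedDistanceMatrix(values=np.zeros((1, 1)), degenerate=True)
    lam = d.sum(axis=1) / (n - 1)  # diagonal of Δ is zero, so plain row sums
    np.fill_diagonal(d, lam)
    return ModifiedDistanceMatrix(values=d)


def hill_nd(
    f: np.ndarray, delta_prime: ModifiedDistanceMatrix, q: float
) -> float:
    """Hill-number nutritional diversity ND_q(Q') under the modified distances.

    ND_q(Q') = [Σ_ij (d'_ij / Q') (f_i f_j)^q]^{1/(2(1-q))} · Q' for q != 1,
    with the exponential form at q = 1.  Q' = Σ_ij d'_ij f_i f_j; if Q' = 0
    (all foods nutritionally identical, or a single-food record) ND = 0.
    """
    if q < 0:
        raise ValueError(f"Hill order must be non-negative, got {q}")
    f = _check_simplex(f)
    d = delta_prime.values
    if d.shape != (f.size, f.size):
        raise ValueError(f"Δ' shape {d.shape} does not match profile {f.size}")
    support = f > 0
    fs = f[support]
    ds = d[np.ix_(support, support)]
    qprime = float(fs @ ds @ fs)
    if qprime <= 0:
        return 0.0
    ff = np.outer(fs, fs)
    if q == 1:
        expo = -0.5 * np.sum((ds / qprime) * ff * np.log(ff))
        return float(np.exp(expo) * qprime)
    total = np.sum((ds / qprime) * ff**q)
    return float(total ** (1.0 / (2.0 * (1.0 - q))) * qprime)


def hill_nr(
    f: np.ndarray,
    delta_prime: ModifiedDistanceMatrix,
    q: float,
    record_id: Optional[tuple] = None,
) -> RedundancyResult:
    """Hill-form redundancy NR_q(Q') = FD_q - ND_q(Q')."""
    fd = hill_fd(f, q)
    nd = hill_nd(f, delta_prime, q)
    return RedundancyResult(q=q, fd=fd, nd=nd, nr=fd - nd, record_id=record_id)


def record_nr(
    records: DietRecordSet,
    net: FoodNutrientNetwork,
    mode: Union[str, float] = "GSI",
    distances: Optional[DistanceMatrix] = None,
) -> pd.DataFrame:
    """Per-record redundancy over a cohort: one row per (subject, timepoint).

    ``mode`` is ``"GSI"`` or a Hill order q.  The pool-level distance matrix is
    computed once from ``net`` (or supplied) and restricted to each record's
    consumed foods; for the Hill form the modified diagonal λ is taken over
    the record's own food set.  Returns columns subject_id, timepoint, FD,
    ND, NR, q.
    """
    if distances is None:
        distances = jaccard_distance_matrix(net)
    keys, foods, F = records.to_matrix(food_ids=list(net.foods))
    D = distances.values
    rows = []
    for key, f in zip(keys, F):
        support = np.where(f > 0)[0]
        fsub = f[support]
        dsub = D[np.ix_(support, support)]
        if isinstance(mode, str) and mode.upper() == "GSI":
            res = nr_gsi(fsub, dsub, record_id=key)
        else:
            q = float(mode)
            res = hill_nr(fsub, modified_distance(dsub), q, record_id=key)
        rows.append(
            {
                "subject_id": key[0],
                "timepoint": key[1],
                "FD": res.fd,
                "ND": res.nd,
                "NR": res.nr,
                "q": res.q,
            }
        )
    return pd.DataFrame(rows)
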