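"""Beta diversity between diet profiles and the personalization test.

Four dissimilarity measures compare two relative-abundance profiles:
Bray-Curtis, root Jensen-Shannon divergence (log base 2, so disjoint profiles
score exactly 1), Yue-Clayton distance, and negative Spearman correlation
(reported raw, range [-1, 1]).

``personalization_test`` asks whether a subject's diet records resemble each
other more than they resemble other subjects' records: intra-individual
pairwise dissimilarities are compared with inter-individual ones via a
subject-label permutation test on the difference of medians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.spatial.distance import jensenshannon, pdist, squareform
from scipy.stats import spearmanr

from .io_units import DietRecordSet

__all__ = [
    "MEASURES",
    "beta",
    "beta_matrix",
    "BetaMatrix",
    "PersonalizationResult",
    "personalization_test",
]

MEASURES = ("bray-curtis", "rjsd", "yue-clayton", "neg-spearman")

_ALIASES = {
    "braycurtis": "bray-curtis",
    "bray-curtis": "bray-curtis",
    "bc": "bray-curtis",
    "rjsd": "rjsd",
    "jsd": "rjsd",
    "yueclayton": "yue-clayton",
    "yue-clayton": "yue-clayton",
    "yc": "yue-clayton",
    "negspearman": "neg-spearman",
    "neg-spearman": "neg-spearman",
    "spearman": "neg-spearman",
}


def _canonical(measure: str) -> str:
    key = measure.lower().replace("_", "-")
    if key not in _ALIASES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    return _ALIASES[key]


def _check_pair(p: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValueError("profiles must be 1-D vectors of equal length")
    if (p < 0).any() or (r < 0).any():
        raise ValueError("profiles must be non-negative")
    if p.sum() <= 0 or r.sum() <= 0:
        raise ValueError("zero profile")
    return p, r


def beta(p: np.ndarray, r: np.ndarray, measure: str = "bray-curtis") -> float:
    """Dissimilarity between two profiles under one of the four measures."""
    p, r = _check_pair(p, r)
    name = _canonical(measure)
    if name == "bray-curtis":
        return float(np.abs(p - r).sum() / (p + r).sum())
    if name == "rjsd":
        return float(jensenshannon(p, r, base=2))
    if name == "yue-clayton":
        num = float(((p - r) ** 2).sum())
        den = float((p**2).sum() + (r**2).sum() - (p * r).sum())
        return num / den if den > 0 else 0.0
    # neg-spearman; ties get average ranks
    rho = spearmanr(p, r).statistic
    return float(-rho)


@dataclass
class BetaMatrix:
    """Pairwise dissimilarities over records for one measure."""

    record_ids: list[tuple]
    values: np.ndarray
    measure: str


def _pairwise(F: np.ndarray, measure: str) -> np.ndarray:
    """Square pairwise dissimilarity matrix over profile rows."""
    name = _canonical(measure)
    if name == "bray-curtis":
        return squareform(pdist(F, metric="braycurtis"))
    if name == "rjsd":
        # scipy's jensenshannon pdist uses natural log; rescale to base 2
        return squareform(pdist(F, metric="jensenshannon")) / np.sqrt(np.log(2.0))
    if name == "yue-clayton":
        sq = (F**2).sum(axis=1)
        cross = F @ F.T
        num = sq[:, None] + sq[None, :] - 2.0 * cross
        den = sq[:, None] + sq[None, :] - cross
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(den > 0, num / den, 0.0)
        np.fill_diagonal(d, 0.0)
        return d
    rho = spearmanr(F, axis=1).statistic
    if np.ndim(rho) == 0:  # two records: spearmanr returns a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    return -np.asarray(rho)


def beta_matrix(
    records: DietRecordSet, measure: str = "bray-curtis"
) -> BetaMatrix:
    """All pairwise record dissimilarities for one measure."""
    keys, _, F = records.to_matrix()
    return BetaMatrix(keys, _pairwise(F, measure), _canonical(measure))


@dataclass
class PersonalizationResult:
    """Intra- vs inter-individual dissimilarities and the permutation p-value."""

    measure: str
    intra: np.ndarray
    inter: np.ndarray
    statistic: float  # median(intra) - median(inter)
    p_value: float
    n_permutations: int
    seed: Optional[int]

    @property
    def intra_median(self) -> float:
        return float(np.median(self.intra))

    @property
    def inter_median(self) -> float:
        return float(np.median(self.inter))


def personalization_test(
    records: DietRecordSet,
    measure: str = "bray-curtis",
    seed: Optional[int] = None,
    n_permutations: int = 10000,
) -> PersonalizationResult:
    """Test whether same-subject records are closer than different-subject ones.

    The statistic is median(intra) - median(inter) over all record pairs.
    Subject labels are permuted across records (10,000 times by default) and
    the one-sided p-value is the fraction of permutations at least as extreme
    (intra at least as much lower than inter) as observed.
    """
    keys, _, F = records.to_matrix()
    subjects = np.array([k[0] for k in keys])
    uniq, counts = np.unique(subjects, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("personalization test needs at least two subjects")
    if (counts < 2).all():
        raise ValueError("personalization test needs subjects with >= 2 records")

    D = _pairwise(F, measure)
    iu = np.triu_indices(len(keys), k=1)
    flat = D[iu]
    same = subjects[iu[0]] == subjects[iu[1]]
    intra = flat[same]
    inter = flat[~same]
    stat = float(np.median(intra) - np.median(inter))

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = subjects[rng.permutation(len(subjects))]
        psame = perm[iu[0]] == perm[iu[1]]
        pstat = np.median(flat[psame]) - np.median(flat[~psame])
        if pstat <= stat:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return PersonalizationResult(
        measure=_canonical(measure),
        intra=intra,
        inter=inter,
        statistic=stat,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )
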