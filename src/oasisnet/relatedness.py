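"""Maximum-likelihood pairwise relatedness from diploid microsatellites.

For a pair of non-inbred diploids, the genotypes at a locus are determined by
how many alleles the pair shares identical by descent (IBD): none, one or two,
with probabilities k = (k0, k1, k2) on the 2-simplex.  The likelihood of the
pair's multilocus genotypes is the product over loci of

    k0 * P0 + k1 * P1 + k2 * P2

where Pm is the probability of the observed (ordered) genotype pair given m
alleles IBD, computed from population allele frequencies under Hardy-Weinberg.
Maximizing over the simplex gives k-hat and the relatedness coefficient
r = k1/2 + k2.  This mirrors the classic ML estimator used by programs such as
ML-Relate; no genotyping-error or inbreeding model is included.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "AlleleFrequencies",
    "RelatednessResult",
    "genotypes_from_frame",
    "estimate_allele_freqs",
    "ibd_pair_probs",
    "pair_loglik",
    "ml_pair",
    "ml_relatedness",
    "compare_r_distributions",
]

#: per locus: allele label -> frequency
AlleleFrequencies = dict[str, dict[int, float]]

_TINY = 1e-300


def genotypes_from_frame(gt: pd.DataFrame) -> tuple[list[str], list[str], np.ndarray]:
    """Unpack a genotype frame into (individuals, loci, (n, L, 2) allele array).

    Expects paired columns ``<locus>_a`` / ``<locus>_b``; missing calls NaN
    (coded -1 in the returned integer array).
    """
    loci = sorted(
        {c[:-2] for c in gt.columns if c.endswith("_a")},
        key=lambda s: (len(s), s),
    )
    for locus in loci:
        if f"{locus}_b" not in gt.columns:
            raise ValueError(f"locus {locus}: missing _b column")
    n = len(gt)
    arr = np.full((n, len(loci), 2), -1, dtype=int)
    for li, locus in enumerate(loci):
        a = gt[f"{locus}_a"].to_numpy(dtype=float)
        b = gt[f"{locus}_b"].to_numpy(dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() != n and (np.isnan(a) != np.isnan(b)).any():
            raise ValueError(f"locus {locus}: half-missing genotype")
        arr[ok, li, 0] = a[ok].astype(int)
        arr[ok, li, 1] = b[ok].astype(int)
    return list(gt.index.astype(str)), loci, arr


def estimate_allele_freqs(gt: pd.DataFrame) -> AlleleFrequencies:
    """Sample allele frequencies per locus: counts over 2 x (typed individuals)."""
    _, loci, arr = genotypes_from_frame(gt)
    freqs: AlleleFrequencies = {}
    for li, locus in enumerate(loci):
        alleles = arr[:, li, :].ravel()
        alleles = alleles[alleles >= 0]
        if len(alleles) < 4:  # two diploid individuals
            raise ValueError(f"locus {locus}: fewer than 2 typed individuals")
        labels, counts = np.unique(alleles, return_counts=True)
        total = counts.sum()
        freqs[locus] = {int(a): c / total for a, c in zip(labels, counts)}
    return freqs


def ibd_pair_probs(ga: tuple[int, int], gb: tuple[int, int], p: dict[int, float]) -> tuple[float, float, float]:
    """(P0, P1, P2): joint probability of the ordered genotype pair given 0/1/2
    alleles IBD, under HWE at frequencies ``p``.

    P0 is the product of the two HWE genotype probabilities.  P1 sums, over
    the candidate shared allele s, the chance s is the IBD copy in each
    genotype times the frequency of each genotype's non-IBD allele.  P2 is the
    HWE probability of the common genotype when the two genotypes coincide.
    """
    for allele in (*ga, *gb):
        if allele not in p:
            raise ValueError(f"allele {allele} absent from frequency table")

    def hwe(g: tuple[int, int]) -> float:
        i, j = g
        return p[i] ** 2 if i == j else 2.0 * p[i] * p[j]

    p0 = hwe(ga) * hwe(gb)
    sa, sb = frozenset(ga), frozenset(gb)
    p2 = hwe(ga) if (sa == sb and sorted(ga) == sorted(gb)) else 0.0
    p1 = 0.0
    for s in sa & sb:
        w = 1.0 if ga[0] == ga[1] else 0.5  # share of ga's alleles equal to s
        other_b = gb[0] if gb[1] == s else gb[1]
        # if gb is s-homozygous, other_b is s itself
        p1 += hwe(ga) * w * p[other_b]
    return p0, p1, p2


def _pair_prob_matrix(
    ga: np.ndarray, gb: np.ndarray, loci: list[str], freqs: AlleleFrequencies
) -> np.ndarray:
    """(L_typed, 3) array of per-locus (P0, P1, P2); loci missing in either
    genotype are skipped."""
    rows = []
    for li, locus in enumerate(loci):
        if ga[li, 0] < 0 or gb[li, 0] < 0:
            continue
        rows.append(ibd_pair_probs(tuple(ga[li]), tuple(gb[li]), freqs[locus]))
    return np.array(rows).reshape(-1, 3)


def _loglik_from_probs(probs: np.ndarray, k: np.ndarray) -> float:
    v = probs @ k
    if (v <= 0).any():
        return -np.inf
    return float(np.sum(np.log(v)))


def pair_loglik(
    genotype_a,
    genotype_b,
    freqs: AlleleFrequencies,
    k: tuple[float, float, float],
    loci: list[str] | None = None,
) -> float:
    """Multilocus log-likelihood of a genotype pair at IBD coefficients k.

    ``genotype_a``/``genotype_b`` are (L, 2) allele arrays (missing = -1);
    ``loci`` defaults to the frequency table's key order.
    """
    k_arr = np.asarray(k, dtype=float)
    if k_arr.shape != (3,) or (k_arr < -1e-12).any() or abs(k_arr.sum() - 1.0) > 1e-9:
        raise ValueError("k must lie on the 2-simplex")
    loci = list(freqs) if loci is None else loci
    ga = np.asarray(genotype_a, dtype=int).reshape(len(loci), 2)
    gb = np.asarray(genotype_b, dtype=int).reshape(len(loci), 2)
    probs = _pair_prob_matrix(ga, gb, loci, freqs)
    return _loglik_from_probs(probs, k_arr)


def _simplex_grid(step: float = 0.02) -> np.ndarray:
    m = int(round(1.0 / step))
    pts = []
    for i in range(m + 1):
        for j in range(m + 1 - i):
            pts.append((i * step, j * step, 1.0 - i * step - j * step))
    return np.asarray(pts)


_GRID = _simplex_grid(0.02)


def ml_pair(probs: np.ndarray, tol: float = 1e-9) -> tuple[float, float, float, float]:
    """Maximize the pair likelihood over the IBD simplex.

    Coarse 0.02-step grid search followed by SLSQP refinement.  ``probs`` is
    the (L, 3) per-locus probability array.  Returns (k0, k1, k2, r).
    """
    if len(probs) == 0:
        return (np.nan, np.nan, np.nan, np.nan)
    vals = probs @ _GRID.T  # (L, G)
    with np.errstate(divide="ignore"):
        ll = np.where(vals > 0, np.log(np.maximum(vals, _TINY)), -np.inf).sum(axis=0)
    k0_grid = _GRID[int(np.argmax(ll))]

    def neg_ll(k12: np.ndarray) -> float:
        k = np.array([1.0 - k12.sum(), k12[0], k12[1]])
        v = probs @ k
        return float(-np.sum(np.log(np.maximum(v, _TINY))))

    res = optimize.minimize(
        neg_ll,
        x0=k0_grid[1:],
        method="SLSQP",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum()}],
        options={"ftol": tol, "maxiter": 200},
    )
    cand = res.x if (res.success and neg_ll(res.x) <= neg_ll(k0_grid[1:])) else k0_grid[1:]
    k1, k2 = float(np.clip(cand[0], 0, 1)), float(np.clip(cand[1], 0, 1))
    if k1 + k2 > 1.0:
        s = k1 + k2
        k1, k2 = k1 / s, k2 / s
    k0 = 1.0 - k1 - k2
    return k0, k1, k2, k1 / 2.0 + k2


@dataclass(frozen=True)
class RelatednessResult:
    """Pairwise ML relatedness over a fixed individual ordering."""

    individuals: list[str]
    pairs: pd.DataFrame  # id_a, id_b, k0, k1, k2, r
    matrix: pd.DataFrame  # square, symmetric, NaN diagonal

    def to_csv(self, pair_path: str | Path, matrix_path: str | Path | None = None) -> None:
        self.pairs.to_csv(pair_path, index=False)
        if matrix_path is not None:
            self.matrix.to_csv(matrix_path)


def ml_relatedness(gt: pd.DataFrame, freqs: AlleleFrequencies | None = None) -> RelatednessResult:
    """ML relatedness for every pair in a genotype table.

    Frequencies default to the sample estimate from the full table (focal pair
    included).  Pairs sharing zero typed loci get NaN.  Deterministic.
    """
    ids, loci, arr = genotypes_from_frame(gt)
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals")
    if freqs is None:
        freqs = estimate_allele_freqs(gt)
    n = len(ids)
    mat = np.full((n, n), np.nan)
    rows = []
    for i, j in itertools.combinations(range(n), 2):
        probs = _pair_prob_matrix(arr[i], arr[j], loci, freqs)
        k0, k1, k2, r = ml_pair(probs)
        rows.append((ids[i], ids[j], k0, k1, k2, r))
        mat[i, j] = mat[j, i] = r
    pairs = pd.DataFrame(rows, columns=["id_a", "id_b", "k0", "k1", "k2", "r"])
    matrix = pd.DataFrame(mat, index=ids, columns=ids)
    return RelatednessResult(individuals=ids, pairs=pairs, matrix=matrix)


def _within_group_values(matrix: pd.DataFrame, members: list[str]) -> np.ndarray:
    sub = matrix.loc[members, members].to_numpy()
    iu = np.triu_indices(len(members), k=1)
    v = sub[iu]
    return v[~np.isnan(v)]


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov D: sup |ECDF_a - ECDF_b|."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    ca = np.searchsorted(a, grid, side="right") / len(a)
    cb = np.searchsorted(b, grid, side="right") / len(b)
    return float(np.abs(ca - cb).max())


def compare_r_distributions(
    rel: RelatednessResult | pd.DataFrame,
    season_labels: pd.Series,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Two-sample KS comparison of within-season relatedness distributions.

    The observed statistic is the KS D between the two sets of within-season
    pairwise r values.  The null permutes individuals' season labels (a
    node-based permutation: dyadic values stay attached to individuals) and
    recomputes D; p = (#{D* >= D} + 1) / (n_perm + 1).
    """
    matrix = rel.matrix if isinstance(rel, RelatednessResult) else rel
    rng = np.random.default_rng(rng)
    labels = season_labels.reindex(matrix.index)
    groups = labels.dropna().unique()
    if len(groups) != 2:
        raise ValueError("need exactly 2 season groups")
    ids = list(labels.dropna().index)
    lab = labels.dropna().to_numpy()
    ga = [i for i, l in zip(ids, lab) if l == groups[0]]
    gb = [i for i, l in zip(ids, lab) if l == groups[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each season needs >= 2 individuals")
    va, vb = _within_group_values(matrix, ga), _within_group_values(matrix, gb)
    d_obs = ks_statistic(va, vb)
    count = 0
    # permute individuals over the matrix index positions once, then slice
    sub = matrix.loc[ids, ids].to_numpy()
    n_all = len(ids)
    n_a = len(ga)
    iu = np.triu_indices(n_a, k=1)
    iu_b = np.triu_indices(n_all - n_a, k=1)
    for _ in range(n_perm):
        perm = rng.permutation(n_all)
        ma = sub[np.ix_(perm[:n_a], perm[:n_a])][iu]
        mb = sub[np.ix_(perm[n_a:], perm[n_a:])][iu_b]
        d_star = ks_statistic(ma[~np.isnan(ma)], mb[~np.isnan(mb)])
        if d_star >= d_obs - 1e-12:
            count += 1
    return {
        "statistic": d_obs,
        "p": (count + 1) / (n_perm + 1),
        "n_perm": n_perm,
        "groups": {str(groups[0]): len(ga), str(groups[1]): len(gb)},
    }
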