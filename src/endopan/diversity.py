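"""Alpha/beta diversity, ordination, PERMANOVA and group tests.

All statistics are computed from their defining formulas:

* Shannon H = -sum p_i ln p_i (natural log), Simpson D = 1 - sum p_i^2,
  bias-corrected Chao1, and the abundance-based coverage estimator (ACE)
  with rare-count cutoff 10;
* rarefaction by random subsampling without replacement, with the exact
  hypergeometric expectation available as a closed form;
* Bray-Curtis dissimilarity, classical PCoA (double-centred eigendecomposition)
  and non-metric MDS minimizing Kruskal stress-1 with isotonic regression;
* one-way PERMANOVA with the pseudo-F of distance sums of squares and a
  label-permutation p-value (exhaustive when feasible);
* Welch's two-sample t-test (Satterthwaite df) and one-way ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression

__all__ = [
    "alpha_diversity",
    "alpha_diversity_table",
    "rarefaction_curve",
    "rarefaction_expected",
    "bray_curtis",
    "pcoa",
    "nmds",
    "permanova",
    "group_tests",
    "DistanceMatrix",
]

ACE_RARE_CUTOFF = 10


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with sample labels."""

    values: np.ndarray
    labels: list

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric within 1e-12")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = d

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _clean_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if x.sum() == 0:
        raise ValueError("counts must not be all zero")
    return x


def _shannon(x: np.ndarray) -> float:
    p = x[x > 0] / x.sum()
    return float(-(p * np.log(p)).sum())


def _simpson(x: np.ndarray) -> float:
    p = x[x > 0] / x.sum()
    return float(1.0 - (p ** 2).sum())


def _chao1(x: np.ndarray) -> float:
    obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _ace(x: np.ndarray, rare_cutoff: int = ACE_RARE_CUTOFF) -> float:
    x = x[x > 0]
    rare = x[x <= rare_cutoff]
    abund = x[x > rare_cutoff]
    s_rare = len(rare)
    s_abund = len(abund)
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        # all rare taxa are singletons; coverage is undefined, fall back to Chao1
        return _chao1(x)
    fk = np.array([(rare == k).sum() for k in range(1, rare_cutoff + 1)])
    ks = np.arange(1, rare_cutoff + 1)
    gamma = max(
        (s_rare / c_ace) * (ks * (ks - 1) * fk).sum() / (n_rare * (n_rare - 1)) - 1.0,
        0.0,
    ) if n_rare > 1 else 0.0
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma)


_INDEX_FUNCS = {
    "observed": lambda x: float((x > 0).sum()),
    "shannon": _shannon,
    "simpson": _simpson,
    "chao1": _chao1,
    "ace": _ace,
}


def alpha_diversity(counts, index: str) -> float:
    """One alpha diversity index of a non-negative count vector.

    ``index`` is one of observed, shannon, simpson, chao1, ace. Shannon
    uses the natural logarithm; Chao1 is bias-corrected; ACE uses the rare
    cutoff of 10.
    """
    x = _clean_counts(counts)
    try:
        fn = _INDEX_FUNCS[index.lower()]
    except KeyError:
        raise ValueError(f"unknown index {index!r}; choose from {sorted(_INDEX_FUNCS)}")
    return fn(x)


def alpha_diversity_table(table: pd.DataFrame,
                          indices=("observed", "shannon", "simpson", "chao1", "ace")
                          ) -> pd.DataFrame:
    """Per-sample alpha diversity for a taxon x sample count table."""
    rows = {}
    for sample in table.columns:
        counts = table[sample].to_numpy()
        rows[sample] = {ix: alpha_diversity(counts, ix) for ix in indices}
    return pd.DataFrame(rows).T


def rarefaction_expected(counts, depth: int) -> float:
    """Closed-form expected richness of a subsample without replacement.

    E[S_d] = sum_i [1 - C(N - n_i, d) / C(N, d)] (hypergeometric form).
    """
    x = _clean_counts(counts)
    n_total = int(x.sum())
    if depth > n_total:
        raise ValueError(f"depth {depth} exceeds total count {n_total}")
    total = 0.0
    for n_i in x[x > 0]:
        num = math.comb(int(n_total - n_i), depth) if n_total - n_i >= depth else 0
        total += 1.0 - num / math.comb(n_total, depth)
    return total


def rarefaction_curve(counts, depths, reps: int = 50, seed: int = 0,
                      method: str = "subsample") -> pd.Series:
    """Mean observed richness at each depth.

    ``method='subsample'`` averages over ``reps`` seeded random subsamples
    without replacement; ``method='exact'`` evaluates the hypergeometric
    closed form (reps ignored).
    """
    x = _clean_counts(counts).astype(int)
    n_total = int(x.sum())
    depths = list(depths)
    for d in depths:
        if d > n_total:
            raise ValueError(f"depth {d} exceeds total count {n_total}")
        if d < 1:
            raise ValueError("depths must be >= 1")
    if method == "exact":
        return pd.Series({d: rarefaction_expected(x, d) for d in depths})
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(x)), x)
    out = {}
    for d in depths:
        richness = np.empty(reps)
        for r in range(reps):
            pick = rng.choice(pool, size=d, replace=False)
            richness[r] = len(np.unique(pick))
        out[d] = float(richness.mean())
    return pd.Series(out)


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    d(x, y) = sum |x_i - y_i| / sum (x_i + y_i).
    """
    if table.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    m = table.to_numpy(dtype=float).T  # samples x taxa
    totals = m.sum(axis=1)
    if (totals == 0).any():
        bad = [table.columns[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"sample(s) with zero total: {bad}")
    n = m.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = np.abs(m[i] - m[j]).sum()
            den = (m[i] + m[j]).sum()
            d[i, j] = d[j, i] = num / den
    return DistanceMatrix(values=d, labels=list(table.columns))


def pcoa(dm: DistanceMatrix):
    """Classical principal coordinates analysis.

    Eigendecomposition of B = -1/2 J D^2 J with J the centring matrix.
    Axes are ordered by eigenvalue; all eigenvalues (including negative
    ones) are reported, but only axes with positive eigenvalues carry
    coordinates.

    Returns ``(coordinates, eigenvalues)``: a DataFrame (samples x axes)
    and an ndarray of all eigenvalues in decreasing order.
    """
    d = dm.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals).max() if len(eigvals) else 0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=dm.labels, columns=cols), eigvals


def _stress1(dist_flat: np.ndarray, dhat: np.ndarray) -> float:
    denom = (dist_flat ** 2).sum()
    return math.sqrt(((dist_flat - dhat) ** 2).sum() / denom) if denom > 0 else 0.0


def nmds(dm: DistanceMatrix, k: int = 2, n_starts: int = 20,
         max_iter: int = 300, tol: float = 1e-6, seed: int = 0):
    """Non-metric MDS minimizing Kruskal stress-1.

    Configurations are refined by alternating isotonic regression of the
    embedded distances on the dissimilarity ranks with a Guttman-transform
    update; the best of ``n_starts`` seeded random starts is returned.

    Returns ``(coordinates, stress)``.
    """
    n = dm.n
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} dimensions")
    iu = np.triu_indices(n, 1)
    diss = dm.values[iu]
    if np.allclose(diss, diss[0]):
        raise ValueError("degenerate distance matrix: all dissimilarities equal")
    order = np.argsort(diss, kind="mergesort")
    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, np.inf
    for _ in range(n_starts):
        x = rng.normal(size=(n, k))
        prev = np.inf
        for _ in range(max_iter):
            diff = x[:, None, :] - x[None, :, :]
            dmat = np.sqrt((diff ** 2).sum(axis=2))
            dflat = dmat[iu]
            fitted = np.empty_like(dflat)
            fitted[order] = isotonic_regression(dflat[order]).x
            stress = _stress1(dflat, fitted)
            if prev - stress < tol:
                break
            prev = stress
            # Guttman transform toward the fitted (monotone) distances
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.zeros_like(dmat)
                full_fit = np.zeros_like(dmat)
                full_fit[iu] = fitted
                full_fit += full_fit.T
                mask = dmat > 0
                ratio[mask] = full_fit[mask] / dmat[mask]
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = (b @ x) / n
            x -= x.mean(axis=0)
        if stress < best_stress:
            best_stress = stress
            best_coords = x.copy()
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return pd.DataFrame(best_coords, index=dm.labels, columns=cols), float(best_stress)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(codes)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0:
        return math.inf if ss_among > 0 else 0.0
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0,
              exhaustive: str = "auto"):
    """One-way PERMANOVA on a distance matrix.

    pseudo-F = ((SS_total - SS_within)/(a-1)) / (SS_within/(N-a)) with the
    distance-based sums of squares; p from label permutations,
    ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)``. When
    ``exhaustive='auto'`` and the total number of label arrangements is
    <= 10,000 (or ``exhaustive='always'``), all arrangements are
    enumerated and p is the exact proportion with F >= F_obs.

    Returns ``(pseudo_F, p_value)``.
    """
    labels = pd.Series(list(groups))
    if len(labels) != dm.n:
        raise ValueError("groups length must match distance matrix size")
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    sizes = labels.value_counts()
    if (sizes < 1).any():
        raise ValueError("every group needs >= 1 member")
    codes = labels.map({u: i for i, u in enumerate(uniq)}).to_numpy()
    d2 = dm.values ** 2
    a = len(uniq)
    f_obs = _pseudo_f(d2, codes, a)

    n = len(codes)
    n_arrangements = math.factorial(n)
    for s in sizes:
        n_arrangements //= math.factorial(int(s))
    use_exhaustive = exhaustive == "always" or (
        exhaustive == "auto" and n_arrangements <= 10_000)
    if use_exhaustive:
        from sympy.utilities.iterables import multiset_permutations

        ge = 0
        total = 0
        for arrangement in multiset_permutations(list(codes)):
            f = _pseudo_f(d2, np.array(arrangement), a)
            ge += f >= f_obs - 1e-12
            total += 1
        return f_obs, ge / total
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        f = _pseudo_f(d2, rng.permutation(codes), a)
        ge += f >= f_obs - 1e-12
    return f_obs, (1 + ge) / (n_perm + 1)


def group_tests(values, groups, kind: str = "welch_t"):
    """Welch's two-sample t-test or one-way ANOVA from formulas.

    Returns ``(statistic, p_value)`` with two-sided p for Welch and the
    upper-tail F p for ANOVA (scipy distributions supply the tails).
    """
    df = pd.DataFrame({"value": list(values), "group": list(groups)})
    parts = [g["value"].to_numpy(dtype=float) for _, g in df.groupby("group", sort=True)]
    if kind == "welch_t":
        if len(parts) != 2:
            raise ValueError("welch_t requires exactly 2 groups")
        x, y = parts
        if len(x) < 2 or len(y) < 2:
            raise ValueError("welch_t requires >= 2 values per group")
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        nx, ny = len(x), len(y)
        se2 = vx / nx + vy / ny
        if se2 == 0:
            return 0.0, 1.0
        t = (x.mean() - y.mean()) / math.sqrt(se2)
        dof = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p = 2.0 * stats.t.sf(abs(t), dof)
        return float(t), float(p)
    if kind == "anova":
        if len(parts) < 2 or any(len(p_) < 1 for p_ in parts):
            raise ValueError("anova requires >= 2 non-empty groups")
        all_vals = np.concatenate(parts)
        grand = all_vals.mean()
        ss_between = sum(len(p_) * (p_.mean() - grand) ** 2 for p_ in parts)
        ss_within = sum(((p_ - p_.mean()) ** 2).sum() for p_ in parts)
        df_b = len(parts) - 1
        df_w = len(all_vals) - len(parts)
        if df_w <= 0:
            raise ValueError("anova requires residual degrees of freedom")
        if ss_within == 0:
            return (0.0, 1.0) if ss_between == 0 else (math.inf, 0.0)
        f = (ss_between / df_b) / (ss_within / df_w)
        p = stats.f.sf(f, df_b, df_w)
        return float(f), float(p)
    raise ValueError(f"unknown test kind {kind!r}")
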