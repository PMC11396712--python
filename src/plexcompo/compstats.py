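"""Compositional inference: Bray-Curtis distances, NMDS ordination,
PERMANOVA (overall and pairwise), SIMPER decomposition, CLR-ANOVA and
Fisher exact tests.

These are the community-ecology style analyses applied to per-sample
cell-type compositions.  The permutation machinery is written here from
first principles (vectorized over permutations); permutation p-values use
the +1 correction p = (#{stat_perm >= stat_obs} + 1) / (n_perm + 1), so
p >= 1/(n_perm+1) and is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.isotonic import IsotonicRegression

_REL_TOL = 1e-9  # ">= observed" comparisons allow this relative slack


# ---------------------------------------------------------------------------
# distances

def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b), in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("compositions must share one category set")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("compositions must be nonnegative")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("both compositions are all-zero")
    return float(np.abs(a - b).sum() / denom)


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with sample labels."""

    data: np.ndarray
    ids: tuple[str, ...]
    method: str = "braycurtis"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("data must be n x n matching ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")

    def __len__(self):
        return len(self.ids)

    def subset(self, keep) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in keep]
        return DistanceMatrix(
            self.data[np.ix_(idx, idx)], tuple(self.ids[i] for i in idx), self.method
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))


def bc_distance_matrix(comp: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis over the category columns of a composition frame."""
    cats = [c for c in comp.columns if c not in ("subtype", "n_cells")]
    x = comp[cats].to_numpy(dtype=float)
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(d, tuple(str(i) for i in comp.index))


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermTestResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int
    method: str


def _group_info(groups):
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    return labels, codes


def _pseudo_f(d2: np.ndarray, codes_batch: np.ndarray, n_groups: int) -> np.ndarray:
    """Pseudo-F for a batch of label vectors (B x n) against squared distances.

    SS_total = (1/n) sum_{i<j} d2_ij; SS_within = sum_g (1/n_g) sum_{i<j in g} d2_ij.
    """
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = np.zeros(codes_batch.shape[0])
    for g in range(n_groups):
        mask = (codes_batch == g).astype(float)  # B x n
        n_g = mask.sum(axis=1)
        quad = np.einsum("bi,ij,bj->b", mask, d2, mask)  # = 2 * sum_{i<j in g}
        ss_w += quad / (2.0 * n_g)
    ss_a = ss_total - ss_w
    df_a = n_groups - 1
    df_w = n - n_groups
    with np.errstate(divide="ignore"):  # ss_w = 0 -> F = inf (perfect separation)
        return (ss_a / df_a) / (ss_w / df_w)


def permanova(
    D: DistanceMatrix, groups, n_perm: int = 9999, seed: int = 0
) -> PermTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F of the observed grouping is compared against ``n_perm``
    seeded random relabelings; requires >= 2 groups with >= 2 samples each.
    """
    labels, codes = _group_info(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = labels[counts.argmin()]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    if len(codes) != len(D):
        raise ValueError("groups must align with the distance matrix")
    d2 = D.data**2
    f_obs = float(_pseudo_f(d2, codes[None, :], len(labels))[0])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    f_perm = _pseudo_f(d2, perms, len(labels))
    tol = _REL_TOL * max(1.0, abs(f_obs))
    count = int((f_perm >= f_obs - tol).sum())
    p = (count + 1) / (n_perm + 1)
    return PermTestResult(f_obs, p, n_perm, seed, "permanova")


def permanova_pairwise(
    D: DistanceMatrix, groups, n_perm: int = 9999, seed: int = 0
) -> pd.DataFrame:
    """PERMANOVA restricted to every pair of groups (p-values unadjusted)."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    rows = []
    child = iter(np.random.SeedSequence(seed).generate_state(
        len(labels) * (len(labels) - 1) // 2))
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            keep = [s for s, g in zip(D.ids, groups) if g in (a, b)]
            sub = D.subset(keep)
            sub_groups = [g for g in groups if g in (a, b)]
            pair_seed = int(next(child) % (2**31))
            res = permanova(sub, sub_groups, n_perm=n_perm, seed=pair_seed)
            rows.append(
                {"group_a": a, "group_b": b, "statistic": res.statistic,
                 "p_value": res.p_value, "n_perm": n_perm, "seed": pair_seed}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SIMPER

def _simper_contributions(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Per-category mean contribution over all cross-group sample pairs.

    contribution_i = mean over pairs (a, b) of |x_ai - x_bi| / sum_k (x_ak + x_bk);
    contributions sum to the mean between-group Bray-Curtis dissimilarity.
    """
    diff = np.abs(xa[:, None, :] - xb[None, :, :])
    den = (xa[:, None, :] + xb[None, :, :]).sum(axis=2, keepdims=True)
    return (diff / den).mean(axis=(0, 1))


def simper(
    comp: pd.DataFrame,
    groups,
    group_a,
    group_b,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """SIMPER decomposition of between-group Bray-Curtis dissimilarity.

    Returns one row per cell type: mean contribution, percent of the total
    dissimilarity, and a permutation p-value (proportion of label
    permutations whose contribution is >= the observed one, +1 corrected).
    Rows are sorted by contribution, largest first.
    """
    groups = np.asarray(groups)
    cats = [c for c in comp.columns if c not in ("subtype", "n_cells")]
    x = comp[cats].to_numpy(dtype=float)
    in_a = groups == group_a
    in_b = groups == group_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    obs = _simper_contributions(x[in_a], x[in_b])

    pool = np.concatenate([np.where(in_a)[0], np.where(in_b)[0]])
    n_a = int(in_a.sum())
    rng = np.random.default_rng(seed)
    count = np.zeros(len(cats))
    tol = _REL_TOL * np.maximum(1.0, np.abs(obs))
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        c = _simper_contributions(x[perm[:n_a]], x[perm[n_a:]])
        count += c >= obs - tol
    p = (count + 1) / (n_perm + 1)
    out = pd.DataFrame(
        {
            "cell_type": cats,
            "contribution": obs,
            "percent": 100.0 * obs / obs.sum(),
            "p_value": p,
            "n_perm": n_perm,
            "seed": seed,
        }
    ).sort_values("contribution", ascending=False, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# NMDS

@dataclass
class OrdinationResult:
    coords: np.ndarray
    stress: float
    n_iter: int
    converged: bool
    seed: int
    ids: tuple[str, ...] = ()
    stress_history: tuple[float, ...] = ()


def _cmdscale(d: np.ndarray, k: int) -> np.ndarray:
    """Classical (Torgerson) metric scaling, top-k axes."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _pair_dists(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def nmds(
    D: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Alternates a monotone (pool-adjacent-violators) regression of the
    configuration distances on the dissimilarity ranks with a Guttman
    (SMACOF) configuration update; ties in the dissimilarities are treated
    as "primary" (tied blocks are free to untie).  Restart 0 starts from
    classical metric scaling; later restarts add seeded jitter.  The best
    restart by final stress is returned; identical seeds give identical
    coordinates.
    """
    n = len(D)
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} samples")
    iu = np.triu_indices(n, 1)
    delta = D.data[iu]
    x0 = _cmdscale(D.data, k)
    scale0 = max(float(np.sqrt((x0**2).mean())), 1e-6)
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression()
    grid = np.arange(len(delta), dtype=float)

    best = None
    for restart in range(n_restarts):
        x = x0.copy() if restart == 0 else x0 + rng.normal(0, 0.25 * scale0, x0.shape)
        stress_prev = np.inf
        stress = np.inf
        converged = False
        history = []
        for it in range(1, max_iter + 1):
            dmat = _pair_dists(x)
            d = dmat[iu]
            order = np.lexsort((d, delta))  # primary tie treatment
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(grid, d[order])
            ssq_d = (d**2).sum()
            if ssq_d <= 0:
                stress = 0.0
                history.append(stress)
                converged = True
                break
            dhat *= np.sqrt(ssq_d / max((dhat**2).sum(), 1e-300))
            stress = float(np.sqrt(((d - dhat) ** 2).sum() / ssq_d))
            history.append(stress)
            if stress_prev - stress < tol:
                converged = stress_prev - stress > -tol or stress < 1e-8
                break
            stress_prev = stress
            # Guttman transform with disparities dhat
            ratio = np.zeros_like(dmat)
            dm = np.where(dmat > 1e-12, dmat, 1.0)
            ratio[iu] = dhat / dm[iu]
            ratio = ratio + ratio.T
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = b @ x / n
            x -= x.mean(axis=0)
        if best is None or stress < best.stress:
            best = OrdinationResult(x, stress, it, converged, seed, D.ids,
                                    tuple(history))
    return best


# ---------------------------------------------------------------------------
# CLR + ANOVA

def clr(x, delta: float | None = None) -> np.ndarray:
    """Centered log-ratio transform ln(x_i / g(x)); output sums to 0.

    Zeros are handled by multiplicative replacement: each zero becomes
    ``delta`` (default: half the smallest nonzero proportion) and nonzero
    proportions are scaled down to keep the row summing to 1.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("composition must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero composition")
    p = x / total
    zero = p == 0
    if zero.any():
        if delta is None:
            delta = 0.5 * p[~zero].min()
        # keep the scaled nonzero part positive even with many zeros
        delta = min(delta, 0.5 / zero.sum())
        p = np.where(zero, delta, p * (1.0 - zero.sum() * delta))
    logp = np.log(p)
    return logp - logp.mean()


def clr_matrix(comp: pd.DataFrame) -> pd.DataFrame:
    """Row-wise CLR of a composition frame; one shared zero-replacement
    delta (half the smallest nonzero proportion in the whole matrix)."""
    cats = [c for c in comp.columns if c not in ("subtype", "n_cells")]
    x = comp[cats].to_numpy(dtype=float)
    p = x / x.sum(axis=1, keepdims=True)
    nonzero = p[p > 0]
    delta = 0.5 * nonzero.min() if len(nonzero) < p.size else None
    out = np.vstack([clr(row, delta=delta) for row in p])
    return pd.DataFrame(out, index=comp.index, columns=cats)


def clr_anova(comp: pd.DataFrame, groups) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per CLR-transformed cell-type column.

    Zero within-group variance with unequal group means is reported with
    the F -> inf convention (p = 0) and flagged.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    z = clr_matrix(comp)
    rows = []
    for cat in z.columns:
        arrays = [z.loc[groups == lab, cat].to_numpy() for lab in labels]
        within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
        means = np.array([a.mean() for a in arrays])
        flagged = False
        if within < 1e-300:
            flagged = True
            if np.ptp(means) > 0:
                f, p = np.inf, 0.0
            else:
                f, p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*arrays)
        rows.append({"cell_type": cat, "F": float(f), "p_value": float(p),
                     "flagged": flagged})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fisher exact

def _table_logprob(t: np.ndarray) -> float:
    """Log hypergeometric probability of an r x c table given its margins."""
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = t.sum()
    return float(
        special.gammaln(r + 1).sum() + special.gammaln(c + 1).sum()
        - special.gammaln(n + 1) - special.gammaln(t + 1).sum()
    )


def fisher_exact(table, n_mc: int = 100_000, seed: int = 0) -> float:
    """Two-sided Fisher exact test p-value for an r x c count table.

    2 x 2 tables are exact (point-probability method over the
    hypergeometric support).  Larger tables use seeded Monte-Carlo over
    tables with the observed margins: p = (#{P(T) <= P(obs)} + 1)/(n_mc + 1).
    """
    t = np.asarray(table)
    if t.ndim != 2 or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = np.asarray(table, dtype=float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("table must hold nonnegative integers")
        t = t.astype(np.int64)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    if t.shape == (2, 2):
        a = t[0, 0]
        r1 = t[0].sum()
        c1 = t[:, 0].sum()
        n = t.sum()
        kmin = max(0, r1 + c1 - n)
        kmax = min(r1, c1)
        support = np.arange(kmin, kmax + 1)
        pmf = stats.hypergeom.pmf(support, n, c1, r1)
        p_obs = pmf[a - kmin]
        return float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())

    rng = np.random.default_rng(seed)
    logp_obs = _table_logprob(t)
    col_margin = t.sum(axis=0)
    row_margin = t.sum(axis=1)
    count = 0
    if t.shape[0] == 2:
        draws = rng.multivariate_hypergeometric(
            col_margin, int(row_margin[0]), size=n_mc, method="marginals"
        )
        g1 = special.gammaln(draws + 1).sum(axis=1)
        g2 = special.gammaln(col_margin[None, :] - draws + 1).sum(axis=1)
        const = (
            special.gammaln(row_margin + 1).sum()
            + special.gammaln(col_margin + 1).sum()
            - special.gammaln(t.sum() + 1)
        )
        logp = const - g1 - g2
        count = int((logp <= logp_obs + 1e-7).sum())
    else:
        for _ in range(n_mc):
            remaining = col_margin.copy()
            sim = np.empty_like(t)
            for i in range(t.shape[0] - 1):
                sim[i] = rng.multivariate_hypergeometric(remaining, int(row_margin[i]))
                remaining -= sim[i]
            sim[-1] = remaining
            if _table_logprob(sim) <= logp_obs + 1e-7:
                count += 1
    return (count + 1) / (n_mc + 1)
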