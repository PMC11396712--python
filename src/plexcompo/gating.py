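"""Marker gating: two-component mixture fits and composite phenotypes.

Each marker's per-cell mean intensities form a bimodal histogram (unstained
vs stained cells).  A two-component mixture (normal, log-normal, or Weibull)
is fitted by EM; a cell is called positive for the marker when its posterior
probability of belonging to the higher-mean ("positive") component exceeds
0.95 (strictly).  Families are compared by BIC.  Composite phenotypes are
then assigned from the per-marker calls via the panel's priority rules;
cells negative for every marker are "other".

The hyperbolic-arcsine transform is applied automatically when it yields a
better fit than the raw scale (compared by BIC mapped back to the original
intensity scale through the transform's Jacobian) or when no family can be
fitted to the raw values at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.cluster import KMeans

from ._families import FAMILIES, dist_mean, logpdf
from .panels import OTHER, PanelSpec

_MIN_N = 50
_N_PARAMS = 5  # 2x(location, scale) + 1 free weight


class MixtureFitError(RuntimeError):
    """No mixture family could be fitted to the values."""


@dataclass(frozen=True)
class MixtureFit:
    """A fitted two-component mixture for one marker.

    Components are ordered by distribution mean: index 0 is the negative
    (unstained) component, index 1 the positive one.  ``transformed`` marks
    fits performed on asinh-transformed intensities (with ``cofactor``).
    """

    family: str
    weights: tuple[float, float]
    params: tuple[tuple[float, float], tuple[float, float]]
    loglik: float
    bic: float
    n: int
    converged: bool
    n_iter: int
    transformed: bool = False
    cofactor: float = 1.0
    low_separation: bool = False
    loglik_history: tuple = ()

    @property
    def component_means(self) -> tuple[float, float]:
        return (dist_mean(self.family, self.params[0]),
                dist_mean(self.family, self.params[1]))


def asinh_transform(x, cofactor: float = 1.0) -> np.ndarray:
    """asinh(x / cofactor): monotone, linear near 0, log-like in the tail."""
    if not cofactor > 0:
        raise ValueError("cofactor must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        warnings.warn("negative intensities passed to asinh_transform")
    return np.arcsinh(x / cofactor)


def _weighted_weibull_mle(x, w, logx):
    """Weighted Weibull MLE (numeric shape solve); returns (shape, scale)."""
    wsum = w.sum()
    wl = (w * logx).sum() / wsum

    def score(k):
        xk = np.exp(k * logx)
        s = (w * xk).sum()
        return (w * xk * logx).sum() / s - 1.0 / k - wl

    lo, hi = 1e-2, 1.0
    while score(hi) < 0 and hi < 1e3:
        hi *= 2.0
    while score(lo) > 0 and lo > 1e-6:
        lo /= 2.0
    k = optimize.brentq(score, lo, hi, xtol=1e-10)
    lam = ((w * np.exp(k * logx)).sum() / wsum) ** (1.0 / k)
    return k, lam


def _init_labels(x, restart):
    """Deterministic split into two starting clusters.

    Restart 0 refines a percentile seed with k-means (balanced modes);
    restarts 1 and 2 are hard splits at the 90th / 99th percentile so that
    rare positive populations (~1% of cells) can seed their own component,
    which plain k-means never isolates; further restarts cycle k-means with
    other percentile seeds.
    """
    if restart in (1, 2):
        cut = np.percentile(x, 90 if restart == 1 else 99)
        labels = (x > cut).astype(int)
        if 0 < labels.sum() < len(x):
            return labels
    q_lo, q_hi = [(25, 75), (10, 60), (40, 90)][restart % 3]
    centers = np.percentile(x, [q_lo, q_hi]).reshape(-1, 1)
    if centers[0, 0] == centers[1, 0]:
        centers[1, 0] += 1e-6
    km = KMeans(n_clusters=2, init=centers, n_init=1, max_iter=50)
    return km.fit_predict(x.reshape(-1, 1))


def _init_params(x, family, restart):
    labels = _init_labels(x, restart)
    params, weights = [], []
    for lab in (0, 1):
        xs = x[labels == lab]
        if len(xs) < 2:
            xs = x
        if family == "normal":
            params.append((float(xs.mean()), float(max(xs.std(), 1e-3))))
        elif family == "lognormal":
            lx = np.log(xs)
            params.append((float(lx.mean()), float(max(lx.std(), 1e-3))))
        else:
            w = np.ones(len(xs))
            params.append(_weighted_weibull_mle(xs, w, np.log(xs)))
        weights.append(max(len(xs) / len(x), 1e-3))
    w = np.array(weights) / sum(weights)
    return list(w), params


def _em_once(x, family, init_w, init_params, max_iter, tol):
    n = len(x)
    w = np.asarray(init_w, dtype=float)
    params = [tuple(p) for p in init_params]
    logx = np.log(x) if family in ("lognormal", "weibull") else None
    loglik_prev = -np.inf
    loglik = -np.inf
    n_iter = 0
    converged = False
    history = []
    for n_iter in range(1, max_iter + 1):
        lp = np.stack([np.log(w[j]) + logpdf(family, params[j], x) for j in (0, 1)])
        tot = special.logsumexp(lp, axis=0)
        loglik = float(tot.sum())
        history.append(loglik)
        resp = np.exp(lp - tot)  # 2 x n responsibilities
        if loglik - loglik_prev < tol and n_iter > 1:
            converged = True
            break
        loglik_prev = loglik
        # M-step
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-8):
            raise MixtureFitError("component collapsed to zero weight")
        w = nk / n
        new_params = []
        for j in (0, 1):
            r = resp[j]
            if family == "normal":
                mu = float((r * x).sum() / nk[j])
                var = float((r * (x - mu) ** 2).sum() / nk[j])
                if var < 1e-12:
                    raise MixtureFitError("degenerate component (scale -> 0)")
                new_params.append((mu, np.sqrt(var)))
            elif family == "lognormal":
                mu = float((r * logx).sum() / nk[j])
                var = float((r * (logx - mu) ** 2).sum() / nk[j])
                if var < 1e-12:
                    raise MixtureFitError("degenerate component (scale -> 0)")
                new_params.append((mu, np.sqrt(var)))
            else:
                k, lam = _weighted_weibull_mle(x, r, logx)
                if lam < 1e-12:
                    raise MixtureFitError("degenerate component (scale -> 0)")
                new_params.append((k, lam))
        params = new_params
    return w, params, loglik, n_iter, converged, history


def _single_component_loglik(x, family) -> float:
    """Max log-likelihood of one component of ``family`` (MLE)."""
    if family == "normal":
        params = (float(x.mean()), float(max(x.std(), 1e-12)))
    elif family == "lognormal":
        lx = np.log(x)
        params = (float(lx.mean()), float(max(lx.std(), 1e-12)))
    else:
        params = _weighted_weibull_mle(x, np.ones(len(x)), np.log(x))
    return float(logpdf(family, params, x).sum())


def fit_mixture(
    values,
    family: str = "normal",
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 3,
    seed: int = 0,
    transformed: bool = False,
    cofactor: float = 1.0,
) -> MixtureFit:
    """Fit a two-component mixture by EM; best of ``n_restarts`` by loglik.

    The EM log-likelihood is non-decreasing across iterations.  Raises
    :class:`MixtureFitError` when every restart collapses or the family's
    support excludes the data (e.g. nonpositive values for log-normal).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    x = np.asarray(values, dtype=float)
    if len(x) < _MIN_N:
        raise ValueError(f"need at least {_MIN_N} values, got {len(x)}")
    if family in ("lognormal", "weibull") and np.any(x <= 0):
        raise MixtureFitError(f"{family} requires strictly positive values")

    best = None
    last_err = None
    for restart in range(n_restarts):
        try:
            w0, p0 = _init_params(x, family, restart)
            w, params, loglik, n_iter, conv, hist = _em_once(x, family, w0, p0, max_iter, tol)
        except MixtureFitError as err:
            last_err = err
            continue
        if best is None or loglik > best[2]:
            best = (w, params, loglik, n_iter, conv, hist)
    if best is None:
        raise MixtureFitError(f"all {n_restarts} restarts failed: {last_err}")

    w, params, loglik, n_iter, conv, hist = best
    means = [dist_mean(family, p) for p in params]
    order = np.argsort(means)  # negative component first
    w = tuple(float(w[j]) for j in order)
    params = tuple(tuple(map(float, params[j])) for j in order)
    means = sorted(means)
    pooled_sd = float(np.std(x))
    bic = _N_PARAMS * np.log(len(x)) - 2.0 * loglik
    # low separation: components nearly coincide, or two components are not
    # decisively better than one (BIC margin 10) -- the hallmark of a
    # single-population marker
    bic1 = 2.0 * np.log(len(x)) - 2.0 * _single_component_loglik(x, family)
    low_sep = (means[1] - means[0]) < 0.1 * max(pooled_sd, 1e-12) or bic > bic1 - 10.0
    return MixtureFit(
        family=family, weights=w, params=params, loglik=loglik, bic=float(bic),
        n=len(x), converged=conv, n_iter=n_iter, transformed=transformed,
        cofactor=cofactor, low_separation=low_sep, loglik_history=tuple(hist),
    )


def select_model(
    values,
    families=FAMILIES,
    seed: int = 0,
    **fit_kwargs,
) -> MixtureFit:
    """Fit each candidate family and return the minimum-BIC fit.

    Ties (and the fit order) follow normal < lognormal < weibull.  Families
    whose support excludes the data are skipped; if every family fails,
    :class:`MixtureFitError` is raised.
    """
    families = [f for f in FAMILIES if f in set(families)]
    if not families:
        raise ValueError("families must be non-empty")
    best = None
    last_err = None
    for fam in families:
        try:
            fit = fit_mixture(values, family=fam, seed=seed, **fit_kwargs)
        except MixtureFitError as err:
            last_err = err
            continue
        if best is None or fit.bic < best.bic - 1e-12:
            best = fit
    if best is None:
        raise MixtureFitError(f"all families failed: {last_err}")
    return best


def posterior_positive(fit: MixtureFit, x) -> np.ndarray:
    """P(cell belongs to the positive component | intensity x).

    Bayes posterior w+ f+(x) / (w+ f+(x) + w- f-(x)); a density is treated
    as 0 outside its support (both zero -> posterior 0).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if fit.transformed:
        x = asinh_transform(x, fit.cofactor)
    lp_neg = np.log(fit.weights[0]) + logpdf(fit.family, fit.params[0], x)
    lp_pos = np.log(fit.weights[1]) + logpdf(fit.family, fit.params[1], x)
    out = np.zeros(x.shape)
    ok = lp_pos > -np.inf
    both = ok & (lp_neg > -np.inf)
    out[ok & ~both] = 1.0
    d = lp_neg[both] - lp_pos[both]
    out[both] = 1.0 / (1.0 + np.exp(d))
    return out


def call_positive(fit: MixtureFit, x, threshold: float = 0.95) -> np.ndarray:
    """Positive call iff posterior strictly exceeds ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return posterior_positive(fit, x) > threshold


def assign_phenotype(
    calls: dict[str, bool],
    panel: PanelSpec,
    posteriors: dict[str, float] | None = None,
) -> str:
    """Map per-marker calls to a composite phenotype via the panel rules.

    The first rule (lowest priority number) whose required markers are all
    positive wins; among matching rules of equal priority the one whose
    distinguishing marker has the higher posterior wins.  A cell matching
    no rule — in particular one negative for all markers — is "other".
    """
    extra = set(calls) - set(panel.markers)
    if extra:
        raise ValueError(f"markers not on panel {panel.name!r}: {sorted(extra)}")
    missing = set().union(*(r.requires for r in panel.rules)) - set(calls)
    if missing:
        raise ValueError(f"calls missing panel markers: {sorted(missing)}")
    matching = [r for r in panel.rules if all(calls[m] for m in r.requires)]
    if not matching:
        return OTHER
    top = min(r.priority for r in matching)
    tied = [r for r in matching if r.priority == top]
    if len(tied) == 1:
        return tied[0].name
    if posteriors is None:
        return tied[0].name  # fall back to declaration order
    shared = set.intersection(*(set(r.requires) for r in tied))

    def tie_key(rule):
        own = [m for m in rule.requires if m not in shared] or list(rule.requires)
        return max(posteriors.get(m, 0.0) for m in own)

    return max(tied, key=tie_key).name


def _assign_phenotypes_bulk(calls: np.ndarray, posts: np.ndarray, panel: PanelSpec):
    """Vectorized assign_phenotype over an n x markers call/posterior grid."""
    from itertools import groupby

    n = calls.shape[0]
    midx = {m: j for j, m in enumerate(panel.markers)}
    result = np.full(n, OTHER, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    rules = sorted(panel.rules, key=lambda r: r.priority)
    for _, grp in groupby(rules, key=lambda r: r.priority):
        grp = list(grp)
        matches = np.stack(
            [calls[:, [midx[m] for m in r.requires]].all(axis=1) for r in grp]
        )
        hit = matches.any(axis=0) & unassigned
        if len(grp) == 1:
            result[hit] = grp[0].name
        else:
            shared = set.intersection(*(set(r.requires) for r in grp))
            scores = np.stack(
                [
                    posts[:, [
                        midx[m]
                        for m in ([x for x in r.requires if x not in shared]
                                  or list(r.requires))
                    ]].max(axis=1)
                    for r in grp
                ]
            )
            scores = np.where(matches, scores, -1.0)
            winner = scores.argmax(axis=0)  # ties -> declaration order
            for gi, r in enumerate(grp):
                result[hit & (winner == gi)] = r.name
        unassigned &= ~hit
    return result


def _original_scale_bic(fit: MixtureFit, x: np.ndarray) -> float:
    """BIC of a fit on the original intensity scale.

    For asinh-space fits the log-likelihood is mapped back through the
    transform's Jacobian (d/dx asinh(x/c) = 1/sqrt(x^2 + c^2)) so raw and
    transformed candidates are comparable.
    """
    if not fit.transformed:
        return fit.bic
    jac = -0.5 * np.log(x**2 + fit.cofactor**2).sum()
    return _N_PARAMS * np.log(fit.n) - 2.0 * (fit.loglik + jac)


def gate_cells(
    cells: pd.DataFrame,
    panel: PanelSpec,
    mode: str = "per-sample",
    families=FAMILIES,
    threshold: float = 0.95,
    transform: str = "auto",
    cofactor: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Gate every marker of a cell table and assign composite phenotypes.

    ``mode`` is ``"per-sample"`` (one fit per marker per sample, robust to
    slide-to-slide staining shifts) or ``"pooled"`` (one fit per marker on
    the whole cohort).  ``transform`` is ``"auto"`` (asinh when the raw
    histogram has |skewness| > 2 or raw fits fail), ``"always"`` or
    ``"never"``.  Returns the table with ``<marker>_posterior``,
    ``<marker>_call`` and ``phenotype`` columns added, plus the fitted
    mixtures keyed by (stratum, marker).
    """
    if mode not in ("per-sample", "pooled"):
        raise ValueError("mode must be 'per-sample' or 'pooled'")
    out = cells.reset_index(drop=True).copy()
    fits: dict[tuple[str, str], MixtureFit] = {}
    if mode == "per-sample":
        strata = sorted(out.groupby("sample_id").indices.items())
    else:
        strata = [("pooled", np.arange(len(out)))]
    n_markers = len(panel.markers)
    posts = np.empty((len(out), n_markers))
    callm = np.empty((len(out), n_markers), dtype=bool)
    for stratum, idx in strata:
        for j, marker in enumerate(panel.markers):
            x = out[marker].to_numpy(dtype=float)[idx]
            fit = _fit_marker(x, families, transform, cofactor, seed)
            fits[(stratum, marker)] = fit
            posts[idx, j] = posterior_positive(fit, x)
    callm[:] = posts > threshold
    for j, marker in enumerate(panel.markers):
        out[f"{marker}_posterior"] = posts[:, j]
        out[f"{marker}_call"] = callm[:, j]
    out["phenotype"] = _assign_phenotypes_bulk(callm, posts, panel)
    return out, fits


def _fit_marker(x, families, transform, cofactor, seed):
    """Fit one marker, choosing raw vs asinh scale.

    ``auto`` fits both candidate scales and keeps the one with the lower
    BIC on the original intensity scale (Jacobian-corrected), falling back
    to whichever succeeds when the other fails.
    """
    raw_fit = raw_err = None
    if transform in ("auto", "never"):
        try:
            raw_fit = select_model(x, families=families, seed=seed)
        except MixtureFitError as err:
            raw_err = err
            if transform == "never":
                raise
    if transform == "never":
        return raw_fit
    xt = asinh_transform(x, cofactor)
    try:
        ft = select_model(xt, families=families, seed=seed)
        t_fit = MixtureFit(
            family=ft.family, weights=ft.weights, params=ft.params,
            loglik=ft.loglik, bic=ft.bic, n=ft.n, converged=ft.converged,
            n_iter=ft.n_iter, transformed=True, cofactor=cofactor,
            low_separation=ft.low_separation,
        )
    except MixtureFitError:
        if raw_fit is None:
            raise MixtureFitError(f"raw and asinh fits both failed: {raw_err}")
        t_fit = None
    if transform == "always" or raw_fit is None:
        return t_fit
    if t_fit is None:
        return raw_fit
    if _original_scale_bic(t_fit, x) < _original_scale_bic(raw_fit, x):
        return t_fit
    return raw_fit
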