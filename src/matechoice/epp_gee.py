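"""Generalized estimating equations for extra-pair paternity.

Two model families are used: binomial with a logit link for the presence of
extra-pair young (EPY) in a litter, and Poisson with a log link for the
number of EPY.  Repeated litters of the same social pair form clusters with
an exchangeable working correlation (every pair of observations within a
cluster shares one correlation alpha), and inference uses the robust
(sandwich) covariance, so the coefficient standard errors are valid even if
the working correlation is wrong.

The solver is Fisher scoring on the GEE score equation

    sum_i D_i' V_i^{-1} (y_i - mu_i) = 0,   V_i = phi A_i^{1/2} R(alpha) A_i^{1/2}

with alpha and the scale phi refreshed each iteration from Pearson-residual
moment estimators (pairwise-product estimator with an N* - p degrees-of-
freedom correction, and Pearson chi-square over N - p, respectively).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .parentage import round_half_up

log = logging.getLogger(__name__)

__all__ = [
    "GEEFit",
    "fit_gee",
    "vertex",
    "ModelSpec",
    "fit_epp_model",
    "build_litters_frame",
    "model_table",
]

_ETA_CLIP = 30.0


def _mean_var(eta: np.ndarray, family: str) -> tuple[np.ndarray, np.ndarray]:
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    if family == "binomial":
        mu = 1.0 / (1.0 + np.exp(-eta))
        return mu, mu * (1.0 - mu)
    if family == "poisson":
        mu = np.exp(eta)
        return mu, mu
    raise ValueError(f"unknown family {family!r}")


@dataclass
class GEEFit:
    params: np.ndarray
    robust_se: np.ndarray
    alpha: float
    scale: float
    zvalues: np.ndarray
    pvalues: np.ndarray
    names: list[str]
    n_clusters: int
    n_obs: int
    iterations: int
    converged: bool
    score_norm: float
    family: str
    robust_cov: np.ndarray
    naive_cov: np.ndarray

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "robust_se": self.robust_se,
                "z": self.zvalues,
                "p": self.pvalues,
            },
            index=self.names,
        )

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.robust_se[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])


def fit_gee(
    y: Sequence[float],
    X: np.ndarray,
    groups: Sequence,
    family: str = "binomial",
    tol: float = 1e-8,
    max_iter: int = 50,
    alpha: float | None = None,
    scale: float | None = None,
    names: Sequence[str] | None = None,
) -> GEEFit:
    """Fit a GEE with exchangeable working correlation.

    Parameters
    ----------
    y, X, groups
        Response vector, design matrix (including the intercept column) and
        cluster labels, all of length ``n_obs``.
    family
        ``'binomial'`` (logit link) or ``'poisson'`` (log link); both use
        the canonical link.
    alpha, scale
        Fix the working correlation and/or the dispersion instead of
        estimating them by moments (``alpha=0`` reproduces an independence
        GLM).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n_obs, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    groups = np.asarray([str(g) for g in groups])
    labels = pd.unique(groups)
    clusters = [np.flatnonzero(groups == g) for g in labels]
    n_clusters = len(clusters)
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not full rank")
    max_n = max(len(c) for c in clusters)
    n_pairs = sum(len(c) * (len(c) - 1) // 2 for c in clusters)

    # starting values: intercept at the mean on the link scale
    beta = np.zeros(p)
    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6) if family == "binomial" else max(y.mean(), 1e-6)
    beta[0] = np.log(ybar / (1 - ybar)) if family == "binomial" else np.log(ybar)

    alpha_hat = 0.0 if alpha is None else float(alpha)
    phi = 1.0 if scale is None else float(scale)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu, var = _mean_var(eta, family)
        resid = y - mu
        pearson = resid / np.sqrt(var)
        if scale is None:
            phi = float(pearson @ pearson) / max(n_obs - p, 1)
        if alpha is None and n_pairs > 0:
            cross = 0.0
            for idx in clusters:
                r = pearson[idx]
                s = r.sum()
                cross += 0.5 * (s * s - (r * r).sum())
            denom = phi * max(n_pairs - p, 1)
            alpha_hat = cross / denom
            lo = -1.0 / (max_n - 1) + 1e-6 if max_n > 1 else -0.999
            alpha_hat = float(np.clip(alpha_hat, max(lo, -0.999), 0.999))
        H = np.zeros((p, p))
        score = np.zeros(p)
        for idx in clusters:
            n_c = len(idx)
            sa = np.sqrt(var[idx])
            Z = X[idx] * (sa[:, None])  # = A^{1/2} X since D = A X for canonical links
            r = pearson[idx]
            c = alpha_hat / (1.0 + (n_c - 1) * alpha_hat)
            # R^{-1} x = (x - c * sum(x) * 1) / (1 - alpha)
            rz = (Z - c * Z.sum(axis=0)) / (1.0 - alpha_hat) if n_c > 1 else Z
            rr = (r - c * r.sum()) / (1.0 - alpha_hat) if n_c > 1 else r
            H += Z.T @ rz
            score += Z.T @ rr
        delta = np.linalg.solve(H, score)
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    eta = X @ beta
    mu, var = _mean_var(eta, family)
    resid = y - mu
    pearson = resid / np.sqrt(var)
    if scale is None:
        phi = float(pearson @ pearson) / max(n_obs - p, 1)
    H = np.zeros((p, p))
    M = np.zeros((p, p))
    total_score = np.zeros(p)
    for idx in clusters:
        n_c = len(idx)
        sa = np.sqrt(var[idx])
        Z = X[idx] * sa[:, None]
        r = pearson[idx]
        c = alpha_hat / (1.0 + (n_c - 1) * alpha_hat)
        rz = (Z - c * Z.sum(axis=0)) / (1.0 - alpha_hat) if n_c > 1 else Z
        rr = (r - c * r.sum()) / (1.0 - alpha_hat) if n_c > 1 else r
        g = Z.T @ rr
        H += Z.T @ rz
        M += np.outer(g, g)
        total_score += g
    Hinv = np.linalg.inv(H)
    robust_cov = Hinv @ M @ Hinv
    naive_cov = phi * Hinv
    se = np.sqrt(np.diag(robust_cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    score_norm = float(np.max(np.abs(total_score)) / max(phi, 1e-12))
    if not converged:
        log.warning("GEE did not converge in %d iterations (score norm %.3g)", it, score_norm)
    if family == "binomial" and np.max(np.abs(np.clip(X @ beta, None, None))) > _ETA_CLIP - 1:
        log.warning("possible separation: |linear predictor| near clip bound")
    return GEEFit(
        params=beta,
        robust_se=se,
        alpha=float(alpha_hat),
        scale=float(phi),
        zvalues=z,
        pvalues=pvals,
        names=names,
        n_clusters=n_clusters,
        n_obs=n_obs,
        iterations=it,
        converged=converged,
        score_norm=score_norm,
        family=family,
        robust_cov=robust_cov,
        naive_cov=naive_cov,
    )


def vertex(beta_linear: float, beta_quad: float) -> float:
    """Stationary point ``-b1 / (2 b2)`` of a fitted quadratic term.

    On the linear-predictor scale this is the covariate value at which the
    fitted response is extremal (a minimum iff the quadratic coefficient is
    positive) -- the "intermediate" relatedness when applied to the pair-
    relatedness quadratic.
    """
    if beta_quad == 0:
        raise ValueError("quadratic coefficient is zero: no vertex")
    return -beta_linear / (2.0 * beta_quad)


# -- model orchestration -------------------------------------------------------

BASE_TERMS = ("litter_size", "n_mature_sub_males", "r_qg", "r_qg_sq")


@dataclass(frozen=True)
class ModelSpec:
    """One EPP model: response, tested genetic term, cluster column.

    Every model carries the base covariates (litter size, number of mature
    subordinate males, pair relatedness and its quadratic); the tested
    genetic term (if any) enters linearly.
    """

    response: str  # 'epy_presence' | 'epy_count'
    term: str | None = None
    cluster: str = "pair_id"

    def family(self) -> str:
        return "binomial" if self.response == "epy_presence" else "poisson"

    def covariates(self) -> list[str]:
        cols = list(BASE_TERMS)
        if self.term is not None and self.term not in cols:
            cols.append(self.term)
        return cols


def fit_epp_model(data: pd.DataFrame, spec: ModelSpec, **kwargs) -> GEEFit:
    """Fit one EPP GEE model from a litters table.

    *data* needs the response column (``epy_presence`` 0/1 or ``epy_count``),
    ``litter_size``, ``n_mature_sub_males``, ``r_qg``, the cluster column and
    the tested term's column.  ``r_qg_sq`` is derived if absent.
    """
    df = data.copy()
    if "r_qg_sq" not in df.columns:
        df["r_qg_sq"] = df["r_qg"] ** 2
    cols = spec.covariates()
    needed = [spec.response, spec.cluster, *cols]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = df.dropna(subset=needed)
    X = np.column_stack([np.ones(len(df)), df[cols].to_numpy(dtype=float)])
    return fit_gee(
        df[spec.response].to_numpy(dtype=float),
        X,
        df[spec.cluster],
        family=spec.family(),
        names=["intercept", *cols],
        **kwargs,
    )


def build_litters_frame(
    events,
    gt,
    calls: Sequence | None = None,
    freqs=None,
) -> pd.DataFrame:
    """Assemble the per-litter model frame for the EPP GEEs.

    One row per reproductive event: cluster id (the social pair), litter
    size, number of mature subordinate males, pair relatedness, EPY
    presence/count (from parentage calls, classified on the fly when *calls*
    is omitted), plus the genetic estimator columns (male SH, MHC protein
    diversities, pair MHC protein dissimilarities).  Rows with an
    unresolved pup keep NaN responses and are dropped at fit time.
    """
    from . import estimators as est
    from .genotype_io import LocusKind, allele_frequencies
    from .parentage import classify_litter

    if freqs is None:
        freqs = allele_frequencies(gt, loci=[l.name for l in gt.microsat_loci])
    if calls is None:
        calls = [c for e in events for c in classify_litter(e, gt)]
    by_litter: dict[str, list] = {}
    for c in calls:
        by_litter.setdefault(c.litter, []).append(c)
    het = est.observed_heterozygosity(gt)
    mhc1 = next(iter(gt.loci_of_kind(LocusKind.MHC_CLASS_I)), None)
    mhc2 = next(iter(gt.loci_of_kind(LocusKind.MHC_CLASS_II)), None)
    rows = []
    for e in events:
        lcalls = by_litter.get(e.litter_id, [])
        resolved = [c for c in lcalls if c.classification in ("WPY", "EPY")]
        n_epy = sum(c.classification == "EPY" for c in resolved)
        row: dict[str, object] = {
            "litter_id": e.litter_id,
            "pair_id": f"{e.female}|{e.social_male}",
            "year": e.year,
            "litter_size": e.litter_size,
            "n_mature_sub_males": e.n_mature_sub_males,
            "epy_presence": float(n_epy > 0) if resolved else np.nan,
            "epy_count": float(n_epy) if resolved else np.nan,
        }
        try:
            row["r_qg"] = est.qg_relatedness(e.female, e.social_male, gt, freqs).value
        except (ValueError, KeyError):
            row["r_qg"] = np.nan
        try:
            row["sh_male"] = est.standardized_heterozygosity(e.social_male, gt, het).value
        except (ValueError, KeyError):
            row["sh_male"] = np.nan
        for label, locus in (("mhc1", mhc1), ("mhc2", mhc2)):
            if locus is None:
                continue
            try:
                row[f"{label}_diversity"] = est.mhc_protein_diversity(
                    e.social_male, gt, locus
                ).value
                row[f"{label}_dissimilarity"] = est.mhc_protein_dissimilarity(
                    e.social_male, e.female, gt, locus
                ).value
            except (ValueError, KeyError):
                row[f"{label}_diversity"] = np.nan
                row[f"{label}_dissimilarity"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df["r_qg_sq"] = df["r_qg"] ** 2
    return df


def model_table(
    fits: Mapping[str, tuple[GEEFit, GEEFit]],
    digits: int = 2,
) -> pd.DataFrame:
    """Tabulate tested genetic terms across presence and count models.

    *fits* maps a tested term name to its (presence, count) fit pair.  One
    row per term: estimate +/- robust SE and P for each response, and N.
    Estimates are rounded half-up to *digits* decimals.
    """
    rows = []
    for term, (fit_pres, fit_cnt) in fits.items():
        row: dict[str, object] = {"term": term}
        for label, fit in (("presence", fit_pres), ("count", fit_cnt)):
            if fit is None:
                continue
            names = [term] if term in fit.names else []
            if term == "r_qg":
                names = ["r_qg", "r_qg_sq"]
            est = " / ".join(
                f"{round_half_up(fit.coef(n), digits)}"
                f"±{round_half_up(fit.se(n), digits)}"
                for n in names
            )
            pv = " / ".join(f"{round_half_up(fit.pvalue(n), 3)}" for n in names)
            row[f"{label}_estimate"] = est
            row[f"{label}_p"] = pv
        row["N"] = fit_pres.n_obs if fit_pres is not None else fit_cnt.n_obs
        rows.append(row)
    return pd.DataFrame(rows)
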