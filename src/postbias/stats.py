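"""Group-level statistics for behavioural and neural accumulation metrics.

Three tools: (1) hierarchical (mixed-effects) regression with subject
random intercepts, for trial-level outcomes such as final RT, accuracy,
confidence, or the neural slope/intercept; (2) multilevel mediation
(positive evidence -> confidence -> change of mind) with a
subjects-then-trials bootstrap; (3) the high-vs-low-confidence contrast of
temporal generalization matrices with a cluster-based sign-flip
permutation test for family-wise error control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.regression.mixed_linear_model import MixedLM

RESULT_COLUMNS = ["term", "estimate", "se", "stat", "df", "p"]


# ---------------------------------------------------------------------------
# Hierarchical regression
# ---------------------------------------------------------------------------


@dataclass
class HierRegResult:
    """Fixed effects of a mixed model with subject random intercepts.

    ``table`` has columns term/estimate/se/stat/df/p; degrees of freedom
    for t statistics are residual-based (n - p), matching the reporting
    convention t(dof) with trial-level dof.
    """

    table: pd.DataFrame
    model_type: str
    n_obs: int
    n_subjects: int

    def __getitem__(self, term: str) -> pd.Series:
        row = self.table[self.table["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]


def _check_collinear(X: pd.DataFrame):
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    bad = []
    cols = list(X.columns)
    for j, name in enumerate(cols):
        others = np.delete(arr, j + 1, axis=1)
        if np.linalg.matrix_rank(others) == rank:
            bad.append(name)
    raise ValueError(f"collinear design: columns {bad or cols} are redundant")


def hier_regress(outcome, predictors: pd.DataFrame, subjects, family: str = "auto") -> HierRegResult:
    """Mixed-effects regression of a trial-level outcome on predictors.

    Subject enters as a random intercept; predictors are fixed effects.
    ``family`` is 'linear', 'logistic', or 'auto' (logistic when the
    outcome is binary).  Linear models are fitted by REML (statsmodels
    MixedLM); logistic models by variational Bayes (statsmodels
    BinomialBayesMixedGLM), whose posterior mean/sd give Wald z tests.
    """
    y = np.asarray(outcome, dtype=float)
    groups = np.asarray(subjects)
    if len(np.unique(groups)) < 2:
        raise ValueError("hierarchical regression requires >= 2 subjects")
    _check_collinear(predictors)
    if family == "auto":
        family = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    X = sm.add_constant(predictors.to_numpy(dtype=float), has_constant="add")
    names = ["intercept"] + list(predictors.columns)
    n, p = X.shape
    df_resid = n - p

    if family == "linear":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = MixedLM(y, X, groups=groups).fit(reml=True)
            except np.linalg.LinAlgError:
                # degenerate (near-zero) group variance: derivative-free refit
                fit = MixedLM(y, X, groups=groups).fit(reml=True, method="powell")
        est = np.asarray(fit.fe_params)
        se = np.asarray(fit.bse_fe)
        tstat = est / se
        pval = 2.0 * sps.t.sf(np.abs(tstat), df_resid)
    elif family == "logistic":
        _, grp_idx = np.unique(groups, return_inverse=True)
        exog_vc = np.zeros((n, len(np.unique(grp_idx))))
        exog_vc[np.arange(n), grp_idx] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BinomialBayesMixedGLM(y, X, exog_vc, ident=np.zeros(exog_vc.shape[1], dtype=int))
            fit = model.fit_vb()
        est = fit.fe_mean
        se = fit.fe_sd
        tstat = est / se
        pval = 2.0 * sps.norm.sf(np.abs(tstat))
    else:
        raise ValueError(f"unknown family {family!r}")

    table = pd.DataFrame(
        {
            "term": names,
            "estimate": est,
            "se": se,
            "stat": tstat,
            "df": df_resid,
            "p": pval,
        }
    )
    return HierRegResult(table=table, model_type=family, n_obs=n, n_subjects=len(np.unique(groups)))


def slope_effects(summaries: pd.DataFrame, outcome: str = "slope") -> HierRegResult:
    """Fixed effects of decision, confidence and their interaction on an
    unsigned accumulation metric ('slope' or 'intercept').

    ``summaries`` needs columns subject_id, decision (+1 confirmatory /
    -1 disconfirmatory), confidence (+1 high / -1 low) and the outcome.
    """
    req = {"subject_id", "decision", "confidence", outcome}
    missing = req - set(summaries.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    dec = np.asarray(summaries["decision"], dtype=float)
    conf = np.asarray(summaries["confidence"], dtype=float)
    if not set(np.unique(dec)) <= {-1.0, 1.0} or not set(np.unique(conf)) <= {-1.0, 1.0}:
        raise ValueError("decision and confidence must be coded +1/-1")
    cells = {(d, c) for d, c in zip(dec, conf)}
    if len(cells) < 4:
        raise ValueError(f"missing condition cells: have only {sorted(cells)}")
    predictors = pd.DataFrame(
        {"decision": dec, "confidence": conf, "interaction": dec * conf}
    )
    return hier_regress(
        summaries[outcome], predictors, summaries["subject_id"], family="linear"
    )


# ---------------------------------------------------------------------------
# Multilevel mediation
# ---------------------------------------------------------------------------


@dataclass
class MediationResult:
    """Path estimates with bootstrap percentile CIs and two-tailed p values.

    Paths: a (predictor -> mediator), b (mediator -> outcome, controlling
    the predictor), ab (the mediated effect, mean of per-subject a*b),
    c (total predictor -> outcome), c_prime (direct effect controlling the
    mediator).
    """

    paths: pd.DataFrame  # columns: path, estimate, ci_lo, ci_hi, p
    n_boot: int
    seed: int
    covariates: tuple[str, ...] = ()

    def __getitem__(self, path: str) -> pd.Series:
        row = self.paths[self.paths["path"] == path]
        if row.empty:
            raise KeyError(path)
        return row.iloc[0]


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _logistic_irls(X: np.ndarray, y: np.ndarray, ridge: float = 1e-3, n_iter: int = 25) -> np.ndarray:
    """Ridge-stabilised IRLS logistic fit (small designs, bootstrap-speed)."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-6)
        H = (X * w[:, None]).T @ X + ridge * np.eye(X.shape[1])
        g = X.T @ (y - mu) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _subject_paths(x, m, y, cov, idx_by_subj):
    """Per-subject path coefficients (a, b, c_prime, c) averaged at group level."""
    a = np.empty(len(idx_by_subj))
    b = np.empty(len(idx_by_subj))
    cp = np.empty(len(idx_by_subj))
    c = np.empty(len(idx_by_subj))
    for s, idx in enumerate(idx_by_subj):
        ones = np.ones(len(idx))
        C = cov[idx] if cov is not None else np.empty((len(idx), 0))
        Xa = np.column_stack([ones, x[idx], C])
        a[s] = _ols(Xa, m[idx])[1]
        Xb = np.column_stack([ones, x[idx], m[idx], C])
        coefs = _logistic_irls(Xb, y[idx])
        cp[s], b[s] = coefs[1], coefs[2]
        c[s] = _logistic_irls(Xa, y[idx])[1]
    return a, b, cp, c


def mediation(
    predictor,
    mediator,
    outcome,
    subjects,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 5000,
    seed: int = 0,
) -> MediationResult:
    """Multilevel mediation of a binary outcome with bootstrap inference.

    Within each subject, path a comes from an OLS mediator model and paths
    b/c'/c from logistic outcome models; group-level estimates are the
    subject means, with the mediated effect ab = mean_s(a_s * b_s) so that
    subject-level covariation of the two paths is retained.  The bootstrap
    resamples subjects with replacement and then trials within each
    sampled subject; CIs are percentile, p values two-tailed.
    """
    x = np.asarray(predictor, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.var(m) <= 0:
        raise ValueError("degenerate mediator: zero variance")
    groups = np.asarray(subjects)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("mediation requires >= 2 subjects")
    if n_boot < 1000:
        warnings.warn(f"n_boot={n_boot} is small; bootstrap p values will be coarse")
    cov = covariates.to_numpy(dtype=float) if covariates is not None else None
    cov_names = tuple(covariates.columns) if covariates is not None else ()

    idx_by_subj = [np.flatnonzero(groups == g) for g in uniq]
    a, b, cp, c = _subject_paths(x, m, y, cov, idx_by_subj)
    point = {
        "a": a.mean(),
        "b": b.mean(),
        "ab": (a * b).mean(),
        "c": c.mean(),
        "c_prime": cp.mean(),
    }

    rng = np.random.default_rng(seed)
    S = len(uniq)
    boot = {k: np.empty(n_boot) for k in point}
    for it in range(n_boot):
        chosen = rng.integers(0, S, S)
        parts_idx = []
        for s in chosen:
            idx = idx_by_subj[s]
            parts_idx.append(rng.choice(idx, size=len(idx), replace=True))
        new_groups = np.concatenate(
            [np.full(len(ix), k) for k, ix in enumerate(parts_idx)]
        )
        flat = np.concatenate(parts_idx)
        sub_idx = [np.flatnonzero(new_groups == k) for k in range(S)]
        ab_, bb_, cpb_, cb_ = _subject_paths(
            x[flat], m[flat], y[flat], cov[flat] if cov is not None else None, sub_idx
        )
        boot["a"][it] = ab_.mean()
        boot["b"][it] = bb_.mean()
        boot["ab"][it] = (ab_ * bb_).mean()
        boot["c"][it] = cb_.mean()
        boot["c_prime"][it] = cpb_.mean()

    rows = []
    for k, est in point.items():
        d = boot[k]
        lo, hi = np.quantile(d, [0.025, 0.975])
        p_pos = (1 + np.sum(d <= 0)) / (n_boot + 1)
        p_neg = (1 + np.sum(d >= 0)) / (n_boot + 1)
        rows.append(
            {"path": k, "estimate": est, "ci_lo": lo, "ci_hi": hi,
             "p": min(1.0, 2.0 * min(p_pos, p_neg))}
        )
    return MediationResult(
        paths=pd.DataFrame(rows), n_boot=n_boot, seed=seed, covariates=cov_names
    )


# ---------------------------------------------------------------------------
# Confidence contrast and cluster permutation
# ---------------------------------------------------------------------------

CELL_NAMES = ("high_stay", "low_stay", "high_com", "low_com")


def confidence_contrast(by_cell: dict[str, np.ndarray]) -> np.ndarray:
    """Main effect of confidence on a TG matrix for one subject:
    (high/no-change - low/no-change) + (high/change - low/change)."""
    missing = [k for k in CELL_NAMES if k not in by_cell]
    if missing:
        raise ValueError(f"missing condition cell(s): {missing}")
    hs, ls, hc, lc = (np.asarray(by_cell[k], dtype=float) for k in CELL_NAMES)
    return (hs - ls) + (hc - lc)


@dataclass
class ClusterTestResult:
    """Observed clusters with sign-flip-permutation corrected p values.

    ``clusters`` rows: label mask index, sign, mass (summed t), n_cells,
    p_corrected.  ``tmap`` is the one-sample t map; ``threshold`` the
    cluster-forming |t| cutoff.
    """

    clusters: pd.DataFrame
    cluster_masks: list[np.ndarray]
    tmap: np.ndarray
    threshold: float
    n_perm: int
    null_pos: np.ndarray = field(repr=False, default=None)
    null_neg: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.clusters[self.clusters["p_corrected"] < alpha]


_ADJACENCY = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def _cluster_masses(tmap: np.ndarray, thr: float):
    """Positive and negative supra-threshold clusters and their t masses."""
    out = []
    for sign in (1.0, -1.0):
        mask = (sign * tmap) > thr
        lab, nlab = ndimage.label(mask, structure=_ADJACENCY)
        for k in range(1, nlab + 1):
            cells = lab == k
            out.append((sign, float(tmap[cells].sum()), cells))
    return out


def cluster_permutation(
    contrasts: np.ndarray,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterTestResult:
    """Cluster-based sign-flip permutation test on per-subject matrices.

    Cells with one-sample |t| exceeding the two-tailed ``cluster_alpha``
    threshold are grouped into 4-connected clusters whose mass is the
    summed t.  The null distribution is the extreme cluster mass over
    random per-subject sign flips, built separately for positive and
    negative clusters; the reported corrected p is two-tailed (twice the
    one-sided (1+count)/(n_perm+1) estimate against the matching-sign
    null), so thresholding at alpha controls family-wise error at alpha
    across both signs jointly.
    """
    X = np.asarray(contrasts, dtype=float)
    if X.ndim != 3:
        raise ValueError("contrasts must be subjects x rows x cols")
    S = X.shape[0]
    if S < 5:
        raise ValueError("cluster permutation requires >= 5 subjects")
    thr = float(sps.t.ppf(1.0 - cluster_alpha / 2.0, S - 1))
    flat = X.reshape(S, -1)
    sumsq = (flat**2).sum(axis=0)  # invariant under sign flips

    def tmap_from_mean(mean_flat):
        var = (sumsq / S - mean_flat**2) * S / (S - 1)
        se = np.sqrt(np.maximum(var, 1e-300) / S)
        return mean_flat / se

    tmap = tmap_from_mean(flat.mean(axis=0)).reshape(X.shape[1:])
    observed = _cluster_masses(tmap, thr)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, S))
    means = (signs @ flat) / S
    null_pos = np.zeros(n_perm)
    null_neg = np.zeros(n_perm)
    for i in range(n_perm):
        tm = tmap_from_mean(means[i]).reshape(X.shape[1:])
        masses = _cluster_masses(tm, thr)
        pos = [m for s, m, _ in masses if s > 0]
        neg = [m for s, m, _ in masses if s < 0]
        null_pos[i] = max(pos) if pos else 0.0
        null_neg[i] = min(neg) if neg else 0.0

    rows, masks = [], []
    for j, (sign, mass, cells) in enumerate(observed):
        if sign > 0:
            p = (1 + int(np.sum(null_pos >= mass))) / (n_perm + 1)
        else:
            p = (1 + int(np.sum(null_neg <= mass))) / (n_perm + 1)
        p = min(1.0, 2.0 * p)
        rows.append(
            {"cluster": j, "sign": "positive" if sign > 0 else "negative",
             "mass": mass, "n_cells": int(cells.sum()), "p_corrected": p}
        )
        masks.append(cells)
    clusters = pd.DataFrame(rows, columns=["cluster", "sign", "mass", "n_cells", "p_corrected"])
    return ClusterTestResult(
        clusters=clusters,
        cluster_masks=masks,
        tmap=tmap,
        threshold=thr,
        n_perm=n_perm,
        null_pos=null_pos,
        null_neg=null_neg,
    )
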