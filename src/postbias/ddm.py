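"""Drift-diffusion modelling of post-decisional evidence accumulation.

Implements the Wiener first-passage-time (WFPT) core under accuracy coding
(upper bound = correct response), a ten-model regression family in which the
starting point, drift rate and boundary separation depend linearly on
trial covariates (initial confidence, initial decision, their interaction,
and post-decision evidence strength), and a hierarchical Bayesian fit:
subject-level base parameters are drawn from group distributions while the
covariate coefficients are group-level fixed effects.

Conventions
-----------
* Diffusion scale ``s = 1`` (all parameter values are relative to it).
* ``z`` is the relative starting point in (0, 1), measured from the
  incorrect (lower) bound; the starting-point linear predictor lives on the
  logit scale so that z stays in (0, 1).
* The boundary-separation predictor lives on the log scale (positivity).
* Drift is linear in its covariates.
* Covariate coding: confidence scaled to [-1, 1]; initial decision +1
  (correct -> confirmatory post-decision evidence) / -1 (incorrect ->
  disconfirmatory); post-decision evidence strength -1 (weak) / +1 (strong);
  interaction = confidence x decision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

SQRT_2PI = math.sqrt(2.0 * math.pi)

# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WienerParams:
    """Parameters of a single Wiener diffusion between two absorbing bounds.

    v : drift rate (evidence units/s, positive = toward the correct bound)
    a : boundary separation (> 0)
    z : relative starting point in (0, 1), from the lower (incorrect) bound
    t0 : non-decision time in seconds (>= 0)
    s : diffusion scale (fixed convention, default 1)
    """

    v: float
    a: float
    z: float = 0.5
    t0: float = 0.0
    s: float = 1.0

    def __post_init__(self):
        if not (self.a > 0):
            raise ValueError(f"boundary separation must be positive, got {self.a}")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"relative starting point must lie in (0,1), got {self.z}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.t0}")
        if not (self.s > 0):
            raise ValueError(f"diffusion scale must be positive, got {self.s}")


COVARIATES = ("confidence", "initial_decision", "interaction", "post_evidence_strength")


@dataclass(frozen=True)
class ModelSpec:
    """Covariate dependency structure of one model in the family (ids 1-10).

    Term lists name the covariates entering each parameter's linear
    predictor; the intercept (a subject-level base parameter) is implicit in
    every list.  Drift always carries post-decision evidence strength and
    the boundary always carries confidence.
    """

    model_id: int
    z_terms: tuple[str, ...]
    v_terms: tuple[str, ...]
    a_terms: tuple[str, ...] = ("confidence",)

    def __post_init__(self):
        if "post_evidence_strength" not in self.v_terms:
            raise ValueError("drift predictor must include post_evidence_strength")
        if "confidence" not in self.a_terms:
            raise ValueError("boundary predictor must include confidence")
        for t in self.z_terms + self.v_terms + self.a_terms:
            if t not in COVARIATES:
                raise ValueError(f"unknown covariate {t!r}")


_INTER = ("confidence", "initial_decision", "interaction")
_FAMILY_TERMS = {0: (), 1: ("confidence",), 2: ("initial_decision",), 3: _INTER}


def build_model(model_id: int) -> ModelSpec:
    """Return the dependency structure for model ``model_id`` (1..10).

    Model 1 is the baseline (no confidence/decision dependencies).  Models
    2-4 form the confidence family, 5-7 the initial-decision family and
    8-10 the interaction family (which, following the hierarchy principle
    and the printed full model, includes both main effects alongside the
    interaction).  Within each family the three variants place the terms on
    the starting point only, the drift only, or both.
    """
    if model_id not in range(1, 11):
        raise ValueError(f"model_id must be in 1..10, got {model_id}")
    if model_id == 1:
        fam, variant = 0, 2
    else:
        fam = (model_id - 2) // 3 + 1
        variant = (model_id - 2) % 3  # 0: z only, 1: v only, 2: both
    terms = _FAMILY_TERMS[fam]
    z_terms = terms if variant in (0, 2) else ()
    v_extra = terms if variant in (1, 2) else ()
    return ModelSpec(
        model_id=model_id,
        z_terms=z_terms,
        v_terms=("post_evidence_strength",) + v_extra,
    )


# ---------------------------------------------------------------------------
# Wiener first-passage density
# ---------------------------------------------------------------------------


def _fpt_norm(u: np.ndarray, w: np.ndarray, err: float) -> np.ndarray:
    """Normalised (v=0, a=1) lower-bound FPT density at scaled times ``u``.

    Evaluates whichever of the small-time and large-time series converges
    faster, with the truncation index chosen from the standard error bound
    so the result is accurate to ``err``.
    """
    u = np.asarray(u, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), u.shape)
    out = np.zeros_like(u)
    pos = u > 0
    if not np.any(pos):
        return out
    up, wp = u[pos], w[pos]

    # terms needed by each series (Navarro-Fuss style bounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = np.where(
            2.0 * np.sqrt(2.0 * np.pi * up) * err < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * up * np.log(2.0 * err * np.sqrt(2.0 * np.pi * up)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(up) + 1.0)
        kl = np.where(
            np.pi * up * err < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(np.pi * up * err), 0.0) / (np.pi**2 * up)),
            1.0 / (np.pi * np.sqrt(up)),
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(up)))

    small = ks < kl
    fp = np.zeros_like(up)

    if np.any(small):
        us, ws = up[small], wp[small]
        K = min(int(np.ceil(ks[small].max())), 60)
        acc = np.zeros_like(us)
        for k in range(-K, K + 1):
            wk = ws + 2.0 * k
            acc += wk * np.exp(-(wk**2) / (2.0 * us))
        fp[small] = acc / (SQRT_2PI * us**1.5)

    large = ~small
    if np.any(large):
        ul, wl = up[large], wp[large]
        K = min(int(np.ceil(kl[large].max())), 600)
        acc = np.zeros_like(ul)
        for k in range(1, K + 1):
            acc += k * np.exp(-(k**2) * np.pi**2 * ul / 2.0) * np.sin(k * np.pi * wl)
        fp[large] = np.pi * acc

    out[pos] = np.maximum(fp, 0.0)
    return out


def _wfpt_lower(t, v, a, w, s=1.0, err=1e-7):
    """Defective density of absorption at the *lower* bound at decision time t."""
    t = np.asarray(t, dtype=float)
    vn = np.asarray(v, dtype=float) / s
    an = np.asarray(a, dtype=float) / s
    w = np.asarray(w, dtype=float)
    t, vn, an, w = np.broadcast_arrays(t, vn, an, w)
    u = np.where(t > 0, t / an**2, 0.0)
    base = _fpt_norm(u, w, err)
    with np.errstate(over="ignore"):
        scale = np.exp(-vn * an * w - vn**2 * t / 2.0) / an**2
    return np.where(t > 0, base * scale, 0.0)


def wiener_fpt_density(t, params: WienerParams, bound: str = "upper", err: float = 1e-7):
    """Defective first-passage density at the named bound.

    ``t`` is measured from stimulus onset; times at or below the
    non-decision time have density 0.  Integrating over t at both bounds
    gives 1.
    """
    if bound not in ("upper", "lower"):
        raise ValueError(f"bound must be 'upper' or 'lower', got {bound!r}")
    t = np.asarray(t, dtype=float)
    td = t - params.t0
    if bound == "upper":
        out = _wfpt_lower(td, -params.v, params.a, 1.0 - params.z, params.s, err)
    else:
        out = _wfpt_lower(td, params.v, params.a, params.z, params.s, err)
    if out.ndim == 0:
        return float(out)
    return out


def choice_probability(params: WienerParams) -> float:
    """Analytic probability of absorbing at the upper (correct) bound."""
    v, a, z, s = params.v, params.a, params.z, params.s
    if abs(v) < 1e-12:
        return float(z)
    k = 2.0 * v * a / s**2
    # numerically stable for large |k|
    num = -np.expm1(-k * z)
    den = -np.expm1(-k)
    return float(num / den)


def simulate_wiener(
    params: WienerParams,
    n: int,
    dt: float = 1e-4,
    seed: int | None = None,
    t_max: float = 20.0,
    rng: np.random.Generator | None = None,
):
    """Simulate ``n`` first passages by Euler-Maruyama at step ``dt``.

    Returns (choices, rts): choices are 1 where the upper (correct) bound
    was hit, 0 for the lower; rts include the non-decision time t0.  Walks
    still unabsorbed at ``t_max`` (vanishingly rare for sensible
    parameters) are assigned the nearer bound at t_max.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    v, a, z, t0, s = params.v, params.a, params.z, params.t0, params.s
    x = np.full(n, z * a)
    choice = np.zeros(n, dtype=np.int64)
    rt = np.full(n, t_max + t0)
    active = np.ones(n, dtype=bool)
    sq = s * math.sqrt(dt)
    n_steps = int(round(t_max / dt))
    for i in range(1, n_steps + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        x[idx] += v * dt + sq * rng.standard_normal(idx.size)
        up = x[idx] >= a
        lo = x[idx] <= 0.0
        done = up | lo
        hit = idx[done]
        choice[hit] = up[done].astype(np.int64)
        rt[hit] = i * dt + t0
        active[hit] = False
    if active.any():
        choice[active] = (x[active] >= a / 2.0).astype(np.int64)
    return choice, rt


def _simulate_wiener_trials(v, a, z, t0, dt, rng, t_max=20.0, s=1.0):
    """Vectorised Euler-Maruyama with per-trial parameters (internal)."""
    v, a, z, t0 = np.broadcast_arrays(
        np.asarray(v, float), np.asarray(a, float), np.asarray(z, float), np.asarray(t0, float)
    )
    n = v.shape[0]
    x = z * a
    x = x.copy()
    choice = np.zeros(n, dtype=np.int64)
    rt = np.full(n, t_max) + t0
    active = np.ones(n, dtype=bool)
    sq = s * math.sqrt(dt)
    n_steps = int(round(t_max / dt))
    for i in range(1, n_steps + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        x[idx] += v[idx] * dt + sq * rng.standard_normal(idx.size)
        up = x[idx] >= a[idx]
        lo = x[idx] <= 0.0
        done = up | lo
        hit = idx[done]
        choice[hit] = up[done].astype(np.int64)
        rt[hit] = i * dt + t0[hit]
        active[hit] = False
    if active.any():
        choice[active] = (x[active] >= a[active] / 2.0).astype(np.int64)
    return choice, rt


# ---------------------------------------------------------------------------
# Covariates, RT filtering, trial likelihood
# ---------------------------------------------------------------------------


def confidence_to_signed(conf: np.ndarray) -> np.ndarray:
    """Map confidence ratings in [0.5, 1] affinely onto [-1, 1]."""
    conf = np.asarray(conf, dtype=float)
    if np.any(conf < 0.5 - 1e-9) or np.any(conf > 1.0 + 1e-9):
        raise ValueError("confidence ratings must lie in [0.5, 1]")
    return np.clip(4.0 * conf - 3.0, -1.0, 1.0)


def make_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Build the coded covariate columns from a behavioural trial table.

    Expects columns ``initial_confidence`` (in [0.5,1], or already in
    [-1,1] if the column ``confidence_signed`` is present), ``initial_correct``
    (0/1) and ``post_strength`` ('weak'/'strong' or +/-1).
    """
    out = pd.DataFrame(index=table.index)
    if "confidence_signed" in table.columns:
        conf = np.asarray(table["confidence_signed"], dtype=float)
    else:
        conf = confidence_to_signed(table["initial_confidence"].to_numpy())
    dec = np.where(table["initial_correct"].to_numpy().astype(int) == 1, 1.0, -1.0)
    ps = table["post_strength"].to_numpy()
    if ps.dtype.kind in "OUS":
        pes = np.where(ps == "strong", 1.0, -1.0)
    else:
        pes = np.asarray(ps, dtype=float)
    out["confidence"] = conf
    out["initial_decision"] = dec
    out["interaction"] = conf * dec
    out["post_evidence_strength"] = pes
    return out


def filter_rts(table: pd.DataFrame, min_rt: float = 0.200) -> pd.DataFrame:
    """Drop trials with final RT below ``min_rt`` seconds (fast guesses)."""
    rt = table["final_rt"].to_numpy(dtype=float)
    keep = rt >= min_rt
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_rts: removed %d of %d trials below %.3f s", n_removed, len(table), min_rt)
    out = table.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("all trials removed by the RT filter; fit impossible")
    return out


def mixture_loglik(rt, correct, v, a, z, t0, p_out: float, rt_range: tuple[float, float]):
    """Per-trial log-likelihood of the WFPT/uniform-contaminant mixture.

    The contaminant is uniform over the observed RT range and over both
    responses, so its density is ``1 / (2 * (hi - lo))``.
    """
    rt = np.asarray(rt, dtype=float)
    correct = np.asarray(correct)
    if not np.all(np.isfinite(np.asarray(v, float))) or not np.all(np.isfinite(np.asarray(z, float))):
        raise ValueError("non-finite diffusion parameters/covariates")
    td = rt - np.asarray(t0, float)
    c = correct.astype(bool)
    v_eff = np.where(c, -np.asarray(v, float), np.asarray(v, float))
    w_eff = np.where(c, 1.0 - np.asarray(z, float), np.asarray(z, float))
    f = _wfpt_lower(td, v_eff, np.asarray(a, float), w_eff)
    lo, hi = rt_range
    u = 1.0 / (2.0 * max(hi - lo, 1e-12))
    dens = (1.0 - p_out) * f + p_out * u
    with np.errstate(divide="ignore"):
        return np.log(dens)


def trial_loglik(rt, correct, covs: pd.DataFrame, coefficients: dict, config: "FitConfig"):
    """Log-likelihood of trials under explicit regression coefficients.

    ``coefficients`` holds scalars: v_intercept, a_intercept (log scale),
    z_intercept (logit scale), t0, plus ``v_<cov>``, ``z_<cov>``, ``a_<cov>``
    entries for covariate effects.
    """
    X = covs
    v = np.full(len(X), coefficients.get("v_intercept", 0.0))
    zeta = np.full(len(X), coefficients.get("z_intercept", 0.0))
    la = np.full(len(X), coefficients.get("a_intercept", 0.0))
    for name in COVARIATES:
        if f"v_{name}" in coefficients:
            v = v + coefficients[f"v_{name}"] * X[name].to_numpy()
        if f"z_{name}" in coefficients:
            zeta = zeta + coefficients[f"z_{name}"] * X[name].to_numpy()
        if f"a_{name}" in coefficients:
            la = la + coefficients[f"a_{name}"] * X[name].to_numpy()
    rt = np.asarray(rt, dtype=float)
    rng_rt = (config.min_rt, float(rt.max()))
    return mixture_loglik(
        rt, correct, v, np.exp(la), expit(zeta), coefficients.get("t0", 0.0),
        config.outlier_probability, rng_rt,
    )


# ---------------------------------------------------------------------------
# Hierarchical fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """MCMC settings.  ``n_samples`` counts total sweeps per chain including
    the ``n_burn`` warm-up; the retained draw count per chain is
    ``(n_samples - n_burn) // thinning``."""

    n_samples: int = 3000
    n_burn: int = 1000
    thinning: int = 1
    chains: int = 4
    seed: int = 0
    outlier_probability: float = 0.05
    min_rt: float = 0.200
    rhat_threshold: float = 1.1

    def __post_init__(self):
        if not self.n_burn < self.n_samples:
            raise ValueError("n_burn must be below n_samples")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if not (0.0 <= self.outlier_probability < 1.0):
            raise ValueError("outlier_probability must be in [0, 1)")


# subject-level base parameters, in sampling order
_SUBJ_KINDS = ("v0", "zeta", "alpha", "tau")  # drift, logit z, log a, log t0
_PRIOR_MU_MEAN = np.array([0.0, 0.0, 0.4, -1.2])
_PRIOR_MU_SD = np.array([3.0, 2.0, 1.5, 1.5])
_PRIOR_VAR_A = 2.0      # inverse-gamma shape for group variances
_PRIOR_VAR_B = 0.125    # inverse-gamma scale (prior sd around 0.35)
_PRIOR_BETA_SD = 2.0


@dataclass
class FitResult:
    """Posterior draws and metadata from :func:`fit_hierarchical`.

    ``draws`` maps parameter names to arrays of shape (chains, n_retained):
    fixed effects are named ``z_<cov>``, ``v_<cov>``, ``a_<cov>``; group
    means/sds ``mu_<kind>``/``sd_<kind>``; subject parameters
    ``<kind>_s<j>``.  ``deviance`` has the same shape.
    """

    draws: dict[str, np.ndarray]
    deviance: np.ndarray
    rhat: dict[str, float]
    converged: bool
    n_retained: int
    model: ModelSpec
    config: FitConfig
    dic_: float | None = None
    acceptance: dict[str, float] = field(default_factory=dict)

    def posterior_mean(self, name: str) -> float:
        return float(self.draws[name].mean())

    def posterior_interval(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - prob) / 2.0
        q = np.quantile(self.draws[name].ravel(), [lo, 1.0 - lo])
        return float(q[0]), float(q[1])


def _prepare_data(table: pd.DataFrame, spec: ModelSpec, config: FitConfig):
    table = filter_rts(table, config.min_rt)
    covs = make_covariates(table)
    subjects, subj_idx = np.unique(table["subject_id"].to_numpy(), return_inverse=True)
    if len(subjects) < 2:
        raise ValueError("hierarchical fit requires at least 2 subjects")
    data = {
        "rt": table["final_rt"].to_numpy(dtype=float),
        "correct": table["final_correct"].to_numpy(dtype=int),
        "subj_idx": subj_idx,
        "n_subj": len(subjects),
        "subjects": subjects,
        "Xz": covs[list(spec.z_terms)].to_numpy() if spec.z_terms else np.zeros((len(table), 0)),
        "Xv": covs[list(spec.v_terms)].to_numpy(),
        "Xa": covs[list(spec.a_terms)].to_numpy(),
    }
    data["rt_range"] = (config.min_rt, float(data["rt"].max()))
    return data


def _loglik_state(data, state, p_out):
    """Per-subject log-likelihood vector under the current state."""
    si = data["subj_idx"]
    v = state["v0"][si] + data["Xv"] @ state["beta_v"]
    zeta = state["zeta"][si] + data["Xz"] @ state["beta_z"]
    la = state["alpha"][si] + data["Xa"] @ state["beta_a"]
    t0 = np.exp(state["tau"])[si]
    ll = mixture_loglik(
        data["rt"], data["correct"], v, np.exp(la), expit(zeta), t0, p_out, data["rt_range"]
    )
    per_subj = np.full(data["n_subj"], -np.inf)
    bad = ~np.isfinite(ll)
    if bad.any():
        ok_subj = np.ones(data["n_subj"], dtype=bool)
        ok_subj[np.unique(data["subj_idx"][bad])] = False
        ll_f = np.where(bad, 0.0, ll)
        sums = np.bincount(si, weights=ll_f, minlength=data["n_subj"])
        per_subj[ok_subj] = sums[ok_subj]
    else:
        per_subj = np.bincount(si, weights=ll, minlength=data["n_subj"])
    return per_subj


def _init_state(data, spec, rng):
    S = data["n_subj"]
    acc = np.bincount(data["subj_idx"], weights=data["correct"], minlength=S) / np.bincount(
        data["subj_idx"], minlength=S
    )
    acc = np.clip(acc, 0.05, 0.95)
    min_rt_subj = np.array(
        [data["rt"][data["subj_idx"] == s].min() for s in range(S)]
    )
    state = {
        "v0": np.clip(logit(acc), -3, 3) * 0.7 + 0.01 * rng.standard_normal(S),
        "zeta": 0.01 * rng.standard_normal(S),
        "alpha": np.full(S, math.log(1.5)) + 0.01 * rng.standard_normal(S),
        "tau": np.log(0.6 * min_rt_subj) + 0.01 * rng.standard_normal(S),
        "mu": np.array([0.5, 0.0, math.log(1.5), math.log(0.2)]),
        "sd": np.full(4, 0.3),
        "beta_z": np.zeros(len(spec.z_terms)),
        "beta_v": np.zeros(len(spec.v_terms)),
        "beta_a": np.zeros(len(spec.a_terms)),
    }
    return state


def _run_chain(data, spec, config, chain_seed, record_names):
    rng = np.random.default_rng(np.random.SeedSequence(chain_seed))
    state = _init_state(data, spec, rng)
    p_out = config.outlier_probability
    S = data["n_subj"]
    n_ret = (config.n_samples - config.n_burn) // config.thinning

    subj_scales = {k: np.full(S, 0.15) for k in _SUBJ_KINDS}
    beta_scales = {b: np.full(len(state[b]), 0.05) for b in ("beta_z", "beta_v", "beta_a")}
    acc_count = {k: np.zeros(S) for k in _SUBJ_KINDS}
    beta_acc = {b: np.zeros(len(state[b])) for b in ("beta_z", "beta_v", "beta_a")}
    adapt_window = 25

    per_subj_ll = _loglik_state(data, state, p_out)
    draws = {name: np.empty(n_ret) for name in record_names}
    deviance = np.empty(n_ret)
    ret = 0

    for sweep in range(config.n_samples):
        # --- subject-level base parameters, blocked over subjects -------
        for ki, kind in enumerate(_SUBJ_KINDS):
            cur = state[kind]
            prop = cur + subj_scales[kind] * rng.standard_normal(S)
            trial_state = dict(state)
            trial_state[kind] = prop
            prop_ll = _loglik_state(data, trial_state, p_out)
            prior_cur = -0.5 * ((cur - state["mu"][ki]) / state["sd"][ki]) ** 2
            prior_prop = -0.5 * ((prop - state["mu"][ki]) / state["sd"][ki]) ** 2
            log_alpha = (prop_ll + prior_prop) - (per_subj_ll + prior_cur)
            accept = np.log(rng.random(S)) < log_alpha
            cur[accept] = prop[accept]
            per_subj_ll[accept] = prop_ll[accept]
            acc_count[kind] += accept

        # --- fixed-effect coefficients ----------------------------------
        for bname in ("beta_z", "beta_v", "beta_a"):
            beta = state[bname]
            for j in range(len(beta)):
                old = beta[j]
                beta[j] = old + beta_scales[bname][j] * rng.standard_normal()
                prop_ll = _loglik_state(data, state, p_out)
                dprior = -0.5 * (beta[j] ** 2 - old**2) / _PRIOR_BETA_SD**2
                if math.log(rng.random()) < (prop_ll.sum() - per_subj_ll.sum()) + dprior:
                    per_subj_ll = prop_ll
                    beta_acc[bname][j] += 1
                else:
                    beta[j] = old

        # --- group means and variances (conjugate Gibbs) -----------------
        for ki, kind in enumerate(_SUBJ_KINDS):
            sd2 = state["sd"][ki] ** 2
            prec = S / sd2 + 1.0 / _PRIOR_MU_SD[ki] ** 2
            mean = (state[kind].sum() / sd2 + _PRIOR_MU_MEAN[ki] / _PRIOR_MU_SD[ki] ** 2) / prec
            state["mu"][ki] = mean + rng.standard_normal() / math.sqrt(prec)

            dev2 = float(np.sum((state[kind] - state["mu"][ki]) ** 2))
            shape = _PRIOR_VAR_A + S / 2.0
            scale = _PRIOR_VAR_B + dev2 / 2.0
            var = scale / rng.gamma(shape)  # inverse-gamma draw
            state["sd"][ki] = math.sqrt(var)

        # --- adaptation during burn-in -----------------------------------
        if sweep < config.n_burn and (sweep + 1) % adapt_window == 0:
            for kind in _SUBJ_KINDS:
                rate = acc_count[kind] / adapt_window
                subj_scales[kind] *= np.exp(np.clip(rate - 0.35, -0.5, 0.5))
                acc_count[kind][:] = 0.0
            for bname in beta_scales:
                rate = beta_acc[bname] / adapt_window
                beta_scales[bname] *= np.exp(np.clip(rate - 0.40, -0.5, 0.5))
                beta_acc[bname][:] = 0.0

        # --- record -------------------------------------------------------
        if sweep >= config.n_burn and (sweep - config.n_burn) % config.thinning == 0 and ret < n_ret:
            vals = _flatten_state(state, spec)
            for name in record_names:
                draws[name][ret] = vals[name]
            deviance[ret] = -2.0 * per_subj_ll.sum()
            ret += 1

    total_updates = config.n_samples
    acc_rates = {
        f"subj_{k}": float(np.mean(acc_count[k])) / max(total_updates - config.n_burn, 1)
        for k in _SUBJ_KINDS
    }
    return draws, deviance, acc_rates


def _flatten_state(state, spec) -> dict[str, float]:
    vals = {}
    for j, name in enumerate(spec.z_terms):
        vals[f"z_{name}"] = state["beta_z"][j]
    for j, name in enumerate(spec.v_terms):
        vals[f"v_{name}"] = state["beta_v"][j]
    for j, name in enumerate(spec.a_terms):
        vals[f"a_{name}"] = state["beta_a"][j]
    for ki, kind in enumerate(_SUBJ_KINDS):
        vals[f"mu_{kind}"] = state["mu"][ki]
        vals[f"sd_{kind}"] = state["sd"][ki]
        for s_i, x in enumerate(state[kind]):
            vals[f"{kind}_s{s_i}"] = x
    return vals


def _record_names(spec, n_subj):
    names = [f"z_{t}" for t in spec.z_terms]
    names += [f"v_{t}" for t in spec.v_terms]
    names += [f"a_{t}" for t in spec.a_terms]
    for kind in _SUBJ_KINDS:
        names.append(f"mu_{kind}")
        names.append(f"sd_{kind}")
        names += [f"{kind}_s{j}" for j in range(n_subj)]
    return names


def fit_hierarchical(table: pd.DataFrame, spec: ModelSpec, config: FitConfig) -> FitResult:
    """Fit one model of the family by adaptive Metropolis-within-Gibbs.

    Subject base parameters (drift/starting-point/boundary intercepts and
    non-decision time) are hierarchical; covariate coefficients are
    group-level fixed effects.  Runs ``config.chains`` independent chains
    with seeds derived deterministically from ``config.seed``; flags
    non-convergence when any R-hat of a fixed effect or group-level
    parameter exceeds the configured threshold.
    """
    data = _prepare_data(table, spec, config)
    names = _record_names(spec, data["n_subj"])
    seeds = np.random.SeedSequence(config.seed).generate_state(config.chains)
    all_draws, all_dev, acc = [], [], {}
    for c in range(config.chains):
        d, dev, a = _run_chain(data, spec, config, int(seeds[c]), names)
        all_draws.append(d)
        all_dev.append(dev)
        acc = a
    draws = {name: np.stack([d[name] for d in all_draws]) for name in names}
    deviance = np.stack(all_dev)

    group_names = [n for n in names if "_s" not in n or not n.rsplit("_s", 1)[1].isdigit()]
    rhat = gelman_rubin({n: draws[n] for n in names}) if config.chains >= 2 else {}
    converged = all(r <= config.rhat_threshold for n, r in rhat.items() if n in group_names)

    result = FitResult(
        draws=draws,
        deviance=deviance,
        rhat=rhat,
        converged=converged,
        n_retained=deviance.shape[1],
        model=spec,
        config=config,
        acceptance=acc,
    )
    result.dic_ = _compute_dic(result, data)
    if not converged:
        logger.warning(
            "fit_hierarchical: model %d flagged non-converged (max rhat %.3f)",
            spec.model_id,
            max((rhat[n] for n in rhat if n in group_names), default=float("nan")),
        )
    return result


def _state_from_means(result: FitResult, n_subj: int):
    spec = result.model
    m = {name: float(arr.mean()) for name, arr in result.draws.items()}
    state = {
        "beta_z": np.array([m[f"z_{t}"] for t in spec.z_terms]),
        "beta_v": np.array([m[f"v_{t}"] for t in spec.v_terms]),
        "beta_a": np.array([m[f"a_{t}"] for t in spec.a_terms]),
        "mu": np.array([m[f"mu_{k}"] for k in _SUBJ_KINDS]),
        "sd": np.array([m[f"sd_{k}"] for k in _SUBJ_KINDS]),
    }
    for kind in _SUBJ_KINDS:
        state[kind] = np.array([m[f"{kind}_s{j}"] for j in range(n_subj)])
    return state


def _compute_dic(result: FitResult, data) -> float:
    dbar = float(result.deviance.mean())
    state = _state_from_means(result, data["n_subj"])
    d_at_mean = -2.0 * float(
        _loglik_state(data, state, result.config.outlier_probability).sum()
    )
    pd_eff = dbar - d_at_mean
    return dbar + pd_eff


def dic(result: FitResult) -> float:
    """Deviance Information Criterion: mean deviance + effective parameters
    (Spiegelhalter pD = mean deviance - deviance at the posterior mean)."""
    if result.dic_ is None or not np.isfinite(result.dic_):
        raise ValueError("DIC undefined for this fit result")
    return result.dic_


def gelman_rubin(chains) -> dict[str, float] | float:
    """Potential scale reduction factor (classic Gelman-Rubin R-hat).

    Accepts either an array of shape (chains, draws) -> float, or a mapping
    of parameter name -> such arrays -> dict of floats.  Requires >= 2
    chains of equal length.
    """
    if isinstance(chains, dict):
        return {k: gelman_rubin(v) for k, v in chains.items()}
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("gelman_rubin requires an array of shape (chains>=2, draws)")
    m, n = x.shape
    chain_means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W <= 0:
        return 1.0 if B <= 0 else float("inf")
    var_hat = (n - 1) / n * W + B / n
    # values below 1 are finite-sample artifacts; report the floor
    return float(max(np.sqrt(var_hat / W), 1.0))


# ---------------------------------------------------------------------------
# Recovery-harness data generation
# ---------------------------------------------------------------------------


def simulate_regression_dataset(
    spec: ModelSpec,
    coefficients: dict[str, float],
    n_subjects: int,
    n_trials: int,
    seed: int,
    group_means: dict[str, float] | None = None,
    group_sds: dict[str, float] | None = None,
    dt: float = 5e-4,
) -> pd.DataFrame:
    """Generate a trial table from a known regression model (ground truth).

    Subject base parameters are drawn from group distributions; covariates
    are balanced post-evidence strength, random +/-1 initial decisions and
    uniform confidence in [-1, 1]; choices and RTs come from per-trial
    Euler-Maruyama diffusion.  Used by parameter-recovery and
    model-selection tests.
    """
    rng = np.random.default_rng(seed)
    gm = {"v0": 0.8, "zeta": 0.0, "alpha": math.log(1.6), "tau": math.log(0.3)}
    gs = {"v0": 0.25, "zeta": 0.15, "alpha": 0.1, "tau": 0.1}
    if group_means:
        gm.update(group_means)
    if group_sds:
        gs.update(group_sds)

    rows = []
    for s in range(n_subjects):
        base = {k: gm[k] + gs[k] * rng.standard_normal() for k in _SUBJ_KINDS}
        conf = rng.uniform(-1, 1, n_trials)
        dec = rng.choice([-1.0, 1.0], n_trials)
        pes = np.tile([-1.0, 1.0], n_trials // 2 + 1)[:n_trials]
        rng.shuffle(pes)
        cov = {
            "confidence": conf,
            "initial_decision": dec,
            "interaction": conf * dec,
            "post_evidence_strength": pes,
        }
        v = base["v0"] + sum(coefficients.get(f"v_{t}", 0.0) * cov[t] for t in spec.v_terms)
        zeta = base["zeta"] + sum(coefficients.get(f"z_{t}", 0.0) * cov[t] for t in spec.z_terms)
        la = base["alpha"] + sum(coefficients.get(f"a_{t}", 0.0) * cov[t] for t in spec.a_terms)
        t0 = math.exp(base["tau"])
        choice, rt = _simulate_wiener_trials(v, np.exp(la), expit(zeta), t0, dt, rng)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": f"s{s:02d}",
                    "confidence_signed": conf,
                    "initial_correct": (dec > 0).astype(int),
                    "post_strength": np.where(pes > 0, "strong", "weak"),
                    "final_correct": choice,
                    "final_rt": rt,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
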