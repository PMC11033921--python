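"""Correlated two-part mixed model for thresholded semicontinuous distances.

After applying the ROC-determined cutoff, tractogram--DES distances are
semicontinuous: a point mass at zero ("overlap", distance <= cutoff) plus
right-skewed positive distances. The model has two parts sharing correlated
subject-level random intercepts:

* part A (logistic): ``logit P(overlap_ij = 1) = x_ij' alpha + u_i``
* part B (lognormal): ``log y_ij = z_ij' beta + v_i + sigma * eps_ij`` for
  non-overlapping pairs (y_ij > cutoff)

with ``(u_i, v_i) ~ N2(0, [[tau_u^2, rho tau_u tau_v], [., tau_v^2]])``.
A negative ``rho`` is the clinically expected pattern: patients whose
tractograms overlap DES sites more often also sit closer when not
overlapping.

The marginal likelihood integrates the random effects out by adaptive
Gauss--Hermite quadrature (default 7 nodes per dimension, mode-centered and
curvature-scaled per subject). Estimation is quasi-Newton (L-BFGS-B) on
transformed parameters (log variances, atanh correlation); standard errors
come from the inverse observed information, and Wald tests use a t reference
with ``df = n_subjects - n_random_effects``, the subject-based convention.

Sign convention: part A models the probability of *overlap*; a positive
method coefficient therefore means "overlaps DES sites more often".
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .spatial import METHODS

__all__ = [
    "TwoPartParams",
    "TwoPartModel",
    "TwoPartFit",
    "ContrastResult",
    "build_design",
    "threshold_distances",
    "fit_two_part",
    "pairwise_contrasts",
    "hochberg_adjust",
    "holm_adjust",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def threshold_distances(
    records: pd.DataFrame,
    cutoff_mm: float = 12.5,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Map integer distances to a semicontinuous outcome at a cutoff.

    Distances <= cutoff become y = 0 ("overlap", absorbing DES localization
    uncertainty such as brain shift); larger distances pass through unchanged.
    Optional per-tractogram covariates (bundle-to-TIV, lesion-to-TIV ratios)
    are joined on their shared key columns; a patient without covariates is an
    error.
    """
    if cutoff_mm <= 0:
        raise ValueError("cutoff_mm must be > 0")
    out = records.copy()
    out["y"] = np.where(out["distance_mm"] <= cutoff_mm, 0.0, out["distance_mm"].astype(float))
    out["overlap"] = (out["y"] == 0).astype(int)
    if covariates is not None:
        keys = [c for c in ("patient_id", "bundle", "hemisphere", "method") if c in covariates.columns]
        merged = out.merge(covariates, on=keys, how="left", validate="many_to_one")
        value_cols = [c for c in covariates.columns if c not in keys]
        if merged[value_cols].isna().any().any():
            bad = merged.loc[merged[value_cols].isna().any(axis=1), "patient_id"].unique()
            raise ValueError(f"missing covariates for patients: {sorted(bad)}")
        out = merged
    return out


@dataclass
class Design:
    matrix: np.ndarray
    names: list[str]
    covariate_scale: dict[str, tuple[float, float]] = field(default_factory=dict)


def build_design(
    frame: pd.DataFrame,
    *,
    include_response: bool = True,
    include_method: bool = True,
    interaction: bool = False,
    covariates: Sequence[str] = (),
    standardize_covariates: bool = True,
) -> Design:
    """Fixed-effect design shared by both model parts.

    Treatment coding with reference levels ``negative`` (DES response) and
    ``FACT`` (tractography method). Continuous covariates are z-scored by
    default for numerical conditioning; the scaling is recorded so effects can
    be mapped back to the raw ratio scale.
    """
    n = len(frame)
    cols = [np.ones(n)]
    names = ["Intercept"]
    if include_response:
        cols.append((frame["response"].to_numpy() == "positive").astype(float))
        names.append("response[positive]")
    method_levels: list[str] = []
    if include_method:
        present = set(frame["method"].unique())
        method_levels = [m for m in METHODS[1:] if m in present]
        for m in method_levels:
            cols.append((frame["method"].to_numpy() == m).astype(float))
            names.append(f"method[{m}]")
    if interaction and include_response and include_method:
        resp = (frame["response"].to_numpy() == "positive").astype(float)
        for m in method_levels:
            cols.append(resp * (frame["method"].to_numpy() == m).astype(float))
            names.append(f"response[positive]:method[{m}]")
    scale: dict[str, tuple[float, float]] = {}
    for cov in covariates:
        v = frame[cov].to_numpy(dtype=float)
        if standardize_covariates:
            mu, sd = float(v.mean()), float(v.std())
            sd = sd if sd > 0 else 1.0
            scale[cov] = (mu, sd)
            v = (v - mu) / sd
        cols.append(v)
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return Design(X, names, scale)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class TwoPartParams:
    """Natural-scale parameters of the correlated two-part model."""

    alpha: np.ndarray  # part-A (logistic) fixed effects
    beta: np.ndarray   # part-B (log-distance) fixed effects
    tau_u: float       # SD of part-A random intercept
    tau_v: float       # SD of part-B random intercept
    rho: float         # correlation of (u, v)
    sigma: float       # part-B residual SD on the log scale
    tau_s: float | None = None  # optional part-B response random-slope SD

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if not (self.tau_u > 0 and self.tau_v > 0 and self.sigma > 0):
            raise ValueError("tau_u, tau_v, sigma must be > 0")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (-1, 1)")
        if self.tau_s is not None and not self.tau_s > 0:
            raise ValueError("tau_s must be > 0 when given")

    @property
    def n_random(self) -> int:
        return 2 if self.tau_s is None else 3

    def cov_matrix(self) -> np.ndarray:
        c = self.rho * self.tau_u * self.tau_v
        sig = np.array([[self.tau_u**2, c], [c, self.tau_v**2]])
        if self.tau_s is None:
            return sig
        out = np.zeros((3, 3))
        out[:2, :2] = sig
        out[2, 2] = self.tau_s**2
        return out


def _pack(params: TwoPartParams) -> np.ndarray:
    extra = [np.log(params.tau_u), np.log(params.tau_v),
             np.arctanh(params.rho), np.log(params.sigma)]
    if params.tau_s is not None:
        extra.append(np.log(params.tau_s))
    return np.concatenate([params.alpha, params.beta, extra])


def _natural_vector(params: TwoPartParams) -> np.ndarray:
    extra = [params.tau_u, params.tau_v, params.rho, params.sigma]
    if params.tau_s is not None:
        extra.append(params.tau_s)
    return np.concatenate([params.alpha, params.beta, extra])


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class TwoPartModel:
    """Correlated two-part mixed model bound to a prepared data frame.

    Parameters
    ----------
    frame : DataFrame with columns ``patient_id``, ``y`` (0 or > cutoff),
        ``response``, ``method`` and any covariates.
    covariates : continuous nuisance covariates entering both parts.
    quadrature : Gauss--Hermite nodes per random-effect dimension.
    random_slope : add an independent subject-level response slope to part B
        (off by default; identifiability is marginal in small cohorts).
    shift_cutoff : model ``log(y - shift_cutoff)`` instead of ``log y`` for
        the positive part (the shifted thresholding variant).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        *,
        covariates: Sequence[str] = (),
        interaction: bool = False,
        quadrature: int = 7,
        random_slope: bool = False,
        shift_cutoff: float = 0.0,
        standardize_covariates: bool = True,
    ) -> None:
        frame = frame.sort_values("patient_id", kind="stable").reset_index(drop=True)
        y = frame["y"].to_numpy(dtype=float)
        if np.any(y < 0):
            raise ValueError("y must be nonnegative")
        o = (y == 0).astype(float)
        if "overlap" in frame.columns and not np.array_equal(
            frame["overlap"].to_numpy(dtype=float), o
        ):
            raise ValueError("overlap indicator inconsistent with y")
        if o.sum() == 0 or o.sum() == len(o):
            raise ValueError("need both zero and positive outcomes")
        pos = y > 0
        if shift_cutoff and np.any(y[pos] <= shift_cutoff):
            raise ValueError("positive y must exceed shift_cutoff")
        design = build_design(
            frame,
            covariates=covariates,
            interaction=interaction,
            standardize_covariates=standardize_covariates,
        )
        self.frame = frame
        self.design = design
        self.X = design.matrix
        self.Z = design.matrix  # same terms in both parts
        self.names_a = [f"A:{n}" for n in design.names]
        self.names_b = [f"B:{n}" for n in design.names]
        self.o = o
        self.logy = np.where(pos, np.log(np.maximum(y - shift_cutoff, 1e-300)), 0.0)
        self.resp = (frame["response"].to_numpy() == "positive").astype(float)
        subjects, sidx = np.unique(frame["patient_id"].to_numpy(), return_inverse=True)
        order = np.argsort(sidx, kind="stable")
        # re-sort observation arrays so each subject is contiguous
        self.X, self.Z = self.X[order], self.Z[order]
        self.o, self.logy, self.resp = self.o[order], self.logy[order], self.resp[order]
        self.sidx = sidx[order]
        self.subjects = subjects
        self.n_subjects = len(subjects)
        self.starts = np.searchsorted(self.sidx, np.arange(self.n_subjects))
        self.quadrature = int(quadrature)
        self.random_slope = bool(random_slope)
        self.d = 3 if random_slope else 2
        nodes, weights = np.polynomial.hermite.hermgauss(self.quadrature)
        grids = np.meshgrid(*([nodes] * self.d), indexing="ij")
        self.t_nodes = np.stack([g.ravel() for g in grids], axis=1)      # (K, d)
        wgrids = np.meshgrid(*([weights] * self.d), indexing="ij")
        self.log_w = np.sum([np.log(w.ravel()) for w in wgrids], axis=0)  # (K,)
        self.t_norm2 = np.sum(self.t_nodes**2, axis=1)

    # -- likelihood -------------------------------------------------------

    def _obs_terms(self, la: np.ndarray, resid: np.ndarray, sigma: float) -> np.ndarray:
        """Per-observation log density at quadrature nodes; inputs are
        (N, K) arrays (observations x nodes)."""
        o = self.o[:, None]
        ll_a = o * la - np.logaddexp(0.0, la)
        ll_b = (1.0 - o) * (
            -0.5 * (resid / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG2PI
        )
        return ll_a + ll_b

    def _modes(self, eta_a, eta_b, sig_inv, sigma):
        """Per-subject mode and negative Hessian of the joint log density in
        the random effects, by (damped) Newton; the objective is concave."""
        S, d = self.n_subjects, self.d
        b = np.zeros((S, d))
        load_s = self.resp  # part-B slope loading (used only when d == 3)
        for _ in range(50):
            u = b[self.sidx, 0]
            v = b[self.sidx, 1] + (b[self.sidx, 2] * load_s if d == 3 else 0.0)
            la = eta_a + u
            p = special.expit(la)
            r = self.logy - eta_b - v
            g = np.zeros((S, d))
            np.add.at(g[:, 0], self.sidx, self.o - p)
            wb = (1.0 - self.o) * r / sigma**2
            np.add.at(g[:, 1], self.sidx, wb)
            if d == 3:
                np.add.at(g[:, 2], self.sidx, wb * load_s)
            g -= b @ sig_inv
            H = np.zeros((S, d, d))
            w_a = p * (1.0 - p)
            np.add.at(H[:, 0, 0], self.sidx, w_a)
            w_bb = (1.0 - self.o) / sigma**2
            np.add.at(H[:, 1, 1], self.sidx, w_bb)
            if d == 3:
                np.add.at(H[:, 1, 2], self.sidx, w_bb * load_s)
                np.add.at(H[:, 2, 2], self.sidx, w_bb * load_s**2)
                H[:, 2, 1] = H[:, 1, 2]
            H += sig_inv  # H is the *negative* Hessian (positive definite)
            step = np.linalg.solve(H, g[:, :, None])[:, :, 0]
            norm = np.linalg.norm(step, axis=1, keepdims=True)
            step = step * np.minimum(1.0, 5.0 / np.maximum(norm, 1e-12))
            b = b + step
            if np.max(np.abs(step)) < 1e-10:
                break
        return b, H

    def loglik(self, params: TwoPartParams) -> float:
        """Marginal log-likelihood by adaptive Gauss--Hermite quadrature."""
        if self.random_slope != (params.tau_s is not None):
            raise ValueError("params random-slope structure does not match model")
        sig = params.cov_matrix()
        sig_inv = np.linalg.inv(sig)
        sign, logdet_sig = np.linalg.slogdet(sig)
        if sign <= 0:
            return -np.inf
        eta_a = self.X @ params.alpha
        eta_b = self.Z @ params.beta
        modes, negH = self._modes(eta_a, eta_b, sig_inv, params.sigma)
        L = np.linalg.cholesky(negH)                   # (S, d, d)
        # C = L^{-T}; nodes b = mode + sqrt(2) C t
        t = self.t_nodes
        S, K = self.n_subjects, t.shape[0]
        Linv = np.linalg.inv(L)                         # (S, d, d)
        Ct = np.einsum("sed,ke->skd", Linv, t)          # C t = L^{-T} t

        B = modes[:, None, :] + np.sqrt(2.0) * Ct       # (S, K, d)
        logdet_C = -np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)  # (S,)

        u = B[self.sidx, :, 0]                          # (N, K)
        v = B[self.sidx, :, 1]
        if self.d == 3:
            v = v + B[self.sidx, :, 2] * self.resp[:, None]
        la = eta_a[:, None] + u
        resid = self.logy[:, None] - eta_b[:, None] - v
        obs = self._obs_terms(la, resid, params.sigma)  # (N, K)
        g = np.add.reduceat(obs, self.starts, axis=0)   # (S, K)
        quad = np.einsum("skd,de,ske->sk", B, sig_inv, B)
        g += -0.5 * quad - 0.5 * (self.d * _LOG2PI + logdet_sig)
        inner = self.log_w[None, :] + self.t_norm2[None, :] + g
        log_Li = (self.d / 2.0) * np.log(2.0) + logdet_C + special.logsumexp(inner, axis=1)
        return float(log_Li.sum())

    # -- parameter vector plumbing ---------------------------------------

    def _unpack(self, vec: np.ndarray) -> TwoPartParams:
        p = self.X.shape[1]
        alpha, beta = vec[:p], vec[p : 2 * p]
        extra = vec[2 * p :]
        return TwoPartParams(
            alpha=alpha,
            beta=beta,
            tau_u=float(np.exp(extra[0])),
            tau_v=float(np.exp(extra[1])),
            rho=float(np.tanh(extra[2])),
            sigma=float(np.exp(extra[3])),
            tau_s=float(np.exp(extra[4])) if self.random_slope else None,
        )

    def _unpack_natural(self, vec: np.ndarray) -> TwoPartParams:
        p = self.X.shape[1]
        extra = vec[2 * p :]
        return TwoPartParams(
            alpha=vec[:p],
            beta=vec[p : 2 * p],
            tau_u=float(extra[0]),
            tau_v=float(extra[1]),
            rho=float(extra[2]),
            sigma=float(extra[3]),
            tau_s=float(extra[4]) if self.random_slope else None,
        )

    def start_values(self) -> TwoPartParams:
        """Separate fixed-effects logistic and log-scale OLS fits, small
        positive variance components, zero correlation."""
        import statsmodels.api as sm

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                alpha = sm.GLM(self.o, self.X, family=sm.families.Binomial()).fit(maxiter=50).params
            if not np.all(np.isfinite(alpha)) or np.max(np.abs(alpha)) > 15:
                raise ValueError
        except Exception:
            alpha = np.zeros(self.X.shape[1])
            pbar = float(np.clip(self.o.mean(), 1e-3, 1 - 1e-3))
            alpha[0] = special.logit(pbar)
        pos = self.o == 0
        Zp, yp = self.Z[pos], self.logy[pos]
        beta, *_ = np.linalg.lstsq(Zp, yp, rcond=None)
        resid = yp - Zp @ beta
        dof = max(len(yp) - Zp.shape[1], 1)
        sigma = float(np.sqrt(max(resid @ resid / dof, 1e-4)))
        return TwoPartParams(
            alpha=np.asarray(alpha, dtype=float),
            beta=beta,
            tau_u=0.3,
            tau_v=0.3,
            rho=0.0,
            sigma=sigma,
            tau_s=0.3 if self.random_slope else None,
        )

    # -- fitting ----------------------------------------------------------

    def fit(self, start: TwoPartParams | None = None, *, compute_se: bool = True,
            maxiter: int = 400) -> "TwoPartFit":
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        start = start if start is not None else self.start_values()
        x0 = _pack(start)
        p = self.X.shape[1]
        n_extra = 5 if self.random_slope else 4
        bounds = [(None, None)] * (2 * p) + [(-7.0, 4.0), (-7.0, 4.0), (-5.0, 5.0),
                                             (-7.0, 4.0)] + ([(-7.0, 4.0)] if self.random_slope else [])

        def nll(vec: np.ndarray) -> float:
            try:
                val = -self.loglik(self._unpack(vec))
            except np.linalg.LinAlgError:
                return 1e12
            return val if np.isfinite(val) else 1e12

        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "maxfun": 40 * maxiter, "ftol": 1e-11, "gtol": 1e-5},
        )
        params = self._unpack(res.x)
        ll = -res.fun
        converged = bool(res.success)
        if not converged:
            warnings.warn(f"two-part fit did not converge: {res.message}", RuntimeWarning)
        vcov = None
        se = None
        theta = _natural_vector(params)
        if compute_se:
            H = self._observed_information(theta)
            vcov = _safe_inverse(H)
            se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
        names = self.names_a + self.names_b + (
            ["tau_u", "tau_v", "rho", "sigma"] + (["tau_s"] if self.random_slope else [])
        )
        return TwoPartFit(
            params=params,
            names=names,
            estimates=theta,
            se=se,
            vcov=vcov,
            loglik=ll,
            n_subjects=self.n_subjects,
            n_obs=len(self.o),
            df=self.n_subjects - (3 if self.random_slope else 2),
            converged=converged,
            message=str(res.message),
            n_fixed=2 * p,
            model=self,
        )

    def _observed_information(self, theta: np.ndarray) -> np.ndarray:
        """Central-difference Hessian of the negative log-likelihood with
        respect to the natural parameter vector."""

        def f(vec: np.ndarray) -> float:
            try:
                return -self.loglik(self._unpack_natural(vec))
            except (ValueError, np.linalg.LinAlgError):
                return np.nan

        k = len(theta)
        h = 5e-4 * (1.0 + np.abs(theta))
        H = np.zeros((k, k))
        f0 = f(theta)
        for i in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
        for i in range(k):
            for j in range(i + 1, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4.0 * h[i] * h[j])
        return H


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    H = 0.5 * (H + H.T)
    H = np.nan_to_num(H, nan=0.0, posinf=0.0, neginf=0.0)
    try:
        V = np.linalg.inv(H)
        if np.all(np.isfinite(V)):
            return 0.5 * (V + V.T)
    except np.linalg.LinAlgError:
        pass
    return 0.5 * (np.linalg.pinv(H) + np.linalg.pinv(H).T)


@dataclass
class TwoPartFit:
    """Fitted two-part model: estimates, observed-information covariance,
    log-likelihood and the subject-based degrees-of-freedom convention."""

    params: TwoPartParams
    names: list[str]
    estimates: np.ndarray
    se: np.ndarray | None
    vcov: np.ndarray | None
    loglik: float
    n_subjects: int
    n_obs: int
    df: int
    converged: bool
    message: str
    n_fixed: int
    model: TwoPartModel | None = field(repr=False, default=None)

    def coef(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        se = self.se if self.se is not None else np.full(len(self.names), np.nan)
        return pd.DataFrame({"name": self.names, "estimate": self.estimates, "se": se})

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "estimates": [float(v) for v in self.estimates],
            "se": None if self.se is None else [float(v) for v in self.se],
            "vcov": None if self.vcov is None else [[float(v) for v in row] for row in self.vcov],
            "loglik": float(self.loglik),
            "df": int(self.df),
            "n_subjects": int(self.n_subjects),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "message": self.message,
        }


def fit_two_part(frame: pd.DataFrame, **kwargs) -> TwoPartFit:
    """Convenience wrapper: build a :class:`TwoPartModel` and fit it."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("start", "compute_se", "maxiter") if k in kwargs}
    return TwoPartModel(frame, **kwargs).fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# Post-hoc contrasts and multiplicity correction
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    label: str
    part: str  # "A" or "B"
    estimate: float
    se: float
    t: float
    ci_low: float
    ci_high: float
    p_uncorrected: float
    p_fwe: float = float("nan")


def _method_coef_index(fit: TwoPartFit, part: str, method: str) -> int | None:
    name = f"{part}:method[{method}]"
    return fit.names.index(name) if name in fit.names else None


def pairwise_contrasts(
    fit: TwoPartFit,
    *,
    adaptive: bool = True,
    alpha: float = 0.05,
) -> list[ContrastResult]:
    """Wald t contrasts for every pairwise tractography-method difference in
    each model part, with (adaptive) Hochberg FWE correction applied within
    part. A label "FACT versus TP" tests coef(FACT) - coef(TP)."""
    if fit.vcov is None:
        raise ValueError("fit has no covariance matrix (compute_se=False?)")
    if not fit.converged:
        warnings.warn("contrasts computed on a non-converged fit", RuntimeWarning)
    present = [m for m in METHODS if m == METHODS[0] or
               _method_coef_index(fit, "A", m) is not None]
    k = len(fit.estimates)
    results: list[ContrastResult] = []
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, fit.df)
    for part in ("A", "B"):
        part_results = []
        for m1, m2 in itertools.combinations(present, 2):
            c = np.zeros(k)
            i1 = _method_coef_index(fit, part, m1)
            i2 = _method_coef_index(fit, part, m2)
            if i1 is not None:
                c[i1] = 1.0
            if i2 is not None:
                c[i2] = -1.0
            est = float(c @ fit.estimates)
            var = float(c @ fit.vcov @ c)
            if var <= 0:
                raise ValueError("singular covariance in contrast")
            se = float(np.sqrt(var))
            t = est / se
            p = float(2.0 * stats.t.sf(abs(t), fit.df))
            part_results.append(
                ContrastResult(
                    label=f"{m1} versus {m2}",
                    part=part,
                    estimate=est,
                    se=se,
                    t=t,
                    ci_low=est - tcrit * se,
                    ci_high=est + tcrit * se,
                    p_uncorrected=p,
                )
            )
        adj = hochberg_adjust([r.p_uncorrected for r in part_results], adaptive=adaptive)
        for r, pf in zip(part_results, adj):
            r.p_fwe = float(pf)
        results.extend(part_results)
    return results


def contrasts_to_frame(contrasts: Sequence[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair": c.label, "part": c.part, "T": c.t,
                "ci_low": c.ci_low, "ci_high": c.ci_high,
                "p_uncorr": c.p_uncorrected, "p_fwe": c.p_fwe,
            }
            for c in contrasts
        ]
    )


def hochberg_adjust(pvals: Sequence[float], adaptive: bool = False) -> np.ndarray:
    """Hochberg step-up adjusted p-values.

    Plain mode uses the family size m; adaptive mode replaces it with the
    lowest-slope estimate of the number of true nulls (Hochberg--Benjamini),
    which sharpens the correction when many hypotheses are clearly false.
    Adjusted values never decrease below the input and are monotone in it.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ps = p[order]
    m_eff = _lowest_slope_m0(ps) if adaptive else m
    mult = np.maximum(m_eff - np.arange(m), 1)  # m' - j + 1 for j = 1..m
    c = np.minimum(mult * ps, 1.0)
    adj_sorted = np.minimum.accumulate(c[::-1])[::-1]  # min over j >= i
    adj_sorted = np.maximum(adj_sorted, ps)            # never below the input
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _lowest_slope_m0(ps: np.ndarray) -> int:
    """Hochberg--Benjamini lowest-slope estimate of the number of true nulls,
    from ascending-sorted p-values."""
    m = len(ps)
    slopes = (1.0 - ps) / (m - np.arange(m))  # (1 - p_(j)) / (m + 1 - j)
    j_star = m - 1
    for j in range(1, m):
        if slopes[j] < slopes[j - 1]:
            j_star = j
            break
    s = slopes[j_star]
    if s <= 0:
        return m
    return int(min(m, np.floor(1.0 / s + 1.0)))


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (used as a conservative comparator)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    c = np.minimum((m - np.arange(m)) * ps, 1.0)
    adj_sorted = np.maximum.accumulate(c)
    out = np.empty(m)
    out[order] = adj_sorted
    return out
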