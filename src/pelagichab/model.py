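"""Latent Gaussian count model: effort offset, polynomial fixed effects,
SPDE-Matérn spatial field, cyclic monthly effect.

The observation model is

    y_i ~ family(mu_i),   log mu_i = log E_i + eta_i,
    eta_i = beta0 + sum_k beta_k . poly(X_k,i) + (A w)_i + gamma[month_i]

with ``family`` Poisson or negative binomial (mean/size), ``w`` a Matérn
GMRF on the mesh vertices, and ``gamma`` a cyclic first-order random walk
over the 12 months with a (soft) sum-to-zero constraint.

Inference is a nested Laplace scheme: for each hyperparameter point
theta = (log kappa, log tau, log seasonal precision, log NB size), the
latent field (beta, w, gamma) is approximated by a Gaussian centered at its
conditional mode, found by Fisher scoring on the sparse joint precision;
the Laplace-approximate marginal posterior of theta is maximized numerically
and then integrated over a small axis design around the mode whose weights
match the Gaussian mean and variance.  Posterior summaries of all latent
quantities mix over the design points; S draws from the mixture supply the
pointwise log-likelihoods for WAIC.  Everything is deterministic given the
settings (the seed only governs the posterior draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import logsumexp

from .likelihoods import count_loglik, grad_hess_eta
from .mesh import Mesh, projector_matrix
from .spde import SpdeParams, cyclic_rw1_structure, fem_matrices
from .structures import ModelStructure

__all__ = ["Priors", "FitSettings", "FitResult", "fit", "waic", "waic_from_loglik"]

# precision of the soft sum-to-zero constraint on the seasonal effect
_SUM_TO_ZERO_PREC = 1.0e6


@dataclass
class Priors:
    """Vague default priors, all configurable.

    Fixed effects get independent N(0, beta_sd^2); the seasonal precision and
    the NB size get Gamma(shape, rate); the SPDE hyperparameters get wide
    normals on the log scale (means default to a range of ~1/5 of the mesh
    extent and unit marginal sd, set at fit time when left None).
    """

    beta_sd: float = 31.6
    seasonal_prec_shape: float = 1.0
    seasonal_prec_rate: float = 5e-5
    size_shape: float = 1.0
    size_rate: float = 5e-5
    log_kappa_mean: float | None = None
    log_kappa_sd: float = 2.0
    log_tau_mean: float | None = None
    log_tau_sd: float = 2.0


@dataclass
class FitSettings:
    max_newton: int = 100
    newton_tol: float = 1e-6
    hyper_method: str = "ccd"       # "ccd" (axis design) or "eb" (mode only)
    max_hyper_evals: int = 60
    n_draws: int = 250
    seed: int = 0
    fixed_hypers: dict = field(default_factory=dict)
    hyper_init: dict = field(default_factory=dict)


@dataclass
class FitResult:
    structure: ModelStructure
    term_names: list[str]
    transform: dict                     # covariate -> (mean, sd)
    fixed_effects: pd.DataFrame         # term, median, sd
    spatial_field: pd.DataFrame | None  # vertex, median, sd
    seasonal_effects: pd.DataFrame | None
    hyper_points: pd.DataFrame          # theta design points + weights
    hyper_summary: dict
    linear_predictor: pd.DataFrame      # per-observation eta median, sd
    waic: float
    p_waic: float
    loglik_draws: np.ndarray            # (n_obs, S)
    u_draws: np.ndarray                 # (S, latent dim)
    draw_sizes: np.ndarray | None       # NB size per draw
    mesh: Mesh | None
    block_slices: dict                  # name -> slice into the latent vector
    n_obs: int
    converged: bool = True

    def summary(self) -> str:
        lines = [f"structure: {self.structure.structure_id}",
                 f"WAIC {self.waic:.2f}  (p_waic {self.p_waic:.2f}, n {self.n_obs})"]
        for _, r in self.fixed_effects.iterrows():
            lines.append(f"  {r['term']:<18s} {r['median']:+.4f} ({r['sd']:.4f})")
        for k, (m, s) in self.hyper_summary.items():
            lines.append(f"  [{k}] {m:.4g} ({s:.3g})")
        return "\n".join(lines)


def _design(structure: ModelStructure, table: pd.DataFrame,
            transform: dict | None = None) -> tuple[np.ndarray, list[str], dict]:
    """Fixed-effect design matrix: intercept + raw powers of standardized covariates."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["intercept"]
    tf = {} if transform is None else dict(transform)
    for name, deg in structure.terms:
        x = np.asarray(table[name], dtype=float)
        if name in tf:
            mu, sd = tf[name]
        else:
            mu, sd = float(x.mean()), float(x.std())
            if sd == 0:
                raise ValueError(f"covariate {name!r} has zero variance")
            tf[name] = (mu, sd)
        z = (x - mu) / sd
        for d in range(1, deg + 1):
            cols.append(z**d)
            names.append(name if d == 1 else f"{name}^{d}")
    return np.column_stack(cols), names, tf


class _Problem:
    """Holds the data-side matrices and evaluates the Laplace approximation."""

    def __init__(self, structure, table, mesh, priors, settings):
        self.structure = structure
        self.priors = priors
        self.settings = settings
        self.mesh = mesh
        self.y = np.asarray(table["yft_count"], dtype=float)
        offset = np.asarray(table[structure.offset_name], dtype=float)
        if np.any(offset <= 0):
            raise ValueError("offset must be positive")
        self.log_offset = np.log(offset)
        self.family = structure.family

        X, self.term_names, self.transform = _design(structure, table)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"design matrix rank deficient for terms {self.term_names}")
        self.p = X.shape[1]
        blocks = [sparse.csr_matrix(X)]
        self.block_slices = {"beta": slice(0, self.p)}
        pos = self.p
        if structure.includes_spatial:
            if mesh is None:
                raise ValueError("structure includes a spatial field but no mesh given")
            locs = np.c_[table["lon"], table["lat"]]
            self.A = projector_matrix(mesh, locs)
            blocks.append(self.A)
            self.m = mesh.n_vertices
            self.block_slices["spatial"] = slice(pos, pos + self.m)
            pos += self.m
        if structure.includes_seasonal:
            months = pd.to_datetime(table["date"]).dt.month.to_numpy() \
                if "date" in table.columns else np.asarray(table["month"], dtype=int)
            Z = sparse.csr_matrix(
                (np.ones(len(self.y)), (np.arange(len(self.y)), months - 1)),
                shape=(len(self.y), 12),
            )
            blocks.append(Z)
            self.block_slices["seasonal"] = slice(pos, pos + 12)
            pos += 12
        self.q = pos
        self.B = sparse.hstack(blocks, format="csr")
        self.R12 = cyclic_rw1_structure(12).toarray()
        self.J12 = np.ones((12, 12))

        # hyperparameter layout
        self.hyper_names: list[str] = []
        if structure.includes_spatial:
            self.hyper_names += ["log_kappa", "log_tau"]
        if structure.includes_seasonal:
            self.hyper_names.append("log_seasonal_prec")
        if self.family == "negative_binomial":
            self.hyper_names.append("log_size")
        self.free_names = [h for h in self.hyper_names if h not in settings.fixed_hypers]

        # data-informed prior centers for the SPDE scales; FEM matrices and the
        # generalized eigenvalues of C^{-1/2} G C^{-1/2} are cached so both the
        # prior precision and its log-determinant are O(m) per hyper point:
        # Q = tau^2 (k^2 C + G) C^{-1} (k^2 C + G), so
        # log|Q| = 2m log tau + log|C| + 2 sum_i log(k^2 + w_i).
        if structure.includes_spatial:
            ext = max(np.ptp(mesh.vertices[:, 0]), np.ptp(mesh.vertices[:, 1]))
            kappa0 = np.sqrt(8.0) / (0.2 * ext)
            self.lk0 = priors.log_kappa_mean if priors.log_kappa_mean is not None \
                else float(np.log(kappa0))
            self.lt0 = priors.log_tau_mean if priors.log_tau_mean is not None \
                else float(np.log(1.0 / (np.sqrt(4 * np.pi) * kappa0)))
            C, G = fem_matrices(mesh)
            c = C.diagonal()
            from scipy.linalg import eigh

            self._c_diag = c
            self._G_dense = G.toarray()
            Cinv = sparse.diags(1.0 / c)
            self._GCG_dense = (G @ Cinv @ G).toarray()
            sym = self._G_dense / np.sqrt(c)[:, None] / np.sqrt(c)[None, :]
            self._spde_eigs = np.maximum(eigh(sym, eigvals_only=True), 0.0)
            self._logdet_c = float(np.sum(np.log(c)))
        self._warm = np.zeros(self.q)
        self.n_newton_fail = 0

    # -- theta handling ----------------------------------------------------
    def theta_init(self) -> np.ndarray:
        init = []
        for h in self.free_names:
            if h in self.settings.hyper_init:
                init.append(self.settings.hyper_init[h])
            elif h == "log_kappa":
                init.append(self.lk0)
            elif h == "log_tau":
                init.append(self.lt0)
            elif h == "log_seasonal_prec":
                init.append(np.log(10.0))
            else:  # log_size
                init.append(0.0)
        return np.array(init)

    def theta_dict(self, theta_free: np.ndarray) -> dict:
        d = dict(self.settings.fixed_hypers)
        d.update(dict(zip(self.free_names, theta_free)))
        return d

    def prior_precision(self, th: dict) -> np.ndarray:
        Q = np.zeros((self.q, self.q))
        sb = self.block_slices["beta"]
        Q[sb, sb] = np.eye(self.p) / self.priors.beta_sd**2
        if "spatial" in self.block_slices:
            s = self.block_slices["spatial"]
            k2 = float(np.exp(2 * th["log_kappa"]))
            t2 = float(np.exp(2 * th["log_tau"]))
            Qs = t2 * (2.0 * k2 * self._G_dense + self._GCG_dense)
            Qs[np.diag_indices_from(Qs)] += t2 * k2**2 * self._c_diag
            Q[s, s] = Qs
        if "seasonal" in self.block_slices:
            s = self.block_slices["seasonal"]
            tau_s = float(np.exp(th["log_seasonal_prec"]))
            Q[s, s] = tau_s * self.R12 + _SUM_TO_ZERO_PREC * self.J12
        return Q

    def logdet_prior(self, th: dict) -> float:
        ld = -2.0 * self.p * np.log(self.priors.beta_sd)
        if "spatial" in self.block_slices:
            k2 = float(np.exp(2 * th["log_kappa"]))
            ld += (2.0 * self.m * th["log_tau"] + self._logdet_c
                   + 2.0 * float(np.sum(np.log(k2 + self._spde_eigs))))
        if "seasonal" in self.block_slices:
            tau_s = float(np.exp(th["log_seasonal_prec"]))
            sign, ld12 = np.linalg.slogdet(tau_s * self.R12 + _SUM_TO_ZERO_PREC * self.J12)
            ld += ld12
        return ld

    def log_prior_theta(self, th: dict) -> float:
        lp = 0.0
        pr = self.priors
        if "log_kappa" in self.hyper_names:
            lp += -0.5 * ((th["log_kappa"] - self.lk0) / pr.log_kappa_sd) ** 2
            lp += -0.5 * ((th["log_tau"] - self.lt0) / pr.log_tau_sd) ** 2
        if "log_seasonal_prec" in self.hyper_names:
            x = th["log_seasonal_prec"]
            lp += pr.seasonal_prec_shape * x - pr.seasonal_prec_rate * np.exp(x)
        if "log_size" in self.hyper_names:
            x = th["log_size"]
            lp += pr.size_shape * x - pr.size_rate * np.exp(x)
        return lp

    # -- inner Laplace -----------------------------------------------------
    def laplace(self, theta_free: np.ndarray):
        """Gaussian approximation at one hyperparameter point.

        Returns (log marginal posterior, mode u*, Cholesky of H, H) with
        H = Q_prior + B' W B the conditional precision of the latent field.
        """
        th = self.theta_dict(theta_free)
        size = float(np.exp(th["log_size"])) if "log_size" in self.hyper_names else None
        Q0 = self.prior_precision(th)
        B, y = self.B, self.y
        u = self._warm.copy()

        def pen_loglik(uv):
            eta = B @ uv
            mu = np.exp(self.log_offset + np.clip(eta, -30, 30))
            return float(np.sum(count_loglik(y, mu, self.family, size)) -
                         0.5 * uv @ (Q0 @ uv))

        obj = pen_loglik(u)
        converged = False
        chol = None
        for _ in range(self.settings.max_newton):
            eta = np.clip(B @ u, -30, 30)
            g, w = grad_hess_eta(y, eta, self.log_offset, self.family, size)
            z = eta + g / w
            Bw = B.multiply(w[:, None])
            H = Q0 + (B.T @ Bw).toarray()
            rhs = B.T @ (w * z)
            chol = cho_factor(H, lower=True)
            u_new = cho_solve(chol, rhs)
            # step-halving on the penalized log-likelihood
            step = 1.0
            for _half in range(8):
                cand = u + step * (u_new - u)
                obj_new = pen_loglik(cand)
                if obj_new >= obj - 1e-10:
                    break
                step *= 0.5
            delta = float(np.max(np.abs(cand - u)))
            u, obj = cand, obj_new
            if delta < self.settings.newton_tol * (1.0 + float(np.max(np.abs(u)))):
                converged = True
                break
        if not converged:
            self.n_newton_fail += 1
        self._warm = u.copy()

        logdet_q0 = self.logdet_prior(th)
        logdet_h = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        lp = (pen_loglik(u) + 0.5 * logdet_q0 - 0.5 * logdet_h
              + self.log_prior_theta(th))
        return lp, u, chol, H


def _integration_points(prob: _Problem, theta_star: np.ndarray, lp_star: float):
    """Axis design around the mode with moment-matched weights.

    Center plus one point at +/- z s_i per free hyperparameter, where s_i is
    the curvature-based scale along axis i; the weights reproduce the mean
    and the per-axis variance of a Gaussian with those scales exactly.
    """
    d = len(theta_star)
    if d == 0 or prob.settings.hyper_method == "eb":
        return [theta_star], np.array([1.0]), [lp_star]
    delta0 = 0.4
    scales = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = delta0
        lp_p, *_ = prob.laplace(theta_star + e)
        lp_m, *_ = prob.laplace(theta_star - e)
        curv = -(lp_p - 2 * lp_star + lp_m) / delta0**2
        scales[i] = 1.0 / np.sqrt(max(curv, 0.25))
    scales = np.clip(scales, 0.05, 2.0)
    z = max(1.3, np.sqrt(d))
    pts = [theta_star]
    for i in range(d):
        e = np.zeros(d)
        e[i] = z * scales[i]
        pts.append(theta_star + e)
        pts.append(theta_star - e)
    w_axis = 1.0 / (2.0 * z**2)
    weights = np.r_[1.0 - d / z**2, np.full(2 * d, w_axis)]
    return pts, weights, None


def fit(
    structure: ModelStructure,
    paired_table: pd.DataFrame,
    mesh: Mesh | None = None,
    priors: Priors | None = None,
    settings: FitSettings | None = None,
) -> FitResult:
    """Fit one model structure; see the module docstring for the contract."""
    priors = priors or Priors()
    settings = settings or FitSettings()
    prob = _Problem(structure, paired_table, mesh, priors, settings)

    theta0 = prob.theta_init()
    if len(theta0):
        res = minimize(
            lambda th: -prob.laplace(th)[0],
            theta0,
            method="Nelder-Mead",
            options={"maxfev": settings.max_hyper_evals, "xatol": 0.01, "fatol": 0.01},
        )
        theta_star = res.x
    else:
        theta_star = theta0
    lp_star, *_ = prob.laplace(theta_star)

    pts, weights, _ = _integration_points(prob, theta_star, lp_star)
    comps = []
    for th in pts:
        lp, u, chol, H = prob.laplace(th)
        Sigma = cho_solve(chol, np.eye(prob.q))
        comps.append({"theta": th, "lp": lp, "u": u, "L": np.linalg.cholesky(H),
                      "Sigma": Sigma})
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()

    if prob.n_newton_fail > 0:
        raise RuntimeError(
            f"inner Newton failed to converge at {prob.n_newton_fail} hyperparameter "
            f"point(s) within {settings.max_newton} iterations"
        )

    # mixture summaries of the latent field
    mean_u = sum(w * c["u"] for w, c in zip(weights, comps))
    ex2 = sum(w * (np.diag(c["Sigma"]) + c["u"] ** 2) for w, c in zip(weights, comps))
    sd_u = np.sqrt(np.maximum(ex2 - mean_u**2, 0.0))

    # posterior draws (for WAIC and prediction); seeded, the only randomness
    rng = np.random.default_rng(settings.seed)
    S = settings.n_draws
    counts = rng.multinomial(S, weights)
    u_draws = np.empty((S, prob.q))
    draw_sizes = np.empty(S) if prob.family == "negative_binomial" else None
    pos = 0
    for c, nk in zip(comps, counts):
        if nk == 0:
            continue
        zmat = rng.standard_normal((prob.q, nk))
        dev = solve_triangular(c["L"].T, zmat, lower=False)
        u_draws[pos:pos + nk] = (c["u"][:, None] + dev).T
        if draw_sizes is not None:
            th = prob.theta_dict(c["theta"])
            draw_sizes[pos:pos + nk] = np.exp(th["log_size"])
        pos += nk

    eta_draws = u_draws @ prob.B.T.toarray()  # (S, n)
    mu_draws = np.exp(prob.log_offset[None, :] + np.clip(eta_draws, -30, 30))
    if prob.family == "negative_binomial":
        ll = np.stack([
            count_loglik(prob.y, mu_draws[s], prob.family, draw_sizes[s])
            for s in range(S)
        ], axis=1)
    else:
        ll = np.stack([
            count_loglik(prob.y, mu_draws[s], prob.family) for s in range(S)
        ], axis=1)
    waic_val, p_waic = waic_from_loglik(ll)

    # assemble result tables
    sb = prob.block_slices["beta"]
    fixed = pd.DataFrame({
        "term": prob.term_names,
        "median": mean_u[sb],
        "sd": sd_u[sb],
    })
    spatial_df = None
    if "spatial" in prob.block_slices:
        s = prob.block_slices["spatial"]
        spatial_df = pd.DataFrame({
            "vertex": np.arange(prob.m),
            "median": mean_u[s],
            "sd": sd_u[s],
        })
    seasonal_df = None
    if "seasonal" in prob.block_slices:
        s = prob.block_slices["seasonal"]
        seasonal_df = pd.DataFrame({
            "month": np.arange(1, 13),
            "median": mean_u[s],
            "sd": sd_u[s],
        })

    eta_med = np.median(eta_draws, axis=0)
    eta_sd = eta_draws.std(axis=0)
    lin = pd.DataFrame({"eta_median": eta_med, "eta_sd": eta_sd})

    hyper_rows = []
    for w, c in zip(weights, comps):
        row = dict(zip(prob.free_names, c["theta"]))
        row.update({"lp": c["lp"], "weight": w})
        hyper_rows.append(row)
    hyper_points = pd.DataFrame(hyper_rows)

    th_star = prob.theta_dict(theta_star)
    hyper_summary: dict = {}
    if "log_kappa" in prob.hyper_names:
        params = SpdeParams(kappa=float(np.exp(th_star["log_kappa"])),
                            tau=float(np.exp(th_star["log_tau"])))
        hyper_summary["spatial_range"] = (params.range, float("nan"))
        hyper_summary["spatial_sd"] = (params.marginal_sd, float("nan"))
    if "log_seasonal_prec" in prob.hyper_names:
        hyper_summary["seasonal_prec"] = (float(np.exp(th_star["log_seasonal_prec"])), float("nan"))
    if "log_size" in prob.hyper_names:
        hyper_summary["nb_size"] = (float(np.exp(th_star["log_size"])), float("nan"))

    if not np.isfinite(waic_val):
        raise RuntimeError("non-finite WAIC")

    return FitResult(
        structure=structure,
        term_names=prob.term_names,
        transform=prob.transform,
        fixed_effects=fixed,
        spatial_field=spatial_df,
        seasonal_effects=seasonal_df,
        hyper_points=hyper_points,
        hyper_summary=hyper_summary,
        linear_predictor=lin,
        waic=waic_val,
        p_waic=p_waic,
        loglik_draws=ll,
        u_draws=u_draws,
        draw_sizes=draw_sizes,
        mesh=prob.mesh if structure.includes_spatial else None,
        block_slices=prob.block_slices,
        n_obs=len(prob.y),
    )


def waic_from_loglik(ll: np.ndarray) -> tuple[float, float]:
    """WAIC from an (n_obs, S) matrix of pointwise posterior log-likelihoods.

    lppd = sum_i log mean_s exp(l_is); p_waic = sum_i var_s(l_is) (sample
    variance, denominator S - 1); WAIC = -2 (lppd - p_waic).
    """
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2 or ll.shape[1] < 2:
        raise ValueError("need an (n_obs, S >= 2) log-likelihood matrix")
    S = ll.shape[1]
    lppd = float(np.sum(logsumexp(ll, axis=1) - np.log(S)))
    p_waic = float(np.sum(ll.var(axis=1, ddof=1)))
    return -2.0 * (lppd - p_waic), p_waic


def waic(fit_result: FitResult) -> tuple[float, float]:
    """(WAIC, p_waic) of a fit, recomputed from its stored pointwise draws."""
    return waic_from_loglik(fit_result.loglik_draws)
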