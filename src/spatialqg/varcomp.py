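"""REML linear mixed models with arbitrary random-effect covariances.

The observed phenotype vector y is modelled as

    y = X b + sum_k Z_k u_k + e,     u_k ~ N(0, s2_k G_k),  e ~ N(0, s2_e I)

where each random term k carries its own covariance G_k: the identity
(permanent environment, year, maternal), the pedigree A matrix (the
"animal" term, whose variance is V_A), the home-range overlap S matrix,
or a separable AR1xAR1 lattice correlation with estimated phi parameters.
Variance components are estimated by maximizing the restricted
log-likelihood

    l_R = -1/2 [ log|V| + log|X'V^-1 X| + y'Py + (n-p) log 2 pi ]

with V = sum_k s2_k Z_k G_k Z_k' + s2_e I and P the REML projection
matrix.  Optimization is bounded quasi-Newton on log-variances (variances
bound at zero externally) with seeded random restarts and a Newton polish;
standard errors come from the numerically differentiated Hessian at the
optimum.  The inference layer provides likelihood-ratio tests for random
effects, Wald tests for fixed effects, AIC, and variance partitions
(proportions, heritability) with delta-method standard errors.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.linalg import cho_factor, cho_solve, qr
from scipy.optimize import minimize

from .lattice import AR1xAR1Kernel, LatticeIndex
from .matrices import OverlapMatrix, RelationshipMatrix

logger = logging.getLogger(__name__)

_LOG_LB = np.log(1e-10)  # lower bound of log-variance (standardized scale)
_LOG_UB = np.log(1e4)
_PHI_BOUND_TOL = 1e-3


class ModelError(ValueError):
    """Raised for malformed model specifications or designs."""


# ---------------------------------------------------------------------------
# model specification


@dataclass
class FixedTerm:
    """One fixed-effect covariate.

    ``kind`` is "continuous" or "categorical" (inferred from dtype when
    None); continuous terms of ``degree`` d contribute the exact powers
    x, x^2, ..., x^d.
    """

    name: str
    kind: str | None = None
    degree: int = 1


@dataclass
class RandomTerm:
    """One variance component and its covariance structure.

    ``column`` names the phenotype-table column holding each
    observation's level (individual id, year, dam id, ...).  ``level_map``
    optionally re-maps those levels (e.g. individual -> lattice cell for a
    spatial term).  ``covariance`` is None for iid levels, a
    Relationship/Overlap matrix, or an :class:`AR1xAR1Kernel`.
    """

    label: str
    column: str
    variance_symbol: str
    covariance: RelationshipMatrix | AR1xAR1Kernel | None = None
    level_map: Mapping | None = None


@dataclass
class ModelSpec:
    """Declarative mixed-model description."""

    response: str
    fixed: list = field(default_factory=list)
    random: list = field(default_factory=list)
    log_transform: bool = False
    residual_symbol: str = "V_Residual"


def pe_term(column: str = "individual") -> RandomTerm:
    """Permanent-environment (among-individual, nongenetic) term."""
    return RandomTerm("permanent_environment", column, "V_PE")


def animal_term(A: RelationshipMatrix, column: str = "individual") -> RandomTerm:
    """Additive-genetic term: individual effect with covariance V_A * A."""
    return RandomTerm("animal", column, "V_A", covariance=A)


def year_term(column: str = "year") -> RandomTerm:
    return RandomTerm("year", column, "V_Year")


def maternal_term(column: str = "dam") -> RandomTerm:
    return RandomTerm("maternal", column, "V_M")


def smatrix_term(S: OverlapMatrix, column: str = "individual") -> RandomTerm:
    """Shared home-range term: covariance V_Smatrix * S."""
    return RandomTerm("smatrix", column, "V_Smatrix", covariance=S)


_SAC_SYMBOL = {
    ("col",): "V_Column",
    ("row",): "V_Row",
    ("row", "col"): "V_Columnandrow",
}


def sac_term(
    idx: LatticeIndex,
    axes: tuple[str, ...] = ("row", "col"),
    column: str = "individual",
    phi_bounds: tuple[float, float] = (0.0, 0.999),
) -> RandomTerm:
    """Spatial-autocorrelation term on the 100-m lattice.

    Individuals sharing a cell share one spatial effect; the effect
    covariance is the separable AR1 (row) x AR1 (col) correlation times
    the estimated spatial variance.
    """
    symbol = _SAC_SYMBOL.get(tuple(axes))
    if symbol is None:
        raise ModelError(f"unknown SAC axes {axes!r}")
    level_map = {i: (int(r), int(c)) for i, r, c in zip(idx.ids, idx.row, idx.col)}
    kernel = AR1xAR1Kernel(cells=idx.occupied_cells, axes=tuple(axes), phi_bounds=phi_bounds)
    return RandomTerm(
        "sac", column, symbol, covariance=kernel, level_map=level_map
    )


# ---------------------------------------------------------------------------
# design construction


@dataclass
class _ProcessedTerm:
    label: str
    symbol: str
    Z: sparse.csr_matrix
    G: np.ndarray | None          # dense covariance over observed levels
    kernel: AR1xAR1Kernel | None  # parametric covariance (SAC)
    levels: list


@dataclass
class DesignBundle:
    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    term_slices: dict[str, list[int]]
    terms: list[_ProcessedTerm]
    n_dropped: int
    index: np.ndarray


def _indicator(levels: Sequence, ordered: Sequence) -> sparse.csr_matrix:
    pos = {v: k for k, v in enumerate(ordered)}
    cols = np.array([pos[v] for v in levels], dtype=int)
    n = len(cols)
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), cols)), shape=(n, len(ordered))
    )


def build_design(spec: ModelSpec, data: pd.DataFrame) -> DesignBundle:
    """Response vector, fixed design and per-term incidence structures.

    Rows with a missing response, covariate or random-term level are
    dropped listwise (count logged).  Categorical covariates are coded
    against the first sorted level; the design is checked for full column
    rank and rank deficiency is an error naming the aliased columns.
    """
    fixed = [FixedTerm(t) if isinstance(t, str) else t for t in spec.fixed]
    needed = [spec.response] + [t.name for t in fixed] + [
        t.column for t in spec.random
    ]
    for col in dict.fromkeys(needed):
        if col not in data.columns:
            raise ModelError(f"column {col!r} not in phenotype table")
        if data[col].isna().all():
            raise ModelError(f"column {col!r} is entirely missing")
    work = data[list(dict.fromkeys(needed))].copy()
    before = len(work)
    work = work.dropna()
    n_dropped = before - len(work)
    if n_dropped:
        logger.info("dropped %d observations with missing values", n_dropped)
    if not len(work):
        raise ModelError("no observations left after missing-data filtering")

    y = work[spec.response].to_numpy(dtype=float)
    if spec.log_transform:
        if (y <= 0).any():
            raise ModelError("log transform requires a positive response")
        y = np.log(y)

    cols = [np.ones(len(work))]
    names = ["(Intercept)"]
    term_slices: dict[str, list[int]] = {}
    for t in fixed:
        kind = t.kind
        if kind is None:
            kind = (
                "continuous"
                if pd.api.types.is_numeric_dtype(work[t.name])
                else "categorical"
            )
        idxs = []
        if kind == "continuous":
            v = work[t.name].to_numpy(dtype=float)
            for d in range(1, t.degree + 1):
                idxs.append(len(names))
                names.append(t.name if d == 1 else f"{t.name}^{d}")
                cols.append(v**d)
        elif kind == "categorical":
            levels = sorted(map(str, work[t.name].unique()))
            vals = work[t.name].astype(str)
            for lev in levels[1:]:
                idxs.append(len(names))
                names.append(f"{t.name}[{lev}]")
                cols.append((vals == lev).to_numpy(dtype=float))
        else:
            raise ModelError(f"unknown fixed-term kind {kind!r}")
        term_slices[t.name] = idxs
    X = np.column_stack(cols)

    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
        raise ModelError(f"fixed design is rank deficient; aliased columns: {bad}")

    terms = []
    seen_identity_cols = set()
    for t in spec.random:
        raw = work[t.column]
        if t.level_map is not None:
            mapped = raw.map(lambda v: t.level_map.get(v, t.level_map.get(str(v))))
            if mapped.isna().any():
                missing = raw[mapped.isna()].iloc[0]
                raise ModelError(
                    f"level {missing!r} of term {t.label!r} has no mapping"
                )
            levels = list(mapped)
        else:
            levels = [str(v) for v in raw]
        observed = sorted(set(levels))
        Z = _indicator(levels, observed)
        G = None
        kernel = None
        if t.covariance is None:
            if t.column in seen_identity_cols:
                warnings.warn(
                    f"duplicate identity random term on {t.column!r}: the two "
                    "variances are not separately identifiable (only their sum)",
                    stacklevel=2,
                )
            seen_identity_cols.add(t.column)
        elif isinstance(t.covariance, AR1xAR1Kernel):
            kernel = AR1xAR1Kernel(
                cells=list(observed),
                axes=t.covariance.axes,
                phi_bounds=t.covariance.phi_bounds,
            )
        else:
            sub = t.covariance.index_of(observed)
            G = t.covariance.values[np.ix_(sub, sub)]
        terms.append(
            _ProcessedTerm(
                label=t.label, symbol=t.variance_symbol, Z=Z, G=G,
                kernel=kernel, levels=observed,
            )
        )
    return DesignBundle(
        y=y, X=X, x_names=names, term_slices=term_slices, terms=terms,
        n_dropped=n_dropped, index=work.index.to_numpy(),
    )


# ---------------------------------------------------------------------------
# fitted model containers


@dataclass
class VarianceEstimate:
    value: float
    se: float
    bound: bool = False


@dataclass
class FittedModel:
    """REML estimates plus everything the inference layer needs."""

    variance_estimates: dict[str, VarianceEstimate]
    phi_estimates: dict[str, VarianceEstimate]
    fixed_effects: pd.DataFrame
    fixed_cov: np.ndarray
    term_slices: dict[str, list[int]]
    restricted_loglik: float
    n_parameters: int
    converged: bool
    iterations: int
    trace: list[float]
    n_obs: int
    param_names: list[str]
    param_cov: np.ndarray
    data_fingerprint: str
    fixed_fingerprint: str
    spec: ModelSpec | None = None

    @property
    def sum_v(self) -> float:
        return float(sum(v.value for v in self.variance_estimates.values()))


@dataclass
class VariancePartition:
    proportions: dict[str, tuple[float, float]]
    h2: tuple[float, float]
    sum_v: float
    credibility_flag: bool = False


# ---------------------------------------------------------------------------
# REML engine


class _REMLProblem:
    def __init__(self, bundle: DesignBundle, scale: float):
        self.X = bundle.X
        self.n, self.p = self.X.shape
        self.y = bundle.y / np.sqrt(scale)
        self.y = self.y - 0.0  # contiguous copy
        self.terms = bundle.terms
        self.K = len(self.terms)
        # precompute dense ZGZ' for terms with fixed covariance
        self.VK: list[np.ndarray | None] = []
        for t in self.terms:
            if t.kernel is not None:
                self.VK.append(None)
            elif t.G is None:
                self.VK.append(np.asarray((t.Z @ t.Z.T).todense()))
            else:
                self.VK.append(np.asarray(t.Z @ (t.Z @ t.G).T).T)
        self.phi_slices: list[slice] = []
        off = self.K + 1
        for t in self.terms:
            nphi = t.kernel.n_phi if t.kernel is not None else 0
            self.phi_slices.append(slice(off, off + nphi))
            off += nphi
        self.n_par = off
        self.const = 0.5 * (self.n - self.p) * np.log(2 * np.pi)

    def split(self, t: np.ndarray):
        s2 = np.exp(t[: self.K + 1])
        phis = [t[sl] for sl in self.phi_slices]
        return s2, phis

    def build_V(self, s2: np.ndarray, phis: list[np.ndarray]) -> np.ndarray:
        V = s2[self.K] * np.eye(self.n)
        for k, term in enumerate(self.terms):
            if term.kernel is not None:
                G = term.kernel.correlation(phis[k])
                Vk = np.asarray(term.Z @ (term.Z @ G).T).T
            else:
                Vk = self.VK[k]
            V += s2[k] * Vk
        return V

    def _core(self, t: np.ndarray):
        s2, phis = self.split(t)
        V = self.build_V(s2, phis)
        try:
            L = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return None
        logdetV = 2.0 * np.log(np.diag(L[0])).sum()
        Vinv_X = cho_solve(L, self.X)
        M = self.X.T @ Vinv_X
        try:
            LM = cho_factor(M, lower=True)
        except np.linalg.LinAlgError:
            return None
        logdetM = 2.0 * np.log(np.diag(LM[0])).sum()
        Vinv_y = cho_solve(L, self.y)
        XtVy = self.X.T @ Vinv_y
        beta = cho_solve(LM, XtVy)
        Py = Vinv_y - Vinv_X @ beta
        quad = float(self.y @ Py)
        negll = 0.5 * (logdetV + logdetM + quad) + self.const
        return dict(
            negll=negll, L=L, LM=LM, Vinv_X=Vinv_X, Py=Py, beta=beta, M=M
        )

    def negloglik(self, t: np.ndarray) -> float:
        core = self._core(t)
        return np.inf if core is None else core["negll"]

    def negloglik_grad(self, t: np.ndarray) -> tuple[float, np.ndarray]:
        core = self._core(t)
        if core is None:
            return np.inf, np.zeros_like(t)
        s2, phis = self.split(t)
        g = np.zeros_like(t)
        L, Py, Vinv_X, LM = core["L"], core["Py"], core["Vinv_X"], core["LM"]
        Vinv = cho_solve(L, np.eye(self.n))
        Minv_Xv = cho_solve(LM, Vinv_X.T)
        for k in range(self.K + 1):
            if k < self.K and self.terms[k].kernel is not None:
                term = self.terms[k]
                G = term.kernel.correlation(phis[k])
                Vk = np.asarray(term.Z @ (term.Z @ G).T).T
            elif k < self.K:
                Vk = self.VK[k]
            else:
                Vk = None  # identity
            if Vk is None:
                trPV = np.trace(Vinv) - np.einsum(
                    "ij,ji->", Minv_Xv, Vinv_X
                )
                quad = float(Py @ Py)
            else:
                trPV = np.einsum("ij,ij->", Vinv, Vk) - np.einsum(
                    "ij,jk,ki->", Minv_Xv, Vk, Vinv_X
                )
                quad = float(Py @ (Vk @ Py))
            # d(-l)/d s2 * s2  (log-scale chain rule)
            g[k] = 0.5 * (trPV - quad) * s2[k]
        # phi coordinates by central differences
        for sl in self.phi_slices:
            for j in range(sl.start, sl.stop):
                h = 1e-5
                tp = t.copy(); tp[j] += h
                tm = t.copy(); tm[j] -= h
                g[j] = (self.negloglik(tp) - self.negloglik(tm)) / (2 * h)
        return core["negll"], g


def _numeric_hessian(f, t: np.ndarray, steps: np.ndarray) -> np.ndarray:
    p = len(t)
    H = np.zeros((p, p))
    f0 = f(t)
    for i in range(p):
        for j in range(i, p):
            hi, hj = steps[i], steps[j]
            if i == j:
                tp = t.copy(); tp[i] += hi
                tm = t.copy(); tm[i] -= hi
                H[i, i] = (f(tp) - 2 * f0 + f(tm)) / hi**2
            else:
                tpp = t.copy(); tpp[i] += hi; tpp[j] += hj
                tpm = t.copy(); tpm[i] += hi; tpm[j] -= hj
                tmp = t.copy(); tmp[i] -= hi; tmp[j] += hj
                tmm = t.copy(); tmm[i] -= hi; tmm[j] -= hj
                H[i, j] = H[j, i] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (
                    4 * hi * hj
                )
    return H


def reml_fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    tolerance: float = 1e-10,
    max_iter: int = 300,
    n_starts: int = 3,
    seed_for_starts: int = 0,
    compute_se: bool = True,
) -> FittedModel:
    """Fit a mixed model by REML.

    The response is standardized internally (variances optimized on a log
    scale, AR1 phis on their bounded natural scale); estimates and the
    restricted log-likelihood are reported on the original scale.  The
    best of ``n_starts`` seeded starting points is polished with Newton
    steps, so the optimum is located to high precision whenever it is
    interior.  Variance components whose optimum lies at the zero
    boundary are reported as 0 with the bound flag set.
    """
    bundle = build_design(spec, data)
    vy = float(np.var(bundle.y, ddof=1))
    if not vy > 0:
        raise ModelError("response has zero variance")
    prob = _REMLProblem(bundle, vy)
    K = prob.K

    bounds = [(_LOG_LB, _LOG_UB)] * (K + 1)
    phi_names: list[str] = []
    for term in prob.terms:
        if term.kernel is not None:
            lo, hi = term.kernel.phi_bounds
            for nm in term.kernel.phi_names:
                phi_names.append(f"{term.label}:{nm}")
                bounds.append((lo, hi))
    bounds_arr = np.array(bounds)

    rng = np.random.default_rng(seed_for_starts)
    starts = []
    base = np.empty(prob.n_par)
    base[: K + 1] = np.log(1.0 / (K + 1))
    for i, (lo, hi) in enumerate(bounds[K + 1 :], start=K + 1):
        base[i] = lo + 0.5 * (hi - lo)
    starts.append(base)
    for _ in range(max(0, n_starts - 1)):
        s = base.copy()
        s[: K + 1] += rng.normal(0, 1.2, K + 1)
        for i, (lo, hi) in enumerate(bounds[K + 1 :], start=K + 1):
            s[i] = rng.uniform(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo))
        starts.append(s)

    best = None
    trace: list[float] = []
    total_iters = 0
    for s in starts:
        run_trace: list[float] = []

        def cb(tk):
            val = prob.negloglik(tk)
            run_trace.append(
                -val if not run_trace else max(-val, run_trace[-1])
            )

        res = minimize(
            prob.negloglik_grad,
            s,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            callback=cb,
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
        )
        total_iters += res.nit
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x, res.success, run_trace)
    fbest, t_opt, success, trace = best

    # Newton polish on coordinates away from their bounds
    t = t_opt.copy()
    for _ in range(15):
        f, g = prob.negloglik_grad(t)
        at_lo = t <= bounds_arr[:, 0] + 1e-8
        at_hi = t >= bounds_arr[:, 1] - 1e-8
        free = ~((at_lo & (g > 0)) | (at_hi & (g < 0)))
        if not free.any() or np.max(np.abs(g[free])) < tolerance:
            break
        idx = np.flatnonzero(free)

        def gfun(sub):
            tt = t.copy()
            tt[idx] = sub
            return prob.negloglik_grad(tt)[1][idx]

        h = 1e-5
        Hs = np.zeros((len(idx), len(idx)))
        for a in range(len(idx)):
            tp = t[idx].copy(); tp[a] += h
            tm = t[idx].copy(); tm[a] -= h
            Hs[:, a] = (gfun(tp) - gfun(tm)) / (2 * h)
        Hs = (Hs + Hs.T) / 2
        try:
            step = np.linalg.solve(Hs + 1e-12 * np.eye(len(idx)), -g[idx])
        except np.linalg.LinAlgError:
            break
        scale_bt = 1.0
        improved = False
        for _bt in range(8):
            t_new = t.copy()
            t_new[idx] = t[idx] + scale_bt * step
            t_new = np.clip(t_new, bounds_arr[:, 0], bounds_arr[:, 1])
            f_new = prob.negloglik(t_new)
            if f_new <= f + 1e-15:
                improved = f_new < f - 1e-15 or not np.allclose(t_new, t)
                t = t_new
                break
            scale_bt *= 0.25
        if not improved:
            break
    f_final = prob.negloglik(t)
    if f_final <= fbest:
        t_opt, fbest = t, f_final
    if trace and -fbest > trace[-1]:
        trace = trace + [-fbest]

    s2_std, phis = prob.split(t_opt)
    n, p = prob.n, prob.p
    # report on the original response scale
    loglik = -fbest - 0.5 * (n - p) * np.log(vy)

    # natural-scale parameter vector for the Hessian: variances then phis
    nat = np.concatenate([s2_std, np.concatenate(phis) if phi_names else []])
    var_bound = s2_std <= 1e-8
    phi_flat = np.concatenate(phis) if phi_names else np.array([])
    phi_bound = np.zeros(len(phi_flat), dtype=bool)
    off = 0
    for term in prob.terms:
        if term.kernel is not None:
            lo, hi = term.kernel.phi_bounds
            for _ in range(term.kernel.n_phi):
                phi_bound[off] = (
                    phi_flat[off] <= lo + _PHI_BOUND_TOL
                    or phi_flat[off] >= hi - _PHI_BOUND_TOL
                )
                off += 1

    def f_nat(v: np.ndarray) -> float:
        tt = np.empty(prob.n_par)
        tt[: K + 1] = np.log(np.maximum(v[: K + 1], 1e-300))
        tt[K + 1 :] = v[K + 1 :]
        return prob.negloglik(tt)

    free_mask = np.concatenate([~var_bound, ~phi_bound]).astype(bool)
    param_cov = np.zeros((prob.n_par, prob.n_par))
    if compute_se and free_mask.any():
        idx = np.flatnonzero(free_mask)
        steps = np.maximum(1e-6, 1e-4 * np.abs(nat[idx]))

        def f_sub(sub):
            v = nat.copy()
            v[idx] = sub
            return f_nat(v)

        H = _numeric_hessian(f_sub, nat[idx].copy(), steps)
        try:
            cov_sub = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_sub = np.linalg.pinv(H)
        param_cov[np.ix_(idx, idx)] = cov_sub

    # scale variances (and their covariance) back to the original units
    scale_vec = np.concatenate(
        [np.full(K + 1, vy), np.ones(len(phi_flat))]
    )
    param_cov = param_cov * np.outer(scale_vec, scale_vec)
    s2 = s2_std * vy

    symbols = [term.symbol for term in prob.terms] + [spec.residual_symbol]
    variance_estimates = {}
    for k, sym in enumerate(symbols):
        val = 0.0 if var_bound[k] else float(s2[k])
        se = float(np.sqrt(max(param_cov[k, k], 0.0)))
        variance_estimates[sym] = VarianceEstimate(val, se, bool(var_bound[k]))
    phi_estimates = {}
    for j, nm in enumerate(phi_names):
        jj = K + 1 + j
        phi_estimates[nm] = VarianceEstimate(
            float(phi_flat[j]),
            float(np.sqrt(max(param_cov[jj, jj], 0.0))),
            bool(phi_bound[j]),
        )

    # fixed effects at the optimum, on the original scale
    core = prob._core(t_opt)
    beta = core["beta"] * np.sqrt(vy)
    C = np.linalg.inv(core["M"]) * vy
    fixed_effects = pd.DataFrame(
        {
            "term": bundle.x_names,
            "estimate": beta,
            "se": np.sqrt(np.diag(C)),
        }
    )

    fp_data = hashlib.sha1(
        bundle.y.tobytes() + bundle.index.tobytes()
    ).hexdigest()
    fp_fixed = hashlib.sha1(bundle.X.tobytes()).hexdigest()

    converged = bool(success) or np.max(
        np.abs(prob.negloglik_grad(t_opt)[1][free_mask])
    ) < 1e-3 if free_mask.any() else bool(success)
    if not converged:
        logger.warning("REML did not converge after %d iterations", total_iters)

    return FittedModel(
        variance_estimates=variance_estimates,
        phi_estimates=phi_estimates,
        fixed_effects=fixed_effects,
        fixed_cov=C,
        term_slices=bundle.term_slices,
        restricted_loglik=float(loglik),
        n_parameters=prob.n_par,
        converged=converged,
        iterations=int(total_iters),
        trace=trace,
        n_obs=n,
        param_names=symbols + phi_names,
        param_cov=param_cov,
        data_fingerprint=fp_data,
        fixed_fingerprint=fp_fixed,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# inference layer


def lrt(null_fit: FittedModel, alt_fit: FittedModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested REML fits.

    chi2 = 2 (l_alt - l_null) truncated at 0; df is the difference in the
    number of estimated (co)variance parameters; the p-value uses the
    naive chi-square upper tail (no boundary mixture).
    """
    if null_fit.data_fingerprint != alt_fit.data_fingerprint:
        raise ModelError("LRT requires fits on identical data")
    if null_fit.fixed_fingerprint != alt_fit.fixed_fingerprint:
        raise ModelError("LRT requires identical fixed effects")
    chi2 = max(0.0, 2.0 * (alt_fit.restricted_loglik - null_fit.restricted_loglik))
    df = alt_fit.n_parameters - null_fit.n_parameters
    if df < 0:
        raise ModelError("null model has more parameters than the alternative")
    if df == 0:
        p = 1.0 if chi2 == 0.0 else 0.0
    else:
        p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def wald_fixed(fit: FittedModel) -> pd.DataFrame:
    """Joint Wald chi-square per fixed-effect term."""
    if not fit.converged:
        raise ModelError("Wald tests require a converged fit")
    rows = []
    beta = fit.fixed_effects["estimate"].to_numpy()
    for term, idxs in fit.term_slices.items():
        if not idxs:
            continue
        b = beta[idxs]
        C = fit.fixed_cov[np.ix_(idxs, idxs)]
        try:
            stat = float(b @ np.linalg.solve(C, b))
        except np.linalg.LinAlgError:
            raise ModelError(f"singular coefficient covariance for {term!r}")
        df = len(idxs)
        rows.append(
            {"term": term, "wald_chi2": stat, "df": df,
             "p": float(stats.chi2.sf(stat, df))}
        )
    return pd.DataFrame(rows, columns=["term", "wald_chi2", "df", "p"])


def partition(
    fit: FittedModel,
    baseline_sum_v: float | None = None,
    credibility_factor: float = 3.0,
) -> VariancePartition:
    """Variance proportions, heritability and the Sum-V credibility check.

    Each component (including the residual) is divided by the total; the
    heritability h2 = V_A / Sum V is reported in percent.  Standard errors
    come from the delta method applied to the variance-parameter
    covariance.  ``credibility_flag`` is raised when Sum V differs from a
    supplied baseline by more than ``credibility_factor``-fold — the guard
    against fits whose total variance explodes.
    """
    if not fit.converged:
        raise ModelError("partition requires a converged fit")
    symbols = list(fit.variance_estimates)
    theta = np.array([fit.variance_estimates[s].value for s in symbols])
    total = float(theta.sum())
    if total <= 0:
        raise ModelError("total variance is not positive")
    kv = len(symbols)
    cov = fit.param_cov[:kv, :kv]
    proportions = {}
    for k, sym in enumerate(symbols):
        grad = -theta / total**2
        grad[k] += 1.0 / total
        se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        proportions[sym] = (float(theta[k] / total), se)
    if "V_A" in symbols:
        k = symbols.index("V_A")
        h2 = (100.0 * proportions["V_A"][0], 100.0 * proportions["V_A"][1])
    else:
        h2 = (0.0, 0.0)
    flag = False
    if baseline_sum_v is not None and baseline_sum_v > 0:
        ratio = total / baseline_sum_v
        flag = ratio > credibility_factor or ratio < 1.0 / credibility_factor
    return VariancePartition(
        proportions=proportions, h2=h2, sum_v=total, credibility_flag=flag
    )


def aic(fit: FittedModel) -> float:
    """REML AIC: -2 l_R + 2 (number of variance parameters).

    Comparable only across fits sharing the same fixed effects and data;
    use :func:`compare_aic` for a checked table.
    """
    if not fit.converged:
        raise ModelError("AIC requires a converged fit")
    return -2.0 * fit.restricted_loglik + 2.0 * fit.n_parameters


def compare_aic(fits: Mapping[str, FittedModel]) -> pd.DataFrame:
    """AIC table over fits with identical data and fixed effects."""
    items = list(fits.items())
    ref = items[0][1]
    for name, f in items[1:]:
        if f.fixed_fingerprint != ref.fixed_fingerprint:
            raise ModelError(
                f"fit {name!r} has different fixed effects; REML AICs are "
                "not comparable"
            )
        if f.data_fingerprint != ref.data_fingerprint:
            raise ModelError(f"fit {name!r} was fitted to different data")
    rows = [
        {"model": name, "aic": aic(f), "n_parameters": f.n_parameters}
        for name, f in items
    ]
    out = pd.DataFrame(rows).sort_values("aic", kind="stable")
    out["delta_aic"] = out["aic"] - out["aic"].min()
    return out.reset_index(drop=True)
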