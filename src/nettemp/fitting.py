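"""Multigroup maximum-likelihood Ising fitting with equality constraints.

Four nested constraint levels tie parameters across groups (measurement
occasions):

1. SATURATED              every group has free edges and thresholds; beta = 1
                          everywhere (scale unidentified).
2. EQUAL_EDGES            one shared edge matrix; per-group thresholds; beta
                          free from group 2 onward with beta_1 = 1 for
                          identification.
3. EQUAL_EDGES_THRESHOLDS shared edges and thresholds; beta free from group 2.
4. EQUAL_ALL              everything shared; beta = 1 everywhere.

Each level may be fitted DENSE (all p(p-1)/2 edges) or SPARSE (edges removed
by backward stepwise Wald pruning).  The likelihood is exact (enumeration of
the 2^p states per group) and is computed from sufficient statistics, so the
cost of an objective evaluation does not depend on sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2 as chi2_dist

from .ising import (ENUMERATION_LIMIT, Encoding, IsingParameters,
                    _pair_products, _state_matrix)
from .panel import BinaryPanel


class ConstraintLevel(str, Enum):
    SATURATED = "saturated"
    EQUAL_EDGES = "equal_edges"
    EQUAL_EDGES_THRESHOLDS = "equal_edges_thresholds"
    EQUAL_ALL = "equal_all"


class Structure(str, Enum):
    DENSE = "dense"
    SPARSE = "sparse"


#: constraint levels in which beta_g (g >= 2) is a free parameter
BETA_FREE_LEVELS = (ConstraintLevel.EQUAL_EDGES,
                    ConstraintLevel.EQUAL_EDGES_THRESHOLDS)


@dataclass
class MultigroupModelSpec:
    """Constraint level x structure x encoding; defines the free parameters."""

    constraint_level: ConstraintLevel
    structure: Structure = Structure.DENSE
    sparse_alpha: float = 0.01
    encoding: Encoding | None = None
    edge_mask: np.ndarray | None = None  # boolean over pairs i<j; None = all

    def __post_init__(self) -> None:
        self.constraint_level = ConstraintLevel(self.constraint_level)
        self.structure = Structure(self.structure)
        if self.encoding is not None:
            self.encoding = Encoding(self.encoding)
        if not 0 < self.sparse_alpha < 1:
            raise ValueError("sparse_alpha must be in (0, 1)")
        if self.edge_mask is not None:
            self.edge_mask = np.asarray(self.edge_mask, dtype=bool)

    def mask_for(self, p: int) -> np.ndarray:
        n_pairs = p * (p - 1) // 2
        if self.edge_mask is None:
            return np.ones(n_pairs, dtype=bool)
        if self.edge_mask.shape != (n_pairs,):
            raise ValueError("edge_mask length must be p(p-1)/2")
        return self.edge_mask


@dataclass
class FitOptions:
    max_iter: int = 500
    ftol: float = 1e-12          # relative log-likelihood change
    gtol: float = 1e-7           # L-BFGS-B gradient tolerance
    newton_tol: float = 1e-9     # target max |grad| per observation
    max_newton: int = 40
    compute_se: bool = True
    theta0: np.ndarray | None = None
    enumeration_limit: int = ENUMERATION_LIMIT


class _ParameterMap:
    """Packs/unpacks the free-parameter vector for a given spec and shape."""

    def __init__(self, spec: MultigroupModelSpec, G: int, p: int):
        self.spec = spec
        self.G, self.p = G, p
        self.mask = spec.mask_for(p)
        self.E = int(self.mask.sum())
        level = spec.constraint_level
        self.shared_omega = level is not ConstraintLevel.SATURATED
        self.shared_tau = level in (ConstraintLevel.EQUAL_EDGES_THRESHOLDS,
                                    ConstraintLevel.EQUAL_ALL)
        self.beta_free = level in BETA_FREE_LEVELS and G > 1
        self.names: list[str] = []
        self.omega_slices: list[slice] = []
        self.tau_slices: list[slice] = []
        pos = 0
        iu, ju = np.triu_indices(p, k=1)
        pairs = [(int(i) + 1, int(j) + 1)
                 for i, j in zip(iu[self.mask], ju[self.mask])]
        n_om_blocks = 1 if self.shared_omega else G
        for b in range(n_om_blocks):
            tag = "" if self.shared_omega else f"[g{b+1}]"
            self.omega_slices.append(slice(pos, pos + self.E))
            self.names += [f"omega{tag}_{i}_{j}" for i, j in pairs]
            pos += self.E
        n_tau_blocks = 1 if self.shared_tau else G
        for b in range(n_tau_blocks):
            tag = "" if self.shared_tau else f"[g{b+1}]"
            self.tau_slices.append(slice(pos, pos + p))
            self.names += [f"tau{tag}_{i+1}" for i in range(p)]
            pos += p
        if self.beta_free:
            self.logbeta_slice = slice(pos, pos + G - 1)
            self.names += [f"log_beta[g{g+2}]" for g in range(G - 1)]
            pos += G - 1
        else:
            self.logbeta_slice = slice(pos, pos)
        self.k = pos

    def unpack(self, theta: np.ndarray
               ) -> list[tuple[np.ndarray, np.ndarray, float]]:
        """Per-group (tau, retained-edge weights, beta)."""
        out = []
        for g in range(self.G):
            om = theta[self.omega_slices[0 if self.shared_omega else g]]
            tau = theta[self.tau_slices[0 if self.shared_tau else g]]
            if self.beta_free:
                beta = 1.0 if g == 0 else float(
                    np.exp(theta[self.logbeta_slice][g - 1]))
            else:
                beta = 1.0
            out.append((tau, om, beta))
        return out

    def omega_matrix(self, omega_vec: np.ndarray) -> np.ndarray:
        full = np.zeros(self.p * (self.p - 1) // 2)
        full[self.mask] = omega_vec
        mat = np.zeros((self.p, self.p))
        iu, ju = np.triu_indices(self.p, k=1)
        mat[iu, ju] = full
        return mat + mat.T


@dataclass
class MultigroupFit:
    """Point estimates, likelihood, parameter counts and convergence record."""

    spec: MultigroupModelSpec
    groups: list[IsingParameters]
    loglik: float
    k: int
    n_per_group: list[int]
    theta: np.ndarray
    free_names: list[str]
    se: np.ndarray | None
    vcov: np.ndarray | None
    converged: bool
    iterations: int
    gradient_norm: float
    ages: list[float]
    item_names: list[str]
    edge_mask: np.ndarray

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_group))

    @property
    def G(self) -> int:
        return len(self.groups)

    @property
    def betas(self) -> np.ndarray:
        return np.array([g.beta for g in self.groups])

    def beta_free_indices(self) -> slice:
        """Location of the log-beta entries in the free-parameter vector."""
        pm = _ParameterMap(self.spec, self.G, self.groups[0].p)
        return pm.logbeta_slice


def _panel_stats(panels: list[BinaryPanel]
                 ) -> list[tuple[int, np.ndarray, np.ndarray]]:
    return [pan.sufficient_stats() for pan in panels]


def _stats_from_counts(counts: np.ndarray, p: int, encoding: Encoding
                       ) -> tuple[int, np.ndarray, np.ndarray]:
    """Sufficient statistics of a panel summarized as 2^p state counts."""
    X = _state_matrix(p, encoding)
    XP = _pair_products(p, encoding)
    return int(counts.sum()), counts @ X, counts @ XP


class _Objective:
    """Negative multigroup log-likelihood with analytic gradient and Hessian.

    Exponential-family structure makes both exact: with t(x) the stacked
    sufficient statistics (x, pairwise products) and u = (tau, omega), each
    group contributes gradient beta * (T_obs - n * E[t]) and Hessian blocks
    built from n * beta^2 * Cov[t] under the current fitted distribution.
    """

    def __init__(self, stats, pmap: _ParameterMap, encoding: Encoding):
        self.stats = stats
        self.pmap = pmap
        p = pmap.p
        self.X = _state_matrix(p, encoding)
        self.XP = _pair_products(p, encoding)[:, pmap.mask]
        self.St = np.hstack([self.X, self.XP])  # (2^p, p + E)
        self.cm = [c[pmap.mask] for (_, _, c) in stats]

    def _group_indices(self, g: int) -> np.ndarray:
        """Free-vector indices of (tau_g, omega_g), in that order."""
        pm = self.pmap
        tau_sl = pm.tau_slices[0 if pm.shared_tau else g]
        om_sl = pm.omega_slices[0 if pm.shared_omega else g]
        return np.concatenate([np.arange(tau_sl.start, tau_sl.stop),
                               np.arange(om_sl.start, om_sl.stop)])

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        pm = self.pmap
        f = 0.0
        grad = np.zeros(pm.k)
        per_group = pm.unpack(theta)
        for g, ((n, s, _), cm) in enumerate(zip(self.stats, self.cm)):
            tau, om, beta = per_group[g]
            negE = self.X @ tau + self.XP @ om      # -H(x) for all states
            eta = beta * negE
            logZ = logsumexp(eta)
            obs = tau @ s + om @ cm                  # observed -H total
            f -= beta * obs - n * logZ
            probs = np.exp(eta - logZ)
            mu = probs @ self.X
            mp = probs @ self.XP
            g_tau = beta * (s - n * mu)
            g_om = beta * (cm - n * mp)
            grad[pm.tau_slices[0 if pm.shared_tau else g]] -= g_tau
            grad[pm.omega_slices[0 if pm.shared_omega else g]] -= g_om
            if pm.beta_free and g >= 1:
                d_beta = obs - n * (tau @ mu + om @ mp)
                grad[pm.logbeta_slice][g - 1] -= beta * d_beta
        return f, grad

    def __call__(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        return self.value_and_grad(theta)

    def hessian(self, theta: np.ndarray) -> np.ndarray:
        """Exact Hessian of the negative log-likelihood."""
        pm = self.pmap
        H = np.zeros((pm.k, pm.k))
        per_group = pm.unpack(theta)
        for g, ((n, s, _), cm) in enumerate(zip(self.stats, self.cm)):
            tau, om, beta = per_group[g]
            u = np.concatenate([tau, om])
            t_obs = np.concatenate([s, cm])
            eta = beta * (self.St @ u)
            logZ = logsumexp(eta)
            probs = np.exp(eta - logZ)
            mu = probs @ self.St
            cov = (self.St.T * probs) @ self.St - np.outer(mu, mu)
            idx = self._group_indices(g)
            H[np.ix_(idx, idx)] += n * beta**2 * cov
            if pm.beta_free and g >= 1:
                j = self.pmap.logbeta_slice.start + g - 1
                dl_dbeta = u @ (t_obs - n * mu)
                h_ub = (t_obs - n * mu) - n * beta * (cov @ u)
                H[idx, j] += -beta * h_ub
                H[j, idx] += -beta * h_ub
                H[j, j] += beta**2 * (n * u @ cov @ u) - beta * dl_dbeta
        return H


def _fd_hessian(grad_fn, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from the analytic gradient."""
    k = theta.size
    H = np.empty((k, k))
    for i in range(k):
        step = h * (1.0 + abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += step
        tm[i] -= step
        H[i] = (grad_fn(tp)[1] - grad_fn(tm)[1]) / (2 * step)
    return 0.5 * (H + H.T)


def _initial_theta(stats, pmap: _ParameterMap, encoding: Encoding
                   ) -> np.ndarray:
    """tau from independent-item logistic closed form; omega = 0; log beta = 0."""
    theta = np.zeros(pmap.k)
    props = []
    for (n, s, _) in stats:
        if encoding is Encoding.PM1:
            prop = (s / n + 1.0) / 2.0
        else:
            prop = s / n
        props.append(np.clip(prop, 1.0 / (2 * n + 2), 1 - 1.0 / (2 * n + 2)))
    scale = 0.5 if encoding is Encoding.PM1 else 1.0
    if pmap.shared_tau:
        pooled_n = sum(n for (n, _, _) in stats)
        pooled = sum(n * pr for (n, _, _), pr in zip(stats, props)) / pooled_n
        theta[pmap.tau_slices[0]] = scale * np.log(pooled / (1 - pooled))
    else:
        for g, pr in enumerate(props):
            theta[pmap.tau_slices[g]] = scale * np.log(pr / (1 - pr))
    return theta


def _fit_from_stats(stats, spec: MultigroupModelSpec, encoding: Encoding,
                    p: int, item_names: list[str], ages: list[float],
                    options: FitOptions | None = None) -> MultigroupFit:
    options = options or FitOptions()
    G = len(stats)
    if p > options.enumeration_limit:
        raise ValueError(f"p={p} exceeds enumeration limit "
                         f"{options.enumeration_limit}")
    if G == 1 and spec.constraint_level in BETA_FREE_LEVELS:
        raise ValueError(
            "beta is unidentified with a single group; use SATURATED or "
            "EQUAL_ALL for one occasion"
        )
    pmap = _ParameterMap(spec, G, p)
    obj = _Objective(stats, pmap, encoding)
    theta0 = (np.asarray(options.theta0, dtype=float)
              if options.theta0 is not None
              else _initial_theta(stats, pmap, encoding))
    if theta0.shape != (pmap.k,):
        raise ValueError("theta0 has wrong length for this spec")

    n_total = sum(n for (n, _, _) in stats)
    res = minimize(obj, theta0, jac=True, method="L-BFGS-B",
                   options=dict(maxiter=options.max_iter,
                                ftol=options.ftol, gtol=options.gtol))
    theta = res.x
    iterations = int(res.nit)

    # Newton polish: quadratic convergence to a sharp optimum, needed for
    # exact saturated moments and encoding-equivariance of the estimates.
    f, grad = obj(theta)
    target = options.newton_tol * max(n_total, 1)
    for _ in range(options.max_newton):
        if np.max(np.abs(grad)) <= target:
            break
        H = obj.hessian(theta)
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H + 1e-8 * np.eye(pmap.k), -grad,
                                   rcond=None)[0]
        # backtracking line search on the objective
        t = 1.0
        for _ls in range(30):
            f_new, grad_new = obj(theta + t * step)
            if np.isfinite(f_new) and f_new <= f + 1e-4 * t * (grad @ step):
                break
            t *= 0.5
        else:
            break  # no admissible step; stop polishing
        theta = theta + t * step
        stalled = (abs(f - f_new) <= options.ftol * (abs(f) + 1)
                   and np.max(np.abs(grad_new)) >= np.max(np.abs(grad)))
        f, grad = f_new, grad_new
        iterations += 1
        if stalled:
            break

    grad_norm = float(np.max(np.abs(grad)) / max(n_total, 1))
    converged = bool(np.max(np.abs(grad)) <= target or grad_norm < 1e-5)
    if not converged:
        warnings.warn(
            f"fit did not fully converge (scaled gradient max-norm "
            f"{grad_norm:.2e})", RuntimeWarning)

    se = vcov = None
    if options.compute_se and pmap.k > 0:
        H = obj.hessian(theta)
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(vcov), 0, None))

    per_group = pmap.unpack(theta)
    groups = []
    for (tau, om, beta) in per_group:
        groups.append(IsingParameters(pmap.omega_matrix(om), tau.copy(),
                                      beta, encoding))
    if pmap.beta_free:
        sl = pmap.omega_slices[0]
        om_hat = np.abs(theta[sl])
        if se is not None and sl.stop > sl.start:
            near_zero = np.all(om_hat < 2.0 * se[sl])
        else:
            near_zero = np.all(om_hat < 1e-4)
        if near_zero:
            warnings.warn(
                "no edge in the shared matrix is distinguishable from zero: "
                "beta is weakly identified and its estimates are unreliable",
                RuntimeWarning)

    return MultigroupFit(
        spec=spec, groups=groups, loglik=float(-f), k=pmap.k,
        n_per_group=[int(n) for (n, _, _) in stats],
        theta=theta, free_names=pmap.names, se=se, vcov=vcov,
        converged=converged, iterations=iterations,
        gradient_norm=grad_norm, ages=list(ages),
        item_names=list(item_names), edge_mask=pmap.mask.copy(),
    )


def fit_multigroup(panels: list[BinaryPanel], spec: MultigroupModelSpec,
                   options: FitOptions | None = None) -> MultigroupFit:
    """Joint maximum-likelihood fit of all occasions under the spec.

    The first occasion's beta is fixed to 1 for identification whenever beta
    varies; SATURATED and EQUAL_ALL fix every beta to 1 (the scale is
    unidentified in the first and fully tied in the second).
    """
    if not panels:
        raise ValueError("need at least one panel")
    p = panels[0].p
    names = panels[0].item_names
    enc = panels[0].encoding
    for pan in panels:
        if pan.p != p or list(pan.item_names) != list(names):
            raise ValueError("panels have inconsistent item sets")
        if pan.encoding != enc:
            raise ValueError("panels have inconsistent encodings")
        if pan.has_missing:
            raise ValueError(
                "complete data required; use the reader's listwise policy "
                "to drop incomplete rows"
            )
    if spec.encoding is not None and spec.encoding != enc:
        raise ValueError("spec encoding differs from panel encoding")
    stats = _panel_stats(panels)
    ages = [pan.age for pan in panels]
    return _fit_from_stats(stats, spec, enc, p, list(names), ages, options)


def edge_wald_pvalues(fit: MultigroupFit) -> np.ndarray:
    """Two-sided Wald p-value per retained edge (combined across groups).

    Shared-edge specs give a 1-df chi-squared per edge; the saturated spec
    has per-group edge estimates, combined as a sum of squared z-scores
    (G degrees of freedom).
    """
    if fit.se is None:
        raise ValueError("fit carries no standard errors")
    pmap = _ParameterMap(fit.spec, fit.G, fit.groups[0].p)
    E = pmap.E
    z2 = np.zeros(E)
    dof = 1 if pmap.shared_omega else fit.G
    blocks = [pmap.omega_slices[0]] if pmap.shared_omega else pmap.omega_slices
    for sl in blocks:
        est = fit.theta[sl]
        se = fit.se[sl]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, est / se, np.inf)
        z2 += z**2
    return chi2_dist.sf(z2, dof)


def prune_edges(panels: list[BinaryPanel], spec: MultigroupModelSpec,
                options: FitOptions | None = None) -> MultigroupModelSpec:
    """Backward stepwise Wald pruning toward a sparse structure.

    Starting from the dense fit at the same constraint level, repeatedly
    removes the single least-significant edge whose two-sided p-value
    exceeds ``spec.sparse_alpha`` (worst first; ties broken toward the
    lexicographically smaller (i, j) pair), refitting after each removal.
    Returns a SPARSE spec carrying the retained edge mask.
    """
    p = panels[0].p
    iu, ju = np.triu_indices(p, k=1)
    mask = spec.mask_for(p).copy()
    work = replace(spec, structure=Structure.DENSE, edge_mask=None)
    while mask.any():
        fit = fit_multigroup(panels, replace(work, edge_mask=mask.copy()),
                             options)
        pvals = edge_wald_pvalues(fit)
        worst = np.max(pvals)
        if worst <= spec.sparse_alpha:
            break
        # ties: lexicographically smallest (i, j) among the worst
        retained_idx = np.flatnonzero(mask)
        cand = retained_idx[np.flatnonzero(pvals >= worst - 1e-300)]
        cand_pairs = sorted((int(iu[c]), int(ju[c]), int(c)) for c in cand)
        mask[cand_pairs[0][2]] = False
    if not mask.any():
        warnings.warn("all edges pruned: returning independence structure",
                      RuntimeWarning)
    return replace(spec, structure=Structure.SPARSE, edge_mask=mask)


@dataclass
class BootstrapResult:
    """Case-bootstrap percentile intervals for beta and T = 1/beta."""

    beta_samples: np.ndarray          # (B_kept, G)
    beta_ci: np.ndarray               # (G, 2)
    t_ci: np.ndarray                  # (G, 2)
    B: int
    n_dropped: int
    level: float = 0.95


def bootstrap_beta(panels: list[BinaryPanel], spec: MultigroupModelSpec,
                   B: int = 1000, seed: int = 0,
                   options: FitOptions | None = None,
                   level: float = 0.95) -> BootstrapResult:
    """Percentile bootstrap CIs for per-wave beta and temperature.

    Individuals are resampled with replacement within each wave (waves are
    independent samples in the model class).  Implemented by multinomial
    resampling of each wave's 2^p state histogram, which is distributionally
    identical to row resampling but costs O(2^p) per wave per replicate.
    Replicate fits warm-start from the point estimate and skip standard
    errors; non-converged replicates are dropped and counted.
    """
    if B < 2:
        raise ValueError("need at least B=2 replicates")
    base_opts = options or FitOptions()
    point = fit_multigroup(panels, spec, base_opts)
    p = panels[0].p
    enc = panels[0].encoding
    counts = [pan.state_counts()[0] for pan in panels]
    ns = [pan.n for pan in panels]
    rep_opts = replace(base_opts, compute_se=False, theta0=point.theta)
    streams = np.random.SeedSequence(seed).spawn(B)
    samples = []
    dropped = 0
    for b in range(B):
        rng = np.random.default_rng(streams[b])
        stats = []
        for n, cnt in zip(ns, counts):
            newc = rng.multinomial(n, cnt / n)
            stats.append(_stats_from_counts(newc.astype(float), p, enc))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                fit = _fit_from_stats(stats, spec, enc, p, point.item_names,
                                      point.ages, rep_opts)
            except (ValueError, np.linalg.LinAlgError):
                dropped += 1
                continue
        if not fit.converged:
            dropped += 1
            continue
        samples.append(fit.betas)
    if dropped > 0.1 * B:
        warnings.warn(f"{dropped}/{B} bootstrap replicates failed to "
                      f"converge and were dropped", RuntimeWarning)
    beta_samples = np.array(samples)
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    beta_ci = np.percentile(beta_samples, [lo, hi], axis=0).T
    t_samples = 1.0 / beta_samples
    t_ci = np.percentile(t_samples, [lo, hi], axis=0).T
    return BootstrapResult(beta_samples=beta_samples, beta_ci=beta_ci,
                           t_ci=t_ci, B=B, n_dropped=dropped, level=level)
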