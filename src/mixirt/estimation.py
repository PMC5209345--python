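"""Marginal-maximum-likelihood estimation of the mixture PCM/GPCM family.

The marginal likelihood integrates the latent trait out by class-rescaled
Gauss–Hermite quadrature and sums over latent classes.  Fitting proceeds in
two phases, mirroring standard practice for mixture IRT software:

1. an EM phase — the E-step computes person responsibilities over
   (class, quadrature node); the M-step updates the mixing weights in
   closed form and improves the expected complete-data log-likelihood over
   item parameters and latent variances with a bounded quasi-Newton step
   (a generalized EM step, so the observed log-likelihood never decreases);
2. a Newton phase — direct quasi-Newton maximization of the observed
   log-likelihood on unconstrained transforms (log slopes, log standard
   deviations, logit-simplex mixing), using the exact gradient obtained
   from the Fisher identity (the observed-data score equals the expected
   complete-data score).

Multi-start: each random start is run for a short EM burn-in, the best is
refined to convergence.  One integer seed governs every start through a
``numpy`` ``SeedSequence`` split, so fits are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import ConfigurationError, ConvergenceError, DataError
from .model import (
    MISSING,
    ModelSpec,
    ParameterSet,
    PROB_FLOOR,
    QuadratureGrid,
    ResponseMatrix,
    count_free_parameters,
    log_probability_table,
    pattern_log_likelihoods,
)

__all__ = [
    "FitOptions",
    "FittedModel",
    "e_step",
    "m_step",
    "fit",
    "posterior_class_probabilities",
    "assign_modal_classes",
    "standard_errors",
]


@dataclass
class FitOptions:
    """Controls for the multi-start EM + Newton fitting procedure."""

    n_starts: int = 100
    max_em_iterations: int = 8000
    max_newton_iterations: int = 600
    em_tolerance: float = 1e-8
    seed: int = 0
    #: EM iterations spent on every random start before the best one is
    #: selected for full refinement (a short-run multi-start strategy).
    burn_in_iterations: int = 40
    #: quasi-Newton iterations inside each M-step.
    m_step_maxiter: int = 20
    #: if True, any missing response raises instead of being skipped.
    strict_missing: bool = False

    def __post_init__(self):
        if min(self.n_starts, self.max_em_iterations, self.max_newton_iterations) < 1:
            raise ConfigurationError("iteration/start counts must be >= 1")
        if not self.em_tolerance > 0:
            raise ConfigurationError("em_tolerance must be positive")


@dataclass
class FittedModel:
    """A converged fit: parameters, likelihood, posteriors, diagnostics."""

    spec: ModelSpec
    params: ParameterSet
    log_likelihood: float
    n_free_parameters: int
    posterior: np.ndarray  # n x G
    trace: dict
    grid: QuadratureGrid
    start_index: int
    converged: bool
    extreme_flags: dict = field(default_factory=dict)
    standard_errors: dict | None = None

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes


# ---------------------------------------------------------------------------
# Parameter packing (free-vector <-> ParameterSet)
# ---------------------------------------------------------------------------


class ParamPacker:
    """Maps a ParameterSet to/from the free-parameter vector of a variant.

    Layout: thresholds (all free), log discriminations (free entries only,
    per the identification scheme), log standard deviations, and — when
    ``include_mixing`` — the multinomial-logit mixing parameters with
    class 1 as reference.
    """

    def __init__(self, spec: ModelSpec, include_mixing: bool):
        self.spec = spec
        self.include_mixing = include_mixing and spec.n_classes > 1
        G, I = spec.n_classes, spec.n_items
        m = spec.category_counts - 1
        self.m_max = int(m.max())
        self.valid = np.zeros((I, self.m_max), dtype=bool)
        for i in range(I):
            self.valid[i, : m[i]] = True
        self.n_tau = G * int(m.sum())
        if spec.variant in ("pcm", "mpcm"):
            self.n_disc = 0
        elif spec.variant in ("gpcm", "rmgpcm"):
            self.n_disc = I - 1
        else:
            self.n_disc = G * I - 1
        self.n_sigma = G
        self.n_mix = (G - 1) if self.include_mixing else 0
        self.n_free = self.n_tau + self.n_disc + self.n_sigma + self.n_mix

    # -- packing ------------------------------------------------------------

    def pack(self, params: ParameterSet) -> np.ndarray:
        spec = self.spec
        parts = [params.thresholds[:, self.valid].ravel()]
        if spec.variant in ("gpcm", "rmgpcm"):
            parts.append(np.log(params.discriminations[0, 1:]))
        elif spec.variant == "mgpcm":
            parts.append(np.log(params.discriminations.ravel()[1:]))
        parts.append(0.5 * np.log(params.variances))
        if self.include_mixing:
            parts.append(np.log(params.mixing[1:] / params.mixing[0]))
        return np.concatenate(parts)

    def unpack(self, vec: np.ndarray, mixing=None) -> ParameterSet:
        spec = self.spec
        G, I = spec.n_classes, spec.n_items
        pos = 0
        thr = np.full((G, I, self.m_max), np.nan)
        thr[:, self.valid] = vec[: self.n_tau].reshape(G, -1)
        pos = self.n_tau
        if spec.variant in ("pcm", "mpcm"):
            disc = np.ones((G, I))
        elif spec.variant in ("gpcm", "rmgpcm"):
            row = np.concatenate([[1.0], np.exp(vec[pos : pos + self.n_disc])])
            disc = np.tile(row, (G, 1))
        else:
            flat = np.concatenate([[1.0], np.exp(vec[pos : pos + self.n_disc])])
            disc = flat.reshape(G, I)
        pos += self.n_disc
        var = np.exp(2.0 * vec[pos : pos + G])
        pos += G
        if self.include_mixing:
            alpha = np.concatenate([[0.0], vec[pos : pos + G - 1]])
            mixing = np.exp(alpha - logsumexp(alpha))
        elif mixing is None:
            mixing = np.full(G, 1.0 / G)
        return ParameterSet(
            thresholds=thr,
            discriminations=disc,
            mixing=np.asarray(mixing, dtype=float),
            variances=var,
            category_counts=spec.category_counts,
        )

    def assemble_grad(self, params, g_tau, g_disc, g_sigma, g_alpha=None):
        """Chain natural-scale partials onto the free-vector scale."""
        spec = self.spec
        parts = [g_tau[:, self.valid].ravel()]
        if spec.variant in ("gpcm", "rmgpcm"):
            parts.append((g_disc.sum(axis=0) * params.discriminations[0])[1:])
        elif spec.variant == "mgpcm":
            parts.append((g_disc * params.discriminations).ravel()[1:])
        parts.append(g_sigma * np.sqrt(params.variances))
        if self.include_mixing:
            parts.append(np.asarray(g_alpha))
        return np.concatenate(parts)


# ---------------------------------------------------------------------------
# E-step / expected counts
# ---------------------------------------------------------------------------


def _e_step_core(values, params, grid, weights):
    """Responsibilities over (class, node), log-likelihood, class posterior."""
    ll = pattern_log_likelihoods(values, params, grid)  # (n, G, Q)
    joint = (
        ll
        + np.log(grid.weights)[None, None, :]
        + np.log(params.mixing)[None, :, None]
    )
    log_marg = logsumexp(joint, axis=(1, 2))
    log_marg = np.maximum(log_marg, np.log(PROB_FLOOR))
    resp = np.exp(joint - log_marg[:, None, None])
    posterior = resp.sum(axis=2)
    loglik = float(weights @ log_marg)
    return resp, loglik, posterior


def e_step(data: ResponseMatrix, params: ParameterSet, grid: QuadratureGrid):
    """Person responsibilities over (class, node) and expected counts.

    Returns ``(responsibilities, expected_counts, class_totals, loglik)``:
    responsibilities are n x G x Q and sum to 1 per person; expected counts
    are (G, Q, I, C) item-category pseudo-counts; class totals are the
    summed posterior class probabilities.
    """
    weights = np.ones(data.n_persons)
    resp, loglik, posterior = _e_step_core(data.values, params, grid, weights)
    r = _expected_counts(data.values, resp, weights, int(params.category_counts.max()))
    return resp, r, posterior.sum(axis=0), loglik


def _expected_counts(values, resp, weights, c_max):
    """Expected (class, node, item, category) counts from responsibilities."""
    n, I = values.shape
    _, G, Q = resp.shape
    flat = (resp * weights[:, None, None]).reshape(n, G * Q)
    r = np.zeros((G * Q, I, c_max))
    for i in range(I):
        x = values[:, i]
        obs = x != MISSING
        tmp = np.zeros((c_max, G * Q))
        np.add.at(tmp, x[obs], flat[obs])
        r[:, i, :] = tmp.T
    return r.reshape(G, Q, I, c_max)


# ---------------------------------------------------------------------------
# Complete-data objective and exact gradients
# ---------------------------------------------------------------------------


def _complete_data_value_grad(params, grid, r):
    """Expected complete-data log-likelihood (item part) and its gradient.

    ``r`` holds expected counts of shape (G, Q, I, C).  Returns the scalar
    value plus natural-scale partials w.r.t. thresholds (G, I, m_max),
    discriminations (G, I) and latent standard deviations (G,).
    """
    G, Q, I, C = r.shape
    table = log_probability_table(params, grid)[:, :, :, :C]  # (G, Q, I, C)
    P = np.exp(table)
    safe_log = np.where(np.isfinite(table), table, 0.0)
    value = float(np.sum(np.where(r > 0, r * safe_log, 0.0)))

    sigma = np.sqrt(params.variances)
    theta = sigma[:, None] * grid.nodes[None, :]  # (G, Q)
    m_max = params.thresholds.shape[2]

    N = r.sum(axis=3)  # (G, Q, I)
    # reverse-cumulative sums over categories: tail[..., s] = sum_{x >= s}
    tail_r = np.flip(np.cumsum(np.flip(r, axis=3), axis=3), axis=3)
    tail_P = np.flip(np.cumsum(np.flip(P, axis=3), axis=3), axis=3)

    # thresholds: dQ/dtau_gis = delta_gi * sum_q (N * P(c>=s) - r(x>=s))
    diff = N[..., None] * tail_P[..., 1:] - tail_r[..., 1:]  # (G, Q, I, C-1)
    g_tau_core = diff.sum(axis=1)  # (G, I, C-1)
    g_tau = np.zeros((G, I, m_max))
    g_tau[:, :, : C - 1] = params.discriminations[:, :, None] * g_tau_core

    # cumulative-threshold sums T_x = sum_{s<=x} tau_s (zeros beyond m_i)
    tau_safe = np.nan_to_num(params.thresholds[:, :, : C - 1], nan=0.0)
    T = np.concatenate(
        [np.zeros((G, I, 1)), np.cumsum(tau_safe, axis=2)], axis=2
    )  # (G, I, C)
    x_idx = np.arange(C)
    A = x_idx[None, None, None, :] * theta[:, :, None, None] - T[:, None, :, :]
    A_bar = np.sum(P * A, axis=3)  # (G, Q, I)
    g_disc = np.sum(np.sum(r * A, axis=3) - N * A_bar, axis=1)  # (G, I)

    # latent scale: dQ/dsigma_g = sum_{q,i} z_q * delta_gi * (sum_x x*r - N*cbar)
    c_bar = np.sum(P * x_idx[None, None, None, :], axis=3)  # (G, Q, I)
    rx = np.sum(r * x_idx[None, None, None, :], axis=3)
    per_node = np.einsum("gi,gqi->gq", params.discriminations, rx - N * c_bar)
    g_sigma = np.einsum("gq,q->g", per_node, grid.nodes)
    return value, g_tau, g_disc, g_sigma


def m_step(
    expected_counts,
    class_totals,
    params: ParameterSet,
    spec: ModelSpec,
    grid: QuadratureGrid,
    maxiter: int = 20,
):
    """One generalized M-step: closed-form mixing, quasi-Newton item update.

    Improves (never worsens) the expected complete-data log-likelihood, so
    the observed log-likelihood is non-decreasing across EM iterations.
    """
    total = class_totals.sum()
    if spec.n_classes > 1:
        mixing = np.clip(class_totals / total, 1e-12, None)
        mixing = mixing / mixing.sum()
    else:
        mixing = np.ones(1)
    packer = ParamPacker(spec, include_mixing=False)
    x0 = packer.pack(params)

    def negQ(vec):
        p = packer.unpack(vec, mixing=mixing)
        val, g_tau, g_disc, g_sigma = _complete_data_value_grad(p, grid, expected_counts)
        return -val, -packer.assemble_grad(p, g_tau, g_disc, g_sigma)

    f0, _ = negQ(x0)
    res = minimize(negQ, x0, jac=True, method="L-BFGS-B", options={"maxiter": maxiter})
    x_new = res.x if res.fun <= f0 else x0
    return packer.unpack(x_new, mixing=mixing)


# ---------------------------------------------------------------------------
# Observed-data objective (Newton phase, SEs)
# ---------------------------------------------------------------------------


def _observed_negll_grad(vec, values, weights, packer, grid, fixed_mixing=None):
    """Negative observed log-likelihood and exact gradient (Fisher identity)."""
    params = packer.unpack(vec, mixing=fixed_mixing)
    resp, loglik, posterior = _e_step_core(values, params, grid, weights)
    r = _expected_counts(values, resp, weights, int(params.category_counts.max()))
    _, g_tau, g_disc, g_sigma = _complete_data_value_grad(params, grid, r)
    g_alpha = None
    if packer.include_mixing:
        S = weights @ posterior
        g_alpha = S[1:] - weights.sum() * params.mixing[1:]
    grad = packer.assemble_grad(params, g_tau, g_disc, g_sigma, g_alpha)
    return -loglik, -grad


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _random_start(spec: ModelSpec, rng) -> ParameterSet:
    G, I = spec.n_classes, spec.n_items
    m = spec.category_counts - 1
    m_max = int(m.max())
    thr = np.full((G, I, m_max), np.nan)
    for g in range(G):
        for i in range(I):
            base = np.sort(rng.uniform(-2.0, 2.0, size=m[i]))
            thr[g, i, : m[i]] = base + rng.normal(0.0, 0.1, size=m[i])
    if spec.variant in ("pcm", "mpcm"):
        disc = np.ones((G, I))
    elif spec.variant in ("gpcm", "rmgpcm"):
        row = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=I))
        row[0] = 1.0
        disc = np.tile(row, (G, 1))
    else:
        disc = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=(G, I)))
        disc[0, 0] = 1.0
    mixing = rng.dirichlet(np.ones(G))
    mixing = np.clip(mixing, 0.05 / G, None)
    mixing /= mixing.sum()
    # the latent scale is only weakly identified early in EM; starts must
    # span small and large trait variances or all starts share one basin
    variances = np.exp(rng.uniform(np.log(0.01), np.log(2.25), size=G))
    return ParameterSet(
        thresholds=thr,
        discriminations=disc,
        mixing=mixing,
        variances=variances,
        category_counts=spec.category_counts,
    )


def _em_phase(values, weights, params, spec, grid, max_iter, tol, m_maxiter):
    """EM iterations until relative log-likelihood change < tol or cap."""
    trace = []
    prev_ll = -np.inf
    prev_params = params
    for _ in range(max_iter):
        resp, loglik, posterior = _e_step_core(values, params, grid, weights)
        # monotonicity guard: back off toward the previous accepted params
        halvings = 0
        while loglik < prev_ll - 1e-10 * (1.0 + abs(prev_ll)) and halvings < 50:
            params = _blend_params(prev_params, params, 0.5)
            resp, loglik, posterior = _e_step_core(values, params, grid, weights)
            halvings += 1
        if halvings == 50:
            warnings.warn("M-step failed to improve the likelihood; keeping previous")
            params, loglik = prev_params, prev_ll
            trace.append(loglik)
            break
        trace.append(loglik)
        if np.isfinite(prev_ll) and abs(loglik - prev_ll) <= tol * (1.0 + abs(loglik)):
            break
        prev_ll, prev_params = loglik, params
        r = _expected_counts(values, resp, weights, int(params.category_counts.max()))
        class_totals = weights @ posterior
        params = m_step(r, class_totals, params, spec, grid, maxiter=m_maxiter)
    return params, trace


def _blend_params(a: ParameterSet, b: ParameterSet, w: float) -> ParameterSet:
    return ParameterSet(
        thresholds=(1 - w) * b.thresholds + w * a.thresholds,
        discriminations=np.exp(
            (1 - w) * np.log(b.discriminations) + w * np.log(a.discriminations)
        ),
        mixing=(1 - w) * b.mixing + w * a.mixing,
        variances=np.exp((1 - w) * np.log(b.variances) + w * np.log(a.variances)),
        category_counts=a.category_counts,
    )


def fit(
    data: ResponseMatrix,
    spec: ModelSpec,
    options: FitOptions | None = None,
    grid: QuadratureGrid | None = None,
    extra_starts: list[ParameterSet] | None = None,
) -> FittedModel:
    """Fit a model variant by multi-start EM followed by Newton refinement.

    ``extra_starts`` allows seeding with specific parameter sets (e.g. a
    nested model's solution embedded in a richer variant), which are run in
    addition to the random starts.
    """
    options = options or FitOptions()
    if not np.array_equal(np.asarray(spec.category_counts), data.category_counts):
        raise DataError("spec category counts do not match the data")
    if options.strict_missing and np.any(data.values == MISSING):
        raise DataError("missing responses present but strict_missing is set")
    grid = grid or QuadratureGrid.gauss_hermite(spec.quadrature_nodes)

    # collapse duplicate response patterns; likelihood is weight-additive
    values, inverse, weights = np.unique(
        data.values, axis=0, return_inverse=True, return_counts=True
    )
    weights = weights.astype(float)

    rng = np.random.default_rng(np.random.SeedSequence(options.seed))
    starts = [_random_start(spec, rng) for _ in range(options.n_starts)]
    if extra_starts:
        starts = list(extra_starts) + starts

    burn = min(options.burn_in_iterations, options.max_em_iterations)
    diagnostics = []
    best = None
    for k, start in enumerate(starts):
        try:
            p_k, tr_k = _em_phase(
                values, weights, start, spec, grid,
                burn, options.em_tolerance, options.m_step_maxiter,
            )
        except Exception as exc:  # keep going; other starts may succeed
            diagnostics.append({"start": k, "error": repr(exc)})
            continue
        diagnostics.append({"start": k, "burn_in_ll": tr_k[-1]})
        if best is None or tr_k[-1] > best[1]:
            best = (k, tr_k[-1], p_k, tr_k)
    if best is None:
        raise ConvergenceError("all starts failed", diagnostics)
    start_index, _, params, trace = best

    # refine the winning start with the full EM budget
    remaining = options.max_em_iterations - burn
    if remaining > 0:
        params, tr2 = _em_phase(
            values, weights, params, spec, grid,
            remaining, options.em_tolerance, options.m_step_maxiter,
        )
        trace = trace + tr2[1:]
    em_ll = trace[-1]

    # Newton refinement on the unconstrained free parameters
    packer = ParamPacker(spec, include_mixing=True)
    x0 = packer.pack(params)
    res = minimize(
        _observed_negll_grad,
        x0,
        args=(values, weights, packer, grid),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": options.max_newton_iterations},
    )
    newton_ll = -res.fun
    if newton_ll >= em_ll:
        params = packer.unpack(res.x)
        final_ll = float(newton_ll)
    else:
        final_ll = float(em_ll)

    # canonical class order: descending mixing proportion
    order = np.argsort(-params.mixing, kind="stable")
    params = params.reorder_classes(order)

    _, _, posterior_u = _e_step_core(values, params, grid, np.ones(len(values)))
    posterior = posterior_u[inverse]
    row_sums = posterior.sum(axis=1, keepdims=True)
    posterior = posterior / row_sums

    flags = {
        "boundary_mixing": int(np.sum(params.mixing < 1e-4)),
        "extreme_discrimination": int(np.sum(params.discriminations > 50)),
        "boundary_variance": int(np.sum(params.variances < 1e-4)),
        "extreme_threshold": int(
            np.nansum(np.abs(params.thresholds) > 5.0)
        ),
    }
    converged = bool(res.success or len(trace) < options.max_em_iterations)
    return FittedModel(
        spec=spec,
        params=params,
        log_likelihood=final_ll,
        n_free_parameters=count_free_parameters(spec),
        posterior=posterior,
        trace={
            "em_log_likelihood": trace,
            "em_iterations": len(trace),
            "newton_iterations": int(res.nit),
            "start_diagnostics": diagnostics,
        },
        grid=grid,
        start_index=start_index,
        converged=converged,
        extreme_flags=flags,
    )


# ---------------------------------------------------------------------------
# Posteriors and classification
# ---------------------------------------------------------------------------


def posterior_class_probabilities(
    fitted: FittedModel, data: ResponseMatrix
) -> np.ndarray:
    """Bayes posterior class membership probabilities, rows summing to 1."""
    _, _, posterior = _e_step_core(
        data.values, fitted.params, fitted.grid, np.ones(data.n_persons)
    )
    return posterior / posterior.sum(axis=1, keepdims=True)


def assign_modal_classes(posterior: np.ndarray):
    """Modal class labels and the mean assignment probability per class.

    Ties go to the lowest class index (and are logged).  A class that wins
    no person gets a NaN mean with a warning.
    """
    posterior = np.asarray(posterior, dtype=float)
    labels = np.argmax(posterior, axis=1)
    n_ties = int(
        np.sum(np.sum(posterior == posterior.max(axis=1, keepdims=True), axis=1) > 1)
    )
    if n_ties:
        warnings.warn(f"{n_ties} tied posterior rows assigned to the lowest class index")
    G = posterior.shape[1]
    means = np.full(G, np.nan)
    for g in range(G):
        members = labels == g
        if members.any():
            means[g] = float(posterior[members, g].mean())
        else:
            warnings.warn(f"class {g} has no modal members; mean probability undefined")
    return labels, means


# ---------------------------------------------------------------------------
# Standard errors
# ---------------------------------------------------------------------------


def _person_scores(values, params, grid, packer):
    """Per-person observed-score matrix (n x n_free), by the Fisher identity."""
    n, I = values.shape
    resp, _, posterior = _e_step_core(values, params, grid, np.ones(n))
    G, Q = resp.shape[1:]
    c_max = int(params.category_counts.max())
    table = log_probability_table(params, grid)[:, :, :, :c_max]
    P = np.exp(table)
    tail_P = np.flip(np.cumsum(np.flip(P, axis=3), axis=3), axis=3)
    sigma = np.sqrt(params.variances)
    theta = sigma[:, None] * grid.nodes[None, :]
    m_max = params.thresholds.shape[2]
    tau_safe = np.nan_to_num(params.thresholds[:, :, : c_max - 1], nan=0.0)
    T = np.concatenate([np.zeros((G, I, 1)), np.cumsum(tau_safe, axis=2)], axis=2)
    x_idx = np.arange(c_max)
    A = x_idx[None, None, None, :] * theta[:, :, None, None] - T[:, None, :, :]
    A_bar = np.sum(P * A, axis=3)  # (G, Q, I)
    c_bar = np.sum(P * x_idx[None, None, None, :], axis=3)

    s_tau = np.zeros((n, G, I, m_max))
    s_disc = np.zeros((n, G, I))
    s_sigma = np.zeros((n, G))
    for i in range(I):
        x = values[:, i]
        obs = x != MISSING
        xo = x[obs]
        ro = resp[obs]  # (no, G, Q)
        # thresholds: delta * sum_q resp * (P(c>=s) - 1{x>=s})
        e_tail = np.einsum("vgq,gqs->vgs", ro, tail_P[:, :, i, 1:])
        ind = (xo[:, None] >= np.arange(1, c_max)[None, :]).astype(float)
        contrib = params.discriminations[None, :, i, None] * (
            e_tail - posterior[obs][:, :, None] * ind[:, None, :]
        )
        s_tau[obs, :, i, : c_max - 1] = contrib
        # discriminations: sum_q resp * (A_x - A_bar)
        A_at = A[:, :, i, :][:, :, xo]  # (G, Q, no)
        s_disc[obs, :, i] = np.einsum("vgq,gqv->vg", ro, A_at) - np.einsum(
            "vgq,gq->vg", ro, A_bar[:, :, i]
        )
        # latent scale via theta: delta * (x - c_bar) * z_q
        dev = xo[None, None, :] - c_bar[:, :, i][:, :, None]  # (G, Q, no)
        s_sigma[obs] += params.discriminations[None, :, i] * np.einsum(
            "vgq,gqv,q->vg", ro, dev, grid.nodes
        )
    scores = np.zeros((n, packer.n_free))
    for v in range(n):
        g_alpha = None
        if packer.include_mixing:
            g_alpha = posterior[v, 1:] - params.mixing[1:]
        scores[v] = packer.assemble_grad(
            params, s_tau[v], s_disc[v], s_sigma[v], g_alpha
        )
    return scores


def standard_errors(
    fitted: FittedModel, data: ResponseMatrix, robust: bool = False, step: float = 1e-5
) -> dict:
    """Standard errors of the free parameters, mapped to the natural scale.

    Default: square roots of the inverse observed-information diagonal,
    with the information matrix obtained by central finite differences of
    the exact analytic score.  ``robust=True`` uses the sandwich estimator
    with per-person score outer products.  Fixed parameters (reference
    discriminations) carry NaN.  Non-finite or huge SEs are flagged.
    """
    spec = fitted.spec
    packer = ParamPacker(spec, include_mixing=True)
    vec = packer.pack(fitted.params)
    values, counts = np.unique(data.values, axis=0, return_counts=True)
    weights = counts.astype(float)

    n_free = packer.n_free
    H = np.zeros((n_free, n_free))
    for j in range(n_free):
        h = step * (1.0 + abs(vec[j]))
        vp, vm = vec.copy(), vec.copy()
        vp[j] += h
        vm[j] -= h
        _, gp = _observed_negll_grad(vp, values, weights, packer, grid=fitted.grid)
        _, gm = _observed_negll_grad(vm, values, weights, packer, grid=fitted.grid)
        H[j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    singular = False
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        singular = True
    if robust:
        scores = _person_scores(data.values, fitted.params, fitted.grid, packer)
        B = scores.T @ scores
        cov = cov @ B @ cov

    se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    # map back to the natural scale
    G, I = spec.n_classes, spec.n_items
    m_max = packer.m_max
    se_tau = np.full((G, I, m_max), np.nan)
    se_tau[:, packer.valid] = se_vec[: packer.n_tau].reshape(G, -1)
    pos = packer.n_tau
    se_disc = np.full((G, I), np.nan)
    if spec.variant in ("gpcm", "rmgpcm"):
        se_row = se_vec[pos : pos + packer.n_disc] * fitted.params.discriminations[0, 1:]
        se_disc[:, 1:] = np.tile(se_row, (G, 1))
    elif spec.variant == "mgpcm":
        flat = np.full(G * I, np.nan)
        flat[1:] = se_vec[pos : pos + packer.n_disc] * fitted.params.discriminations.ravel()[1:]
        se_disc = flat.reshape(G, I)
    pos += packer.n_disc
    se_var = se_vec[pos : pos + G] * 2.0 * fitted.params.variances
    pos += G
    se_mixing = np.full(G, np.nan)
    if packer.include_mixing:
        cov_alpha = cov[pos:, pos:]
        pi = fitted.params.mixing
        J = np.zeros((G, G - 1))
        for g in range(G):
            for h in range(1, G):
                J[g, h - 1] = pi[g] * ((g == h) - pi[h])
        se_mixing = np.sqrt(np.clip(np.diag(J @ cov_alpha @ J.T), 0.0, None))

    n_extreme = int(np.sum(~np.isfinite(se_vec)) + np.sum(se_vec > 1e3))
    result = {
        "thresholds": se_tau,
        "discriminations": se_disc,
        "variances": se_var,
        "mixing": se_mixing,
        "free_vector": se_vec,
        "covariance": cov,
        "singular_information": singular,
        "n_extreme_se": n_extreme,
        "robust": robust,
    }
    fitted.standard_errors = result
    return result
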