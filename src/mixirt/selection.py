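"""Class enumeration and variant comparison.

Candidate mixtures are compared with information criteria (the consistent
AIC is the primary criterion: CAIC = -2 LL + p (ln n + 1), lower is
better), absolute fit is assessed with parametric-bootstrap p-values for
the Pearson and Cressie–Read chi-square statistics, and nested variants
are compared with a bootstrapped likelihood-ratio difference test — the
regularity conditions of the asymptotic chi-square reference fail for
mixtures, so the null distribution of the statistics is simulated from the
fitted (restricted) model.

Response-pattern tables for five 11-category items are astronomically
sparse, so the goodness-of-fit cell set is the observed unique patterns
plus one pooled remainder cell (a documented dialect; software packages
differ in their internal pooling scheme).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .estimation import FitOptions, FittedModel, fit
from .model import (
    ModelSpec,
    ParameterSet,
    ResponseMatrix,
    pattern_log_likelihoods,
)
from .simulate import generate_responses

__all__ = [
    "information_criteria",
    "IcTable",
    "pearson_statistic",
    "cressie_read_statistic",
    "GofResult",
    "observed_expected_cells",
    "parametric_bootstrap_gof",
    "bootstrap_lr_difference_test",
    "enumerate_classes",
    "embed_params",
]


def information_criteria(log_likelihood: float, n_free_parameters: int, n_persons: int):
    """AIC, BIC and Bozdogan's consistent AIC (all lower-is-better)."""
    if n_persons < 1:
        raise ConfigurationError("n_persons must be >= 1")
    ll, p, n = float(log_likelihood), n_free_parameters, n_persons
    return {
        "AIC": -2.0 * ll + 2.0 * p,
        "BIC": -2.0 * ll + p * np.log(n),
        "CAIC": -2.0 * ll + p * (np.log(n) + 1.0),
    }


@dataclass
class IcTable:
    """Information-criterion comparison across candidate models."""

    table: pd.DataFrame
    best_index: int  # row label of the lowest-CAIC model

    def __repr__(self):
        return f"IcTable(best={self.best_index})\n{self.table}"


# ---------------------------------------------------------------------------
# Goodness-of-fit statistics
# ---------------------------------------------------------------------------


def _check_cells(observed, expected):
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise DataError("observed/expected shapes differ")
    if abs(observed.sum() - expected.sum()) > 1e-6 * max(1.0, observed.sum()):
        raise DataError("observed and expected totals differ")
    if np.any(expected <= 0):
        raise DataError("zero or negative expected count on an included cell")
    return observed, expected


def pearson_statistic(observed, expected) -> float:
    """Pearson chi-square statistic sum (O - E)^2 / E over the cell set."""
    observed, expected = _check_cells(observed, expected)
    return float(np.sum((observed - expected) ** 2 / expected))


def cressie_read_statistic(observed, expected, lam: float = 2.0 / 3.0) -> float:
    """Power-divergence statistic; lambda = 2/3 is the Cressie–Read member.

    ``(2 / (lam (lam + 1))) * sum O [(O/E)^lam - 1]``.  At lambda = 1 it
    equals the Pearson statistic when the totals match.  The limiting
    members lambda = 0 (G^2) and lambda = -1 are rejected here.
    """
    if lam in (0.0, -1.0):
        raise ConfigurationError(
            "lambda 0 and -1 are limiting cases not handled by this routine"
        )
    observed, expected = _check_cells(observed, expected)
    o = observed
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(o > 0, o * ((o / expected) ** lam - 1.0), 0.0)
    return float(2.0 / (lam * (lam + 1.0)) * np.sum(term))


def observed_expected_cells(fitted: FittedModel, data: ResponseMatrix):
    """Observed vs model-expected counts on the pooled-pattern cell set.

    Cells are the unique observed response patterns plus one remainder cell
    absorbing all never-observed patterns, so expected counts stay positive
    in sparse tables.
    """
    values, counts = np.unique(data.values, axis=0, return_counts=True)
    n = data.n_persons
    from scipy.special import logsumexp

    ll = pattern_log_likelihoods(values, fitted.params, fitted.grid)
    logp = logsumexp(
        ll
        + np.log(fitted.grid.weights)[None, None, :]
        + np.log(fitted.params.mixing)[None, :, None],
        axis=(1, 2),
    )
    probs = np.exp(logp)
    expected = n * probs
    remainder = max(n - expected.sum(), 1e-10)
    observed = np.concatenate([counts.astype(float), [0.0]])
    expected = np.concatenate([expected, [remainder]])
    return observed, expected


@dataclass
class GofResult:
    """Observed statistic, its bootstrap null sample and the p-value."""

    statistic_kind: str
    observed: float
    bootstrap: np.ndarray
    p_value: float
    seed: int
    n_dropped: int = 0


_STATISTICS = {
    "pearson": pearson_statistic,
    "cressie_read": cressie_read_statistic,
}


def _bootstrap_options(options: FitOptions | None, n_starts: int) -> FitOptions:
    base = options or FitOptions()
    return FitOptions(
        n_starts=n_starts,
        max_em_iterations=base.max_em_iterations,
        max_newton_iterations=base.max_newton_iterations,
        em_tolerance=base.em_tolerance,
        seed=base.seed,
        burn_in_iterations=base.burn_in_iterations,
        m_step_maxiter=base.m_step_maxiter,
    )


def parametric_bootstrap_gof(
    fitted: FittedModel,
    data: ResponseMatrix,
    statistic_kind: str = "pearson",
    B: int = 500,
    seed: int = 0,
    refit_starts: int = 10,
    fit_options: FitOptions | None = None,
) -> GofResult:
    """Parametric-bootstrap p-value for an absolute goodness-of-fit statistic.

    B datasets of the original size are simulated from the fitted
    parameters and refit under the same specification (with a reduced
    number of starts, seeded additionally at the generating parameters);
    the p-value is ``(1 + #{boot >= observed}) / (B + 1)``.  Replicates
    whose refit fails are dropped and counted.
    """
    if statistic_kind not in _STATISTICS:
        raise ConfigurationError(f"unknown statistic '{statistic_kind}'")
    stat_fn = _STATISTICS[statistic_kind]
    obs_o, obs_e = observed_expected_cells(fitted, data)
    observed_stat = stat_fn(obs_o, obs_e)

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(B)]
    boot_stats = []
    n_dropped = 0
    for b in range(B):
        sim, _ = generate_responses(fitted.params, data.n_persons, child_seeds[b])
        opts = _bootstrap_options(fit_options, refit_starts)
        opts.seed = child_seeds[b]
        try:
            refit = fit(sim, fitted.spec, opts, extra_starts=[fitted.params])
        except Exception:
            n_dropped += 1
            continue
        o, e = observed_expected_cells(refit, sim)
        boot_stats.append(stat_fn(o, e))
    if n_dropped > 0.1 * B:
        warnings.warn(
            f"{n_dropped}/{B} bootstrap replicates dropped due to refit failure"
        )
    boot_stats = np.asarray(boot_stats)
    b_eff = boot_stats.size
    p = (1.0 + np.sum(boot_stats >= observed_stat)) / (b_eff + 1.0)
    return GofResult(
        statistic_kind=statistic_kind,
        observed=observed_stat,
        bootstrap=boot_stats,
        p_value=float(p),
        seed=seed,
        n_dropped=n_dropped,
    )


def embed_params(params: ParameterSet, restricted_variant: str, general_spec: ModelSpec):
    """Embed a nested solution into a more general variant's parameter space."""
    return ParameterSet(
        thresholds=params.thresholds.copy(),
        discriminations=params.discriminations.copy(),
        mixing=params.mixing.copy(),
        variances=params.variances.copy(),
        category_counts=params.category_counts,
    )


def bootstrap_lr_difference_test(
    restricted_fit: FittedModel,
    general_fit: FittedModel,
    data: ResponseMatrix,
    B: int = 500,
    seed: int = 0,
    refit_starts: int = 10,
    fit_options: FitOptions | None = None,
) -> dict:
    """Bootstrapped likelihood-ratio difference test for nested variants.

    ``delta = 2 (LL_general - LL_restricted)``; ``df`` is the difference in
    free-parameter counts; the null distribution of delta is simulated from
    the restricted fit, refitting both models on each replicate (the
    general refit is additionally seeded from the restricted solution, so
    negative deltas cannot arise from start failures).  A significant
    result favours the more complex model.
    """
    df = general_fit.n_free_parameters - restricted_fit.n_free_parameters
    if df < 0:
        raise ConfigurationError("general model has fewer parameters than restricted")
    delta = 2.0 * (general_fit.log_likelihood - restricted_fit.log_likelihood)
    if delta < -1e-6:
        raise ConfigurationError(
            "general fit has lower likelihood than the restricted fit; "
            "re-run the general fit seeded from the restricted solution"
        )
    delta = max(delta, 0.0)

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(B)]
    deltas = []
    n_dropped = 0
    for b in range(B):
        sim, _ = generate_responses(restricted_fit.params, data.n_persons, child_seeds[b])
        opts = _bootstrap_options(fit_options, refit_starts)
        opts.seed = child_seeds[b]
        try:
            r_fit = fit(sim, restricted_fit.spec, opts, extra_starts=[restricted_fit.params])
            g_fit = fit(
                sim,
                general_fit.spec,
                opts,
                extra_starts=[
                    embed_params(r_fit.params, restricted_fit.spec.variant, general_fit.spec),
                    general_fit.params,
                ],
            )
        except Exception:
            n_dropped += 1
            continue
        deltas.append(max(2.0 * (g_fit.log_likelihood - r_fit.log_likelihood), 0.0))
    if n_dropped > 0.1 * B:
        warnings.warn(f"{n_dropped}/{B} bootstrap replicates dropped")
    deltas = np.asarray(deltas)
    p = (1.0 + np.sum(deltas >= delta)) / (deltas.size + 1.0)
    return {"delta": float(delta), "df": int(df), "p": float(p), "bootstrap": deltas}


def enumerate_classes(
    data: ResponseMatrix,
    variant: str,
    G_range,
    options: FitOptions | None = None,
) -> tuple[IcTable, FittedModel | None]:
    """Fit a variant for each class count and select the lowest-CAIC model.

    Ties break toward the smaller class count (parsimony).  A class count
    whose fit fails leaves a gap row (NaNs) with the error recorded.
    """
    G_range = list(G_range)
    if not G_range:
        raise ConfigurationError("G_range is empty")
    options = options or FitOptions()
    rows = []
    fits = {}
    for G in G_range:
        v = variant
        if G == 1 and variant in ("mpcm", "rmgpcm", "mgpcm"):
            v = {"mpcm": "pcm", "rmgpcm": "gpcm", "mgpcm": "gpcm"}[variant]
        spec = ModelSpec(
            variant=v, n_classes=G, category_counts=data.category_counts
        )
        try:
            fitted = fit(data, spec, options)
        except Exception as exc:
            rows.append(
                {"n_classes": G, "variant": v, "error": repr(exc), "LL": np.nan,
                 "n_par": np.nan, "AIC": np.nan, "BIC": np.nan, "CAIC": np.nan}
            )
            continue
        fits[G] = fitted
        ic = information_criteria(
            fitted.log_likelihood, fitted.n_free_parameters, data.n_persons
        )
        rows.append(
            {
                "n_classes": G,
                "variant": v,
                "LL": fitted.log_likelihood,
                "n_par": fitted.n_free_parameters,
                **ic,
                "error": "",
            }
        )
    table = pd.DataFrame(rows).set_index("n_classes")
    valid = table["CAIC"].dropna().sort_index()
    if valid.empty:
        raise ConfigurationError("no class count could be fitted")
    best_G = int(valid.index[np.argmin(valid.values)])  # idxmin is first min: tie -> smaller G
    return IcTable(table=table, best_index=best_G), fits.get(best_G)
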