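"""Scale-usage diagnostics from fitted mixture PCM/GPCM parameters.

Fitted thresholds translate into statements about how a latent class uses
the rating scale:

* ordered thresholds mean every category owns a segment of the latent
  continuum; an inversion (tau_s > tau_{s+1}) buries the intervening
  category under its neighbours' characteristic curves — an *avoided*
  category;
* adjacent-threshold distances are the widths of the latent categories;
  an extreme-response-style class shows very wide extreme categories;
* expected category frequencies combine the item parameters with the
  class-specific latent distribution and show which categories a class is
  actually expected to produce.

The module also compares the mixture-based marginal (EAP) reliability with
Cronbach's alpha on the raw scores: alpha absorbs scale-usage variance and
typically overstates precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .estimation import FittedModel, _e_step_core
from .model import (
    MISSING,
    ParameterSet,
    ResponseMatrix,
    category_probabilities,
)

__all__ = [
    "threshold_order_report",
    "modal_category_set",
    "ccc_curve_data",
    "latent_category_widths",
    "expected_category_frequencies",
    "marginal_reliability",
    "cronbach_alpha",
    "ScaleUsageReport",
    "scale_usage_report",
]


def threshold_order_report(params: ParameterSet) -> pd.DataFrame:
    """Adjacent-threshold inversions per class and item.

    A pair (s, s+1) is inverted when tau_s > tau_{s+1}; ties count as
    ordered (non-strict convention).  Returns one row per class x item
    with the inversion pair list and the count of correctly ordered
    adjacent pairs.
    """
    rows = []
    G, I = params.discriminations.shape
    for g in range(G):
        for i in range(I):
            m = int(params.category_counts[i]) - 1
            tau = params.thresholds[g, i, :m]
            d = np.diff(tau)
            inverted = [(s + 1, s + 2) for s in np.flatnonzero(d < 0)]
            rows.append(
                {
                    "class": g + 1,
                    "item": i,
                    "inversions": inverted,
                    "n_inversions": len(inverted),
                    "n_ordered_pairs": int(np.sum(d >= 0)),
                }
            )
    return pd.DataFrame(rows)


def modal_category_set(
    thresholds,
    discrimination: float,
    theta_range=(-6.0, 6.0),
    grid_step: float = 0.01,
    tie_tolerance: float = 1e-9,
):
    """Categories that are the modal response somewhere on the trait range.

    The avoided set is the complement: categories never attaining the
    (strict) maximum characteristic-curve probability on the evaluation
    grid.  Near-ties within ``tie_tolerance`` count as covered.  With a
    sufficiently wide range the extreme categories are always modal.
    """
    lo, hi = theta_range
    if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo and grid_step > 0):
        raise ConfigurationError("theta_range must be finite with positive step")
    theta = np.arange(lo, hi + grid_step / 2, grid_step)
    p = category_probabilities(theta, thresholds, discrimination)
    top = p.max(axis=1, keepdims=True)
    covered = np.any(p >= top - tie_tolerance, axis=0)
    modal = set(np.flatnonzero(covered).tolist())
    avoided = set(range(p.shape[1])) - modal
    return modal, avoided


def ccc_curve_data(thresholds, discrimination: float, theta_grid) -> pd.DataFrame:
    """Category characteristic curves evaluated on a trait grid.

    Rows are grid points, columns ``cat_0..cat_m``; each row sums to 1.
    Intended as plot-ready export.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    p = category_probabilities(theta_grid, thresholds, discrimination)
    df = pd.DataFrame(p, columns=[f"cat_{c}" for c in range(p.shape[1])])
    df.insert(0, "theta", theta_grid)
    return df


def latent_category_widths(params: ParameterSet):
    """Signed adjacent-threshold distances per class/item + class summaries.

    The distance ``tau_{s+1} - tau_s`` is the width of latent category s on
    the trait continuum (negative when the pair is inverted).  The summary
    reports min/max over each class's *ordered* adjacent pairs across all
    items; which pairs enter such a summary is a reporting choice, so the
    summary is descriptive rather than canonical.
    """
    G, I = params.discriminations.shape
    per_item = {}
    summary = []
    for g in range(G):
        ordered_widths = []
        for i in range(I):
            m = int(params.category_counts[i]) - 1
            widths = np.diff(params.thresholds[g, i, :m])
            per_item[(g + 1, i)] = widths
            ordered_widths.extend(widths[widths > 0].tolist())
        summary.append(
            {
                "class": g + 1,
                "min_ordered_width": min(ordered_widths) if ordered_widths else np.nan,
                "max_ordered_width": max(ordered_widths) if ordered_widths else np.nan,
            }
        )
    return per_item, pd.DataFrame(summary).set_index("class")


def expected_category_frequencies(fitted: FittedModel) -> pd.DataFrame:
    """Model-implied category frequency distribution per class and overall.

    For each class the item-category probabilities are averaged over the
    class's latent N(0, sigma_g^2) distribution (by quadrature) and over
    items; the overall row is the mixing-weighted combination.  Every
    vector sums to 1.
    """
    params, grid = fitted.params, fitted.grid
    G, I = params.discriminations.shape
    c_max = int(params.category_counts.max())
    out = np.zeros((G, c_max))
    sigma = np.sqrt(params.variances)
    for g in range(G):
        theta = sigma[g] * grid.nodes
        acc = np.zeros(c_max)
        for i in range(I):
            m = int(params.category_counts[i]) - 1
            p = category_probabilities(
                theta, params.thresholds[g, i, :m], params.discriminations[g, i]
            )
            acc[: m + 1] += grid.weights @ p
        out[g] = acc / I
    overall = params.mixing @ out
    df = pd.DataFrame(
        np.vstack([out, overall]),
        index=[f"class_{g + 1}" for g in range(G)] + ["overall"],
        columns=[f"cat_{c}" for c in range(c_max)],
    )
    return df


def marginal_reliability(fitted: FittedModel, data: ResponseMatrix) -> float:
    """EAP-based marginal reliability of the latent trait within the mixture.

    Person-level expected-a-posteriori trait scores are computed across
    classes and nodes; reliability is var(EAP) / (var(EAP) + mean posterior
    variance), bounded in [0, 1].  Items with vanishing discrimination
    carry no information and drive the coefficient to 0.
    """
    params, grid = fitted.params, fitted.grid
    resp, _, _ = _e_step_core(data.values, params, grid, np.ones(data.n_persons))
    theta_nodes = np.sqrt(params.variances)[:, None] * grid.nodes[None, :]  # (G, Q)
    eap = np.einsum("vgq,gq->v", resp, theta_nodes)
    second = np.einsum("vgq,gq->v", resp, theta_nodes**2)
    post_var = np.maximum(second - eap**2, 0.0)
    total = np.var(eap) + post_var.mean()
    if total <= 0:
        warnings.warn("zero total trait variance; reliability undefined")
        return float("nan")
    return float(np.var(eap) / total)


def cronbach_alpha(data: ResponseMatrix) -> float:
    """Cronbach's alpha of the raw item scores (complete rows only)."""
    if data.n_items < 2:
        raise DataError("alpha needs at least two items")
    complete = ~np.any(data.values == MISSING, axis=1)
    x = data.values[complete].astype(float)
    if x.shape[0] < 2:
        raise DataError("alpha needs at least two complete rows")
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        warnings.warn("zero total-score variance; alpha undefined")
        return float("nan")
    k = data.n_items
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


@dataclass
class ScaleUsageReport:
    """Bundle of all scale-usage diagnostics for one fitted model."""

    threshold_orders: pd.DataFrame
    avoided: pd.DataFrame  # class, item, avoided category set
    widths_summary: pd.DataFrame
    expected_frequencies: pd.DataFrame
    reliability: float
    alpha: float


def scale_usage_report(
    fitted: FittedModel,
    data: ResponseMatrix,
    theta_range=(-6.0, 6.0),
    grid_step: float = 0.01,
) -> ScaleUsageReport:
    """Assemble the full diagnostics bundle for a fitted mixture model."""
    params = fitted.params
    G, I = params.discriminations.shape
    avoided_rows = []
    for g in range(G):
        for i in range(I):
            m = int(params.category_counts[i]) - 1
            modal, avoided = modal_category_set(
                params.thresholds[g, i, :m],
                params.discriminations[g, i],
                theta_range=theta_range,
                grid_step=grid_step,
            )
            avoided_rows.append(
                {"class": g + 1, "item": i, "avoided": sorted(avoided),
                 "n_avoided": len(avoided)}
            )
    _, widths_summary = latent_category_widths(params)
    return ScaleUsageReport(
        threshold_orders=threshold_order_report(params),
        avoided=pd.DataFrame(avoided_rows),
        widths_summary=widths_summary,
        expected_frequencies=expected_category_frequencies(fitted),
        reliability=marginal_reliability(fitted, data),
        alpha=cronbach_alpha(data),
    )
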