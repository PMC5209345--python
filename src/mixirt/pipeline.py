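"""End-to-end analysis pipeline: descriptives -> enumeration -> diagnostics
-> (optional) covariate regression, with a machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import scale_usage_report
from .errors import ConfigurationError
from .estimation import FitOptions, assign_modal_classes, standard_errors
from .io import descriptives_report, read_responses
from .selection import enumerate_classes
from .threestep import classification_error_matrix, dummy_encode, three_step_multinomial

logger = logging.getLogger("mixirt")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run (YAML/JSON loadable)."""

    responses_path: str
    output_dir: str
    covariates_path: str | None = None
    variant: str = "rmgpcm"
    class_range: tuple = (1, 2, 3)
    missing_token: str = "NA"
    n_starts: int = 10
    seed: int = 0
    bootstrap_B: int = 0
    predict_classes: bool = False
    categorical_references: dict = field(default_factory=dict)
    compute_standard_errors: bool = False

    def __post_init__(self):
        if not os.path.exists(self.responses_path):
            raise ConfigurationError(f"responses file not found: {self.responses_path}")
        if self.predict_classes:
            if not self.covariates_path:
                raise ConfigurationError("predict_classes requires covariates_path")
            if not os.path.exists(self.covariates_path):
                raise ConfigurationError(
                    f"covariates file not found: {self.covariates_path}"
                )
        if any(g < 1 or g > 10 for g in self.class_range):
            raise ConfigurationError("class_range must lie within [1, 10]")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["class_range"] = tuple(raw.get("class_range", (1, 2, 3)))
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all tables under the output dir.

    Returns the manifest dict.  A stage failure marks the bundle partial
    and records the failing stage's diagnostics instead of raising.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items() if not k.startswith("_")},
        "stages": {},
        "partial": False,
    }
    t_all = time.time()

    def stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
            manifest["stages"][name] = {"ok": True, "seconds": time.time() - t0}
            return result
        except Exception as exc:
            logger.exception("stage %s failed", name)
            manifest["stages"][name] = {
                "ok": False,
                "seconds": time.time() - t0,
                "error": repr(exc),
            }
            manifest["partial"] = True
            return None

    data = stage(
        "read", lambda: read_responses(config.responses_path, config.missing_token)
    )
    if data is None:
        _write_manifest(config, manifest, t_all)
        return manifest

    stage(
        "descriptives",
        lambda: descriptives_report(data).to_csv(
            os.path.join(config.output_dir, "descriptives.csv")
        ),
    )

    options = FitOptions(n_starts=config.n_starts, seed=config.seed)

    def _enumerate():
        ic, best = enumerate_classes(data, config.variant, config.class_range, options)
        ic.table.to_csv(os.path.join(config.output_dir, "model_comparison.csv"))
        return ic, best

    enum = stage("enumerate", _enumerate)
    if enum is None or enum[1] is None:
        _write_manifest(config, manifest, t_all)
        return manifest
    ic, best = enum
    manifest["selected_classes"] = int(ic.best_index)
    manifest["log_likelihood"] = float(best.log_likelihood)

    def _params_out():
        best.params.to_json(os.path.join(config.output_dir, "parameters.json"))
        if config.compute_standard_errors:
            se = standard_errors(best, data)
            np.savetxt(
                os.path.join(config.output_dir, "se_free_vector.csv"),
                se["free_vector"], delimiter=",",
            )
        pd.DataFrame(
            best.posterior,
            columns=[f"class_{g + 1}" for g in range(best.n_classes)],
        ).to_csv(os.path.join(config.output_dir, "posterior.csv"), index=False)

    stage("parameters", _params_out)

    def _diagnose():
        report = scale_usage_report(best, data)
        report.threshold_orders.to_csv(
            os.path.join(config.output_dir, "threshold_orders.csv"), index=False
        )
        report.avoided.to_csv(
            os.path.join(config.output_dir, "avoided_categories.csv"), index=False
        )
        report.expected_frequencies.to_csv(
            os.path.join(config.output_dir, "expected_frequencies.csv")
        )
        manifest["reliability"] = report.reliability
        manifest["cronbach_alpha"] = report.alpha

    stage("diagnose", _diagnose)

    if config.predict_classes:

        def _predict():
            covars = pd.read_csv(config.covariates_path)
            labels, _ = assign_modal_classes(best.posterior)
            D = classification_error_matrix(best.posterior, labels)
            design, _ = dummy_encode(covars, config.categorical_references)
            result = three_step_multinomial(labels, D, design)
            result.coefficients.to_csv(
                os.path.join(config.output_dir, "class_regression.csv"), index=False
            )
            manifest["pseudo_r2"] = result.pseudo_r2

        stage("predict_classes", _predict)

    _write_manifest(config, manifest, t_all)
    return manifest


def _write_manifest(config, manifest, t_all):
    manifest["total_seconds"] = time.time() - t_all
    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
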