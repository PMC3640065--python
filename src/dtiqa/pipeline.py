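"""End-to-end orchestration: load -> fit -> QA metrics -> report.

Every stage logs its parameters and duration into the run manifest, and all
randomness flows from one master seed that is split per stage, so a rerun
with the same configuration reproduces every output bit-for-bit.  Failures
surface with the stage name attached; partially written outputs are kept.

Settings come in two flavours: ``paper`` (bootstrap 1000 replicates, SIMEX
2000/4000/6000/8000 per omega) and ``fast`` (bootstrap 100, SIMEX 200 per
omega), the latter sized for interactive runs and the test suite.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import dti_core, gof, io_formats, noise_and_sampling, phantom, power
from . import qa_features, report, uncertainty

logger = logging.getLogger(__name__)

FAST_SETTINGS = {
    "bootstrap_reps": 100,
    "simex_reps": (200, 200, 200, 200),
    "target_fraction": noise_and_sampling.DEFAULT_TARGET_FRACTION,
}
PAPER_SETTINGS = {
    "bootstrap_reps": uncertainty.DEFAULT_BOOTSTRAP_REPS,
    "simex_reps": uncertainty.DEFAULT_SIMEX_REPS,
    "target_fraction": noise_and_sampling.DEFAULT_TARGET_FRACTION,
}


class StageError(RuntimeError):
    """Failure wrapped with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class QaMetrics:
    """Container for everything the QA stages compute on one study."""

    chi_pix: Optional[np.ndarray] = None
    chi_slice: Optional[np.ndarray] = None
    noise: Optional[noise_and_sampling.NoiseEstimate] = None
    outlier_counts: Optional[np.ndarray] = None
    sample: Optional[noise_and_sampling.VoxelSample] = None
    sample_table: Optional[pd.DataFrame] = None
    power_curve_objects: Optional[list] = None
    power_curves: Optional[pd.DataFrame] = None
    regional_summary: Optional[qa_features.RegionalSummary] = None
    feature_vector: Optional[pd.DataFrame] = None
    labels: Optional[np.ndarray] = None
    stage_log: list = field(default_factory=list)


def _spawn_seeds(master_seed: int, n: int) -> list:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_study(
    study: io_formats.DwiStudy,
    seed: int = 0,
    settings: Optional[dict] = None,
    out_dir: Optional[str] = None,
    reference: Optional[pd.DataFrame] = None,
    render: bool = True,
) -> tuple:
    """Run the full QA chain on one loaded study.

    Returns ``(fit, metrics, manifest)``.  When ``out_dir`` is given the
    stored outputs and (optionally) the four-page report are written there.
    """
    cfg = dict(FAST_SETTINGS)
    cfg.update(settings or {})
    seeds = _spawn_seeds(seed, 4)
    metrics = QaMetrics(labels=study.labels)
    manifest = {"seed": seed, "settings": {k: str(v) for k, v in cfg.items()},
                "stages": []}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(name, exc) from exc
        dt = time.perf_counter() - t0
        manifest["stages"].append({"stage": name, "seconds": round(dt, 3)})
        logger.info("stage %-12s %.2fs", name, dt)
        return result

    fit = _stage("fit", lambda: dti_core.fit_study(study))

    def _noise():
        if study.labels is None:
            return None
        return noise_and_sampling.estimate_noise(study)

    metrics.noise = _stage("noise", _noise)

    def _gof():
        maps = gof.compute_gof(fit)
        metrics.chi_pix = maps.chi_pix
        metrics.chi_slice = maps.chi_slice
        if metrics.noise is not None and metrics.noise.chosen_sigma > 0:
            sigma_norm = metrics.noise.chosen_sigma
            metrics.outlier_counts = dti_core.outlier_voxels_per_dwi(
                fit, study.b0, sigma_norm
            )
        return maps

    _stage("gof", _gof)

    if study.labels is not None:
        def _sample():
            return noise_and_sampling.subsample_voxels(
                study.labels,
                fit.mask,
                target_fraction=cfg["target_fraction"],
                seed=seeds[0],
            )

        metrics.sample = _stage("sample", _sample)
        idx = metrics.sample.indices
        s_m_vox = study.dwis[idx[:, 0], idx[:, 1], idx[:, 2]] / study.b0[
            idx[:, 0], idx[:, 1], idx[:, 2]
        ][:, None]

        def _bootstrap():
            return uncertainty.wild_bootstrap_fa(
                s_m_vox, study.scheme, n_reps=cfg["bootstrap_reps"], seed=seeds[1]
            )

        boot = _stage("bootstrap", _bootstrap)

        def _simex():
            sigma = metrics.noise.chosen_sigma if metrics.noise else 0.0
            return uncertainty.simex_bias_fa(
                study.dwis[idx[:, 0], idx[:, 1], idx[:, 2]],
                study.b0[idx[:, 0], idx[:, 1], idx[:, 2]],
                study.scheme,
                sigma_hat=sigma,
                reps=cfg["simex_reps"],
                seed=seeds[2],
            )

        simex = _stage("simex", _simex)

        metrics.sample_table = pd.DataFrame(
            {
                "x": idx[:, 0],
                "y": idx[:, 1],
                "z": idx[:, 2],
                "region": metrics.sample.regions,
                "fa": boot.fa_measured,
                "sigma_fa": boot.sigma_fa,
                "bias_fa": simex.bias_fa,
            }
        )

        def _power():
            curves = power.regional_power_curves(
                boot.sigma_fa, simex.bias_fa, metrics.sample.regions
            )
            metrics.power_curve_objects = curves
            return power.curves_to_frame(curves)

        metrics.power_curves = _stage("power", _power)

        def _summaries():
            summary = qa_features.summarize_regions(
                fit, study.labels, metrics.sample_table
            )
            metrics.regional_summary = summary
            vec = qa_features.build_feature_vector(summary)
            return pd.DataFrame([dict(zip(vec.names, vec.values))])

        metrics.feature_vector = _stage("summaries", _summaries)

    if out_dir is not None:
        out = Path(out_dir)
        files = _stage("save", lambda: io_formats.save_outputs(fit, metrics, out))
        manifest["outputs"] = files
        if render:
            pdf_path = out / "qa_report.pdf"
            _stage(
                "report",
                lambda: report.render_report(
                    study, fit, metrics, pdf_path, reference=reference
                ),
            )
            manifest["outputs"]["qa_report"] = str(pdf_path)
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return fit, metrics, manifest


def run_all(config) -> dict:
    """Config-driven end-to-end run (YAML path or dict).

    Config keys: ``input`` (either ``phantom: {spec...}`` or paths ``dwi``,
    ``bval``, ``bvec`` + optional ``mask``/``labels``/``motion``), ``out``,
    ``seed``, ``settings`` ('fast' | 'paper' | explicit mapping), optional
    ``reference`` CSV path.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out_dir = config.get("out", "dtiqa_out")
    seed = int(config.get("seed", 0))
    settings = config.get("settings", "fast")
    if settings == "fast":
        settings = FAST_SETTINGS
    elif settings == "paper":
        settings = PAPER_SETTINGS

    source = config.get("input", {})
    if "phantom" in source:
        spec_kwargs = dict(source["phantom"])
        spec_kwargs.setdefault("seed", seed)
        if "grid_shape" in spec_kwargs:
            spec_kwargs["grid_shape"] = tuple(spec_kwargs["grid_shape"])
        spec = phantom.PhantomSpec(**spec_kwargs)
        study, _ = phantom.generate(spec)
    else:
        try:
            study = io_formats.load_study(
                source["dwi"],
                source["bval"],
                source["bvec"],
                mask_path=source.get("mask"),
                labels_path=source.get("labels"),
                motion_path=source.get("motion"),
            )
        except KeyError as exc:
            raise StageError("load", ValueError(f"missing input path {exc}")) from exc
        except Exception as exc:
            raise StageError("load", exc) from exc

    reference = None
    if config.get("reference"):
        reference = pd.read_csv(config["reference"])

    _, _, manifest = run_study(
        study, seed=seed, settings=settings, out_dir=out_dir, reference=reference
    )
    return manifest
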