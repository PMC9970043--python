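"""End-to-end orchestration: diagnostics, component initialisation,
training and sampling, validation — with a machine-readable run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .components import robust_scale_fit, select_components
from .curation import CurationConfig, CuratedDataset, curate, load_table
from .engine import fit_variational, make_priors, sample
from .metrics import QualityReport, kde_overlay, quality_report

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "sweep_population_sizes"]

_FLOAT_FMT = "%.12g"  # fixed CSV float format so reruns are byte-identical


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run from the input file alone."""

    input_path: str
    input_format: str = "csv"
    n_virtual: int = 1000
    k_min: int = 2
    k_max: int = 20
    db_rule: str = "max"
    patience: int = 5
    gamma_mode: str = "exp"
    weight_mode: str = "posterior_draw"
    seed: int = 0
    vi_tol: float = 1e-5
    vi_max_iter: int = 500
    out_dir: str = "bgmm_oce_output"
    curation: CurationConfig = field(default_factory=CurationConfig)
    write_kde_overlays: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    """Paths and summaries of everything a pipeline run produced."""

    config: RunConfig
    opt: int
    n_eligible_features: int
    n_excluded_features: int
    n_outliers_flagged: int
    quality: QualityReport | None
    synthetic_path: str
    model_path: str
    scan_path: str
    report_path: str
    curation_log_path: str
    timings: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "opt": self.opt,
            "n_eligible_features": self.n_eligible_features,
            "n_excluded_features": self.n_excluded_features,
            "n_outliers_flagged": self.n_outliers_flagged,
            "quality": None if self.quality is None else self.quality.to_dict(),
            "artifacts": {
                "synthetic": self.synthetic_path,
                "model": self.model_path,
                "scan": self.scan_path,
                "report": self.report_path,
                "curation_log": self.curation_log_path,
            },
            "timings": self.timings,
        }


def _train(config: RunConfig) -> tuple[CuratedDataset, "object", "object"]:
    """Shared front half: curation, scaling, component scan, VI fit."""
    table = load_table(
        config.input_path, config.input_format,
        missing_markers=config.curation.missing_markers,
    )
    curated = curate(table, config.curation)
    model_rows = curated.model_rows()
    scaling = robust_scale_fit(model_rows)
    scaled = scaling.transform(model_rows)
    scan = select_components(
        scaled,
        k_range=(config.k_min, config.k_max),
        rule=config.db_rule,
        patience=config.patience,
        seed=config.seed,
    )
    priors = make_priors(scaled, scan.opt, gamma_mode=config.gamma_mode)
    posterior = fit_variational(
        scaled, priors,
        tol=config.vi_tol, max_iter=config.vi_max_iter,
        seed=config.seed, scaling=scaling,
    )
    return curated, scan, posterior


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the four-stage workflow and write all artefacts.

    Stages: diagnostics, spectral component initialisation, variational
    training plus sampling of ``n_virtual`` patients, and validation of
    the synthetic cohort against the curated real one.  With n_virtual=0
    the metrics stage is skipped and an empty synthetic CSV is written.
    Any stage failure aborts with a stage-tagged error and removes
    partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}

    def _clock(stage: str, start: float) -> None:
        timings[stage] = round(time.perf_counter() - start, 4)

    try:
        t0 = time.perf_counter()
        try:
            curated, scan, posterior = _train(config)
        except Exception as exc:
            raise RuntimeError(f"[train] {exc}") from exc
        _clock("train", t0)

        t0 = time.perf_counter()
        try:
            synth = sample(
                posterior, config.n_virtual,
                seed=config.seed, weight_mode=config.weight_mode,
            )
        except Exception as exc:
            raise RuntimeError(f"[sample] {exc}") from exc
        _clock("sample", t0)

        names = curated.eligible_features
        synth_path = out / "synthetic.csv"
        pd.DataFrame(synth.matrix, columns=names).to_csv(
            synth_path, index=False, float_format=_FLOAT_FMT
        )
        written.append(synth_path)

        model_path = out / "model.json"
        posterior.save(model_path)
        written.append(model_path)

        scan_path = out / "cluster_scan.json"
        scan_path.write_text(scan.to_json())
        written.append(scan_path)

        log_path = out / "curation_log.jsonl"
        log_path.write_text(curated.log_jsonl())
        written.append(log_path)

        quality = None
        if config.n_virtual > 0:
            t0 = time.perf_counter()
            try:
                real = curated.model_rows()
                quality = quality_report(real, synth.matrix, feature_names=names)
            except Exception as exc:
                raise RuntimeError(f"[validate] {exc}") from exc
            _clock("validate", t0)
            pf_path = out / "quality_per_feature.csv"
            quality.per_feature.to_csv(pf_path, index=False, float_format=_FLOAT_FMT)
            written.append(pf_path)
            if config.write_kde_overlays:
                frames = []
                for j, name in enumerate(names):
                    grid, dr, ds = kde_overlay(real, synth.matrix, j)
                    frames.append(pd.DataFrame({
                        "feature": name, "grid": grid,
                        "density_real": dr, "density_synth": ds,
                    }))
                kde_path = out / "kde_overlays.csv"
                pd.concat(frames).to_csv(
                    kde_path, index=False, float_format=_FLOAT_FMT
                )
                written.append(kde_path)
        else:
            logger.info("n_virtual=0: metrics stage skipped")

        report = RunReport(
            config=config,
            opt=scan.opt,
            n_eligible_features=len(names),
            n_excluded_features=len(curated.excluded_features),
            n_outliers_flagged=int(curated.outlier_flags.sum()),
            quality=quality,
            synthetic_path=str(synth_path),
            model_path=str(model_path),
            scan_path=str(scan_path),
            report_path=str(out / "report.json"),
            curation_log_path=str(log_path),
            timings=timings,
        )
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report.to_dict(), indent=2))
        return report
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def sweep_population_sizes(
    config: RunConfig,
    sizes: list[int],
    seeds: list[int] | None = None,
    retrain_per_size: bool = False,
) -> pd.DataFrame:
    """Quality indicators across virtual-population sizes.

    The model is trained once and resampled at each size (pass
    ``retrain_per_size=True`` to refit for every size instead); with
    multiple ``seeds`` each (size, seed) pair is one sampling pass.
    Returns a tidy frame of (P, seed, cv_diff, inter, intra, gof, kl).
    """
    if any(P <= 0 for P in sizes):
        raise ValueError("population sizes must be positive")
    seeds = seeds if seeds is not None else [config.seed]
    rows = []
    if not retrain_per_size:
        curated, _, posterior = _train(config)
        real = curated.model_rows()
    for P in sizes:
        if retrain_per_size:
            curated, _, posterior = _train(config)
            real = curated.model_rows()
        for s in seeds:
            synth = sample(posterior, P, seed=s, weight_mode=config.weight_mode)
            rep = quality_report(real, synth.matrix)
            rows.append({
                "P": P, "seed": s,
                "cv_diff": rep.cv_diff,
                "inter_corr_diff": rep.inter_corr_diff,
                "intra_corr_diff": rep.intra_corr_diff,
                "gof": rep.gof,
                "kl": rep.kl,
            })
    return pd.DataFrame(rows)
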