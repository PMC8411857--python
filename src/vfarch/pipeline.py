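"""End-to-end pipeline: curate → fit/select-k → calibrate → decompose → score.

``run_pipeline`` executes the whole analysis for a config, writes every
artifact (model JSON, report CSVs) into an output directory together with
the resolved config and a manifest of content hashes, and is deterministic
for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration, scoring, selection, vf_data
from .aa import decompose, export_archetype_grid, fit_archetypes, serialize_model
from .errors import ValidationError, VfarchError


@dataclass
class PipelineConfig:
    cohort: str
    controls: str
    out_dir: str
    k_min: int = 2
    k_max: int = 20
    folds: int = 10
    seed: int = 0
    n_restarts: int = 5
    max_iter: int = 200
    threshold: float | None = None  # fixed threshold; None → calibrate
    margin: float = 2.0
    sign_rule: str = "median_split"
    include_blind_spot: bool = True
    mirror_os: bool = True
    cv_n_restarts: int = 1
    cv_max_iter: int = 60

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Stages: curate the cohort (reliability, failures, outcome window), fit
    archetype models over the k range and select k by the CV elbow, fit the
    final model on the uncurated reliable fields, calibrate the
    meaningful-weight threshold on the controls (unless fixed), decompose
    baseline fields, and emit the scoring report tables.  A stage failure
    aborts with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "validate"
    try:
        for p in (config.cohort, config.controls):
            if not Path(p).exists():
                raise ValidationError(f"input file {p} does not exist")
        (out / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))

        stage = "curate"
        cohort = vf_data.read_cohort(config.cohort, mirror_os=config.mirror_os)
        reliable = [vf_data.filter_reliable(s) for s in cohort]
        reliable = [s for s in reliable if s.fields]
        for s in reliable:
            failed, visit = vf_data.detect_treatment_failure(s)
            if failed:
                s.failure_status, s.failure_visit = "treatment_failure", visit
        curated = [vf_data.curate_outcome_window(s) for s in reliable]
        vf_data.write_cohort(curated, out / "curated.csv", mirror_os=config.mirror_os)

        stage = "fit"
        # model fit uses all reliable fields (unaveraged), as the fitting set
        fit_fields = [f for s in reliable for f in s.fields]
        X = vf_data.td_matrix(fit_fields, config.include_blind_spot)
        if config.k_max > X.shape[0]:
            raise ValidationError(
                f"k_max={config.k_max} exceeds the {X.shape[0]} available fields"
            )

        stage = "select-k"
        curve = selection.rss_curve(
            X,
            k_values=range(config.k_min, config.k_max + 1),
            folds=config.folds,
            seed=config.seed,
            n_restarts=config.n_restarts,
            max_iter=config.max_iter,
            cv_n_restarts=config.cv_n_restarts,
            cv_max_iter=config.cv_max_iter,
        )
        curve.to_frame().to_csv(out / "rss_curve.csv", index=False)
        k = selection.select_k_elbow(curve)

        stage = "fit-final"
        grid_name = "24-2/54" if config.include_blind_spot else "24-2/52"
        model = fit_archetypes(
            X,
            k,
            seed=config.seed,
            n_restarts=config.n_restarts,
            max_iter=config.max_iter,
            grid=grid_name,
        )
        serialize_model(model, out / "model.json")
        export_archetype_grid(model, out / "archetypes.csv")

        stage = "calibrate"
        if config.threshold is not None:
            threshold = float(config.threshold)
        else:
            controls = vf_data.read_cohort(config.controls, mirror_os=config.mirror_os)
            cal = calibration.calibrate(
                controls,
                model,
                margin=config.margin,
                seed=config.seed,
                include_blind_spot=config.include_blind_spot,
            )
            cal.to_frame().to_csv(out / "calibration.csv", index=False)
            (out / "threshold.json").write_text(
                json.dumps(
                    {
                        "threshold": cal.threshold,
                        "max_abnormal_upper": cal.max_abnormal_upper,
                        "margin": cal.margin,
                        "normal_archetype_ids": list(cal.normal_archetype_ids),
                    }
                )
            )
            threshold = float(cal.threshold)

        stage = "decompose"
        baselines = [
            f for s in curated for f in s.fields if f.visit == "baseline"
        ]
        decomps = [
            decompose(vf_data.td_matrix([f], config.include_blind_spot)[0], model)
            for f in baselines
        ]
        for d, f in zip(decomps, baselines):
            d.field_ref = f"{f.eye_id}/{f.visit}"
        weights = pd.DataFrame(
            [d.weights for d in decomps],
            columns=[f"w_{j+1}" for j in range(model.k)],
        )
        weights.insert(0, "eye_id", [f.eye_id for f in baselines])
        weights.to_csv(out / "baseline_weights.csv", index=False)

        stage = "score"
        signs = scoring.assign_signs(model, rule=config.sign_rule)
        meta = pd.DataFrame(
            {
                "md": [f.md for f in baselines],
                "psd": [f.psd for f in baselines],
                "arm": [f.arm for f in baselines],
            }
        )
        has_groups = meta["arm"].nunique(dropna=True) == 2
        report = scoring.cohort_report(
            decomps,
            threshold=threshold,
            signs=signs,
            metadata=meta,
            covariates=("md", "psd"),
            group_col="arm" if has_groups else None,
        )
        for name, df in report.items():
            df.to_csv(out / f"{name}.csv", index=False)
        at_sums = pd.DataFrame(
            {
                "eye_id": [f.eye_id for f in baselines],
                "at_sum": [scoring.at_sum(d, signs).value for d in decomps],
            }
        )
        at_sums.to_csv(out / "at_sum.csv", index=False)
    except VfarchError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
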