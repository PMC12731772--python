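"""End-to-end orchestration: simulate -> EDA -> label -> train -> calibrate
-> evaluate -> recommend, with artifact and manifest emission.

``run_pipeline`` executes every stage on a (possibly simulated) cohort and
writes all artifacts into an output directory: cohort CSV, EDA tables,
labeled table, classifier and calibration archives, evaluation reports for
both partitions and both probability variants, per-class recommendation
samples, and a manifest with seeds, stage warnings and SHA-256 checksums of
every artifact.  A single global seed fans out deterministically to the
cohort generator, the split and the network, so two runs with the same
configuration produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import yaml

from . import __version__, eda
from .ann import ANNConfig
from .cohort import CohortConfig, generate_cohort, write_cohort
from .fuzzy import CLASS_ORDER, RiskBands, SMFParams
from .model import T2DRiskModel
from .recommender import recommend

__all__ = ["PipelineConfig", "run_pipeline"]


class PipelineConfig:
    """Nested stage configuration, loadable from YAML.

    Sections: ``cohort`` (:class:`CohortConfig` fields), ``fuzzy``
    (``smf_a``, ``smf_b``, ``weights``, ``band_moderate``, ``band_high``),
    ``ann`` (:class:`ANNConfig` fields), ``calibration`` (``fit_on``),
    ``split`` (``train_frac``) and a global ``seed`` that propagates to
    every stage.
    """

    def __init__(self, seed=0, cohort=None, fuzzy=None, ann=None,
                 calibration=None, split=None):
        self.seed = int(seed)
        cohort = dict(cohort or {})
        for key in ("age_bands",):
            if key in cohort:
                cohort[key] = tuple(tuple(b) for b in cohort[key])
        for key in ("band_sizes", "band_cases", "thirst_params",
                    "urination_params", "fatigue_p", "family_history_p",
                    "smoking_p", "drinking_p"):
            if key in cohort:
                cohort[key] = tuple(cohort[key])
        cohort.setdefault("seed", self.seed)
        self.cohort = CohortConfig(**cohort)
        fuzzy = dict(fuzzy or {})
        self.smf_params = SMFParams(fuzzy.get("smf_a", 0.1), fuzzy.get("smf_b", 0.9))
        self.weights = fuzzy.get("weights")
        self.bands = RiskBands(fuzzy.get("band_moderate", 0.4), fuzzy.get("band_high", 0.7))
        ann = dict(ann or {})
        if "hidden_sizes" in ann:
            ann["hidden_sizes"] = tuple(ann["hidden_sizes"])
        ann.setdefault("seed", self.seed)
        self.ann = ANNConfig(**ann)
        self.calibrate_on = (calibration or {}).get("fit_on", "train")
        self.train_frac = (split or {}).get("train_frac", 0.7)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def run_pipeline(config: PipelineConfig | None = None, out_dir="t2drisk_run",
                 data=None, verbose: bool = False) -> dict:
    """Run every stage and persist artifacts; returns the manifest dict.

    ``data`` may supply an existing cohort DataFrame; otherwise one is
    simulated from ``config.cohort``.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    stage = "simulate"
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            if data is None:
                data = generate_cohort(config.cohort)
            write_cohort(data, out / "cohort.csv")

            stage = "eda"
            eda_dir = out / "eda"
            eda_dir.mkdir(exist_ok=True)
            eda.summarize(data).to_csv(eda_dir / "summary.csv")
            eda.cohort_prevalence(data, config.cohort.age_bands).to_csv(
                eda_dir / "prevalence.csv", index=False
            )
            eda.associations(data).to_csv(eda_dir / "associations.csv")
            _write_json(eda.quality_checks(data), eda_dir / "quality.json")

            stage = "fit"
            model = T2DRiskModel(
                data,
                smf_params=config.smf_params,
                weights=config.weights,
                bands=config.bands,
                ann_config=config.ann,
                train_frac=config.train_frac,
                calibrate_on=config.calibrate_on,
                seed=config.seed,
            )
            results = model.fit()
            results.labeled.to_csv(out / "labeled.csv", index=False)
            results.classifier.save(out / "classifier.json")
            results.calibration.to_json(out / "calibration.json")

            stage = "evaluate"
            for part in ("train", "test"):
                payload = {
                    tag: results.report(part, tag) for tag in ("raw", "calibrated")
                }
                _write_json(payload, out / f"evaluation_{part}.json")
                for tag in ("raw", "calibrated"):
                    results.confusion(part, tag).to_csv(
                        out / f"confusion_{part}_{tag}.csv"
                    )
            results.anova.to_csv(out / "feature_importance.csv")
            (out / "summary.txt").write_text(results.summary() + "\n")

            stage = "recommend"
            recs = {cls: recommend(cls).to_dict() for cls in CLASS_ORDER}
            _write_json(recs, out / "recommendations.json")
            caught = sorted({str(w.message) for w in wlist})
    except Exception as exc:
        _write_json(
            {"failed_stage": stage, "error": str(exc)}, out / "manifest.json"
        )
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    artifacts = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_total": config.cohort.n_total,
        "stages": ["simulate", "eda", "fit", "evaluate", "recommend"],
        "warnings": caught,
        "test_accuracy": results.test_accuracy,
        "test_macro_auc": results.test_macro_auc,
        "checksums": {a: _sha256(out / a) for a in artifacts},
    }
    _write_json(manifest, out / "manifest.json")
    if verbose:
        print(results.summary())
    return manifest
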