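"""Model/Results interface tying the pipeline stages together.

:class:`T2DRiskModel` is built from a lifestyle cohort DataFrame and owns
the configuration of every stage: fuzzy risk labeling (S-membership
parameters, composite weights, class bands), the feed-forward classifier,
and the monotone-spline probability calibration.  ``fit()`` labels the
cohort, performs a stratified 70/30 split, trains the network on the
normalized original features (never on the fuzzified score), fits the
calibration on the training partition, and returns a
:class:`T2DRiskResults` carrying confusion matrices, threshold metrics and
one-vs-rest AUCs for raw and calibrated probabilities on both partitions,
ANOVA-F feature importances, and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import eda
from .ann import ANNConfig, FeedForwardClassifier, stratified_split
from .calibration import apply_calibration, fit_calibration
from .cohort import COLUMNS
from .evaluation import (
    anova_f_scores,
    confusion_and_metrics,
    format_percent,
    ovr_roc_auc,
    report_to_text,
)
from .fuzzy import (
    CLASS_ORDER,
    DEFAULT_WEIGHTS,
    FeatureScaler,
    RiskBands,
    SMFParams,
    label_table,
)
from .recommender import recommend

__all__ = ["T2DRiskModel", "T2DRiskResults"]

#: All ten predictor columns fed to the classifier.
PREDICTORS = tuple(c for c in COLUMNS if c != "outcome")


class T2DRiskModel:
    """Fuzzy-labeled multi-class risk model over a lifestyle cohort."""

    def __init__(
        self,
        data: pd.DataFrame,
        smf_params: SMFParams = SMFParams(),
        weights: dict | None = None,
        bands: RiskBands = RiskBands(),
        ann_config: ANNConfig | None = None,
        train_frac: float = 0.7,
        calibrate_on: str = "train",
        seed: int = 0,
    ):
        missing = [c for c in COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"cohort data missing columns: {missing}")
        if calibrate_on not in ("train", "test"):
            raise ValueError("calibrate_on must be 'train' or 'test'")
        self.data = data.reset_index(drop=True)
        self.smf_params = smf_params
        self.weights = dict(weights) if weights is not None else dict(DEFAULT_WEIGHTS)
        self.bands = bands
        self.seed = int(seed)
        self.ann_config = ann_config or ANNConfig(seed=self.seed)
        self.train_frac = float(train_frac)
        self.calibrate_on = calibrate_on

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "T2DRiskModel":
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "T2DRiskModel":
        from .cohort import read_cohort

        return cls(read_cohort(path), **kwargs)

    def fit(self) -> "T2DRiskResults":
        data = self.data
        quality = eda.quality_checks(data)

        labeled, _ = label_table(data, self.smf_params, self.weights, self.bands)
        y = labeled["risk_class"].to_numpy()

        scaler = FeatureScaler().fit(data, PREDICTORS)
        X = scaler.transform(data).to_numpy()

        train_idx, test_idx = stratified_split(y, train_frac=self.train_frac, seed=self.seed)
        clf = FeedForwardClassifier(self.ann_config, classes=CLASS_ORDER)
        clf.fit(X[train_idx], y[train_idx])

        P_train = clf.predict_proba(X[train_idx])
        P_test = clf.predict_proba(X[test_idx])
        cal_idx = train_idx if self.calibrate_on == "train" else test_idx
        P_cal = P_train if self.calibrate_on == "train" else P_test
        calibration = fit_calibration(P_cal, y[cal_idx], classes=CLASS_ORDER)

        return T2DRiskResults(
            model=self,
            labeled=labeled,
            scaler=scaler,
            classifier=clf,
            calibration=calibration,
            train_idx=train_idx,
            test_idx=test_idx,
            y=y,
            quality=quality,
        )


class T2DRiskResults:
    """Fitted-model container with metrics, diagnostics and predictions."""

    def __init__(
        self, model, labeled, scaler, classifier, calibration, train_idx, test_idx, y, quality
    ):
        self.model = model
        self.labeled = labeled
        self.scaler = scaler
        self.classifier = classifier
        self.calibration = calibration
        self.train_idx = train_idx
        self.test_idx = test_idx
        self.y = y
        self.quality = quality
        self._evaluate()

    # -- evaluation --------------------------------------------------------
    def _features(self, data=None) -> np.ndarray:
        data = self.model.data if data is None else data
        return self.scaler.transform(data).to_numpy()

    def _evaluate(self):
        X = self._features()
        self.reports = {}
        for part, idx in (("train", self.train_idx), ("test", self.test_idx)):
            P_raw = self.classifier.predict_proba(X[idx])
            P_cal = apply_calibration(self.calibration, P_raw)
            y_part = self.y[idx]
            for tag, P in (("raw", P_raw), ("calibrated", P_cal)):
                pred = np.asarray(CLASS_ORDER, dtype=object)[P.argmax(axis=1)]
                confusion, report = confusion_and_metrics(y_part, pred, CLASS_ORDER)
                auc = ovr_roc_auc(P, y_part, CLASS_ORDER)
                self.reports[(part, tag)] = {
                    "confusion": confusion,
                    "metrics": report,
                    "auc": auc,
                }
        self.anova = anova_f_scores(
            pd.DataFrame(X, columns=PREDICTORS), self.y
        ).sort_values("F", ascending=False)

    # -- convenience accessors --------------------------------------------
    @property
    def test_accuracy(self) -> float:
        return self.reports[("test", "calibrated")]["metrics"]["accuracy"]

    @property
    def test_macro_auc(self) -> float:
        return self.reports[("test", "calibrated")]["auc"]["macro"]

    def confusion(self, partition="test", probabilities="calibrated"):
        return self.reports[(partition, probabilities)]["confusion"]

    def report(self, partition="test", probabilities="calibrated") -> dict:
        r = self.reports[(partition, probabilities)]
        return {"metrics": r["metrics"], "auc": r["auc"]}

    # -- prediction on new data -------------------------------------------
    def predict_proba(self, data: pd.DataFrame, calibrated: bool = True) -> np.ndarray:
        P = self.classifier.predict_proba(self._features(data))
        return apply_calibration(self.calibration, P) if calibrated else P

    def predict(self, data: pd.DataFrame, calibrated: bool = True) -> np.ndarray:
        P = self.predict_proba(data, calibrated=calibrated)
        return np.asarray(CLASS_ORDER, dtype=object)[P.argmax(axis=1)]

    def recommend(self, risk_class: str, profile: dict | None = None):
        """Lifestyle recommendation plan for a predicted class."""
        return recommend(risk_class, profile)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        n = len(self.model.data)
        counts = pd.Series(self.y).value_counts().reindex(CLASS_ORDER, fill_value=0)
        lines = [
            "T2D lifestyle risk model",
            "========================",
            f"observations: {n}   train: {len(self.train_idx)}   test: {len(self.test_idx)}",
            "class counts: " + "  ".join(f"{c}={counts[c]}" for c in CLASS_ORDER),
            f"epochs trained: {self.classifier.n_epochs_}",
            "",
        ]
        for tag in ("raw", "calibrated"):
            r = self.reports[("test", tag)]
            lines.append(
                report_to_text(r["metrics"], r["auc"], title=f"test partition ({tag})")
            )
            lines.append("")
        top = self.anova.head(4)
        lines.append(
            "top features by ANOVA F: "
            + ", ".join(f"{f} ({row.F:.0f})" for f, row in top.iterrows())
        )
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<T2DRiskResults n={len(self.model.data)} "
            f"test_accuracy={format_percent(self.test_accuracy)} "
            f"macro_auc={format_percent(self.test_macro_auc)}>"
        )
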