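"""Subject-specific attention model: calibration, scoring, persistence.

Calibration takes labelled epochs (attentive vs relaxed), extracts the
24 band-power features per epoch, ranks features by mutual information
with the label, and fits a ridge-regularised linear regression of the
±1 label coding on the top-k standardised features.  The regression
output is the raw BASM (BCI ADHD severity measure) — unbounded, higher
when more attentive — and a logistic display map anchored to the class
means turns it into the 0–100 score shown to the player.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import Ridge

from . import preprocessing
from .features import FeatureVector, FilterBank, default_bank, extract_features
from .recording import EEGRecording
from .synthetic import CalibrationDataset

SCHEMA_VERSION = 1
LABEL_CODING = {"attentive": 1.0, "relaxed": -1.0}
_LOGIT_75 = float(np.log(3.0))  # logit of the 75% anchor
_SD_FLOOR = 1e-12


@dataclass
class BASMScore:
    """Raw (unbounded) attention score and its 0–100 display transform."""

    raw: float
    display: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.display <= 100.0:
            raise ValueError(f"display score {self.display} outside [0, 100]")


def mutual_information(feature: np.ndarray, labels: np.ndarray,
                       n_bins: int = 8) -> float:
    """Mutual information (bits) between a discretised feature and a label.

    The feature is discretised into ``n_bins`` equal-frequency bins
    (quantile edges) and the plug-in MI of the bin x label contingency is
    computed, with the Miller–Madow bias correction
    (occupied_bins − 1)(labels − 1) / (2 N ln 2) subtracted and the result
    floored at zero.  Equal-frequency binning makes the estimate invariant
    under strictly monotone feature transforms; a constant feature gives
    exactly 0.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("feature and labels must be equal-length 1-D arrays")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = len(x)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    bins = np.searchsorted(edges, x, side="right")
    _, bins = np.unique(bins, return_inverse=True)
    _, ys = np.unique(y, return_inverse=True)
    r, c = bins.max() + 1, ys.max() + 1
    if r < 2 or c < 2:
        return 0.0
    joint = np.zeros((r, c))
    np.add.at(joint, (bins, ys), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float((joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum())
    mi -= (r - 1) * (c - 1) / (2.0 * n * np.log(2.0))
    return max(mi, 0.0)


def select_features(features: np.ndarray, labels: np.ndarray,
                    k: int = 6, n_bins: int = 8) -> list[int]:
    """Top-k feature indices by MI with the label, descending.

    Ties are broken by ascending feature index, so selection is stable.
    """
    F = np.asarray(features, dtype=float)
    if F.ndim != 2:
        raise ValueError("features must be an (epochs x features) matrix")
    if not 1 <= k <= F.shape[1]:
        raise ValueError(f"k must be in [1, {F.shape[1]}], got {k}")
    mi = np.array([mutual_information(F[:, j], labels, n_bins)
                   for j in range(F.shape[1])])
    order = sorted(range(F.shape[1]), key=lambda j: (-mi[j], j))
    return order[:k]


@dataclass
class AttentionModel:
    """Calibrated subject-specific scorer.

    ``selected`` are the feature indices kept by MI ranking; ``weights``
    and ``intercept`` the ridge regression of the ±1 label coding on the
    standardised selected features; ``display_center``/``display_scale``
    parameterise display = 100 · logistic((raw − center) / scale),
    anchored so the mean attentive calibration epoch lands near 75 and
    the mean relaxed epoch near 25.
    """

    selected: list[int]
    weights: np.ndarray
    intercept: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    display_center: float
    display_scale: float
    bank: FilterBank = field(default_factory=default_bank)
    log_scale: bool = True
    block_len: float = 2.0
    subject_id: str = "anon"
    visit_tag: str = "week0"
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.feature_mean = np.asarray(self.feature_mean, dtype=float)
        self.feature_sd = np.asarray(self.feature_sd, dtype=float)
        n_feat = len(self.feature_mean)
        if len(set(self.selected)) != len(self.selected) or any(
                not 0 <= j < n_feat for j in self.selected):
            raise ValueError(f"selected indices must be unique and in [0, {n_feat - 1}]")
        if (self.feature_sd <= 0).any():
            raise ValueError("standardizer sds must be positive")
        if self.display_scale <= 0:
            raise ValueError("display_scale must be positive")

    # -- scoring ---------------------------------------------------------

    def raw_score(self, values: np.ndarray) -> float:
        values = np.asarray(values, dtype=float)
        if values.shape != self.feature_mean.shape:
            raise ValueError(
                f"feature length mismatch: model expects "
                f"{self.feature_mean.shape[0]}, got {values.shape}")
        z = (values - self.feature_mean) / self.feature_sd
        return float(z[self.selected] @ self.weights + self.intercept)

    def display_score(self, raw: float) -> float:
        from scipy.special import expit  # overflow-safe logistic

        z = (raw - self.display_center) / self.display_scale
        return float(100.0 * expit(z))

    # -- persistence -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema_version": self.schema_version,
            "subject_id": self.subject_id,
            "visit_tag": self.visit_tag,
            "selected": list(map(int, self.selected)),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "display_center": self.display_center,
            "display_scale": self.display_scale,
            "bank": [list(b) for b in self.bank.bands],
            "log_scale": self.log_scale,
            "block_len": self.block_len,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AttentionModel":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema {d.get('schema_version')!r}")
        return cls(
            selected=list(d["selected"]),
            weights=np.array(d["weights"]),
            intercept=d["intercept"],
            feature_mean=np.array(d["feature_mean"]),
            feature_sd=np.array(d["feature_sd"]),
            display_center=d["display_center"],
            display_scale=d["display_scale"],
            bank=FilterBank(tuple(tuple(b) for b in d["bank"])),
            log_scale=d["log_scale"],
            block_len=d["block_len"],
            subject_id=d["subject_id"],
            visit_tag=d["visit_tag"],
        )


def epoch_features(epoch: EEGRecording, bank: FilterBank,
                   log_scale: bool = True,
                   block_len: float = 2.0,
                   screen: bool = True) -> FeatureVector:
    """Screen one epoch for artifacts and extract its feature vector."""
    mask = (preprocessing.detect_artifacts(epoch) if screen
            else preprocessing.ArtifactMask())
    blocks = preprocessing.apply_mask(epoch, mask, block_len=block_len)
    return extract_features(blocks, bank=bank, log_scale=log_scale)


def calibration_features(cal: CalibrationDataset, bank: FilterBank,
                         log_scale: bool = True, block_len: float = 2.0,
                         screen: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (epochs x 24) and ±1 label coding for a dataset."""
    rows, ys = [], []
    for epoch, label in cal.epochs:
        if label not in LABEL_CODING:
            raise ValueError(f"unknown label {label!r}")
        try:
            fv = epoch_features(epoch, bank, log_scale, block_len, screen)
        except ValueError:
            warnings.warn(f"epoch at {epoch.start_time}s fully masked; skipped")
            continue
        rows.append(fv.values)
        ys.append(LABEL_CODING[label])
    return np.array(rows), np.array(ys)


def _fit_from_features(F: np.ndarray, y: np.ndarray, k: int, ridge: float,
                       n_bins: int, bank: FilterBank, log_scale: bool,
                       block_len: float, subject_id: str,
                       visit_tag: str) -> AttentionModel:
    if len(np.unique(y)) < 2:
        raise ValueError("calibration needs both attentive and relaxed epochs")
    mean = F.mean(axis=0)
    sd = np.maximum(F.std(axis=0, ddof=0), _SD_FLOOR)
    Z = (F - mean) / sd
    selected = select_features(Z, y, k=k, n_bins=n_bins)
    reg = Ridge(alpha=ridge, fit_intercept=True)
    reg.fit(Z[:, selected], y)
    weights = np.asarray(reg.coef_, dtype=float)
    intercept = float(reg.intercept_)

    # Display map anchors: raw score at the class-mean feature vectors.
    r_att = float(Z[y > 0][:, selected].mean(axis=0) @ weights + intercept)
    r_rel = float(Z[y < 0][:, selected].mean(axis=0) @ weights + intercept)
    center = 0.5 * (r_att + r_rel)
    scale = max((r_att - r_rel) / (2.0 * _LOGIT_75), _SD_FLOOR)
    return AttentionModel(
        selected=selected, weights=weights, intercept=intercept,
        feature_mean=mean, feature_sd=sd,
        display_center=center, display_scale=scale,
        bank=bank, log_scale=log_scale, block_len=block_len,
        subject_id=subject_id, visit_tag=visit_tag)


def fit_attention_model(cal: CalibrationDataset,
                        bank: FilterBank | None = None,
                        k: int = 6,
                        ridge: float = 1.0,
                        n_bins: int = 8,
                        log_scale: bool = True,
                        block_len: float = 2.0,
                        visit_tag: str = "week0",
                        screen: bool = True) -> AttentionModel:
    """Calibrate a subject-specific attention model from labelled epochs.

    The fit is fully deterministic: refitting on identical data returns an
    identical model.

    Parameters
    ----------
    cal : CalibrationDataset
        Labelled attentive/relaxed epochs for one subject.
    bank : FilterBank, optional
        Band layout (default: 8 equal bands over 4–30 Hz).
    k : int
        Number of features kept by MI ranking (default 6).
    ridge : float
        L2 penalty of the regression (default 1.0).
    """
    if bank is None:
        bank = default_bank()
    F, y = calibration_features(cal, bank, log_scale, block_len, screen)
    if len(F) == 0:
        raise ValueError("no usable epochs after artifact screening")
    return _fit_from_features(F, y, k, ridge, n_bins, bank, log_scale,
                              block_len, cal.subject_id, visit_tag)


def basm_score(model: AttentionModel, fv: FeatureVector | np.ndarray) -> BASMScore:
    """Score one feature vector with a calibrated model.

    Returns the raw BASM (regression output; unbounded, higher = more
    attentive) and the 0–100 display score used for game feedback.
    """
    if isinstance(fv, FeatureVector):
        if fv.bank.bands != model.bank.bands:
            raise ValueError("feature vector was built with a different filter bank")
        if fv.log_scale != model.log_scale:
            raise ValueError("feature vector log-scale flag differs from the model's")
        values = fv.values
    else:
        values = np.asarray(fv, dtype=float)
    raw = model.raw_score(values)
    return BASMScore(raw=raw, display=model.display_score(raw))


def leave_one_out_accuracy(cal: CalibrationDataset,
                           bank: FilterBank | None = None,
                           k: int = 6, ridge: float = 1.0,
                           n_bins: int = 8,
                           labels_override: np.ndarray | None = None) -> float:
    """Leave-one-out accuracy of sign(raw) as an attentive/relaxed classifier.

    Features are extracted once and the model refit per held-out epoch.
    ``labels_override`` substitutes an arbitrary ±1 labelling (e.g. a
    shuffled one, to establish the chance floor).
    """
    if bank is None:
        bank = default_bank()
    F, y = calibration_features(cal, bank)
    if labels_override is not None:
        y = np.asarray(labels_override, dtype=float)
        if y.shape != (len(F),):
            raise ValueError("labels_override length mismatch")
    hits = 0
    idx = np.arange(len(F))
    for i in idx:
        tr = idx != i
        model = _fit_from_features(F[tr], y[tr], k, ridge, n_bins, bank,
                                   True, 2.0, cal.subject_id, "loo")
        pred = 1.0 if model.raw_score(F[i]) > 0 else -1.0
        hits += pred == y[i]
    return hits / len(F)
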