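"""Consensus ground truth, the focus-vs-rosette classifier, and error rates.

Ground truth comes from multiple independent raters: each rater marks the
N-cadherin⁺ polarization areas in a tissue and says which of them are
rosettes. A region becomes ground truth only when a quorum of raters (4 of 5
by default) agrees on its class. A logistic-regression classifier is then
trained on the standardized eight-descriptor vectors of the consensus
regions, and identification error rates are computed against the consensus.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .descriptors import DESCRIPTOR_NAMES, DescriptorVector

__all__ = [
    "FOCUS",
    "ROSETTE",
    "ABSENT",
    "NO_CONSENSUS",
    "ExpertAnnotation",
    "ConsensusLabel",
    "ClassifierModel",
    "ErrorReport",
    "build_consensus",
    "train_classifier",
    "predict",
    "compute_error_rates",
    "match_by_centroid",
]

FOCUS = "focus"
ROSETTE = "rosette"
ABSENT = "absent"
NO_CONSENSUS = "no_consensus"


@dataclass(frozen=True)
class ExpertAnnotation:
    """One rater's labels for the regions of one tissue.

    ``labels`` maps region id to ``focus`` / ``rosette`` / ``absent``
    (absent = the rater did not identify this polarization area).
    """

    expert_id: str
    tissue_id: str
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {FOCUS, ROSETTE, ABSENT}
        if bad:
            raise ValueError(f"unknown labels {bad}; expected focus/rosette/absent")


@dataclass(frozen=True)
class ConsensusLabel:
    region_id: str
    label: str  # focus | rosette | no_consensus
    votes: Mapping[str, int]


@dataclass(frozen=True)
class ClassifierModel:
    """Standardized logistic discriminator over the 8 descriptors.

    ``P(rosette | x) = sigmoid(intercept + weights · (x - center) / scale)``;
    a region is called a rosette when the probability reaches
    ``decision_threshold`` (ties at the threshold go to rosette).
    """

    weights: np.ndarray  # (8,)
    intercept: float
    center: np.ndarray  # (8,)
    scale: np.ndarray  # (8,) all > 0
    decision_threshold: float = 0.5
    feature_names: tuple[str, ...] = DESCRIPTOR_NAMES
    config_hash: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)) or not math.isfinite(self.intercept):
            raise ValueError("model parameters must be finite")
        if np.any(self.scale <= 0):
            raise ValueError("standardization scales must be > 0")

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "rosettequant-classifier-v1",
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "decision_threshold": self.decision_threshold,
            "config_hash": self.config_hash,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "rosettequant-classifier-v1":
            raise ValueError(f"{path}: not a rosettequant classifier file")
        return cls(
            weights=np.asarray(payload["weights"], dtype=np.float64),
            intercept=float(payload["intercept"]),
            center=np.asarray(payload["center"], dtype=np.float64),
            scale=np.asarray(payload["scale"], dtype=np.float64),
            decision_threshold=float(payload["decision_threshold"]),
            feature_names=tuple(payload["feature_names"]),
            config_hash=payload.get("config_hash", ""),
        )


@dataclass(frozen=True)
class ErrorReport:
    foci_error_pct: float
    rosette_error_pct: float
    counts: Mapping[str, int]
    capped: bool = False


def build_consensus(
    annotations: Sequence[ExpertAnnotation],
    quorum: int = 4,
    n_experts: int = 5,
) -> list[ConsensusLabel]:
    """Quorum voting over rater annotations.

    A region's label is the class voted for by at least ``quorum`` of the
    ``n_experts`` raters; raters that did not mention a region vote
    ``absent`` for it. Regions where no class reaches quorum — including
    those the quorum agrees are absent — are ``no_consensus`` and excluded
    from training.
    """
    if quorum > n_experts:
        raise ValueError(f"quorum {quorum} exceeds number of experts {n_experts}")
    experts = [a.expert_id for a in annotations]
    if len(set(experts)) != len(experts):
        raise ValueError("duplicate expert_id in annotations")
    if len(annotations) != n_experts:
        raise ValueError(f"expected {n_experts} annotations, got {len(annotations)}")
    region_ids = sorted({rid for a in annotations for rid in a.labels})
    out: list[ConsensusLabel] = []
    for rid in region_ids:
        votes = {FOCUS: 0, ROSETTE: 0, ABSENT: 0}
        for a in annotations:
            votes[a.labels.get(rid, ABSENT)] += 1
        label = NO_CONSENSUS
        for cls in (FOCUS, ROSETTE):
            if votes[cls] >= quorum:
                label = cls
        out.append(ConsensusLabel(region_id=rid, label=label, votes=votes))
    return out


def _stack_vectors(vectors: Sequence[DescriptorVector | np.ndarray]) -> np.ndarray:
    rows = []
    for v in vectors:
        if isinstance(v, DescriptorVector):
            if not v.scorable:
                raise ValueError("unscorable descriptor vector passed to classifier")
            rows.append(v.as_array())
        else:
            rows.append(np.asarray(v, dtype=np.float64))
    X = np.vstack(rows)
    if X.shape[1] != len(DESCRIPTOR_NAMES):
        raise ValueError(f"expected {len(DESCRIPTOR_NAMES)} features, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    return X


def train_classifier(
    vectors: Sequence[DescriptorVector | np.ndarray],
    labels: Sequence[str],
    seed: int = 0,
    l2_c: float = 1.0,
    config_hash: str = "",
) -> ClassifierModel:
    """Fit the logistic focus-vs-rosette discriminator.

    Features are standardized with training-set mean and standard deviation;
    constant features are kept but neutralized (unit scale, zero weight by
    construction) with a warning. The fit is a maximum-likelihood logistic
    regression with light L2 regularization: at the default ``l2_c=1`` the
    penalty strength is 1/n in the average-loss parameterization, i.e.
    near-MLE at the few-hundred-sample scale this tool operates at.
    """
    X = _stack_vectors(vectors)
    y = np.asarray([1 if l == ROSETTE else 0 for l in labels], dtype=np.int64)
    if len(y) != X.shape[0]:
        raise ValueError("vectors and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    for cls in (0, 1):
        if np.sum(y == cls) < 2:
            raise ValueError("need at least 2 examples per class")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    const = scale == 0
    if const.any():
        names = [DESCRIPTOR_NAMES[i] for i in np.flatnonzero(const)]
        warnings.warn(f"constant feature(s) dropped from fit: {names}", stacklevel=2)
        scale = np.where(const, 1.0, scale)
    Z = (X - center) / scale
    clf = LogisticRegression(
        C=l2_c, solver="lbfgs", max_iter=5000, random_state=seed
    )
    clf.fit(Z, y)
    return ClassifierModel(
        weights=clf.coef_[0].astype(np.float64),
        intercept=float(clf.intercept_[0]),
        center=center,
        scale=scale,
        config_hash=config_hash,
    )


def predict(
    model: ClassifierModel, vector: DescriptorVector | np.ndarray
) -> tuple[str, float]:
    """Class label and rosette probability for one descriptor vector."""
    if isinstance(vector, DescriptorVector):
        if not vector.scorable:
            raise ValueError("cannot predict on an unscorable vector")
        x = vector.as_array()
    else:
        x = np.asarray(vector, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features")
    z = (x - model.center) / model.scale
    logit = model.intercept + float(np.dot(model.weights, z))
    prob = 1.0 / (1.0 + math.exp(-logit)) if logit > -700 else 0.0
    label = ROSETTE if prob >= model.decision_threshold else FOCUS
    return label, prob


def compute_error_rates(
    predicted: Mapping[str, str],
    consensus: Sequence[ConsensusLabel],
) -> ErrorReport:
    """Identification error rates of a set of predictions vs. the consensus.

    Foci (identification) error: consensus polarization areas the detector
    missed plus spurious detections, over the total number of consensus
    areas. Rosette error: consensus rosettes missed or called focus, plus
    non-rosette consensus areas called rosette, over the same denominator.
    Detections that fall on ``no_consensus`` regions are ignored. Rates are
    capped at 100% (flagged) when spurious detections outnumber areas.
    """
    if not consensus:
        raise ValueError("consensus is empty")
    area_labels = {c.region_id: c.label for c in consensus if c.label in (FOCUS, ROSETTE)}
    nc_ids = {c.region_id for c in consensus if c.label == NO_CONSENSUS}
    total = len(area_labels)
    if total == 0:
        raise ValueError("consensus contains no polarization areas")
    missed = [rid for rid in area_labels if rid not in predicted]
    spurious = [rid for rid in predicted if rid not in area_labels and rid not in nc_ids]
    rosette_err = 0
    for rid, truth in area_labels.items():
        pred = predicted.get(rid)
        if truth == ROSETTE and pred != ROSETTE:
            rosette_err += 1  # missed or mislabeled rosette
        elif truth == FOCUS and pred == ROSETTE:
            rosette_err += 1  # focus promoted to rosette
    foci_pct = (len(missed) + len(spurious)) / total * 100.0
    rosette_pct = rosette_err / total * 100.0
    capped = foci_pct > 100.0 or rosette_pct > 100.0
    counts = {
        "total_consensus_areas": total,
        "missed": len(missed),
        "spurious": len(spurious),
        "rosette_label_errors": rosette_err,
    }
    return ErrorReport(
        foci_error_pct=min(foci_pct, 100.0),
        rosette_error_pct=min(rosette_pct, 100.0),
        counts=counts,
        capped=capped,
    )


def match_by_centroid(
    region_centroids: Sequence[tuple[float, float]],
    region_radii: Sequence[float],
    points: Sequence[tuple[float, float]],
    min_match_px: float = 20.0,
) -> dict[int, int]:
    """Greedy nearest matching of annotated points to detected regions.

    A point matches region i when it is the nearest point to that region's
    centroid and lies within ``max(radius_px, min_match_px)``. Returns a
    point-index → region-index mapping; unmatched points are detector
    misses, unmatched regions spurious detections.
    """
    if not points or not region_centroids:
        return {}
    cent = np.asarray(region_centroids, dtype=np.float64)
    pts = np.asarray(points, dtype=np.float64)
    dist = np.linalg.norm(pts[:, None, :] - cent[None, :, :], axis=2)
    tol = np.maximum(np.asarray(region_radii, dtype=np.float64), min_match_px)
    pairs = sorted(
        ((dist[p, r], p, r) for p in range(len(pts)) for r in range(len(cent)) if dist[p, r] <= tol[r]),
    )
    matched: dict[int, int] = {}
    used_regions: set[int] = set()
    for _, p, r in pairs:
        if p in matched or r in used_regions:
            continue
        matched[p] = r
        used_regions.add(r)
    return matched
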