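"""Cross-dataset prediction, robust affine correction, outlier taxonomy.

A model trained on one dataset predicts the other; a systematic offset from
the differing level of theory is compensated a posteriori by a robust
affine fit (Huber loss, reference regressed on predicted so the correction
applies to new predictions).  Errors are then reported separately for the
common and exclusive subsets, outliers beyond fixed thresholds (30 kcal/mol
for energies, 1.5 eV for orbital energies) are extracted, and every outlier
is attributed to classes: open-shell species (multiplicity > 1), functional
groups, or unclassified.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import HuberRegressor

from .models import KRRModel, ModelSpec, predict_krr

#: default outlier thresholds: energies in kcal/mol, orbitals in eV
DEFAULT_THRESHOLDS = {"E": 30.0, "homo": 1.5, "lumo": 1.5}


def cross_predict(model, spec: ModelSpec, X_other: np.ndarray) -> np.ndarray:
    """Raw predictions of a trained model on another dataset's descriptors.

    The caller must have built ``X_other`` with the same n_max and scaling
    statistics as the training set; a feature-length mismatch is refused.
    """
    if isinstance(model, KRRModel) and X_other.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"descriptor length mismatch: model expects {model.X_train.shape[1]} "
            f"features, got {X_other.shape[1]} (different n_max?)"
        )
    return spec.predict(model, X_other)


@dataclass
class AffineCorrection:
    """reference ~ a * predicted + b, fitted with Huber loss."""

    slope: float
    intercept: float
    epsilon: float
    n: int
    residual_scale: float

    def apply(self, predicted: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(predicted) + self.intercept


def fit_affine_correction(
    predicted: np.ndarray,
    reference: np.ndarray,
    epsilon: float = 1.35,
) -> AffineCorrection:
    """Robust a-posteriori linear correction of systematic prediction bias.

    Minimizes the Huber loss of (reference - a*predicted - b); ``epsilon``
    is the Huber threshold in units of the jointly estimated residual
    scale, so gross outliers get linear (not quadratic) weight.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(predicted) < 3:
        raise ValueError("need at least 3 pairs to fit an affine correction")
    if np.std(predicted) == 0:
        raise ValueError("zero-variance predictions: affine correction undefined")
    huber = HuberRegressor(epsilon=epsilon, alpha=0.0, max_iter=1000, tol=1e-10)
    huber.fit(predicted[:, None], reference)
    resid = reference - huber.predict(predicted[:, None])
    scale = float(np.median(np.abs(resid - np.median(resid))) / 0.6744897501960817)
    return AffineCorrection(
        slope=float(huber.coef_[0]),
        intercept=float(huber.intercept_),
        epsilon=epsilon,
        n=len(predicted),
        residual_scale=scale,
    )


def subset_mae(
    corrected: np.ndarray,
    reference: np.ndarray,
    common_index: np.ndarray | list[int],
    exclusive_index: np.ndarray | list[int],
) -> dict[str, float | None]:
    """MAE on the common (A) and exclusive (B) subsets, plus pooled."""
    corrected = np.asarray(corrected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    err = np.abs(corrected - reference)

    def _mae(idx):
        idx = np.asarray(idx, dtype=int)
        return float(err[idx].mean()) if len(idx) else None

    return {
        "mae_common": _mae(common_index),
        "mae_exclusive": _mae(exclusive_index),
        "mae_pooled": float(err.mean()) if len(err) else None,
        "n_common": len(common_index),
        "n_exclusive": len(exclusive_index),
    }


@dataclass
class OutlierReport:
    property_name: str
    threshold: float
    outlier_index: np.ndarray
    n_total: int
    #: class tallies over the outliers (a molecule may appear in several)
    n_multiplet: int = 0
    group_tallies: dict[str, int] = field(default_factory=dict)
    n_unclassified: int = 0

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_index)

    @property
    def outlier_fraction(self) -> float:
        return self.n_outliers / self.n_total if self.n_total else 0.0


def extract_outliers(
    corrected: np.ndarray,
    reference: np.ndarray,
    property_name: str = "E",
    threshold: float | None = None,
    multiplicities: np.ndarray | None = None,
    group_table: list[set[str]] | None = None,
) -> OutlierReport:
    """Molecules whose absolute (corrected) error strictly exceeds the threshold.

    When multiplicity metadata and a per-molecule group table are supplied,
    the outliers are tallied into an open-shell class and per-functional-group
    classes; outliers in neither are counted unclassified.
    """
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[property_name]
    err = np.abs(np.asarray(corrected, dtype=float) - np.asarray(reference, dtype=float))
    idx = np.flatnonzero(err > threshold)
    report = OutlierReport(
        property_name=property_name,
        threshold=threshold,
        outlier_index=idx,
        n_total=len(err),
    )
    for i in idx:
        classified = False
        if multiplicities is not None and multiplicities[i] > 1:
            report.n_multiplet += 1
            classified = True
        if group_table is not None:
            for g in group_table[i]:
                report.group_tallies[g] = report.group_tallies.get(g, 0) + 1
                classified = True
        if not classified:
            report.n_unclassified += 1
    return report


def group_mae(
    corrected: np.ndarray,
    reference: np.ndarray,
    group_table: list[set[str]],
) -> pd.DataFrame:
    """Per-functional-group occurrence counts and MAE.

    A molecule bearing several groups contributes to every matching row;
    groups with zero members are omitted.
    """
    err = np.abs(np.asarray(corrected, dtype=float) - np.asarray(reference, dtype=float))
    members: dict[str, list[int]] = {}
    for i, groups in enumerate(group_table):
        for g in groups:
            members.setdefault(g, []).append(i)
    rows = [
        {"group": g, "occurrences": len(idx), "mae": float(err[idx].mean())}
        for g, idx in sorted(members.items())
    ]
    return pd.DataFrame(rows, columns=["group", "occurrences", "mae"])
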