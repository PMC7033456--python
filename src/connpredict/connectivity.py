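"""From ROI time courses to connectivity matrices and edge features.

The connectivity weight between two ROIs is the Pearson correlation of
their mean BOLD time courses. For a network of n ROIs each subject
contributes a symmetric n x n correlation matrix, vectorized to its strict
upper triangle — n(n-1)/2 non-redundant edges — in row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .atlas import NetworkDefinition
from .exceptions import (
    DataError,
    ExtractionError,
    NumericError,
    OrientationError,
    UndefinedCorrelationError,
)

__all__ = [
    "SubjectTimecourses",
    "ConnectivityMatrix",
    "FeatureTable",
    "extract_roi_timecourses",
    "connectivity_matrix",
    "vectorize_features",
    "edge_labels_for",
    "build_feature_table",
    "ConnectivityVectorizer",
]

_SYMMETRY_TOL = 1e-8


@dataclass
class SubjectTimecourses:
    """Per-subject ROI x time matrix of mean BOLD signal."""

    subject_id: str
    data: np.ndarray  # (n_rois, n_timepoints)
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("time-course data must be 2-D (rois x time)")
        if self.data.shape[0] != len(self.roi_labels):
            raise DataError("roi_labels length does not match data rows")
        if self.data.shape[1] < 3:
            raise DataError("need at least 3 timepoints")

    def subset(self, labels: list[str]) -> "SubjectTimecourses":
        """Rows for `labels`, in that order (a network's ROI ordering)."""
        index = {lab: i for i, lab in enumerate(self.roi_labels)}
        try:
            rows = [index[lab] for lab in labels]
        except KeyError as exc:
            raise DataError(f"ROI label {exc.args[0]!r} not in time courses") from exc
        return SubjectTimecourses(self.subject_id, self.data[rows], list(labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.roi_labels)


@dataclass
class ConnectivityMatrix:
    """Symmetric matrix of pairwise Pearson connectivity weights."""

    subject_id: str
    weights: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DataError("connectivity weights must be square")
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class FeatureTable:
    """Subjects x edges matrix of (optionally residualized) edge weights."""

    subjects: list[str]
    X: np.ndarray  # (n_subjects, m)
    edge_labels: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.subjects), len(self.edge_labels)):
            raise DataError("feature matrix shape inconsistent with labels")
        if len(set(self.edge_labels)) != len(self.edge_labels):
            raise DataError("edge labels are not unique")

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{a}--{b}" for a, b in self.edge_labels]
        return pd.DataFrame(self.X, index=self.subjects, columns=cols)


def extract_roi_timecourses(
    volume,
    rois: NetworkDefinition,
    radius_mm: float | None = None,
    subject_id: str = "subject",
) -> SubjectTimecourses:
    """Mean time course over the voxels of each ROI sphere.

    A voxel belongs to an ROI when its center lies within `radius_mm` of
    the ROI coordinate (closed ball, distances in mm via the image
    affine). Overlapping spheres each keep all of their voxels.

    Parameters
    ----------
    volume : nibabel spatial image or path
        4-D volume in MNI space (RAS-oriented affine).
    rois : NetworkDefinition
        ROIs to extract, in network order.
    radius_mm : float, optional
        Overrides each ROI's own radius when given.
    """
    import nibabel as nib

    img = nib.load(str(volume)) if isinstance(volume, (str,)) or hasattr(volume, "__fspath__") else volume
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DataError(f"expected a 4-D volume, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    if affine.shape != (4, 4) or np.linalg.det(affine[:3, :3]) == 0:
        raise OrientationError("volume affine is singular or malformed")

    nx, ny, nz, _ = data.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers_mm = vox @ affine[:3, :3].T + affine[:3, 3]
    flat = data.reshape(-1, data.shape[3])

    rows = []
    for roi in rois.rois:
        r = radius_mm if radius_mm is not None else roi.radius
        d2 = np.sum((centers_mm - roi.center) ** 2, axis=1)
        mask = d2 <= r * r + 1e-9
        if not mask.any():
            raise ExtractionError(
                f"ROI {roi.label} ({roi.region_name}) sphere contains no voxels"
            )
        rows.append(flat[mask].mean(axis=0))
    return SubjectTimecourses(subject_id, np.vstack(rows), rois.labels())


def connectivity_matrix(tc: SubjectTimecourses) -> ConnectivityMatrix:
    """Pairwise Pearson correlations between ROI time courses."""
    sd = tc.data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [tc.roi_labels[i] for i in bad]
        raise UndefinedCorrelationError(
            f"zero-variance time course(s) for ROI(s): {names}"
        )
    w = np.corrcoef(tc.data)
    np.fill_diagonal(w, 1.0)
    w = np.clip(w, -1.0, 1.0)
    return ConnectivityMatrix(tc.subject_id, w, list(tc.roi_labels))


def edge_labels_for(roi_labels: list[str]) -> list[tuple[str, str]]:
    """Strict-upper-triangle (row-major) edge labels for an ROI ordering."""
    n = len(roi_labels)
    return [(roi_labels[i], roi_labels[j]) for i in range(n) for j in range(i + 1, n)]


def vectorize_features(cm: ConnectivityMatrix) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Strict upper triangle of the connectivity matrix, row-major.

    Returns the n(n-1)/2 edge weights together with their (roi_i, roi_j)
    labels, i < j in network order.
    """
    w = cm.weights
    if not np.allclose(w, w.T, atol=_SYMMETRY_TOL):
        raise NumericError("connectivity matrix is asymmetric beyond tolerance")
    iu = np.triu_indices(cm.n, k=1)
    return w[iu].copy(), edge_labels_for(cm.roi_labels)


def build_feature_table(matrices: list[ConnectivityMatrix]) -> FeatureTable:
    """Stack per-subject edge vectors into a subjects x m feature table."""
    if not matrices:
        raise DataError("no connectivity matrices given")
    labels0 = matrices[0].roi_labels
    rows, subjects = [], []
    for cm in matrices:
        if cm.roi_labels != labels0:
            raise DataError("connectivity matrices have inconsistent ROI order")
        vec, edges = vectorize_features(cm)
        rows.append(vec)
        subjects.append(cm.subject_id)
    return FeatureTable(subjects, np.vstack(rows), edges)


class ConnectivityVectorizer(BaseEstimator, TransformerMixin):
    """Transformer: stacked ROI time courses -> edge-feature matrix.

    Accepts an array of shape (n_subjects, n_rois, n_timepoints) and
    returns (n_subjects, n_rois*(n_rois-1)/2) upper-triangle Pearson
    weights. Stateless; provided so the connectivity step composes with
    sklearn pipelines.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise DataError("expected (n_subjects, n_rois, n_timepoints)")
        self.n_rois_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise DataError("expected (n_subjects, n_rois, n_timepoints)")
        iu = np.triu_indices(X.shape[1], k=1)
        out = np.empty((X.shape[0], iu[0].size))
        for s in range(X.shape[0]):
            tc = SubjectTimecourses(f"s{s}", X[s], [f"r{i}" for i in range(X.shape[1])])
            out[s] = connectivity_matrix(tc).weights[iu]
        return out
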