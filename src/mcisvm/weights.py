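"""Deployment model training and classifier weight mapping.

After cross-validated evaluation, a final model is trained on all subjects
and its weight vector is turned into brain maps: positive weights pull the
decision toward cognitive stability, negative weights toward decline.
Within each sign class, weights are normalized to percent contributions
(each sign class sums to 100%), voxel contributions are aggregated per
atlas parcel and ranked, and a thresholded NIfTI volume retaining the top
fraction of voxels by contribution magnitude is written for display.

Connectivity weights have no unique voxel embedding, so they are reported
in a separate parcel-pair table rather than painted into the volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .crossval import CVConfig, inner_select_C, _stratified_assignment
from .features import MODALITY_CONN, MODALITY_T1, FeatureMatrix, assemble_features
from .svm import LinearSVMModel, SelectionMask, fit_fold_model
from .synthetic import AtlasDefinition, SubjectScan

__all__ = [
    "WeightMapReport",
    "train_deployment_model",
    "percent_contributions",
    "roi_rank",
    "connection_table",
    "write_weight_map",
    "build_weight_map_report",
]


@dataclass(frozen=True)
class WeightMapReport:
    """Percent-contribution tables derived from a deployment model."""

    feature_table: pd.DataFrame  # per selected feature: modality, weight, sign class, percent
    roi_table: pd.DataFrame  # per parcel: mean percent contribution, volume share, rank
    connection_table: pd.DataFrame  # per selected parcel pair: weight, sign class, percent


def train_deployment_model(
    cohort: list[SubjectScan],
    atlas: AtlasDefinition,
    modalities={"t1", "conn"},
    config: CVConfig = CVConfig(),
    features: FeatureMatrix | None = None,
) -> tuple[LinearSVMModel, FeatureMatrix]:
    """Train the all-subject model used for weight mapping and scoring.

    The selection mask and standardizer are fitted on the full sample; C is
    chosen by the same inner stratified cross-validation procedure used in
    the nested evaluation, applied to the full sample.
    """
    if features is None:
        features = assemble_features(cohort, atlas, frozenset(modalities))
    X = features.values
    y = np.array([s.label for s in cohort])
    all_rows = np.arange(X.shape[0])
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xF1)))
    inner_fold_of = _stratified_assignment(y, all_rows, config.inner_k, rng)
    C = inner_select_C(
        X,
        y,
        all_rows,
        config.C_grid,
        inner_fold_of,
        alpha=config.alpha,
        t_variant=config.t_variant,
    )
    model = fit_fold_model(X, y, all_rows, C, alpha=config.alpha, t_variant=config.t_variant)
    return model, features


def percent_contributions(model: LinearSVMModel) -> np.ndarray:
    """Signed percent contribution of every selected feature.

    Positive weights are divided by the sum of positive weights, negative
    weights by the sum of absolute negative weights, each scaled to 100, so
    each sign class sums to 100%. The returned vector keeps the sign
    (+ stability, - decline); zero weights contribute to neither class.
    """
    w = model.w
    if w.size == 0 or not np.any(w != 0):
        raise ValueError("degenerate model: no nonzero weights")
    contrib = np.zeros_like(w)
    pos = w > 0
    neg = w < 0
    if pos.any():
        contrib[pos] = w[pos] / w[pos].sum() * 100.0
    if neg.any():
        contrib[neg] = w[neg] / np.abs(w[neg]).sum() * 100.0  # stays negative
    return contrib


def _selected_t1_info(
    selection: SelectionMask, features: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """(positions within the selected-feature vector, voxel coords) of t1 columns."""
    keep_idx = np.flatnonzero(selection.keep)
    is_t1 = features.modality[keep_idx] == MODALITY_T1
    return np.flatnonzero(is_t1), features.voxel_coords[keep_idx[is_t1]]


def roi_rank(
    contribs: np.ndarray,
    atlas: AtlasDefinition,
    selection: SelectionMask,
    features: FeatureMatrix,
) -> pd.DataFrame:
    """Rank parcels by their average voxel percent contribution.

    The average is taken over *all* voxels of the parcel: selected voxels
    carry their contribution magnitude (share within their own sign
    class), unselected voxels carry zero weight. This denominator keeps a
    parcel with a single spuriously selected voxel from outranking a
    parcel whose signal spans many voxels, which is what makes the ranking
    usable for localization. Parcels with no selected voxel are excluded
    from the table entirely. A secondary column gives the parcel's share
    of all selected voxels by count. Ties in the mean rank in atlas label
    order.
    """
    pos_in_sel, coords = _selected_t1_info(selection, features)
    if pos_in_sel.size == 0:
        return pd.DataFrame(
            columns=[
                "parcel_id", "parcel_name", "network",
                "mean_percent_contribution", "mean_stability_percent",
                "mean_decline_percent", "percent_of_selected_voxels", "rank",
            ]
        )
    c = contribs[pos_in_sel]
    parcels = atlas.label_volume[tuple(coords.T)]
    voxel_counts = atlas.voxel_counts

    rows = []
    for p in np.unique(parcels):
        sel = parcels == p
        cp = c[sel]
        n_vox = voxel_counts[int(p)]
        rows.append(
            {
                "parcel_id": int(p),
                "parcel_name": atlas.parcel_names[int(p) - 1],
                "network": atlas.network_of_parcel[int(p)],
                "mean_percent_contribution": float(np.abs(cp).sum() / n_vox),
                "mean_stability_percent": float(cp[cp > 0].sum() / n_vox),
                "mean_decline_percent": float(-cp[cp < 0].sum() / n_vox),
                "percent_of_selected_voxels": float(sel.sum() / parcels.size * 100.0),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["mean_percent_contribution", "parcel_id"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def connection_table(
    contribs: np.ndarray,
    atlas: AtlasDefinition,
    selection: SelectionMask,
    features: FeatureMatrix,
) -> pd.DataFrame:
    """Selected connectivity features with their signed percent contribution."""
    keep_idx = np.flatnonzero(selection.keep)
    is_conn = features.modality[keep_idx] == MODALITY_CONN
    pos = np.flatnonzero(is_conn)
    pairs = features.parcel_pairs[keep_idx[is_conn]]
    df = pd.DataFrame(
        {
            "parcel_i": pairs[:, 0],
            "parcel_j": pairs[:, 1],
            "network_i": [atlas.network_of_parcel[int(p)] for p in pairs[:, 0]],
            "network_j": [atlas.network_of_parcel[int(p)] for p in pairs[:, 1]],
            "percent_contribution": contribs[pos],
        }
    )
    df["sign_class"] = np.where(df["percent_contribution"] >= 0, "stability", "decline")
    return df.sort_values(
        "percent_contribution", key=np.abs, ascending=False
    ).reset_index(drop=True)


def write_weight_map(
    contribs: np.ndarray,
    atlas: AtlasDefinition,
    selection: SelectionMask,
    features: FeatureMatrix,
    top_fraction: float = 0.5,
    path: str | Path | None = None,
) -> np.ndarray:
    """Voxelwise volume of signed percent contributions, thresholded to the
    top ``ceil(top_fraction * n_selected_voxels)`` voxels by magnitude.

    Background (and below-threshold) voxels are 0. If ``path`` is given the
    volume is written as NIfTI-1.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    pos_in_sel, coords = _selected_t1_info(selection, features)
    volume = np.zeros(atlas.shape, dtype=np.float64)
    if pos_in_sel.size:
        c = contribs[pos_in_sel]
        n_keep = int(np.ceil(top_fraction * c.size))
        order = np.argsort(-np.abs(c), kind="stable")[:n_keep]
        kept_coords = coords[order]
        volume[tuple(kept_coords.T)] = c[order]
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(volume, np.eye(4)), path)
    return volume


def build_weight_map_report(
    model: LinearSVMModel,
    atlas: AtlasDefinition,
    features: FeatureMatrix,
) -> WeightMapReport:
    """Assemble the full contribution report for a fitted deployment model."""
    if model.selection is None:
        raise ValueError("model carries no selection mask")
    contribs = percent_contributions(model)
    keep_idx = np.flatnonzero(model.selection.keep)
    feature_table = pd.DataFrame(
        {
            "column": keep_idx,
            "modality": features.modality[keep_idx],
            "weight": model.w,
            "sign_class": np.where(model.w >= 0, "stability", "decline"),
            "percent_contribution": contribs,
        }
    )
    return WeightMapReport(
        feature_table=feature_table,
        roi_table=roi_rank(contribs, atlas, model.selection, features),
        connection_table=connection_table(contribs, atlas, model.selection, features),
    )
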