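"""Feature construction and standardization.

Maps scans into the analysis feature space:

* ``t1`` columns — every in-mask T1 voxel intensity, in a fixed scan order
  (first grid axis fastest), so weight maps round-trip bit-for-bit;
* ``conn`` columns — Fisher z-transformed Pearson correlations between all
  R(R-1)/2 unordered parcel pairs of the ROI time series;
* a train-fitted z-score standardizer, applied after feature selection so
  no held-out subject influences the column statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import AtlasDefinition, SubjectScan

__all__ = [
    "FeatureMatrix",
    "Standardizer",
    "connection_count",
    "connectivity_features",
    "vectorize_t1",
    "devectorize_t1",
    "assemble_features",
    "fit_standardizer",
    "apply_standardizer",
]

R_CLIP = 1.0 - 1e-7  # |r| clipped here before atanh to keep features finite

MODALITY_T1 = "t1"
MODALITY_CONN = "conn"
MODALITY_NPSYCH = "npsych"


@dataclass(frozen=True)
class FeatureMatrix:
    """N x P feature matrix with per-column provenance.

    ``modality`` tags each column as ``t1``, ``conn`` or ``npsych``;
    ``voxel_coords`` holds the (i, j, k) grid coordinate of t1 columns
    (-1 elsewhere) and ``parcel_pairs`` the ordered (i < j) parcel-id pair
    of conn columns (-1 elsewhere).
    """

    values: np.ndarray
    modality: np.ndarray  # (P,) str
    voxel_coords: np.ndarray  # (P, 3) int, -1 where not applicable
    parcel_pairs: np.ndarray  # (P, 2) int, -1 where not applicable
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        P = self.values.shape[1]
        if not (len(self.modality) == P == len(self.voxel_coords) == len(self.parcel_pairs)):
            raise ValueError("provenance length must equal column count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def columns_of(self, modality: str) -> np.ndarray:
        return np.flatnonzero(self.modality == modality)


@dataclass(frozen=True)
class Standardizer:
    """Column-wise z-score transform fitted on training rows only.

    Constant training columns (SD = 0) are centered but not scaled
    (divisor 1), so they map to an exact zero on the training rows instead
    of NaN.
    """

    mean: np.ndarray
    sd: np.ndarray  # effective divisor: 1.0 where the training column is constant
    fitted_on: tuple[int, ...]


def connection_count(n_parcels: int) -> int:
    """Number of unique (unordered, off-diagonal) parcel pairs, n(n-1)/2."""
    if n_parcels < 1:
        raise ValueError("n_parcels must be >= 1")
    return n_parcels * (n_parcels - 1) // 2


def pair_order(n_parcels: int) -> np.ndarray:
    """The canonical (i, j) pair enumeration, i < j, 1-based parcel ids.

    Row-major upper triangle: (1,2), (1,3), ..., (1,R), (2,3), ...
    """
    iu = np.triu_indices(n_parcels, k=1)
    return np.stack([iu[0] + 1, iu[1] + 1], axis=1)


def connectivity_features(ts: np.ndarray) -> np.ndarray:
    """Fisher z-transformed Pearson correlations of all parcel pairs.

    Parameters
    ----------
    ts
        T x R time-series matrix, one column per parcel.

    Returns
    -------
    Vector of length R(R-1)/2 in :func:`pair_order` order. Correlations
    with ``|r| >= 1 - 1e-7`` are clipped before atanh.
    """
    ts = np.asarray(ts, dtype=np.float64)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("time series must be T x R with T >= 3")
    sd = ts.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        raise ValueError(
            f"constant time series for parcel(s) {(degenerate + 1).tolist()}: "
            "correlation undefined"
        )
    r = np.corrcoef(ts, rowvar=False)
    iu = np.triu_indices(ts.shape[1], k=1)
    vals = np.clip(r[iu], -R_CLIP, R_CLIP)
    return np.arctanh(vals)


def vectorize_t1(volume: np.ndarray, atlas: AtlasDefinition) -> np.ndarray:
    """In-mask voxel intensities in Fortran scan order (first axis fastest)."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.shape != atlas.shape:
        raise ValueError(
            f"volume shape {volume.shape} != atlas shape {atlas.shape}"
        )
    mask_flat = atlas.mask.flatten(order="F")
    return volume.flatten(order="F")[mask_flat]


def t1_voxel_coords(atlas: AtlasDefinition) -> np.ndarray:
    """Grid coordinates of the in-mask voxels, in vectorize_t1 order."""
    mask_flat = atlas.mask.flatten(order="F")
    flat_idx = np.flatnonzero(mask_flat)
    return np.stack(
        np.unravel_index(flat_idx, atlas.shape, order="F"), axis=1
    ).astype(np.int64)


def devectorize_t1(
    vector: np.ndarray, atlas: AtlasDefinition, background: float = 0.0
) -> np.ndarray:
    """Inverse of :func:`vectorize_t1`; background voxels get ``background``."""
    mask_flat = atlas.mask.flatten(order="F")
    if vector.shape[0] != mask_flat.sum():
        raise ValueError("vector length does not match atlas mask size")
    flat = np.full(mask_flat.shape, background, dtype=np.float64)
    flat[mask_flat] = vector
    return flat.reshape(atlas.shape, order="F")


def assemble_features(
    cohort: list[SubjectScan],
    atlas: AtlasDefinition,
    modalities: set[str] | frozenset[str] = frozenset({MODALITY_T1, MODALITY_CONN}),
) -> FeatureMatrix:
    """Stack per-subject feature vectors; t1 columns precede conn columns."""
    modalities = frozenset(modalities)
    unknown = modalities - {MODALITY_T1, MODALITY_CONN}
    if unknown or not modalities:
        raise ValueError(f"modalities must be a nonempty subset of {{t1, conn}}, got {set(modalities)}")
    R = atlas.n_parcels
    shapes = {s.t1.shape for s in cohort} | {(atlas.shape)}
    if len(shapes) != 1:
        raise ValueError("all subjects must share the atlas grid")
    Rs = {s.timeseries.shape[1] for s in cohort}
    if Rs != {R}:
        raise ValueError("all subjects must have one time-series column per parcel")

    blocks: list[np.ndarray] = []
    mods: list[np.ndarray] = []
    coords_list: list[np.ndarray] = []
    pairs_list: list[np.ndarray] = []

    if MODALITY_T1 in modalities:
        X = np.stack([vectorize_t1(s.t1, atlas) for s in cohort])
        P = X.shape[1]
        blocks.append(X)
        mods.append(np.full(P, MODALITY_T1, dtype=object))
        coords_list.append(t1_voxel_coords(atlas))
        pairs_list.append(np.full((P, 2), -1, dtype=np.int64))
    if MODALITY_CONN in modalities:
        X = np.stack([connectivity_features(s.timeseries) for s in cohort])
        P = X.shape[1]
        blocks.append(X)
        mods.append(np.full(P, MODALITY_CONN, dtype=object))
        coords_list.append(np.full((P, 3), -1, dtype=np.int64))
        pairs_list.append(pair_order(R))

    return FeatureMatrix(
        values=np.concatenate(blocks, axis=1),
        modality=np.concatenate(mods).astype(str),
        voxel_coords=np.concatenate(coords_list, axis=0),
        parcel_pairs=np.concatenate(pairs_list, axis=0),
        subject_ids=tuple(s.subject_id for s in cohort),
    )


def fit_standardizer(values: np.ndarray, train_rows) -> Standardizer:
    """Column means/SDs (ddof=1) from the training rows only."""
    train_rows = np.asarray(sorted(int(i) for i in train_rows))
    if train_rows.size < 2:
        raise ValueError("need at least 2 training rows to standardize")
    Xt = np.asarray(values)[train_rows]
    mean = Xt.mean(axis=0)
    sd = Xt.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)  # constant columns: center only
    return Standardizer(mean=mean, sd=sd, fitted_on=tuple(train_rows.tolist()))


def apply_standardizer(std: Standardizer, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    return (values - std.mean) / std.sd
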