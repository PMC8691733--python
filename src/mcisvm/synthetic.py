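"""Synthetic cohort generator.

Emulates the data structure of a single-site amnestic-MCI conversion study:
a T1-like intensity volume per subject on a common grid, a parcellated BOLD
ROI time-series table, a binary outcome label (stable vs decline to
dementia), an aMCI subtype (single- vs multi-domain), and a six-measure
neuropsychological battery with missing-at-random cells.

The generator plants controllable group differences — parcel-level mean
intensity shifts in the T1 volume and latent-correlation shifts in
designated parcel pairs of the time series — so that every downstream stage
(feature selection, classification, weight mapping) can be tested by
parameter recovery rather than against restricted clinical data.

All randomness is keyed to ``(seed, subject index)`` sub-streams, so a
subject's data never depends on how many other subjects are generated or in
which order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AtlasDefinition",
    "SubjectScan",
    "EffectSpec",
    "NeuropsychTable",
    "make_atlas",
    "simulate_cohort",
    "simulate_neuropsych",
    "write_cohort",
    "load_cohort",
]

#: The seven canonical large-scale networks of the parcellation scheme.
SEVEN_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "cingulo_opercular",
    "limbic",
    "frontoparietal_control",
    "default_mode",
)

#: Battery of six neuropsychological measures (the global screener is not a
#: model feature because it partially defines the diagnosis being predicted).
NEUROPSYCH_MEASURES = (
    "hvlt_delayed_recall",
    "craft_story_delayed_recall",
    "mint_naming",
    "benson_figure_drawing",
    "trailmaking_b",
    "semantic_fluency",
)

LABEL_STABLE = 1
LABEL_DECLINE = -1

# Proportion of single-domain subtype per outcome class (stable, decline).
_SINGLE_DOMAIN_RATE = {LABEL_STABLE: 0.512, LABEL_DECLINE: 0.143}


@dataclass(frozen=True)
class AtlasDefinition:
    """Integer-labeled parcellation on a regular grid.

    Label 0 is background; labels ``1..R`` are parcels, each assigned to one
    of the large-scale networks.
    """

    label_volume: np.ndarray
    parcel_names: tuple[str, ...]
    network_of_parcel: dict[int, str]

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_names)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_volume.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean in-brain mask (any nonzero label)."""
        return self.label_volume > 0

    @property
    def voxel_counts(self) -> dict[int, int]:
        labels, counts = np.unique(
            self.label_volume[self.label_volume > 0], return_counts=True
        )
        return dict(zip(labels.tolist(), counts.tolist()))

    @property
    def networks(self) -> tuple[str, ...]:
        seen: list[str] = []
        for p in range(1, self.n_parcels + 1):
            net = self.network_of_parcel[p]
            if net not in seen:
                seen.append(net)
        return tuple(seen)


@dataclass(frozen=True)
class SubjectScan:
    """One subject's imaging data and outcome.

    ``label`` is +1 for diagnostically stable subjects and -1 for subjects
    who declined to dementia at follow-up.
    """

    subject_id: str
    t1: np.ndarray
    timeseries: np.ndarray  # T x R
    label: int
    baseline_subtype: str  # "single_domain" | "multi_domain"

    def __post_init__(self) -> None:
        if self.label not in (LABEL_STABLE, LABEL_DECLINE):
            raise ValueError(f"label must be +1 or -1, got {self.label}")
        if self.timeseries.shape[0] < 3:
            raise ValueError("time series needs at least 3 timepoints")


@dataclass(frozen=True)
class EffectSpec:
    """Planted group differences (decline relative to stable).

    Parameters
    ----------
    t1_effect_parcels
        Parcel ids whose mean T1 intensity is lowered in the decline class.
    t1_effect_size
        Standardized mean difference, in units of the voxel noise SD.
    conn_effect_pairs
        Parcel-id pairs whose latent time-series correlation differs
        between classes.
    conn_effect_size
        Additive shift of the pair correlation in the decline class.
    noise_sd
        Voxel noise standard deviation of the T1 volume.
    conn_base_corr
        Pair correlation in the stable class for the designated pairs.
    """

    t1_effect_parcels: tuple[int, ...] = ()
    t1_effect_size: float = 0.0
    conn_effect_pairs: tuple[tuple[int, int], ...] = ()
    conn_effect_size: float = 0.0
    noise_sd: float = 1.0
    conn_base_corr: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        hi = self.conn_base_corr + self.conn_effect_size
        if not (-0.9 < hi < 0.9) or not (-0.9 < self.conn_base_corr < 0.9):
            raise ValueError("pair correlations must stay within (-0.9, 0.9)")

    def validate_against(self, atlas: AtlasDefinition) -> None:
        valid = set(range(1, atlas.n_parcels + 1))
        bad = set(self.t1_effect_parcels) - valid
        if bad:
            raise ValueError(f"effect parcels not in atlas: {sorted(bad)}")
        for i, j in self.conn_effect_pairs:
            if i == j or i not in valid or j not in valid:
                raise ValueError(f"invalid effect pair ({i}, {j})")


@dataclass(frozen=True)
class NeuropsychTable:
    """N x 6 matrix of test scores with an explicit missingness mask."""

    values: np.ndarray
    missing_mask: np.ndarray
    measure_names: tuple[str, ...] = NEUROPSYCH_MEASURES

    def __post_init__(self) -> None:
        if len(self.measure_names) != 6 or self.values.shape[1] != 6:
            raise ValueError("the battery has exactly 6 measures")
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        # masked cells carry no value; unmasked cells always do
        if not np.all(np.isnan(self.values[self.missing_mask])):
            raise ValueError("masked cells must be NaN")
        if np.isnan(self.values[~self.missing_mask]).any():
            raise ValueError("unmasked cells must carry values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.measure_names))


def _network_names(n_networks: int) -> list[str]:
    if n_networks <= len(SEVEN_NETWORKS):
        return list(SEVEN_NETWORKS[:n_networks])
    extra = [f"network_{k}" for k in range(len(SEVEN_NETWORKS) + 1, n_networks + 1)]
    return list(SEVEN_NETWORKS) + extra


def make_atlas(
    grid_dims: tuple[int, int, int] = (20, 20, 20),
    n_parcels: int = 51,
    n_networks: int = 7,
    seed: int = 0,
) -> AtlasDefinition:
    """Build a synthetic parcellation: an ellipsoidal "brain" mask tiled
    into ``n_parcels`` Voronoi cells around randomly placed centroids.

    Deterministic for a fixed seed. Each parcel contains at least one voxel
    (its own centroid); parcels are assigned to networks so that every
    network receives at least one parcel.
    """
    grid_dims = tuple(int(d) for d in grid_dims)
    if n_parcels < 1:
        raise ValueError("n_parcels must be >= 1")
    if n_networks < 1 or n_networks > n_parcels:
        raise ValueError("need 1 <= n_networks <= n_parcels")
    if int(np.prod(grid_dims)) < n_parcels:
        raise ValueError(
            f"grid {grid_dims} too small to tile {n_parcels} parcels"
        )

    # Ellipsoid inscribed in the grid: roughly half the voxels are in-mask,
    # preserving a background margin around the "brain".
    center = (np.asarray(grid_dims) - 1) / 2.0
    semi = np.asarray(grid_dims) / 2.0
    ii, jj, kk = np.indices(grid_dims)
    dist2 = (
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    )
    mask = dist2 <= 1.0
    coords = np.argwhere(mask)
    if coords.shape[0] < n_parcels:
        raise ValueError(
            f"in-mask volume ({coords.shape[0]} voxels) too small for "
            f"{n_parcels} parcels"
        )

    rng = np.random.default_rng(seed)
    centroid_idx = rng.choice(coords.shape[0], size=n_parcels, replace=False)
    centroids = coords[centroid_idx]

    # nearest-centroid assignment; ties broken by lowest parcel id
    d2 = ((coords[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assignment = np.argmin(d2, axis=1) + 1
    # centroids always belong to their own parcel
    assignment[centroid_idx] = np.arange(1, n_parcels + 1)

    label_volume = np.zeros(grid_dims, dtype=np.int32)
    label_volume[tuple(coords.T)] = assignment

    networks = _network_names(n_networks)
    order = rng.permutation(n_parcels)
    network_of_parcel = {
        int(p + 1): networks[int(rank) % n_networks]
        for rank, p in zip(np.argsort(order), range(n_parcels))
    }
    parcel_names = tuple(
        f"{network_of_parcel[p]}_p{p:02d}" for p in range(1, n_parcels + 1)
    )
    return AtlasDefinition(
        label_volume=label_volume,
        parcel_names=parcel_names,
        network_of_parcel=network_of_parcel,
    )


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # independent per-subject sub-stream: values do not depend on cohort
    # size or generation order
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def _simulate_subject(
    atlas: AtlasDefinition,
    label: int,
    index: int,
    T: int,
    effects: EffectSpec,
) -> SubjectScan:
    rng = _subject_rng(effects.seed, index)
    R = atlas.n_parcels
    lv = atlas.label_volume

    # --- T1-like volume: uniform tissue intensity + iid voxel noise ---
    t1 = np.zeros(atlas.shape, dtype=np.float64)
    in_mask = atlas.mask
    t1[in_mask] = 100.0
    if label == LABEL_DECLINE and effects.t1_effect_parcels:
        shift = effects.t1_effect_size * effects.noise_sd
        for p in effects.t1_effect_parcels:
            t1[lv == p] -= shift
    t1[in_mask] += rng.normal(0.0, effects.noise_sd, size=int(in_mask.sum()))

    # --- BOLD-like time series: mixtures of latent network signals ---
    networks = atlas.networks
    net_index = {name: k for k, name in enumerate(networks)}
    g = rng.standard_normal((T, len(networks)))  # one latent per network
    eps = rng.standard_normal((T, R))
    pair_latent = rng.standard_normal((T, max(len(effects.conn_effect_pairs), 1)))

    a = 0.3  # network loading; within-network r ~ a^2, weak by design
    rho = effects.conn_base_corr
    if label == LABEL_DECLINE:
        rho = rho + effects.conn_effect_size
    # second member of a pair takes sign(rho) so the pair correlation is rho
    pair_of_parcel: dict[int, tuple[int, float]] = {}
    for q, (i, j) in enumerate(effects.conn_effect_pairs):
        pair_of_parcel[i] = (q, 1.0)
        pair_of_parcel[j] = (q, float(np.sign(rho)) if rho != 0 else 1.0)

    ts = np.empty((T, R))
    for r in range(1, R + 1):
        net = g[:, net_index[atlas.network_of_parcel[r]]]
        if r in pair_of_parcel:
            q, sgn = pair_of_parcel[r]
            h = pair_latent[:, q]
            resid = max(1.0 - a**2 - abs(rho), 0.0)
            ts[:, r - 1] = (
                np.sqrt(resid) * eps[:, r - 1]
                + a * net
                + sgn * np.sqrt(abs(rho)) * h
            )
        else:
            ts[:, r - 1] = np.sqrt(1.0 - a**2) * eps[:, r - 1] + a * net

    subtype = (
        "single_domain"
        if rng.random() < _SINGLE_DOMAIN_RATE[label]
        else "multi_domain"
    )
    return SubjectScan(
        subject_id=f"sub-{index + 1:03d}",
        t1=t1,
        timeseries=ts,
        label=label,
        baseline_subtype=subtype,
    )


def simulate_cohort(
    atlas: AtlasDefinition,
    n_stable: int = 41,
    n_decline: int = 14,
    T: int = 150,
    effects: EffectSpec = EffectSpec(),
) -> list[SubjectScan]:
    """Generate a labeled cohort with the requested class imbalance.

    Stable subjects occupy indices ``0..n_stable-1`` and decline subjects
    the following indices; each subject is generated from its own random
    sub-stream, so the data of subject *k* is identical whether or not any
    other subject is generated.
    """
    if n_stable < 1 or n_decline < 1:
        raise ValueError("both classes need at least one subject")
    if T < 3:
        raise ValueError("T must be >= 3")
    effects.validate_against(atlas)

    cohort = [
        _simulate_subject(atlas, LABEL_STABLE, i, T, effects)
        for i in range(n_stable)
    ]
    cohort += [
        _simulate_subject(atlas, LABEL_DECLINE, n_stable + i, T, effects)
        for i in range(n_decline)
    ]
    return cohort


def simulate_neuropsych(
    labels: list[int] | np.ndarray,
    group_shift: float = 0.0,
    n_incomplete: int = 27,
    seed: int = 0,
) -> NeuropsychTable:
    """Six-measure battery with missing-at-random cells.

    Scores are standard normal; decline-class column means are shifted by
    ``group_shift`` (negative = worse performance in decliners). Exactly
    ``n_incomplete`` subjects — chosen uniformly, independent of label —
    receive one or two masked cells each.
    """
    labels = np.asarray(labels)
    N = labels.shape[0]
    if n_incomplete > N:
        raise ValueError(f"n_incomplete ({n_incomplete}) exceeds N ({N})")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x6E70)))
    values = rng.standard_normal((N, 6))
    values[labels == LABEL_DECLINE] += group_shift

    missing = np.zeros((N, 6), dtype=bool)
    who = rng.choice(N, size=n_incomplete, replace=False)
    for s in who:
        k = rng.integers(1, 3)  # 1 or 2 missing measures
        cols = rng.choice(6, size=k, replace=False)
        missing[s, cols] = True
    values = values.copy()
    values[missing] = np.nan
    return NeuropsychTable(values=values, missing_mask=missing)


# ---------------------------------------------------------------------------
# on-disk round trip (NIfTI volumes, CSV tables, JSON manifest)
# ---------------------------------------------------------------------------

def write_cohort(
    cohort: list[SubjectScan],
    atlas: AtlasDefinition,
    outdir: str | Path,
    neuropsych: NeuropsychTable | None = None,
) -> Path:
    """Write atlas + cohort to ``outdir``; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)

    nib.save(
        nib.Nifti1Image(atlas.label_volume.astype(np.int32), affine),
        outdir / "atlas_labels.nii.gz",
    )
    pd.DataFrame(
        {
            "parcel_id": np.arange(1, atlas.n_parcels + 1),
            "parcel_name": list(atlas.parcel_names),
            "network": [
                atlas.network_of_parcel[p] for p in range(1, atlas.n_parcels + 1)
            ],
        }
    ).to_csv(outdir / "atlas_parcels.csv", index=False)

    entries = []
    for s in cohort:
        t1_path = outdir / f"{s.subject_id}_t1.nii.gz"
        ts_path = outdir / f"{s.subject_id}_timeseries.csv"
        nib.save(nib.Nifti1Image(s.t1, affine), t1_path)
        pd.DataFrame(
            s.timeseries, columns=[f"parcel_{r:02d}" for r in range(1, atlas.n_parcels + 1)]
        ).to_csv(ts_path, index=False)
        entries.append(
            {
                "subject_id": s.subject_id,
                "label": int(s.label),
                "baseline_subtype": s.baseline_subtype,
                "t1": t1_path.name,
                "timeseries": ts_path.name,
            }
        )
    if neuropsych is not None:
        df = neuropsych.to_frame()
        df.insert(0, "subject_id", [s.subject_id for s in cohort])
        df.to_csv(outdir / "neuropsych.csv", index=False)

    manifest = {
        "atlas": "atlas_labels.nii.gz",
        "parcels": "atlas_parcels.csv",
        "neuropsych": "neuropsych.csv" if neuropsych is not None else None,
        "subjects": entries,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_cohort(
    manifest_path: str | Path,
) -> tuple[list[SubjectScan], AtlasDefinition, NeuropsychTable | None]:
    """Read back a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())

    label_volume = np.asarray(
        nib.load(root / manifest["atlas"]).dataobj, dtype=np.int32
    )
    parcels = pd.read_csv(root / manifest["parcels"])
    network_of_parcel = dict(
        zip(parcels["parcel_id"].astype(int), parcels["network"])
    )
    atlas = AtlasDefinition(
        label_volume=label_volume,
        parcel_names=tuple(parcels["parcel_name"]),
        network_of_parcel=network_of_parcel,
    )

    cohort = []
    for e in manifest["subjects"]:
        t1 = np.asarray(nib.load(root / e["t1"]).dataobj, dtype=np.float64)
        ts = pd.read_csv(root / e["timeseries"]).to_numpy(dtype=np.float64)
        cohort.append(
            SubjectScan(
                subject_id=e["subject_id"],
                t1=t1,
                timeseries=ts,
                label=int(e["label"]),
                baseline_subtype=e["baseline_subtype"],
            )
        )

    npsych = None
    if manifest.get("neuropsych"):
        df = pd.read_csv(root / manifest["neuropsych"])
        vals = df[list(NEUROPSYCH_MEASURES)].to_numpy(dtype=np.float64)
        npsych = NeuropsychTable(values=vals, missing_mask=np.isnan(vals))
    return cohort, atlas, npsych
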