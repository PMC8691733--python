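"""Neuropsychological-table handling and cohort contingency statistics.

Two strategies for missing-at-random battery scores are provided:
class-mean filling (impute from the diagnostic class's observed mean) and
list-wise deletion (drop incomplete subjects and rebalance the class
costs). For genuinely held-out subjects the class is unknown at test time,
so the default filling uses the overall training mean for them; a
``paper_faithful`` flag reproduces the full-sample class-mean variant,
which leaks outcome information and exists only for comparison.

The contingency statistics quantify the association between baseline aMCI
subtype (single- vs multi-domain) and the follow-up outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .features import MODALITY_NPSYCH, FeatureMatrix
from .svm import class_cost_from_counts
from .synthetic import NeuropsychTable

__all__ = [
    "ContingencyTable2x2",
    "class_mean_impute",
    "listwise_delete",
    "combined_feature_model",
    "chi_square_2x2",
    "counts_from_percentages",
    "subtype_outcome_table",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = outcome (stable, decline), columns = subtype
    (single-domain, multi-domain)."""

    a: int  # stable, single-domain
    b: int  # stable, multi-domain
    c: int  # decline, single-domain
    d: int  # decline, multi-domain

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.float64)


def class_mean_impute(
    table: NeuropsychTable,
    y: np.ndarray,
    train_rows=None,
    paper_faithful: bool = False,
) -> NeuropsychTable:
    """Fill missing battery scores from class means of the training rows.

    * training subject, measure m missing -> mean of observed training
      values of that subject's class for m;
    * held-out subject -> overall training mean for m (its class is what
      the classifier is trying to predict, so it cannot be used);
    * ``paper_faithful=True`` fills every row from full-sample class means
      instead (leaky; comparison only).

    Observed cells are never altered.
    """
    y = np.asarray(y)
    N = table.n_subjects
    if train_rows is None:
        train_rows = np.arange(N)
    train_rows = np.asarray(sorted(int(i) for i in train_rows))
    values = table.values.copy()
    mask = table.missing_mask

    if paper_faithful:
        train_rows = np.arange(N)

    train_set = np.zeros(N, dtype=bool)
    train_set[train_rows] = True

    for m in range(values.shape[1]):
        observed_tr = train_set & ~mask[:, m]
        overall_mean = values[observed_tr, m].mean() if observed_tr.any() else np.nan
        for cls in (1, -1):
            obs_cls = observed_tr & (y == cls)
            fill_rows = mask[:, m] & (y == cls) & train_set
            if fill_rows.any():
                if not obs_cls.any():
                    raise ValueError(
                        f"no observed training value for class {cls}, measure {m}"
                    )
                values[fill_rows, m] = values[obs_cls, m].mean()
        if not paper_faithful:
            heldout_fill = mask[:, m] & ~train_set
            if heldout_fill.any():
                if not np.isfinite(overall_mean):
                    raise ValueError(f"no observed training value for measure {m}")
                values[heldout_fill, m] = overall_mean

    return NeuropsychTable(
        values=values,
        missing_mask=np.zeros_like(mask),
        measure_names=table.measure_names,
    )


def listwise_delete(table: NeuropsychTable, cohort):
    """Drop subjects with any missing measure; rebalance class costs.

    ``cohort`` is a sequence aligned with the table rows — either
    :class:`~mcisvm.synthetic.SubjectScan` objects or +-1 labels. Returns
    ``(survivor_indices, survivors, class_cost)``.
    """
    complete = ~table.missing_mask.any(axis=1)
    idx = np.flatnonzero(complete)
    if idx.size == 0:
        raise ValueError("list-wise deletion removed every subject")
    survivors = [cohort[i] for i in idx]
    labels = np.array(
        [s.label if hasattr(s, "label") else int(s) for s in survivors]
    )
    return idx, survivors, class_cost_from_counts(labels)


def combined_feature_model(
    imaging: FeatureMatrix, table: NeuropsychTable
) -> FeatureMatrix:
    """Append the six battery measures to the imaging feature matrix.

    The table must be complete (impute or delete first) and aligned with
    the imaging rows. The new columns carry the ``npsych`` modality tag;
    scaling is left to the fold-internal standardizer downstream.
    """
    if table.n_subjects != imaging.n_subjects:
        raise ValueError(
            f"row mismatch: imaging N={imaging.n_subjects}, table N={table.n_subjects}"
        )
    if table.missing_mask.any():
        raise ValueError("neuropsych table still has missing cells")
    P6 = len(table.measure_names)
    return FeatureMatrix(
        values=np.concatenate([imaging.values, table.values], axis=1),
        modality=np.concatenate(
            [imaging.modality, np.full(P6, MODALITY_NPSYCH, dtype=object)]
        ).astype(str),
        voxel_coords=np.concatenate(
            [imaging.voxel_coords, np.full((P6, 3), -1, dtype=np.int64)]
        ),
        parcel_pairs=np.concatenate(
            [imaging.parcel_pairs, np.full((P6, 2), -1, dtype=np.int64)]
        ),
        subject_ids=imaging.subject_ids,
    )


def chi_square_2x2(t: ContingencyTable2x2) -> dict[str, float]:
    """Pearson chi-square (no continuity correction), df = 1, with the
    odds ratio ad/bc."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    marginals = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in marginals):
        raise ValueError("chi-square undefined: zero marginal")
    chi2 = n * (a * d - b * c) ** 2 / np.prod(marginals)
    p = float(stats.chi2.sf(chi2, df=1))
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return {"chi_square": float(chi2), "df": 1, "p_value": p, "odds_ratio": float(odds)}


def counts_from_percentages(group_n: int, pct: float) -> int:
    """Nearest-integer count for a group size and a printed percentage."""
    if not (0.0 <= pct <= 100.0):
        raise ValueError("pct must be within [0, 100]")
    return int(np.floor(group_n * pct / 100.0 + 0.5))


def subtype_outcome_table(
    n_stable: int = 41,
    n_decline: int = 14,
    pct_single_stable: float = 51.2,
    pct_single_decline: float = 14.3,
) -> ContingencyTable2x2:
    """Reconstruct the subtype-by-outcome table from group sizes and the
    printed single-domain percentages of each outcome group."""
    a = counts_from_percentages(n_stable, pct_single_stable)
    c = counts_from_percentages(n_decline, pct_single_decline)
    return ContingencyTable2x2(a=a, b=n_stable - a, c=c, d=n_decline - c)
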