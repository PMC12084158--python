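"""Discovery of clock-like DML and the PC1-based DNAm age model.

Clock-like differentially methylated loci (DML) are CpG sites whose
methylation fraction (beta) drifts with donor age. Discovery correlates
per-locus beta against age and keeps loci with |Pearson r| above a
cutoff (0.7 by default). The selected loci are clustered into groups by
hierarchical clustering of their beta profiles; the group whose mean
beta correlates most negatively with age is flagged as the clock group
(the hypomethylating family used as the accessibility reference).

The DNAm age model filters loci for coverage strictly above 30x, takes
PC1 of the centred beta matrix and regresses age on the PC1 score:
``age = a + b * score`` with the PC1 sign fixed so b >= 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.stats import pearsonr

from .io import BetaMatrix

logger = logging.getLogger(__name__)


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of X against y; zero-variance rows get 0."""
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    y_norm = np.sqrt((yc**2).sum())
    Xc = X - X.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (x_norm * y_norm)
    return np.where((x_norm > 0) & (y_norm > 0), r, 0.0)


def discover_clockdml(
    bm: BetaMatrix, r_cutoff: float = 0.7
) -> tuple[np.ndarray, np.ndarray]:
    """Select loci with |Pearson r(beta, age)| >= ``r_cutoff``.

    Returns ``(selected_indices, r)`` where ``r`` holds the correlation
    for every locus (selected or not).
    """
    if bm.n_samples < 3 or np.unique(bm.sample_ages).size < 2:
        raise ValueError("need >= 3 samples with distinct ages")
    if np.ptp(bm.sample_ages) == 0:
        raise ValueError("constant sample ages: correlation undefined")
    r = _pearson_rows(bm.beta, bm.sample_ages)
    selected = np.flatnonzero(np.abs(r) >= r_cutoff)
    return selected, r


@dataclass
class ClockGroup:
    """One cluster of clock-like loci with its mean-beta age correlation."""

    group_id: int
    member_loci: np.ndarray            # indices into the BetaMatrix
    mean_beta_per_sample: np.ndarray
    correlation_with_age: float
    is_clock_group: bool = False       # most negative r, the G-group analogue


def group_clockdml(
    bm: BetaMatrix,
    clock_idx: np.ndarray,
    k: int = 10,
    linkage: str = "average",
    metric: str = "euclidean",
) -> list[ClockGroup]:
    """Cluster clock-like loci into k groups and flag the clock group.

    Hierarchical clustering (average linkage, Euclidean distance by
    default) of per-locus beta profiles, cut into k flat groups. Each
    group's mean beta across samples is correlated with age; the group
    with the most negative correlation is flagged (ties broken toward
    the lower group id).
    """
    clock_idx = np.asarray(clock_idx, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if clock_idx.size < k:
        raise ValueError(f"need >= k={k} loci, got {clock_idx.size}")
    profiles = bm.beta[clock_idx, :]
    # order columns by age so the profile geometry reflects the age axis
    order = np.argsort(bm.sample_ages, kind="stable")
    Z = sch.linkage(profiles[:, order], method=linkage, metric=metric)
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    groups: list[ClockGroup] = []
    for gid in np.unique(labels):
        members = clock_idx[labels == gid]
        mean_beta = bm.beta[members, :].mean(axis=0)
        if np.ptp(mean_beta) > 0 and np.ptp(bm.sample_ages) > 0:
            r = float(pearsonr(mean_beta, bm.sample_ages).statistic)
        else:
            r = 0.0
        groups.append(
            ClockGroup(
                group_id=int(gid),
                member_loci=members,
                mean_beta_per_sample=mean_beta,
                correlation_with_age=r,
            )
        )
    best = min(groups, key=lambda g: (g.correlation_with_age, g.group_id))
    best.is_clock_group = True
    return groups


@dataclass
class DNAmAgeResults:
    """Fitted PC1 age model: loadings, calibration line and training fit."""

    locus_subset: np.ndarray        # indices passing the coverage filter
    pc1_loadings: np.ndarray        # unit-norm loadings over the subset
    locus_means: np.ndarray         # training means used for centering
    intercept: float                # a in age = a + b * score (years)
    slope: float                    # b >= 0 by the PC1 sign convention
    training_r: float               # Pearson r on training samples
    training_ages: np.ndarray

    def predict(self, bm_new: BetaMatrix, train_locus_ids: list[str] | None = None) -> np.ndarray:
        return predict_dnam_age(self, bm_new, train_locus_ids=train_locus_ids)

    def fitted_values(self, bm_train: BetaMatrix) -> np.ndarray:
        scores = self.pc1_loadings @ (
            bm_train.beta[self.locus_subset, :] - self.locus_means[:, None]
        )
        return self.intercept + self.slope * scores

    def summary(self) -> str:
        return (
            "PC1 DNAm age model\n"
            f"  loci (coverage > 30x): {len(self.locus_subset)}\n"
            f"  age = {self.intercept:.3f} + {self.slope:.4f} * PC1 score\n"
            f"  training Pearson r:    {self.training_r:.4f}"
        )


class DNAmAgeModel:
    """statsmodels-style wrapper: ``DNAmAgeModel(bm).fit()``."""

    def __init__(self, bm: BetaMatrix, min_coverage: float = 30.0) -> None:
        self.bm = bm
        self.min_coverage = min_coverage

    def fit(self) -> DNAmAgeResults:
        return fit_dnam_age(self.bm, min_coverage=self.min_coverage)


def fit_dnam_age(bm: BetaMatrix, min_coverage: float = 30.0) -> DNAmAgeResults:
    """Fit the PC1 age model on loci with coverage strictly > 30x.

    PCA is taken on the centred loci x samples beta matrix; the sample
    scores on PC1 are regressed against donor age by ordinary least
    squares. The PC1 sign is chosen so the regression slope is
    non-negative, making predictions deterministic. Ages are used
    untransformed (the model targets adult cohorts).
    """
    if bm.n_samples < 2:
        raise ValueError("need >= 2 samples to fit the age model")
    keep = np.flatnonzero(bm.coverage > min_coverage)
    if keep.size < 2:
        raise ValueError(
            f"fewer than 2 loci pass the coverage > {min_coverage:g}x filter"
        )
    X = bm.beta[keep, :]
    locus_means = X.mean(axis=1)
    Xc = X - locus_means[:, None]
    # PC1 via SVD of the centred loci x samples matrix
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = U[:, 0]
    scores = loadings @ Xc                    # per-sample PC1 score
    ages = bm.sample_ages
    var = scores.var()
    if var == 0:
        slope, intercept = 0.0, float(ages.mean())
    else:
        slope = float(np.cov(scores, ages, bias=True)[0, 1] / var)
        intercept = float(ages.mean() - slope * scores.mean())
    if slope < 0:                             # fix the PC1 sign ambiguity
        loadings = -loadings
        scores = -scores
        slope = -slope
        intercept = float(ages.mean() - slope * scores.mean())
    fitted = intercept + slope * scores
    if np.ptp(fitted) > 0 and np.ptp(ages) > 0:
        training_r = float(pearsonr(fitted, ages).statistic)
    else:
        training_r = 0.0
    return DNAmAgeResults(
        locus_subset=keep,
        pc1_loadings=loadings,
        locus_means=locus_means,
        intercept=intercept,
        slope=slope,
        training_r=training_r,
        training_ages=ages.copy(),
    )


def predict_dnam_age(
    model: DNAmAgeResults,
    bm_new: BetaMatrix,
    train_locus_ids: list[str] | None = None,
) -> np.ndarray:
    """Predict ages for new samples: a + b * (centred betas . loadings).

    When ``train_locus_ids`` is given, model loci are matched to the new
    matrix by locus id; loci missing from the new matrix are imputed at
    their training mean (with a warning). More than 50% missing is an
    error. Without ids the new matrix must have identical row layout.
    """
    if train_locus_ids is None:
        if bm_new.n_loci <= int(model.locus_subset.max()):
            raise ValueError(
                "new beta matrix lacks the model's locus rows; "
                "pass train_locus_ids to match by id"
            )
        X = bm_new.beta[model.locus_subset, :]
    else:
        subset_ids = [train_locus_ids[i] for i in model.locus_subset]
        new_index = {lid: i for i, lid in enumerate(bm_new.locus_ids)}
        rows = np.array([new_index.get(lid, -1) for lid in subset_ids])
        n_missing = int((rows < 0).sum())
        if n_missing > 0.5 * len(rows):
            raise ValueError(
                f"{n_missing}/{len(rows)} model loci missing from the new matrix"
            )
        if n_missing:
            logger.warning(
                "%d model loci missing from the new matrix; imputing training means",
                n_missing,
            )
        X = np.empty((len(rows), bm_new.n_samples))
        for i, row in enumerate(rows):
            X[i, :] = bm_new.beta[row, :] if row >= 0 else model.locus_means[i]
    scores = model.pc1_loadings @ (X - model.locus_means[:, None])
    return model.intercept + model.slope * scores
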