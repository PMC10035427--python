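"""Synthetic two-group cohorts of ROI time series.

Real resting-state cohorts (e.g. MCI vs. healthy controls) differ between
groups in the second-order structure of their ROI signals.  Since every
downstream connectivity estimator here (Pearson, sparse, low-rank) consumes
only second-order structure, a zero-mean multivariate normal with a
block-structured correlation matrix is a fully controllable stand-in: the
two groups share a unit-diagonal latent correlation matrix except on a
chosen set of ROI pairs (`effect_block`), where group 1's latent
correlation is shifted by `effect_delta`.

Each subject is drawn as ``m`` i.i.d. time points from its group's
distribution, plus independent Gaussian measurement noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bfn import TimeSeriesMatrix

logger = logging.getLogger(__name__)

__all__ = ["CohortSpec", "SyntheticCohort", "make_group_covariance", "sample_cohort"]


def _normalize_block(pairs) -> frozenset[tuple[int, int]]:
    out = set()
    for i, j in pairs:
        if i == j:
            raise ValueError(f"effect_block pair ({i},{j}) is on the diagonal")
        out.add((min(i, j), max(i, j)))
    return frozenset(out)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated two-group cohort.

    Defaults mirror the shape of a 116-ROI AAL cohort with 135 retained
    volumes; every field is overridable.
    """

    n_rois: int = 116
    n_timepoints: int = 135
    n_subjects_per_group: int = 40
    effect_block: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    effect_delta: float = 0.0
    base_correlation: float = 0.2
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "effect_block", _normalize_block(self.effect_block))
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        if not -1.0 < self.base_correlation < 1.0:
            raise ValueError("base_correlation must lie in (-1, 1)")
        if not 0.0 <= self.effect_delta < 1.0:
            raise ValueError("effect_delta must lie in [0, 1)")
        if abs(self.base_correlation) + self.effect_delta >= 1.0:
            raise ValueError(
                "|base_correlation| + effect_delta must be < 1 to keep "
                "generated covariances positive definite"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for i, j in self.effect_block:
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"effect_block pair ({i},{j}) outside 0..{self.n_rois - 1}")


@dataclass
class SyntheticCohort:
    subjects: list[TimeSeriesMatrix]
    labels: list[int]
    spec: CohortSpec

    def __post_init__(self):
        if len(self.subjects) != len(self.labels):
            raise ValueError("subjects and labels length mismatch")


def block_pairs(rois) -> frozenset[tuple[int, int]]:
    """All unordered ROI pairs within an index set (a fully-connected block)."""
    rois = sorted(set(rois))
    return frozenset((a, b) for k, a in enumerate(rois) for b in rois[k + 1 :])


def make_group_covariance(spec: CohortSpec, group: int) -> np.ndarray:
    """Unit-diagonal latent covariance (= correlation) matrix for one group.

    Entries on ``effect_block`` equal ``base_correlation`` for group 0 and
    ``base_correlation + effect_delta`` for group 1; all other off-diagonal
    entries are 0.  Positive definiteness is verified by eigendecomposition;
    an indefinite matrix is repaired by diagonal loading (logged) and the
    result rescaled back to unit diagonal.
    """
    if group not in (0, 1):
        raise ValueError("group must be 0 or 1")
    r = spec.base_correlation + (spec.effect_delta if group == 1 else 0.0)
    cov = np.eye(spec.n_rois)
    for i, j in spec.effect_block:
        cov[i, j] = cov[j, i] = r
    lam_min = np.linalg.eigvalsh(cov)[0]
    if lam_min <= 1e-10:
        eps = abs(lam_min) + 1e-6
        logger.warning(
            "group-%d covariance not positive definite (min eig %.3e); "
            "diagonal loading with eps=%.3e", group, lam_min, eps,
        )
        cov = cov + eps * np.eye(spec.n_rois)
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        if np.linalg.eigvalsh(cov)[0] <= 1e-10:
            raise ValueError(f"covariance not positive definite after loading: {spec}")
    return cov


def sample_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full two-group cohort, reproducible from ``spec.seed``.

    Subject ``k`` of group ``g`` is an ``n_rois x n_timepoints`` matrix of
    ``n_timepoints`` i.i.d. draws from N(0, cov_g), plus independent
    N(0, noise_sd^2) noise on every entry.  Group 0 subjects come first.
    """
    rng = np.random.default_rng(spec.seed)
    roi_ids = [f"ROI{idx + 1:03d}" for idx in range(spec.n_rois)]
    subjects: list[TimeSeriesMatrix] = []
    labels: list[int] = []
    for group in (0, 1):
        chol = np.linalg.cholesky(make_group_covariance(spec, group))
        for k in range(spec.n_subjects_per_group):
            z = rng.standard_normal((spec.n_rois, spec.n_timepoints))
            values = chol @ z
            if spec.noise_sd > 0:
                values = values + spec.noise_sd * rng.standard_normal(values.shape)
            subjects.append(
                TimeSeriesMatrix(
                    values=values,
                    roi_ids=roi_ids,
                    subject_id=f"g{group}_s{k:03d}",
                )
            )
            labels.append(group)
    return SyntheticCohort(subjects=subjects, labels=labels, spec=spec)
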