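"""Normative reference model of edge-wise connectivity from a control cohort.

Structural matrices (streamline counts) are analyzed as log1p(count);
functional matrices (correlations) are shrunk toward the identity, embedded
in the tangent space at the cohort's SPD geometric mean, and analyzed as
tangent coefficients. On either representation the model stores a per-edge
mean and sample standard deviation over controls, and a mask excluding the
top third of edges by between-subject variance — the edges too variable in
healthy subjects for an individual deviation to be meaningful.

Edges are the n(n-1)/2 unordered off-diagonal pairs, ordered row-major over
the upper triangle (numpy `triu_indices`).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .atlas import Atlas
from . import spd

DEFAULT_EXCLUSION_FRACTION = 1.0 / 3.0
DEFAULT_K_SIGMA = 3.0
DEFAULT_SHRINKAGE = 1e-3


class Modality(str, enum.Enum):
    STRUCTURAL = "structural"
    FUNCTIONAL = "functional"


class Representation(str, enum.Enum):
    LOG1P_COUNT = "log1p_count"
    RAW_COUNT = "raw_count"
    TANGENT = "tangent"


class MeanKind(str, enum.Enum):
    GEOMETRIC = "geometric"
    LOG_EUCLIDEAN = "log_euclidean"


@dataclass
class ConnectivityMatrix:
    """One subject's region-by-region connectivity matrix, atlas-aligned.

    Structural values are non-negative streamline counts with zero diagonal;
    functional values are correlations in [-1, 1] with unit diagonal. Mild
    asymmetry (<= 1e-8 by default) is symmetrized by averaging on
    construction.
    """

    subject_id: str
    modality: Modality
    values: np.ndarray
    _ASYM_TOL = 1e-8

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"{self.subject_id}: matrix must be square, got {v.shape}")
        asym = np.abs(v - v.T).max() if v.size else 0.0
        if asym > self._ASYM_TOL:
            raise ValueError(f"{self.subject_id}: asymmetry {asym:.2e} exceeds tolerance")
        v = (v + v.T) / 2.0
        self.modality = Modality(self.modality)
        if self.modality is Modality.STRUCTURAL:
            if v.min() < 0:
                raise ValueError(f"{self.subject_id}: negative streamline count")
        else:
            if v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9:
                raise ValueError(f"{self.subject_id}: correlations outside [-1, 1]")
            np.fill_diagonal(v, 1.0)
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def check_atlas(self, atlas: Atlas) -> None:
        if self.n_regions != len(atlas):
            raise ValueError(
                f"{self.subject_id}: matrix has {self.n_regions} regions, "
                f"atlas has {len(atlas)}"
            )


def edge_index_pairs(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the unordered off-diagonal edges, in edge order."""
    return np.triu_indices(n_regions, k=1)


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def edge_vector(matrix: np.ndarray) -> np.ndarray:
    """Flatten a symmetric matrix to its per-edge vector (upper triangle)."""
    i, j = edge_index_pairs(matrix.shape[0])
    return matrix[i, j]


def edge_matrix(values: np.ndarray, n_regions: int, *, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of `edge_vector`: symmetric matrix with the given diagonal."""
    out = np.full((n_regions, n_regions), diagonal, dtype=values.dtype)
    i, j = edge_index_pairs(n_regions)
    out[i, j] = values
    out[j, i] = values
    return out


@dataclass
class NormativeReference:
    """Per-edge normative moments plus the exclusion mask, for one modality."""

    modality: Modality
    representation: Representation
    n_regions: int
    n_controls: int
    mu: np.ndarray                      # per-edge mean on the representation
    sigma: np.ndarray                   # per-edge sample sd (ddof=1)
    variance_rank: np.ndarray           # 0 = highest between-subject variance
    excluded_mask: np.ndarray           # True where edge is excluded
    exclusion_fraction: float = DEFAULT_EXCLUSION_FRACTION
    k_sigma: float = DEFAULT_K_SIGMA
    reference_matrix: np.ndarray | None = None  # SPD geometric mean (functional only)
    shrinkage: float = DEFAULT_SHRINKAGE
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = n_edges(self.n_regions)
        for name in ("mu", "sigma", "variance_rank", "excluded_mask"):
            if getattr(self, name).shape != (m,):
                raise ValueError(f"{name} must have shape ({m},)")
        if (self.sigma < 0).any():
            raise ValueError("sigma must be non-negative")
        if int(self.excluded_mask.sum()) != excluded_count(self.exclusion_fraction, m):
            raise ValueError("excluded count does not match floor(fraction * n_edges)")

    @property
    def degenerate_mask(self) -> np.ndarray:
        """Edges with zero between-subject spread; z-scores are undefined there."""
        return self.sigma == 0.0

    @property
    def retained_mask(self) -> np.ndarray:
        return ~self.excluded_mask & ~self.degenerate_mask

    def transform(self, subject: ConnectivityMatrix) -> np.ndarray:
        """Map a subject matrix onto the reference's detection representation,
        returning the per-edge vector."""
        if subject.modality is not self.modality:
            raise ValueError(
                f"modality mismatch: subject {subject.modality.value}, "
                f"reference {self.modality.value}"
            )
        if subject.n_regions != self.n_regions:
            raise ValueError(
                f"{subject.subject_id}: {subject.n_regions} regions, "
                f"reference has {self.n_regions}"
            )
        if self.representation is Representation.LOG1P_COUNT:
            return edge_vector(np.log1p(subject.values))
        if self.representation is Representation.RAW_COUNT:
            return edge_vector(subject.values)
        if self.reference_matrix is None:
            raise ValueError("tangent representation requires a reference matrix")
        shrunk = spd.shrink_correlation(subject.values, self.shrinkage)
        # A subject's matrix can be indefinite (e.g. edited entries); clip the
        # spectrum so the embedding stays defined. SPD inputs are unchanged.
        return edge_vector(spd.tangent_embed(spd.clip_spd(shrunk),
                                             self.reference_matrix))


def excluded_count(fraction: float, m: int) -> int:
    """floor(fraction * m), guarded against binary round-off of the product."""
    return int(np.floor(fraction * m + 1e-9))


def variance_exclusion_mask(variances: np.ndarray, fraction: float) -> np.ndarray:
    """Mask the floor(fraction * n_edges) edges with the highest variance.

    Ties are broken by ascending edge index (stable), so the mask is fully
    reproducible.
    """
    variances = np.asarray(variances, dtype=float)
    if not 0 <= fraction < 1:
        raise ValueError(f"exclusion fraction must be in [0, 1), got {fraction}")
    m = variances.shape[0]
    k = excluded_count(fraction, m)
    mask = np.zeros(m, dtype=bool)
    if k:
        order = np.argsort(-variances, kind="stable")
        mask[order[:k]] = True
    return mask


def _variance_ranks(variances: np.ndarray) -> np.ndarray:
    order = np.argsort(-variances, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(order.size)
    return ranks


def fc_from_timeseries(series: np.ndarray, subject_id: str = "subject") -> ConnectivityMatrix:
    """Pearson correlation matrix of a (time x region) BOLD series.

    For the 379-region atlas this is the full square matrix of
    379^2 = 143,641 correlations.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError(f"series must be 2-D (time x region), got shape {series.shape}")
    if series.shape[0] < 2:
        raise ValueError("need at least 2 timepoints to correlate")
    sd = series.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"region(s) with zero variance at column(s) {flat.tolist()}")
    corr = np.corrcoef(series, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return ConnectivityMatrix(subject_id=subject_id, modality=Modality.FUNCTIONAL,
                              values=corr)


def fit_normative(
    cohort: list[ConnectivityMatrix],
    modality: Modality | str | None = None,
    exclusion_fraction: float = DEFAULT_EXCLUSION_FRACTION,
    k_sigma: float = DEFAULT_K_SIGMA,
    *,
    representation: Representation | None = None,
    mean_kind: MeanKind = MeanKind.GEOMETRIC,
    shrinkage: float = DEFAULT_SHRINKAGE,
    atlas: Atlas | None = None,
) -> NormativeReference:
    """Fit the normative reference for one modality from a control cohort.

    Structural cohorts are represented as log1p(count) per edge; functional
    cohorts are shrunk toward the identity, the SPD geometric mean is taken
    as the tangent reference, and each subject is embedded there. Per-edge
    sample mean/sd (ddof=1) and between-subject variance ranks are computed
    on that representation, and the top `exclusion_fraction` of edges by
    variance is masked out. Invariant to subject ordering.
    """
    if len(cohort) < 3:
        raise ValueError(f"need at least 3 control subjects, got {len(cohort)}")
    modalities = {c.modality for c in cohort}
    if len(modalities) != 1:
        raise ValueError(f"mixed modalities in cohort: {sorted(m.value for m in modalities)}")
    cohort_modality = cohort[0].modality
    if modality is not None and Modality(modality) is not cohort_modality:
        raise ValueError(f"cohort is {cohort_modality.value}, requested {Modality(modality).value}")
    shapes = {c.n_regions for c in cohort}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent matrix sizes: {sorted(shapes)}")
    n = shapes.pop()
    if atlas is not None and n != len(atlas):
        raise ValueError(f"matrices have {n} regions, atlas has {len(atlas)}")
    if not 0 <= exclusion_fraction < 1:
        raise ValueError(f"exclusion fraction must be in [0, 1), got {exclusion_fraction}")
    if k_sigma <= 0:
        raise ValueError(f"k_sigma must be positive, got {k_sigma}")

    reference_matrix = None
    if cohort_modality is Modality.STRUCTURAL:
        rep = representation or Representation.LOG1P_COUNT
        if rep is Representation.TANGENT:
            raise ValueError("tangent representation applies to functional matrices")
        stack = np.stack([
            edge_vector(np.log1p(c.values) if rep is Representation.LOG1P_COUNT
                        else c.values)
            for c in cohort
        ])
    else:
        rep = representation or Representation.TANGENT
        shrunk = [spd.shrink_correlation(c.values, shrinkage) for c in cohort]
        if mean_kind is MeanKind.GEOMETRIC:
            reference_matrix = spd.geometric_mean_spd(shrunk)
        else:
            reference_matrix = spd.log_euclidean_mean_spd(shrunk)
        stack = np.stack([
            edge_vector(spd.tangent_embed(s, reference_matrix)) for s in shrunk
        ])

    mu = stack.mean(axis=0)
    sigma = stack.std(axis=0, ddof=1)
    variances = sigma ** 2
    return NormativeReference(
        modality=cohort_modality,
        representation=rep,
        n_regions=n,
        n_controls=len(cohort),
        mu=mu,
        sigma=sigma,
        variance_rank=_variance_ranks(variances),
        excluded_mask=variance_exclusion_mask(variances, exclusion_fraction),
        exclusion_fraction=exclusion_fraction,
        k_sigma=k_sigma,
        reference_matrix=reference_matrix,
        shrinkage=shrinkage,
        region_names=atlas.names if atlas is not None else [],
    )
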