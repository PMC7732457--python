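"""Per-edge 3-sigma anomaly detection against the normative reference.

Each retained edge of a subject is z-scored on the reference's detection
representation, z = (x_e - mu_e) / sigma_e, and flagged anomalous when
|z| strictly exceeds k_sigma (default 3). Excluded (high-variance) and
degenerate (sigma = 0) edges are never flagged; the boundary |z| = k is
normal. Patients are always scored against a control-fitted reference —
they never contribute to it.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .normative import ConnectivityMatrix, Modality, NormativeReference, n_edges

logger = logging.getLogger(__name__)


class EdgeStatus(enum.IntEnum):
    NORMAL = 0
    ANOMALY_LOW = 1
    ANOMALY_HIGH = 2
    EXCLUDED = 3
    DEGENERATE = 4

STATUS_LABELS = {s: s.name.lower() for s in EdgeStatus}


class Direction(str, enum.Enum):
    """Which tail(s) count as reportable anomalies."""

    LOW = "low"
    HIGH = "high"
    BOTH = "both"

    def admits(self, status: "EdgeStatus") -> bool:
        if status is EdgeStatus.ANOMALY_LOW:
            return self in (Direction.LOW, Direction.BOTH)
        if status is EdgeStatus.ANOMALY_HIGH:
            return self in (Direction.HIGH, Direction.BOTH)
        return False


# Reporting defaults: the structural fingerprint counts fiber loss (low tail)
# only; the functional fingerprint counts deviations in either direction.
DEFAULT_DIRECTION = {Modality.STRUCTURAL: Direction.LOW,
                     Modality.FUNCTIONAL: Direction.BOTH}


@dataclass
class AnomalyMatrix:
    """Per-edge detection outcome for one subject."""

    subject_id: str
    modality: Modality
    status: np.ndarray   # EdgeStatus codes, one per unordered edge
    zscore: np.ndarray   # NaN where excluded or degenerate
    k_sigma: float
    n_regions: int

    def __post_init__(self) -> None:
        m = n_edges(self.n_regions)
        if self.status.shape != (m,) or self.zscore.shape != (m,):
            raise ValueError(f"status/zscore must have shape ({m},)")

    def anomaly_mask(self, direction: Direction = Direction.BOTH) -> np.ndarray:
        mask = np.zeros_like(self.status, dtype=bool)
        if direction in (Direction.LOW, Direction.BOTH):
            mask |= self.status == EdgeStatus.ANOMALY_LOW
        if direction in (Direction.HIGH, Direction.BOTH):
            mask |= self.status == EdgeStatus.ANOMALY_HIGH
        return mask

    @property
    def n_anomalies(self) -> int:
        return int(self.anomaly_mask().sum())


def detect_anomalies(subject: ConnectivityMatrix,
                     reference: NormativeReference) -> AnomalyMatrix:
    """Score one subject against the reference and flag 3-sigma outliers.

    Functional subjects are embedded with the reference's stored geometric
    mean (never re-fit). Deterministic given (subject, reference).
    """
    x = reference.transform(subject)
    z = np.full(x.shape, np.nan)
    ok = ~reference.degenerate_mask
    z[ok] = (x[ok] - reference.mu[ok]) / reference.sigma[ok]

    k = reference.k_sigma
    status = np.full(x.shape, EdgeStatus.NORMAL, dtype=np.int8)
    status[z < -k] = EdgeStatus.ANOMALY_LOW
    status[z > k] = EdgeStatus.ANOMALY_HIGH
    status[reference.degenerate_mask] = EdgeStatus.DEGENERATE
    status[reference.excluded_mask] = EdgeStatus.EXCLUDED
    z[~np.isfinite(z)] = np.nan
    z[reference.excluded_mask] = np.nan
    z[reference.degenerate_mask] = np.nan
    return AnomalyMatrix(
        subject_id=subject.subject_id,
        modality=subject.modality,
        status=status,
        zscore=z,
        k_sigma=k,
        n_regions=reference.n_regions,
    )


def cohort_detect(subjects: list[ConnectivityMatrix],
                  reference: NormativeReference) -> list[AnomalyMatrix]:
    """Score every subject in order; abort naming the offending subject."""
    if not subjects:
        raise ValueError("empty subject list")
    out = []
    for subject in subjects:
        try:
            am = detect_anomalies(subject, reference)
        except Exception as exc:
            raise RuntimeError(f"detection failed for subject "
                               f"{subject.subject_id!r}: {exc}") from exc
        logger.info(
            "%s (%s): %d low, %d high of %d retained edges",
            am.subject_id, am.modality.value,
            int((am.status == EdgeStatus.ANOMALY_LOW).sum()),
            int((am.status == EdgeStatus.ANOMALY_HIGH).sum()),
            int(reference.retained_mask.sum()),
        )
        out.append(am)
    return out
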