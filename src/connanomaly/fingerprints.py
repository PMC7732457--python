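"""Fingerprint summaries of cohort anomaly matrices.

Three result surfaces:

* per-region anomaly burden — for each region, anomalies incident to it
  pooled over subjects, as a percentage of `retained incident edges x
  subjects` (the region's total potential anomalies);
* cross-subject edge frequency — for each flagged edge, in how many subjects
  it was flagged, annotated with network affiliations and the edge's
  hemisphere/relationship class;
* network submatrices — a subject's per-edge status restricted to the members
  of one large-scale network.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .atlas import Atlas, EdgeClass, classify_edge, network_members
from .detect import DEFAULT_DIRECTION, AnomalyMatrix, Direction, EdgeStatus
from .normative import NormativeReference, edge_index_pairs


def round_half_up(value: float, decimals: int = 2) -> float:
    """Display rounding, half-up (so 0.125 -> 0.13), as in printed tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class BurdenRow:
    """One region's anomaly burden pooled over subjects."""

    region: str
    n_anomalies: int
    n_subjects_with_anomaly: int
    n_low_variance: int        # retained (non-excluded, non-degenerate) incident edges
    n_subjects: int

    @property
    def total_potential(self) -> int:
        return self.n_low_variance * self.n_subjects

    @property
    def percentage_exact(self) -> float:
        return 100.0 * self.n_anomalies / self.total_potential if self.total_potential else 0.0

    @property
    def percentage(self) -> float:
        return round_half_up(self.percentage_exact, 2)


@dataclass
class FrequencyRow:
    """One edge's cross-subject anomaly frequency with anatomical annotation."""

    n_patients: int
    region_a: str
    region_b: str
    affiliation_a: str
    affiliation_b: str
    edge_class: EdgeClass


def _check_consistent(anomalies: list[AnomalyMatrix]) -> None:
    if not anomalies:
        raise ValueError("empty anomaly list")
    if len({a.modality for a in anomalies}) != 1:
        raise ValueError("anomaly matrices mix modalities")
    if len({a.n_regions for a in anomalies}) != 1:
        raise ValueError("anomaly matrices have inconsistent sizes")


def burden_table(
    anomalies: list[AnomalyMatrix],
    atlas: Atlas,
    reference: NormativeReference,
    direction_filter: Direction | None = None,
) -> list[BurdenRow]:
    """Per-region burden, sorted by percentage (exact, pre-rounding) descending.

    Every flagged (subject, edge) pair increments both endpoint regions once,
    so the sum of n_anomalies over regions is twice the number of flagged
    pairs. Ties in percentage are broken by region name ascending.
    """
    _check_consistent(anomalies)
    if anomalies[0].n_regions != len(atlas):
        raise ValueError("anomaly matrices do not match the atlas size")
    if reference.n_regions != len(atlas) or reference.modality is not anomalies[0].modality:
        raise ValueError("reference does not match the anomaly matrices")
    direction = direction_filter or DEFAULT_DIRECTION[anomalies[0].modality]

    n = len(atlas)
    i_idx, j_idx = edge_index_pairs(n)
    retained = reference.retained_mask
    n_low_variance = np.bincount(i_idx[retained], minlength=n) + \
        np.bincount(j_idx[retained], minlength=n)

    n_anom = np.zeros(n, dtype=int)
    n_subj_with = np.zeros(n, dtype=int)
    for am in anomalies:
        flagged = am.anomaly_mask(direction) & retained
        inc = np.bincount(i_idx[flagged], minlength=n) + \
            np.bincount(j_idx[flagged], minlength=n)
        n_anom += inc
        n_subj_with += inc > 0

    rows = [
        BurdenRow(
            region=name,
            n_anomalies=int(n_anom[r]),
            n_subjects_with_anomaly=int(n_subj_with[r]),
            n_low_variance=int(n_low_variance[r]),
            n_subjects=len(anomalies),
        )
        for r, name in enumerate(atlas.names)
    ]
    rows.sort(key=lambda row: (-row.percentage_exact, row.region))
    return rows


def edge_frequency_table(anomalies: list[AnomalyMatrix], atlas: Atlas,
                         direction_filter: Direction | None = None) -> list[FrequencyRow]:
    """One row per edge flagged in at least one subject, sorted by frequency
    descending then region names ascending."""
    _check_consistent(anomalies)
    if anomalies[0].n_regions != len(atlas):
        raise ValueError("anomaly matrices do not match the atlas size")
    direction = direction_filter or DEFAULT_DIRECTION[anomalies[0].modality]

    counts = np.zeros(anomalies[0].status.shape[0], dtype=int)
    for am in anomalies:
        counts += am.anomaly_mask(direction)
    i_idx, j_idx = edge_index_pairs(len(atlas))
    rows = []
    for e in np.flatnonzero(counts):
        a, b = atlas.names[i_idx[e]], atlas.names[j_idx[e]]
        rows.append(FrequencyRow(
            n_patients=int(counts[e]),
            region_a=a,
            region_b=b,
            affiliation_a=atlas.region(a).network,
            affiliation_b=atlas.region(b).network,
            edge_class=classify_edge(atlas, a, b),
        ))
    rows.sort(key=lambda r: (-r.n_patients, r.region_a, r.region_b))
    return rows


def network_submatrix(anomaly: AnomalyMatrix, atlas: Atlas, network: str) -> "NetworkSubmatrix":
    """A subject's per-edge status restricted to one network's members."""
    members = network_members(atlas, network)
    if len(members) < 2:
        raise ValueError(f"network {network!r} has fewer than 2 members")
    idx = [atlas.index[m] for m in members]
    n = len(atlas)
    full = np.full((n, n), EdgeStatus.NORMAL, dtype=np.int8)
    i_idx, j_idx = edge_index_pairs(n)
    full[i_idx, j_idx] = anomaly.status
    full[j_idx, i_idx] = anomaly.status
    sub = full[np.ix_(idx, idx)]
    np.fill_diagonal(sub, EdgeStatus.EXCLUDED)  # self-edges are undefined
    return NetworkSubmatrix(network=network, members=members, status=sub)


@dataclass
class NetworkSubmatrix:
    network: str
    members: list[str]
    status: np.ndarray  # square EdgeStatus grid over members, atlas order

    def render(self) -> str:
        """Plain-text grid: '.' normal, 'v' low, '^' high, ' ' excluded/degenerate.

        Excluded, degenerate and normal cells all read as background, the
        anomalies stand out — the textual analogue of a dotted submatrix plot.
        """
        glyph = {EdgeStatus.NORMAL: ".", EdgeStatus.ANOMALY_LOW: "v",
                 EdgeStatus.ANOMALY_HIGH: "^", EdgeStatus.EXCLUDED: " ",
                 EdgeStatus.DEGENERATE: " "}
        width = max(len(m) for m in self.members)
        lines = [f"network {self.network} ({len(self.members)} regions)"]
        for name, row in zip(self.members, self.status):
            lines.append(f"{name:>{width}} " + " ".join(glyph[EdgeStatus(s)] for s in row))
        return "\n".join(lines)


def burden_profile(rows: list[BurdenRow], width: int = 60) -> str:
    """Plain-text bar profile of burden percentages, highest first."""
    if not rows:
        return ""
    top = max(row.percentage_exact for row in rows) or 1.0
    name_w = max(len(r.region) for r in rows)
    lines = []
    for row in rows:
        bar = "#" * int(round(width * row.percentage_exact / top))
        lines.append(f"{row.region:>{name_w}} {row.percentage:6.2f} {bar}")
    return "\n".join(lines)
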