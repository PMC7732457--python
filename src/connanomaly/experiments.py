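"""Validation experiments on synthetic data, shared by the analysis scripts,
the test suite, and the acceptance script.

Each experiment is a self-contained, seeded computation returning plain
numbers: the planted-anomaly recovery study, the null 3-sigma calibration,
and the parcellation recovery study.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import Direction, cohort_detect
from .normative import (
    Modality,
    NormativeReference,
    Representation,
    ConnectivityMatrix,
    edge_index_pairs,
    fit_normative,
    n_edges,
)
from .parcellation import (
    assign_voxels,
    simulate_voxel_grid,
    train_parcellation_model,
)
from .simulate import (
    AnomalySpec,
    SimulationConfig,
    choose_planted_edges,
    simulate_controls,
    simulate_patients,
    simulation_atlas,
)


@dataclass
class RecoveryResult:
    sensitivities: list[float]
    fprs: list[float]

    @property
    def median_sensitivity(self) -> float:
        return float(np.median(self.sensitivities))

    @property
    def median_fpr(self) -> float:
        return float(np.median(self.fprs))


def planted_structural_recovery(
    n_regions: int = 100,
    n_controls: int = 41,
    n_patients: int = 21,
    n_planted: int = 10,
    sc_multiplier: float = 0.3,
    n_seeds: int = 20,
    base_seed: int = 0,
) -> RecoveryResult:
    """End-to-end recovery of planted fiber-loss edges, per seed.

    For each seed: simulate controls and patients, plant `n_planted`
    structural edges at `sc_multiplier`, fit the normative reference on
    controls only, flag low-tail 3-sigma outliers in patients, and score
    sensitivity on planted (subject, edge) pairs and the false-positive
    rate on unplanted retained edges.
    """
    atlas = simulation_atlas(n_regions)
    i_idx, j_idx = edge_index_pairs(n_regions)
    sens, fprs = [], []
    for s in range(n_seeds):
        seed = base_seed + s
        cfg = SimulationConfig(n_regions=n_regions, n_controls=n_controls,
                               n_patients=n_patients, seed=seed)
        controls = simulate_controls(cfg)
        planted = choose_planted_edges(controls, atlas, n_planted, seed=seed)
        spec = AnomalySpec(edges=tuple(planted), sc_multiplier=sc_multiplier,
                           fc_shift_sigmas=0.0)
        patients, _ = simulate_patients(cfg, spec, atlas=atlas, controls=controls)
        reference = fit_normative([c.structural for c in controls], atlas=atlas)
        anomalies = cohort_detect([p.structural for p in patients], reference)
        planted_set = set(planted)
        tp = fp = 0
        for am in anomalies:
            for e in np.flatnonzero(am.anomaly_mask(Direction.LOW)):
                edge = (atlas.names[i_idx[e]], atlas.names[j_idx[e]])
                tp += edge in planted_set
                fp += edge not in planted_set
        n_retained = int(reference.retained_mask.sum())
        sens.append(tp / (n_planted * n_patients))
        fprs.append(fp / ((n_retained - n_planted) * n_patients))
    return RecoveryResult(sensitivities=sens, fprs=fprs)


def null_flag_rate(
    n_regions: int = 144,
    n_subjects: int = 10,
    k_sigma: float = 3.0,
    seed: int = 0,
) -> tuple[float, int]:
    """Two-sided flag rate on edges drawn from the exact normative Gaussian.

    Builds a reference with analytically known per-edge moments (mu=100,
    sigma=1, no exclusion) and scores subjects whose edges are iid draws
    from that distribution. Returns (rate, number of edge draws); the
    expected rate is 2*Phi(-k).
    """
    m = n_edges(n_regions)
    reference = NormativeReference(
        modality=Modality.STRUCTURAL,
        representation=Representation.RAW_COUNT,
        n_regions=n_regions,
        n_controls=n_subjects,
        mu=np.full(m, 100.0),
        sigma=np.ones(m),
        variance_rank=np.arange(m),
        excluded_mask=np.zeros(m, dtype=bool),
        exclusion_fraction=0.0,
        k_sigma=k_sigma,
    )
    rng = np.random.default_rng(seed)
    i_idx, j_idx = edge_index_pairs(n_regions)
    flagged = 0
    for s in range(n_subjects):
        vals = 100.0 + rng.standard_normal(m)
        mat = np.zeros((n_regions, n_regions))
        mat[i_idx, j_idx] = vals
        mat[j_idx, i_idx] = vals
        subject = ConnectivityMatrix(f"null_{s}", Modality.STRUCTURAL, mat)
        am = cohort_detect([subject], reference)[0]
        flagged += int(am.anomaly_mask(Direction.BOTH).sum())
    total = m * n_subjects
    return flagged / total, total


@dataclass
class ParcellationResult:
    holdout_accuracy: float
    assignment_agreement: float
    n_radius_violations: int
    n_unassigned: int


def parcellation_recovery(
    n_parcels: int = 8,
    voxels_per_parcel: int = 500,
    holdout_fraction: float = 0.25,
    seed: int = 0,
) -> ParcellationResult:
    """Train on synthetic planted parcels and measure held-out recovery.

    Splits the grid into train/held-out voxels, fits the centroid-
    constrained classifier, and reports held-out accuracy, full-grid
    assignment agreement with the planted labels, and the number of
    assignments violating the centroid-radius constraint (must be zero by
    construction).
    """
    voxels, truth = simulate_voxel_grid(n_parcels=n_parcels,
                                        voxels_per_parcel=voxels_per_parcel,
                                        seed=seed)
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(len(voxels))
    n_hold = int(len(voxels) * holdout_fraction)
    holdout = [voxels[k] for k in order[:n_hold]]
    training = [voxels[k] for k in order[n_hold:]]

    model = train_parcellation_model(training, seed=seed)
    hold_assign = assign_voxels(model, holdout)
    hold_correct = np.mean([hold_assign[v.voxel_id] == truth[v.voxel_id]
                            for v in holdout])
    full_assign = assign_voxels(model, voxels)
    agreement = np.mean([full_assign[v.voxel_id] == truth[v.voxel_id]
                         for v in voxels])

    violations = 0
    for v in voxels:
        label = full_assign[v.voxel_id]
        if label is not None:
            dist = np.linalg.norm(model.centroids[label] - v.coords)
            violations += dist > model.radius
    return ParcellationResult(
        holdout_accuracy=float(hold_correct),
        assignment_agreement=float(agreement),
        n_radius_violations=int(violations),
        n_unassigned=sum(lab is None for lab in full_assign.values()),
    )
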