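"""Synthetic control and patient cohorts with known ground truth.

The generator emulates the study design the pipeline expects: a healthy
control cohort (default n=41) and a patient cohort (default n=21), each
subject contributing one structural matrix (streamline counts) and one
functional matrix (BOLD correlations) over a shared atlas.

Generative model
----------------
* Structural: each edge e has a fixed population log-mean m_e drawn once
  uniformly from `sc_log_mean_range`; subject counts are lognormal(m_e,
  sc_log_sd) rounded to integers. This reproduces the heavy right tail of
  streamline counts, with zero counts permitted.
* Functional: one population covariance from a low-rank factor model
  (rank `fc_base_rank` plus diagonal noise); each subject's covariance is a
  Wishart draw around it with `fc_sample_df` degrees of freedom, converted
  to a correlation matrix. Between-subject variance scales as 1/df.

Patients are drawn from the identical generative model, then effects are
planted post hoc: planted structural edges are multiplied by
`sc_multiplier` (< 1 encodes fiber loss) and planted functional edges are
shifted by `fc_shift_sigmas` control-model standard deviations, with
symmetry and the unit diagonal restored. Ground truth therefore lists
exactly the modified (subject, edge) pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import Atlas, default_atlas, make_atlas
from .normative import (
    ConnectivityMatrix,
    Modality,
    edge_index_pairs,
    fit_normative,
)

_TOY_LOBES = ("frontal", "parietal", "temporal", "occipital")
_TOY_NETWORKS = ("DMN", "CEN", "DAN", "VAN")


@dataclass(frozen=True)
class SimulationConfig:
    n_regions: int = 379
    n_controls: int = 41
    n_patients: int = 21
    seed: int = 0
    sc_log_mean_range: tuple[float, float] = (0.0, 5.0)
    sc_log_sd: float = 0.25
    fc_base_rank: int = 10
    fc_sample_df: int | None = None   # defaults to 2 * n_regions
    timepoints: int = 200

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be at least 2")
        if self.n_controls < 3:
            raise ValueError("n_controls must be at least 3")
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        if self.sc_log_sd <= 0:
            raise ValueError("sc_log_sd must be positive")
        lo, hi = self.sc_log_mean_range
        if not lo <= hi:
            raise ValueError("sc_log_mean_range must be (low, high) with low <= high")
        if self.df < self.n_regions:
            raise ValueError(
                f"fc_sample_df ({self.df}) must be >= n_regions ({self.n_regions}) "
                "so sampled covariances are full rank"
            )
        if self.fc_base_rank < 1:
            raise ValueError("fc_base_rank must be at least 1")

    @property
    def df(self) -> int:
        return self.fc_sample_df if self.fc_sample_df is not None else 2 * self.n_regions


@dataclass(frozen=True)
class AnomalySpec:
    """Planted edge-level effects for the patient cohort.

    `carriers` maps a planted edge to the subject ids carrying it; edges not
    in the mapping (or a None mapping) are carried by every patient.
    """

    edges: tuple[tuple[str, str], ...]
    sc_multiplier: float = 0.3
    fc_shift_sigmas: float = -4.0
    carriers: dict[tuple[str, str], tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        canon = [tuple(sorted(e)) for e in self.edges]
        if len(set(canon)) != len(canon):
            raise ValueError("planted edges must be distinct")
        if not 0 < self.sc_multiplier <= 1:
            raise ValueError("sc_multiplier must be in (0, 1]")

    def carriers_of(self, edge: tuple[str, str], all_subjects: list[str]) -> list[str]:
        if self.carriers is None:
            return list(all_subjects)
        for key in (edge, (edge[1], edge[0])):
            if key in self.carriers:
                return list(self.carriers[key])
        return list(all_subjects)


@dataclass
class SubjectData:
    subject_id: str
    structural: ConnectivityMatrix
    functional: ConnectivityMatrix
    covariance: np.ndarray = field(repr=False, default=None)  # subject FC covariance


def simulation_atlas(n_regions: int) -> Atlas:
    """The bundled 379-region atlas, or a deterministic toy atlas otherwise.

    Toy regions are split into left/right cortical halves (plus a midline
    brain stem when n is odd) with lobes and networks assigned cyclically.
    """
    if n_regions == 379:
        return default_atlas()
    rows = []
    n_cortical = n_regions if n_regions % 2 == 0 else n_regions - 1
    for i in range(n_cortical):
        hemi = "left" if i < n_cortical // 2 else "right"
        prefix = "L_" if hemi == "left" else "R_"
        rows.append((
            f"{prefix}s{(i % (n_cortical // 2)) + 1:03d}", hemi, "cortical", "none",
            _TOY_LOBES[i % len(_TOY_LOBES)], _TOY_NETWORKS[i % len(_TOY_NETWORKS)],
        ))
    if n_cortical != n_regions:
        rows.append(("Brain stem", "midline", "subcortical", "brainstem",
                     "subcortical", "Brainstem"))
    return make_atlas(rows)


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    """Independent, reproducible random streams derived from the config seed.

    The population stream is shared by controls and patients so both cohorts
    come from one generative model; the sampling streams differ.
    """
    root = np.random.SeedSequence(config.seed)
    pop, controls, patients, timeseries = root.spawn(4)
    return {
        "population": np.random.default_rng(pop),
        "controls": np.random.default_rng(controls),
        "patients": np.random.default_rng(patients),
        "timeseries": np.random.default_rng(timeseries),
    }


def _population_model(config: SimulationConfig,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Fixed per-edge structural log-means and the population FC covariance."""
    n = config.n_regions
    m = n * (n - 1) // 2
    lo, hi = config.sc_log_mean_range
    sc_log_means = rng.uniform(lo, hi, size=m)

    k = config.fc_base_rank
    w = rng.normal(size=(n, k)) / np.sqrt(k)
    noise = rng.uniform(0.5, 1.5, size=n)
    cov = w @ w.T + np.diag(noise)
    return sc_log_means, cov


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def _sample_cohort(config: SimulationConfig, n_subjects: int, prefix: str,
                   rng: np.random.Generator, sc_log_means: np.ndarray,
                   pop_cov: np.ndarray) -> list[SubjectData]:
    """Single sampling path shared by controls and patients."""
    n = config.n_regions
    i_idx, j_idx = edge_index_pairs(n)
    chol = np.linalg.cholesky(pop_cov + 1e-10 * np.eye(n))
    df = config.df
    subjects = []
    for s in range(n_subjects):
        sid = f"{prefix}{s + 1:03d}"
        counts = np.rint(rng.lognormal(mean=sc_log_means, sigma=config.sc_log_sd))
        sc = np.zeros((n, n))
        sc[i_idx, j_idx] = counts
        sc[j_idx, i_idx] = counts

        z = rng.standard_normal(size=(df, n)) @ chol.T
        cov = z.T @ z / df
        fc = _cov_to_corr(cov)
        subjects.append(SubjectData(
            subject_id=sid,
            structural=ConnectivityMatrix(sid, Modality.STRUCTURAL, sc),
            functional=ConnectivityMatrix(sid, Modality.FUNCTIONAL, fc),
            covariance=cov,
        ))
    return subjects


def simulate_controls(config: SimulationConfig) -> list[SubjectData]:
    """Sample the control cohort. Identical config (incl. seed) gives
    bit-identical output."""
    config.validate()
    streams = _streams(config)
    sc_log_means, pop_cov = _population_model(config, streams["population"])
    return _sample_cohort(config, config.n_controls, "control_",
                          streams["controls"], sc_log_means, pop_cov)


def _control_fc_sigma(controls: list[SubjectData]) -> np.ndarray:
    """Per-edge sd of raw control correlations — the sigma unit for FC plants."""
    stack = np.stack([s.functional.values for s in controls])
    i_idx, j_idx = edge_index_pairs(stack.shape[1])
    return stack[:, i_idx, j_idx].std(axis=0, ddof=1)


def simulate_patients(
    config: SimulationConfig,
    spec: AnomalySpec,
    atlas: Atlas | None = None,
    controls: list[SubjectData] | None = None,
) -> tuple[list[SubjectData], pd.DataFrame]:
    """Sample the patient cohort and plant the specified edge effects.

    Patients come from the same generative model as controls (identity
    effects reproduce the un-modified draw exactly); planted structural
    edges are scaled by `sc_multiplier` and rounded, planted functional
    edges shifted by `fc_shift_sigmas` control-model sigmas and clipped to
    [-1, 1]. Returns the cohort and the ground-truth table of modified
    (subject, edge) pairs.
    """
    config.validate()
    atlas = atlas if atlas is not None else simulation_atlas(config.n_regions)
    if len(atlas) != config.n_regions:
        raise ValueError("atlas size does not match config.n_regions")
    for a, b in spec.edges:
        for name in (a, b):
            if name not in atlas.index:
                raise ValueError(f"planted edge references unknown region {name!r}")
        if a == b:
            raise ValueError(f"planted self-edge ({a!r})")

    streams = _streams(config)
    sc_log_means, pop_cov = _population_model(config, streams["population"])
    patients = _sample_cohort(config, config.n_patients, "patient_",
                              streams["patients"], sc_log_means, pop_cov)

    fc_sigma = None
    if spec.fc_shift_sigmas != 0.0 and spec.edges:
        if controls is None:
            controls = _sample_cohort(config, config.n_controls, "control_",
                                      streams["controls"], sc_log_means, pop_cov)
        fc_sigma = _control_fc_sigma(controls)

    n = config.n_regions
    i_idx, j_idx = edge_index_pairs(n)
    edge_pos = {(int(i), int(j)): e for e, (i, j) in enumerate(zip(i_idx, j_idx))}
    patient_ids = [p.subject_id for p in patients]
    truth_rows = []
    for a, b in spec.edges:
        ia, ib = sorted((atlas.index[a], atlas.index[b]))
        e = edge_pos[(ia, ib)]
        for sid in spec.carriers_of((a, b), patient_ids):
            if sid not in patient_ids:
                raise ValueError(f"carrier {sid!r} is not a simulated patient")
            p = patients[patient_ids.index(sid)]
            # Identity effects leave values untouched, but the plant is
            # still recorded: ground truth lists planted pairs, not effects.
            if spec.sc_multiplier != 1.0:
                sc = p.structural.values
                sc[ia, ib] = sc[ib, ia] = np.rint(sc[ia, ib] * spec.sc_multiplier)
            truth_rows.append((sid, atlas.names[ia], atlas.names[ib],
                               "structural", spec.sc_multiplier))
            if spec.fc_shift_sigmas != 0.0:
                fc = p.functional.values
                shifted = np.clip(fc[ia, ib] + spec.fc_shift_sigmas * fc_sigma[e],
                                  -1.0, 1.0)
                fc[ia, ib] = fc[ib, ia] = shifted
            truth_rows.append((sid, atlas.names[ia], atlas.names[ib],
                               "functional", spec.fc_shift_sigmas))
    truth = pd.DataFrame(truth_rows, columns=["subject", "region_a", "region_b",
                                              "modality", "effect"])
    return patients, truth


def emit_timeseries(config: SimulationConfig, covariance: np.ndarray,
                    seed: int | None = None) -> np.ndarray:
    """Draw a (timepoints x region) Gaussian BOLD series whose sample
    correlation converges to the covariance's correlation."""
    config.validate()
    if config.timepoints < 2:
        raise ValueError("timepoints must be at least 2")
    covariance = np.asarray(covariance, dtype=float)
    if covariance.shape != (config.n_regions, config.n_regions):
        raise ValueError("covariance shape does not match config.n_regions")
    rng = (np.random.default_rng(seed) if seed is not None
           else _streams(config)["timeseries"])
    chol = np.linalg.cholesky(covariance + 1e-10 * np.eye(config.n_regions))
    return rng.standard_normal(size=(config.timepoints, config.n_regions)) @ chol.T


def choose_planted_edges(
    controls: list[SubjectData],
    atlas: Atlas,
    n_planted: int = 10,
    seed: int = 0,
    modality: Modality = Modality.STRUCTURAL,
    min_mean_count: float = 5.0,
) -> list[tuple[str, str]]:
    """Pick planted edges among the low-variance (retained) edges of a
    control-fitted reference.

    Reported anomalies in the target analysis live on retained edges by
    construction (excluded edges can never be flagged), so planted effects
    sample the same population: retained, non-degenerate edges under the
    reference the controls induce. Structural plants additionally require a
    normative mean of at least `min_mean_count` streamlines: a fractional
    loss on a near-empty edge is erased by integer rounding and does not
    represent a fiber-loss lesion.
    """
    cohort = [getattr(s, modality.value) for s in controls]
    reference = fit_normative(cohort, atlas=atlas)
    eligible = reference.retained_mask.copy()
    if modality is Modality.STRUCTURAL and min_mean_count > 0:
        eligible &= reference.mu >= np.log1p(min_mean_count)
    candidates = np.flatnonzero(eligible)
    if candidates.size < n_planted:
        raise ValueError(f"only {candidates.size} retained edges; "
                         f"cannot plant {n_planted}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_planted, replace=False)
    i_idx, j_idx = edge_index_pairs(len(atlas))
    return [(atlas.names[i_idx[e]], atlas.names[j_idx[e]]) for e in sorted(chosen)]
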