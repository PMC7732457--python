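"""Readers, writers, pipeline orchestration, and the run manifest.

All artifacts are tab-separated UTF-8 text (human-diffable, adequate at
379^2 scale) plus JSON sidecars. Matrices are written with region names as
both header row and first column; readers validate names against the atlas
and accept permuted files by reordering.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import Atlas, default_atlas, load_atlas
from .detect import (
    DEFAULT_DIRECTION,
    AnomalyMatrix,
    Direction,
    EdgeStatus,
    STATUS_LABELS,
    cohort_detect,
)
from .fingerprints import (
    BurdenRow,
    FrequencyRow,
    burden_profile,
    burden_table,
    edge_frequency_table,
    network_submatrix,
)
from .normative import (
    ConnectivityMatrix,
    Modality,
    NormativeReference,
    Representation,
    edge_index_pairs,
    fit_normative,
)
from .simulate import (
    AnomalySpec,
    SimulationConfig,
    choose_planted_edges,
    simulate_controls,
    simulate_patients,
    simulation_atlas,
)

logger = logging.getLogger(__name__)

READ_ASYM_TOL = 1e-6

# Printed-table column headers, in the published order.
BURDEN_COLUMNS = [
    "Parcellation", "No. of anomalies", "No. of subjects with at least one anomaly",
    "No. of low variance connections", "Total potential anomalies",
    "Percentage of total %",
]
FREQUENCY_COLUMNS = [
    "Patients", "Affiliation 1", "Parcellation 1", "Parcellation 2",
    "Affiliation 2", "Hemisphere", "Relationship",
]

_HEMI_LABEL = {"left": "Left", "right": "Right", "bilateral": "Bilateral",
               "midline_involved": "Midline"}
_REL_LABEL = {
    "intralobar": "Intralobar", "long_range": "Long range",
    "interhemispheric": "Interhemispheric", "corticobasal": "Corticobasal",
    "corticothalamic": "Corticothalamic", "corticohippocampal": "Corticohippocampal",
    "cortico_subcortical_other": "Cortico-subcortical",
    "subcortico_subcortical": "Subcortico-subcortical",
}


# ---------------------------------------------------------------------------
# matrices

def read_matrix(path: str | Path, atlas: Atlas,
                modality: Modality | str) -> ConnectivityMatrix:
    """Read a region-by-region matrix, validating and reordering to atlas order."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    names = list(frame.columns)
    if list(frame.index) != names:
        raise ValueError(f"{path}: row and column names differ")
    unknown = [n for n in names if n not in atlas.index]
    if unknown:
        raise ValueError(f"{path}: unknown region name(s) {unknown[:5]}")
    if set(names) != set(atlas.names):
        missing = sorted(set(atlas.names) - set(names))
        raise ValueError(f"{path}: missing region(s) {missing[:5]}")
    frame = frame.loc[atlas.names, atlas.names]
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"{path}: non-numeric or missing cell")
    asym = np.abs(values - values.T).max()
    if asym > READ_ASYM_TOL:
        raise ValueError(f"{path}: asymmetry {asym:.2e} exceeds {READ_ASYM_TOL:.0e}")
    values = (values + values.T) / 2.0
    return ConnectivityMatrix(subject_id=path.stem, modality=Modality(modality),
                              values=values)


def write_matrix(path: str | Path, matrix: ConnectivityMatrix, atlas: Atlas) -> None:
    matrix.check_atlas(atlas)
    frame = pd.DataFrame(matrix.values, index=atlas.names, columns=atlas.names)
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_timeseries(path: str | Path) -> np.ndarray:
    """Delimited (time x region) series with a region-name header line."""
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# normative reference

def write_reference(stem: str | Path, reference: NormativeReference,
                    atlas: Atlas, atlas_checksum: str = "") -> list[Path]:
    """Serialize a reference as <stem>_edges.tsv, <stem>.json and, for the
    tangent representation, <stem>_reference_matrix.tsv."""
    stem = Path(stem)
    i_idx, j_idx = edge_index_pairs(reference.n_regions)
    names = atlas.names
    table = pd.DataFrame({
        "region_a": [names[i] for i in i_idx],
        "region_b": [names[j] for j in j_idx],
        "mu": reference.mu,
        "sigma": reference.sigma,
        "variance": reference.sigma ** 2,
        "rank": reference.variance_rank,
        "excluded": reference.excluded_mask.astype(int),
    })
    paths = [stem.with_name(stem.name + "_edges.tsv")]
    table.to_csv(paths[0], sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "modality": reference.modality.value,
        "representation": reference.representation.value,
        "n_regions": reference.n_regions,
        "n_controls": reference.n_controls,
        "exclusion_fraction": reference.exclusion_fraction,
        "k_sigma": reference.k_sigma,
        "shrinkage": reference.shrinkage,
        "atlas_checksum": atlas_checksum,
    }
    paths.append(stem.with_suffix(".json"))
    paths[-1].write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    if reference.reference_matrix is not None:
        paths.append(stem.with_name(stem.name + "_reference_matrix.tsv"))
        pd.DataFrame(reference.reference_matrix, index=names, columns=names) \
            .to_csv(paths[-1], sep="\t", float_format="%.17g")
    return paths


def read_reference(stem: str | Path, atlas: Atlas) -> NormativeReference:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    table = pd.read_csv(stem.with_name(stem.name + "_edges.tsv"), sep="\t")
    ref_path = stem.with_name(stem.name + "_reference_matrix.tsv")
    reference_matrix = None
    if ref_path.exists():
        frame = pd.read_csv(ref_path, sep="\t", index_col=0)
        reference_matrix = frame.loc[atlas.names, atlas.names].to_numpy(dtype=float)
        reference_matrix = (reference_matrix + reference_matrix.T) / 2.0
    return NormativeReference(
        modality=Modality(sidecar["modality"]),
        representation=Representation(sidecar["representation"]),
        n_regions=sidecar["n_regions"],
        n_controls=sidecar["n_controls"],
        mu=table["mu"].to_numpy(),
        sigma=table["sigma"].to_numpy(),
        variance_rank=table["rank"].to_numpy(),
        excluded_mask=table["excluded"].to_numpy().astype(bool),
        exclusion_fraction=sidecar["exclusion_fraction"],
        k_sigma=sidecar["k_sigma"],
        reference_matrix=reference_matrix,
        shrinkage=sidecar["shrinkage"],
        region_names=atlas.names,
    )


# ---------------------------------------------------------------------------
# anomalies and fingerprint tables

def write_anomalies(path: str | Path, anomalies: list[AnomalyMatrix],
                    atlas: Atlas) -> None:
    """Long-format TSV: subject, region_a, region_b, modality, zscore, status."""
    i_idx, j_idx = edge_index_pairs(len(atlas))
    names = atlas.names
    frames = []
    for am in anomalies:
        frames.append(pd.DataFrame({
            "subject": am.subject_id,
            "region_a": [names[i] for i in i_idx],
            "region_b": [names[j] for j in j_idx],
            "modality": am.modality.value,
            "zscore": am.zscore,
            "status": [STATUS_LABELS[EdgeStatus(s)] for s in am.status],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.6g")


def read_anomalies(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def burden_frame(rows: list[BurdenRow]) -> pd.DataFrame:
    return pd.DataFrame({
        BURDEN_COLUMNS[0]: [r.region for r in rows],
        BURDEN_COLUMNS[1]: [r.n_anomalies for r in rows],
        BURDEN_COLUMNS[2]: [r.n_subjects_with_anomaly for r in rows],
        BURDEN_COLUMNS[3]: [r.n_low_variance for r in rows],
        BURDEN_COLUMNS[4]: [r.total_potential for r in rows],
        BURDEN_COLUMNS[5]: [f"{r.percentage:.2f}" for r in rows],
    })


def frequency_frame(rows: list[FrequencyRow]) -> pd.DataFrame:
    return pd.DataFrame({
        FREQUENCY_COLUMNS[0]: [r.n_patients for r in rows],
        FREQUENCY_COLUMNS[1]: [r.affiliation_a for r in rows],
        FREQUENCY_COLUMNS[2]: [r.region_a for r in rows],
        FREQUENCY_COLUMNS[3]: [r.region_b for r in rows],
        FREQUENCY_COLUMNS[4]: [r.affiliation_b for r in rows],
        FREQUENCY_COLUMNS[5]: [_HEMI_LABEL[r.edge_class.hemisphere_relation.value]
                               for r in rows],
        FREQUENCY_COLUMNS[6]: [_REL_LABEL[r.edge_class.relationship.value]
                               for r in rows],
    })


def write_burden_table(path: str | Path, rows: list[BurdenRow]) -> None:
    burden_frame(rows).to_csv(path, sep="\t", index=False)


def write_frequency_table(path: str | Path, rows: list[FrequencyRow]) -> None:
    frequency_frame(rows).to_csv(path, sep="\t", index=False)


def read_burden_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_frequency_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    """End-to-end run configuration; flags of the CLI mirror these fields."""

    output_dir: str = "connanomaly_out"
    seed: int = 0
    atlas_path: str | None = None          # None -> bundled default atlas
    modalities: tuple[str, ...] = ("structural", "functional")
    exclusion_fraction: float = 1.0 / 3.0
    k_sigma: float = 3.0
    structural_direction: str = "low"
    functional_direction: str = "both"
    log_level: str = "INFO"
    # simulated-cohort mode (used when no file lists are given)
    simulation: SimulationConfig | None = None
    n_planted: int = 10
    sc_multiplier: float = 0.3
    fc_shift_sigmas: float = -4.0
    # file mode: per-modality lists of matrix paths
    control_paths: dict[str, list[str]] = field(default_factory=dict)
    patient_paths: dict[str, list[str]] = field(default_factory=dict)
    submatrix_networks: tuple[str, ...] = ("DMN", "CEN", "DAN", "VAN")

    def __post_init__(self) -> None:
        if not 0 <= self.exclusion_fraction < 1:
            raise ValueError(f"exclusion_fraction must be in [0, 1), "
                             f"got {self.exclusion_fraction}")
        if self.k_sigma <= 0:
            raise ValueError(f"k_sigma must be positive, got {self.k_sigma}")
        for mod in self.modalities:
            Modality(mod)
        Direction(self.structural_direction)
        Direction(self.functional_direction)

    def direction(self, modality: Modality) -> Direction:
        return Direction(self.structural_direction
                         if modality is Modality.STRUCTURAL
                         else self.functional_direction)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if sim is not None:
            sim.setdefault("seed", cfg.seed)
            cfg.simulation = SimulationConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()})
        return cfg


@dataclass
class ModalityResult:
    reference: NormativeReference
    anomalies: list[AnomalyMatrix]
    burden: list[BurdenRow]
    frequency: list[FrequencyRow]


@dataclass
class PipelineBundle:
    config: PipelineConfig
    atlas: Atlas
    results: dict[Modality, ModalityResult]
    ground_truth: pd.DataFrame | None
    manifest_path: Path
    output_dir: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _atlas_checksum(atlas: Atlas) -> str:
    blob = "\n".join(
        "\t".join((r.name, r.hemisphere.value, r.kind.value,
                   r.subcortical_class.value, r.lobe, r.network))
        for r in atlas
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def _load_cohort(paths: list[str], atlas: Atlas,
                 modality: Modality) -> list[ConnectivityMatrix]:
    return [read_matrix(p, atlas, modality) for p in paths]


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    """fit -> detect -> fingerprint for each modality; write all artifacts
    and a manifest. Identical config + seed reproduces identical files."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    simulated = not config.control_paths
    ground_truth = None
    if simulated:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        atlas = (load_atlas(config.atlas_path) if config.atlas_path
                 else simulation_atlas(sim.n_regions))
        logger.info("simulating %d controls and %d patients over %d regions",
                    sim.n_controls, sim.n_patients, sim.n_regions)
        controls = simulate_controls(sim)
        planted = choose_planted_edges(controls, atlas, config.n_planted,
                                       seed=sim.seed)
        spec = AnomalySpec(edges=tuple(planted),
                           sc_multiplier=config.sc_multiplier,
                           fc_shift_sigmas=config.fc_shift_sigmas)
        patients, ground_truth = simulate_patients(sim, spec, atlas=atlas,
                                                   controls=controls)
        cohorts = {
            Modality(m): ([getattr(s, m) for s in controls],
                          [getattr(s, m) for s in patients])
            for m in config.modalities
        }
        ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    else:
        atlas = load_atlas(config.atlas_path) if config.atlas_path else default_atlas()
        cohorts = {}
        for m in config.modalities:
            mod = Modality(m)
            cohorts[mod] = (_load_cohort(config.control_paths[m], atlas, mod),
                            _load_cohort(config.patient_paths[m], atlas, mod))

    checksum = _atlas_checksum(atlas)
    results: dict[Modality, ModalityResult] = {}
    outputs: list[Path] = []
    if simulated:
        outputs.append(out / "ground_truth.tsv")
    for mod, (controls_m, patients_m) in cohorts.items():
        stage = f"{mod.value} fit"
        try:
            reference = fit_normative(
                controls_m, exclusion_fraction=config.exclusion_fraction,
                k_sigma=config.k_sigma, atlas=atlas)
            stage = f"{mod.value} detect"
            anomalies = cohort_detect(patients_m, reference)
            stage = f"{mod.value} fingerprint"
            direction = config.direction(mod)
            burden = burden_table(anomalies, atlas, reference, direction)
            frequency = edge_frequency_table(anomalies, atlas, direction)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        logger.info("%s: %d edges, %d excluded, %d degenerate, %d flagged pairs",
                    mod.value, reference.mu.shape[0],
                    int(reference.excluded_mask.sum()),
                    int(reference.degenerate_mask.sum()),
                    sum(int(a.anomaly_mask(direction).sum()) for a in anomalies))
        results[mod] = ModalityResult(reference, anomalies, burden, frequency)

        outputs += write_reference(out / f"normative_{mod.value}", reference,
                                   atlas, checksum)
        write_anomalies(out / f"anomalies_{mod.value}.tsv", anomalies, atlas)
        write_burden_table(out / f"burden_{mod.value}.tsv", burden)
        write_frequency_table(out / f"frequency_{mod.value}.tsv", frequency)
        (out / f"burden_profile_{mod.value}.txt").write_text(
            burden_profile(burden) + "\n")
        outputs += [out / f"anomalies_{mod.value}.tsv",
                    out / f"burden_{mod.value}.tsv",
                    out / f"frequency_{mod.value}.tsv",
                    out / f"burden_profile_{mod.value}.txt"]
        available = set(atlas.networks)
        for network in config.submatrix_networks:
            if network not in available:
                continue
            sub = network_submatrix(results[mod].anomalies[0], atlas, network)
            p = out / f"submatrix_{mod.value}_{network.replace(' ', '_')}.txt"
            p.write_text(sub.render() + "\n")
            outputs.append(p)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "atlas_checksum": checksum,
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k != "simulation"},
        "simulation": (dataclasses.asdict(config.simulation)
                       if config.simulation else None),
        "files": {p.name: _sha256(p) for p in sorted(set(outputs))},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                        default=str) + "\n")
    return PipelineBundle(config=config, atlas=atlas, results=results,
                          ground_truth=ground_truth, manifest_path=manifest_path,
                          output_dir=out)


def write_report(bundle: PipelineBundle, top_k: int = 10) -> str:
    """Plain-text summary: top burden and frequency rows per modality."""
    lines = []
    for mod, res in bundle.results.items():
        lines.append(f"== {mod.value} ==")
        lines.append(f"top {min(top_k, len(res.burden))} regions by anomaly burden:")
        lines.append(burden_frame(res.burden[:top_k]).to_string(index=False))
        lines.append("")
        lines.append(f"top {min(top_k, len(res.frequency))} most frequent anomalous edges:")
        freq = frequency_frame(res.frequency[:top_k])
        lines.append(freq.to_string(index=False) if len(freq) else "(no anomalies)")
        lines.append("")
    return "\n".join(lines)
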