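"""Score the 21 simulated patients against the fitted normative references.

Each retained edge is z-scored on the reference representation and flagged
when |z| > 3. Writes long-format anomaly tables and a per-subject summary;
reads the references serialized by 02_fit_normative.py (run that first).
"""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from connanomaly.detect import Direction, cohort_detect  # noqa: E402
from connanomaly.io import read_reference, write_anomalies  # noqa: E402
from connanomaly.simulate import (  # noqa: E402
    AnomalySpec,
    SimulationConfig,
    choose_planted_edges,
    simulate_controls,
    simulate_patients,
    simulation_atlas,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
REF_DIR = ROOT / "results" / "normative"
OUT = ROOT / "results"


def main() -> None:
    if not (REF_DIR / "structural.json").exists():
        sys.exit("run analysis/02_fit_normative.py first")
    cfg = SimulationConfig(seed=SEED)
    atlas = simulation_atlas(cfg.n_regions)
    controls = simulate_controls(cfg)
    planted = choose_planted_edges(controls, atlas, n_planted=10, seed=SEED)
    patients, _ = simulate_patients(cfg, AnomalySpec(edges=tuple(planted)),
                                    atlas=atlas, controls=controls)
    rows = []
    for modality, direction in (("structural", Direction.LOW),
                                ("functional", Direction.BOTH)):
        ref = read_reference(REF_DIR / modality, atlas)
        anomalies = cohort_detect([getattr(p, modality) for p in patients], ref)
        write_anomalies(OUT / f"03_anomalies_{modality}.tsv", anomalies, atlas)
        for am in anomalies:
            rows.append({"subject": am.subject_id, "modality": modality,
                         "n_flagged": int(am.anomaly_mask(direction).sum())})
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "03_anomaly_counts.tsv", sep="\t", index=False)
    print(summary.groupby("modality")["n_flagged"].describe().round(1))
    print(f"wrote anomaly tables under {OUT}")


if __name__ == "__main__":
    main()
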