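"""Fit the normative references from the 41 simulated controls.

Structural connectivity is modeled as per-edge log1p(count) statistics;
functional connectivity is embedded in the tangent space at the cohort's
SPD geometric mean. The top third of edges by between-subject variance is
excluded per modality. Serializes both references under results/normative/.
"""
import sys
import time
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from connanomaly.io import _atlas_checksum, write_reference  # noqa: E402
from connanomaly.normative import fit_normative  # noqa: E402
from connanomaly.simulate import (  # noqa: E402
    SimulationConfig,
    simulate_controls,
    simulation_atlas,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "normative"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    atlas = simulation_atlas(cfg.n_regions)
    controls = simulate_controls(cfg)
    checksum = _atlas_checksum(atlas)
    for modality in ("structural", "functional"):
        t0 = time.time()
        cohort = [getattr(s, modality) for s in controls]
        ref = fit_normative(cohort, atlas=atlas)
        write_reference(OUT / modality, ref, atlas, checksum)
        q = np.percentile(ref.sigma[ref.retained_mask], [25, 50, 75])
        print(f"{modality}: {ref.mu.size} edges, "
              f"{int(ref.excluded_mask.sum())} excluded, "
              f"{int(ref.degenerate_mask.sum())} degenerate; "
              f"retained sigma quartiles {q.round(4)} "
              f"({time.time() - t0:.1f}s)")
    print(f"references written under {OUT}")


if __name__ == "__main__":
    main()
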