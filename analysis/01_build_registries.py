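#!/usr/bin/env python
"""Build the analysis inputs.

Writes (a) the published-counts registry pair — engineered so linkage and
stratified estimation reproduce the study's summary table exactly — and
(b) one synthetic dual-registry draw from the study-like generator defaults,
with its ground truth, for the validation analyses.
"""

import json
from pathlib import Path

from recapture.fixtures import write_table1_fixture
from recapture.records import missingness_profile, write_registry
from recapture.synthetic import SimulationConfig, generate, save_config

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    h_path, p_path = write_table1_fixture(OUT / "table1")
    print(f"published-counts fixture: {h_path}, {p_path}")

    cfg = SimulationConfig(seed=seed)
    hospital, police, truth = generate(cfg)
    sim_dir = OUT / "synthetic"
    sim_dir.mkdir(parents=True, exist_ok=True)
    write_registry(hospital, sim_dir / "hospital.csv")
    write_registry(police, sim_dir / "police.csv")
    save_config(cfg, sim_dir / "config.yaml")
    (sim_dir / "truth_links.csv").write_text(
        "hospital_id,police_id\n" + "".join(f"{h},{p}\n" for h, p in truth.links)
    )
    counts = truth.capture_counts()
    (sim_dir / "truth_summary.json").write_text(
        json.dumps({"n_true": truth.n_true, "d1": counts.d1, "d2": counts.d2, "m": counts.m}, indent=2)
    )
    print(
        f"synthetic draw (seed {seed}): {counts.d1} hospital / {counts.d2} police "
        f"records, {counts.m} true overlaps of {truth.n_true} deaths"
    )
    print(f"hospital missingness: {missingness_profile(hospital)}")


if __name__ == "__main__":
    main()
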