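#!/usr/bin/env python
"""Generate the synthetic 26-participant play cohort and write CSV bundles.

Each participant's bundle holds the raw streams a real session would
produce: 25 Hz chair-pressure (12 channels, mV), beat-by-beat inter-beat
intervals and BPM, mouse telemetry, the game phase log, sparse in-game
events, the 1 Hz annotation trace, and (synthetic-only) the latent
engagement ground truth.  About half the cohort reaches Mission-2,
mirroring the study protocol.

Writes: scratch/sessions/pNN/*.csv (heavy data) and
results/cohort_summary.csv
"""

from pathlib import Path

import pandas as pd

from engagesense import SessionConfig, generate_cohort
from engagesense.io import write_bundle

ROOT = Path(__file__).resolve().parents[1]
SESSIONS = ROOT / "scratch" / "sessions"
RESULTS = ROOT / "results"


def main(seed: int = 1) -> None:
    cfg = SessionConfig(seed=seed)
    bundles = generate_cohort(cfg)
    rows = []
    for b in bundles:
        write_bundle(b, SESSIONS)
        rows.append(
            {
                "participant": b.participant,
                "session_s": b.phases.phases[-1].end,
                "phases": len(b.phases.phases),
                "plays_mission2": any(p.name == "Mission-2" for p in b.phases.phases),
                "n_events": len(b.events),
                "n_beats": len(b.ibi),
            }
        )
    RESULTS.mkdir(exist_ok=True)
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False)
    print(f"wrote {len(bundles)} bundles under {SESSIONS}")
    print(f"Mission-2 players: {int(summary['plays_mission2'].sum())}/{len(summary)}")
    print(f"total in-game events: {int(summary['n_events'].sum())}")


if __name__ == "__main__":
    main()
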