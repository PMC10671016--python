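#!/usr/bin/env python
"""Generate the synthetic study: 3 animals x {morphine, cocaine, saline}.

Each session emulates the implanted 40x90-pixel CMOS sensor recording
dLight fluorescence from 15 min before to 225 min after a subcutaneous
injection (one frame per 5 s).  Stacks land under scratch/sessions/ as
multi-page TIFF with JSON sidecars carrying the planted ground truth.
"""

from pathlib import Path

from microdff import PipelineConfig, simulate_session, write_session

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "sessions"


def main() -> None:
    config = PipelineConfig(seed=1)
    for drug in config.drugs:
        for i in range(config.n_animals):
            seed = config.seed + i
            params = config.simulation_params(drug, seed)
            recording, truth = simulate_session(params)
            session_dir = OUT / f"{drug}_{i + 1}"
            write_session(recording, session_dir, truth=truth)
            print(f"{session_dir.relative_to(ROOT)}: {recording.n_frames} frames, "
                  f"{len(truth.sites)} planted sites, seed {seed}")
    print(f"\nSessions written under {OUT.relative_to(ROOT)}/ "
          "(regenerate any time; stacks are not kept in the repository).")


if __name__ == "__main__":
    main()
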