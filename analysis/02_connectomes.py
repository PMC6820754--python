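#!/usr/bin/env python
"""Reduce every recording to one z-scored directed connectome.

Per subject: causal 0.5 Hz high-pass + 50 Hz notch + zero-phase 35 Hz
low-pass; eight pseudo-random non-overlapping 8-s epochs after the first
minute; Hilbert phases; a per-epoch prediction delay from the pooled phase
sign-flip rate; all-pairs phase transfer entropy per epoch; epoch-averaged
and z-scored over the off-diagonal.  Writes one connectome file per subject.
"""

import json
from pathlib import Path

import numpy as np

from ptenet.io import read_cohort, write_connectome
from ptenet.pipeline import PipelineConfig, compute_subject_connectome

HERE = Path(__file__).resolve().parent


def main() -> None:
    cfg = PipelineConfig.from_yaml(HERE / "config.yaml")
    out = Path(cfg.out_dir)
    cohort = read_cohort(out / "cohort")
    conn_dir = out / "connectomes"
    conn_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence([cfg.seed, 1]).generate_state(len(cohort)) % (2**31)
    groups: dict[str, list[str]] = {"control": [], "patient": []}
    for (ts, rec), s in zip(cohort, seeds):
        conn = compute_subject_connectome(ts, cfg, seed=int(s))
        write_connectome(conn, conn_dir / f"{rec.subject_id}.txt")
        groups[rec.group].append(rec.subject_id)
        print(f"  {rec.subject_id} ({rec.group}): connectome written")
    (conn_dir / "groups.json").write_text(json.dumps(groups, indent=2))
    print(f"wrote {len(cohort)} z-scored {cohort[0][0].n_nodes}-node connectomes to {conn_dir}")


if __name__ == "__main__":
    main()
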