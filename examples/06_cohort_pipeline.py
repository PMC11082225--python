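"""Run the whole chain on a small synthetic CLL-vs-RS cohort.

simulate_cohort writes FCS tubes plus a manifest; run_pipeline gates every
tube, builds profiles, derives dependencies and compares the groups with a
pooled-variance t test, writing all artifacts (including the loss heatmap)
to an output directory.
"""

import tempfile
from pathlib import Path

from bh3flow import GatingConfig, make_preset, run_pipeline, simulate_cohort

panel = ["PUMA2A", "alamethicin", ("BIM", 10.0), ("BAD", 10.0), ("HRK", 10.0)]
with tempfile.TemporaryDirectory() as tmp:
    manifest = simulate_cohort(
        [(make_preset("CLL"), 3), (make_preset("RS"), 3)],
        panel, n_events=5000, seed=6, out_dir=Path(tmp) / "tubes",
    )
    summary = run_pipeline(manifest, GatingConfig(min_gated_events=2000),
                           out_dir=Path(tmp) / "out")
    print(f"{len(manifest)} tubes gated; groups: "
          + ", ".join(f"{g} (n={len(m)})" for g, m in summary.groups.items()))
    cols = ["reagent", "mean_CLL", "mean_RS", "p", "stars"]
    print(summary.group_stats[cols].round(3).to_string(index=False))
    print("artifacts written:", sorted(p.name for p in (Path(tmp) / "out").iterdir()))
print("Each row compares mean % cyt c loss between the groups; the CLL")
print("preset is more primed and more BCL-2 dependent, so BIM and BAD")
print("separate the groups while HRK (BCL-xL) does not.")
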