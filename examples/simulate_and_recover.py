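"""Full pipeline round trip on a synthetic study-scale bundle.

Simulates the study conditions (32 species, root 74 MYA, 145 query genes
labelled 45 de novo + 100 cancer, 66-MY temperature curve with injected
warm periods), writes the bundle in the same text formats the real pipeline
reads, runs every stage, and summarizes emergence against the warming
record.
"""

import tempfile
from pathlib import Path

import pandas as pd

from paleogene.pipeline import RunConfig, run, simulate_bundle

with tempfile.TemporaryDirectory() as tmp:
    bundle = Path(tmp) / "bundle"
    simulate_bundle(bundle, seed=11)
    config = RunConfig.from_yaml(bundle / "config.yaml",
                                 out_dir=Path(tmp) / "results")
    paths = run(config)

    est = pd.read_csv(paths["estimates"], sep="\t")
    lwps = pd.read_csv(paths["lwps"], sep="\t")
    summary = pd.read_csv(paths["summary"], sep="\t")

print("per-gene emergence categories:")
print(est["category"].value_counts().to_string())
print(f"\nwarming periods detected: {len(lwps)}")
in_lwp = int(summary.query("record == 'lwp_in'")["value"].iloc[0])
out_lwp = int(summary.query("record == 'lwp_out'")["value"].iloc[0])
print(f"dated genes emerging inside LWPs: {in_lwp}, outside: {out_lwp}")
for rec in ("window_0_10", "window_0_13"):
    sub = summary[summary["record"] == rec]
    total = int(sub["value"].sum())
    print(f"{rec.replace('window_0_', 'emerged in recent ')} MY: {total}")

print(
    "\n'dated' genes received an emergence node on the tree; 'pre_root'\n"
    "genes are present in (almost) all species and predate the root;\n"
    "'undetected' genes never passed the 80/80 filter anywhere. The recent-\n"
    "window and LWP tallies are the quantities the association analysis\n"
    "compares between gene sets."
)
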