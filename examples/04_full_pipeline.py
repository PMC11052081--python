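"""Run the whole pipeline end to end and print the run report.

Uses the bundled demo configuration: simulate plate readings and an ASV
table, profile every plate (AWCD, richness, Simpson, Shannon, category
utilization, growth phases), compute Bray-Curtis + ANOSIM on the community
table, and build one co-occurrence network per habitat layer.  All outputs
are plain CSV/TSV under the chosen directory, and manifest.json records
config, seeds, and output hashes so the run can be replayed and verified.
"""

import tempfile
from pathlib import Path

from clpp.pipeline import DEMO_CONFIG, report, run_pipeline

out_dir = Path(tempfile.mkdtemp(prefix="clpp_demo_"))
manifest = run_pipeline(DEMO_CONFIG, out_dir)

print(report(manifest))
print(f"outputs under {out_dir}:")
for stage, info in manifest["stages"].items():
    for name, path in info["outputs"].items():
        print(f"  [{stage}] {name}: {Path(path).name}")
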