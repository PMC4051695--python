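"""Run the whole pipeline end to end and inspect the manifest.

Equivalent to `sarcotrack run --config cfg.yaml`: simulates every input,
then runs morphometry, turnover, qPCR, screen scoring and enrichment,
writing plain-text outputs plus a manifest that records files, parameters
and seeds for reproducibility.
"""

import json
from pathlib import Path

from sarcotrack.pipeline import PipelineConfig, run_pipeline

out = Path("scratch/example_pipeline")
config = PipelineConfig(
    seed=1,
    output_dir=str(out),
    params={"simulate": {"n_profiles": 5, "class_counts": [5, 13, 28, 86]}},
)
manifest = run_pipeline(config)

print(f"wrote {len(manifest['files'])} files to {out}")
with open(out / "screen_summary.json") as fh:
    summary = json.load(fh)
print("screen counts:", summary["counts"])
print(f"reference-line climbing decline: {summary['percent_decline_reference_line']:.1f}%")
print("Re-running with the same seed and config reproduces every output "
      "byte for byte; the manifest records exactly what was run.")
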