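"""Run the whole pipeline with one call and inspect the manifest.

Equivalent to the CLI's `stresspair run-all`; writes every artifact as
plain-text TSV/JSON plus a manifest with SHA-256 checksums so reruns are
verifiably identical.
"""

import json
from pathlib import Path
from tempfile import mkdtemp

from stresspair import RunConfig, run_pipeline

out = Path(mkdtemp(prefix="stresspair_"))
report = run_pipeline(
    RunConfig(output_dir=out, seed=1, null_iterations=2000, bootstrap_replicates=2000)
)

print(f"selected pair: {tuple(report['tsp']['pair'])}")
for name, ev in report["evaluation"].items():
    print(f"{name}: {ev['correct']}/{ev['total']} correct, p = {ev['p_value']:.5f}, "
          f"bootstrap CI [{ev['ci_low']:.3f}, {ev['ci_high']:.3f}]")

manifest = json.loads((out / "manifest.json").read_text())
print(f"\n{len(manifest['artifacts'])} artifacts in {out}:")
for name, entry in manifest["artifacts"].items():
    print(f"  {entry['path']:24s} sha256 {entry['sha256'][:12]}…")
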