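"""One-call demonstration of the full pipeline on a synthetic bundle.

Writes a small input bundle (100 miRNAs, 5 planted positives, 500
perturbation probes, 20 UTRs) to disk, runs every stage from the files, and
prints the manifest counts.  The same run is available from the shell as
``mirmet demo --seed 7``.
"""

import json

from mirmet import demo

out = demo(seed=7, out_dir="mirmet_demo")
manifest = json.loads((out / "manifest.json").read_text())
print("reports in", out)
for stage, count in manifest["stage_counts"].items():
    print(f"  {stage:24s} {count}")
# 'nominated' counts miRNAs that pass the discovery filters, confirm in the
# validation set and are paired-significant; with seed 7 all five planted
# miRNAs are nominated.
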