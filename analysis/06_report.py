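"""Aggregate all stage outputs under results/ into a single report."""

import json
from pathlib import Path

from barlattice.io import save_config, default_config
from barlattice.postprocess import report

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)
save_config(RESULTS / "config.json", default_config())
summary = report(RESULTS)
missing = summary["missing_stages"]
print("report written to results/report.json")
if missing:
    print("stages not yet run:", ", ".join(missing))
if "converged_symmetry" in summary:
    cs = summary["converged_symmetry"]
    print(f"converged symmetry: {cs['rise_A']:.2f} Å / {cs['twist_deg']:.2f}°")
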