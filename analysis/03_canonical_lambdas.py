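#!/usr/bin/env python
"""The headline four-IPM comparison from the published parameter table.

Builds the four origin x treatment kernels with the canonical (published)
vital rates, computes lambda per cell, the range, the intact-vs-autoclaved
percentage increases, eviction diagnostics and stability checks (mesh 50/100/
200, limits widened by 20% of the span), and writes report.json / report.txt.
"""

import json
from pathlib import Path

from lupine_ipm import RunConfig, run_reproduction
from lupine_ipm.pipeline import format_report

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    report = run_reproduction(RunConfig(mode="canonical", out_dir=str(OUT / "canonical")))
    print(format_report(report))
    pct = report["percent_increase_intact_vs_autoclaved"]
    print(
        "Published comparison: range 1.83-4.21 with +130% (invasive) and +30% (native).\n"
        f"Computed from the published table as printed: range "
        f"{report['lambda_min']:.2f}-{report['lambda_max']:.2f} with "
        f"+{pct['invasive_FI']:.0f}% (invasive) and +{pct['native_US']:.0f}% (native).\n"
        "The native-origin effect reproduces; the invasive-origin cells come out\n"
        "~2x higher than printed under every defensible reading of the published\n"
        "equations and constants (see docs/methods.md, 'Relation to the published\n"
        "growth rates')."
    )


if __name__ == "__main__":
    main()
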