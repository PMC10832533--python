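#!/usr/bin/env python
"""One-command demo: the whole pipeline on a fresh synthetic study.

Runs simulate -> quantify -> boundaries -> regulatory elements -> codon
usage -> differential expression and prints the assembled report.
"""

import argparse
import json

from plasmidtx.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--outdir", default="results/pipeline")
    args = ap.parse_args()

    report = run_pipeline(PipelineConfig(seed=args.seed), args.outdir)
    print(json.dumps(report, indent=1, default=str))
    print(f"full report and intermediates -> {args.outdir}/")


if __name__ == "__main__":
    main()
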