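#!/usr/bin/env python
"""Render the human-readable report for the pipeline run of step 02."""
from pathlib import Path

from dfcstates.report import make_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results" / "pipeline"
    if not out.exists():
        raise SystemExit("run analysis/02_run_pipeline.py first")
    path = make_report(out)
    print(f"report written to {path}")


if __name__ == "__main__":
    main()
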