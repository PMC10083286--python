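"""Render the run's figures and the HTML index report.

Produces the span-class count bars, full-length length and repeat-number
distributions, and a waterfall schematic (one colored rectangle per motif
unit, 5' upper-left to 3' lower-right, rare motifs blacked out) of the
highest-repeat full-length subread of each sample.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from cohort_config import RUN  # noqa: E402

from repeatspan.pipeline import stage_report  # noqa: E402


def main() -> None:
    report = stage_report(RUN)
    fig_dir = Path(RUN.outdir) / "figures"
    for p in sorted(fig_dir.glob("*.svg")):
        print(f"wrote {p}")
    print(f"report index: {report}")


if __name__ == "__main__":
    main()
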