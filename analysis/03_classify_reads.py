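"""Classify every read by repeat-tract span and extract its tract.

Prints the per-sample class-count table (forward/reverse full span,
5'/3' partial, non-spanning) and, where truth TSVs exist, the agreement
between predicted and true classes.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort_config import RUN  # noqa: E402

from repeatspan.pipeline import stage_classify  # noqa: E402
from repeatspan.spanclasses import SPAN_CLASSES  # noqa: E402


def main() -> None:
    paths = stage_classify(RUN)
    run_dir = Path(RUN.outdir)
    for sample_id, path in sorted(paths.items()):
        cls = pd.read_csv(path, sep="\t")
        counts = cls.span_class.value_counts()
        parts = ", ".join(f"{c}={counts.get(c, 0)}" for c in SPAN_CLASSES)
        print(f"{sample_id}: {parts}")
        truth_path = run_dir / "truth" / f"{sample_id}.tsv"
        if truth_path.exists():
            truth = pd.read_csv(truth_path, sep="\t")
            merged = cls.merge(truth, on="read_id")
            agree = (merged.span_class == merged.true_class).mean()
            print(f"  agreement with simulator truth: {100 * agree:.1f}%")


if __name__ == "__main__":
    main()
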