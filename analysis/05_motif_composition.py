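"""Decompose full-length tracts into interruption motifs.

Prints, per sample, the motif nucleotide-ratio table pooled over all
full-length subreads, the top motifs overall and within the 5/6/7-nt
groups, and which labels fall under the <1% rarity (blackout) rule.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort_config import RUN  # noqa: E402

from repeatspan.motifs import MotifRatioTable, rare_motif_labels, \
    top_motifs  # noqa: E402
from repeatspan.pipeline import stage_motifs  # noqa: E402


def main() -> None:
    paths = stage_motifs(RUN)
    for sample_id, path in sorted(paths.items()):
        frame = pd.read_csv(path, sep="\t")
        table = MotifRatioTable(dict(zip(frame.label, frame.nucleotides)),
                                scope=sample_id)
        print(f"\n{sample_id}: {table.total_nt} nt pooled over full-length "
              f"subreads")
        pct = table.percentages()
        for label in top_motifs(table, k=5):
            print(f"  {label:10s} {pct[label]:6.2f}%")
        for length in (5, 6, 7):
            grp = table.group(length)
            if grp.nucleotide_counts:
                top = top_motifs(grp, k=3)
                print(f"  top {length}-nt motifs: {', '.join(top)}")
        rare = sorted(rare_motif_labels(table, RUN.rare_threshold_pct))
        print(f"  rare (<{RUN.rare_threshold_pct:g}%, blacked out): "
              f"{', '.join(rare) if rare else 'none'}")


if __name__ == "__main__":
    main()
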