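"""Build the native/expanded ("fake") reference pair.

The expanded reference inserts 1000 core units before the 4 native units so
expansion-spanning reads have a target long enough to align across; the
length identity len(fake) - len(native) = 1000 x 6 bp is printed as a
sanity check.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from cohort_config import RUN  # noqa: E402

from repeatspan.io import read_sequences  # noqa: E402
from repeatspan.pipeline import stage_build_ref  # noqa: E402


def main() -> None:
    paths = stage_build_ref(RUN)
    native = read_sequences(paths["native"])[0][1]
    fake = read_sequences(paths["fake"])[0][1]
    print(f"native reference: {len(native)} bp "
          f"({RUN.n_native} core units)")
    print(f"fake reference:   {len(fake)} bp "
          f"({RUN.n_insert} units inserted before the native tract)")
    print(f"length delta:     {len(fake) - len(native)} bp "
          f"(= {RUN.n_insert} x 6)")


if __name__ == "__main__":
    main()
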