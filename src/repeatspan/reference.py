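"""Native/expanded ("fake") reference pair construction.

Expansion-carrying reads cannot align across a reference that carries only
the short native tract (4 core units at the SCA36 locus).  The standard
workaround is a modified reference in which a long run of core units
(default 1000) is inserted immediately before the native tract, giving
alignment anchoring room for multi-kilobase expanded alleles.  This module
builds that native/fake pair over user-supplied flanks and records both
repeat intervals in 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .catalog import CORE_MOTIF
from .errors import ParameterError
from .io import write_bed, write_fasta
from .sequence import require_dna
from .simulate import validate_flank


@dataclass(frozen=True)
class ReferencePair:
    """Native and expanded references plus their repeat intervals."""

    native: str
    fake: str
    n_native: int
    n_insert: int
    core: str
    native_interval: tuple[int, int]
    fake_interval: tuple[int, int]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write native.fa / fake.fa (interval in the header as
        ``repeat=<start>-<end>``) plus a 3-column BED sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "native": outdir / "native.fa",
            "fake": outdir / "fake.fa",
            "bed": outdir / "repeats.bed",
        }
        ns, ne = self.native_interval
        fs, fe = self.fake_interval
        write_fasta(paths["native"], [(f"native repeat={ns}-{ne}", self.native)])
        write_fasta(paths["fake"], [(f"fake repeat={fs}-{fe}", self.fake)])
        write_bed(paths["bed"], [("native", ns, ne), ("fake", fs, fe)])
        return paths


def build_reference_pair(left_flank: str, right_flank: str,
                         core: str = CORE_MOTIF,
                         n_native: int = 4,
                         n_insert: int = 1000) -> ReferencePair:
    """Build the reference pair: ``n_insert`` core units inserted before the
    ``n_native`` native units, between the same flanks.

    Length identity: ``len(fake) == len(native) + n_insert * len(core)``, and
    the native tract is a suffix of the fake tract.
    """
    require_dna(core, "core motif")
    if n_native < 0:
        raise ParameterError(f"n_native={n_native} must be >= 0")
    if n_insert < 1:
        raise ParameterError(f"n_insert={n_insert} must be >= 1")
    validate_flank(left_flank, core, what="left_flank")
    validate_flank(right_flank, core, what="right_flank")
    native_tract = core * n_native
    fake_tract = core * (n_insert + n_native)
    native = left_flank + native_tract + right_flank
    fake = left_flank + fake_tract + right_flank
    a = len(left_flank)
    return ReferencePair(
        native=native, fake=fake, n_native=n_native, n_insert=n_insert,
        core=core,
        native_interval=(a, a + len(native_tract)),
        fake_interval=(a, a + len(fake_tract)),
    )
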