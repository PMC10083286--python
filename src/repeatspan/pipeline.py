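"""Run configuration and the staged pipeline driver.

Stages communicate through files in the run directory, so any stage can be
re-run from the previous stage's outputs:

``simulate -> build-ref -> classify -> quantify -> motifs -> report``

All stochastic stages draw their seeds deterministically from the single
run seed, and every table writer is deterministic, so a run repeated with
the same configuration produces byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .catalog import DEFAULT_CATALOG, MotifCatalog
from .errors import ConfigError, DataError
from .io import (read_sequences, read_tsv, write_fasta, write_fastq,
                 write_truth_tsv, write_tsv)
from .motifs import motif_ratios, rare_motif_labels, ratio_frame, \
    tokenize_sample, tokens_frame
from .quantify import (ClassifiedTract, count_core_repeats, summaries_frame,
                       summarize_sample)
from .reference import build_reference_pair
from .simulate import DEFAULT_ERROR_MIX, random_flanks, simulate_sample
from .spanclasses import FULL_CLASSES, NON_SPANNING, SPAN_CLASSES
from .spanning import classify_sequences
from .viz import (plot_class_counts, plot_full_length_distributions,
                  render_waterfall, write_html_report)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleConfig:
    sample_id: str
    mean_core: float
    jitter_sd: float = 150.0
    coverage: float | None = None   # overrides RunConfig.coverage


def _default_samples() -> tuple[SampleConfig, ...]:
    # three synthetic carriers emulating the spread of expanded-allele
    # sizes seen across affected individuals (mean core units 600/790/870)
    return (SampleConfig("S1", 600.0),
            SampleConfig("S2", 790.0),
            SampleConfig("S3", 870.0))


@dataclass(frozen=True)
class RunConfig:
    outdir: str = "runs/default"
    seed: int = 1
    samples: tuple[SampleConfig, ...] = field(default_factory=_default_samples)
    interruption_fraction: float = 0.02
    variant_weights: tuple[float, ...] | None = None
    coverage: float = 60.0
    error_rate: float = 0.12
    error_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ERROR_MIX))
    strand_fraction: float = 0.5
    read_length_model: Mapping | None = None
    flank_length: int = 200
    anchor_len: int = 30
    max_edit_fraction: float = 0.25
    min_tract_bp: int = 1
    pathogenic_threshold: int = 650
    rare_threshold_pct: float = 1.0
    count_mode: str = "dp"
    n_native: int = 4
    n_insert: int = 1000
    row_width: int = 50

    @property
    def catalog(self) -> MotifCatalog:
        return DEFAULT_CATALOG

    def sample_seed(self, index: int) -> int:
        return (self.seed * 100003 + 7919 * index + 17) % (2 ** 31)

    @property
    def flank_seed(self) -> int:
        return (self.seed * 31 + 5) % (2 ** 31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["samples"] = [dataclasses.asdict(s) for s in self.samples]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "samples" in d:
            try:
                d["samples"] = tuple(SampleConfig(**s) for s in d["samples"])
            except TypeError as exc:
                raise ConfigError(f"bad sample block: {exc}") from exc
        if "variant_weights" in d and d["variant_weights"] is not None:
            d["variant_weights"] = tuple(float(w) for w in d["variant_weights"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"config root must be a mapping, got "
                              f"{type(data).__name__}")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Stage helpers


def _run_dir(config: RunConfig) -> Path:
    d = Path(config.outdir)
    d.mkdir(parents=True, exist_ok=True)
    return d


def write_manifest(config: RunConfig) -> Path:
    run_dir = _run_dir(config)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "catalog": {"core": config.catalog.core,
                    "variants": list(config.catalog.variants)},
        "sample_seeds": [config.sample_seed(i)
                         for i in range(len(config.samples))],
        "flank_seed": config.flank_seed,
    }
    path = run_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def load_flanks(run_dir: Path) -> tuple[str, str]:
    entries = dict(read_sequences(run_dir / "flanks.fa"))
    try:
        return entries["left_flank"], entries["right_flank"]
    except KeyError as exc:
        raise DataError(f"flanks.fa lacks entry {exc}") from exc


def stage_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate the synthetic cohort: FASTQ reads + truth TSV per sample."""
    run_dir = _run_dir(config)
    left, right = random_flanks(config.flank_length, seed=config.flank_seed,
                                core=config.catalog.core)
    write_fasta(run_dir / "flanks.fa",
                [("left_flank", left), ("right_flank", right)])
    paths: dict[str, Path] = {}
    for i, sc in enumerate(config.samples):
        sample = simulate_sample(
            sc.sample_id, left, right,
            mean_core=sc.mean_core, jitter_sd=sc.jitter_sd,
            interruption_fraction=config.interruption_fraction,
            variant_weights=config.variant_weights,
            coverage=sc.coverage or config.coverage,
            read_length_model=config.read_length_model,
            error_rate=config.error_rate, error_mix=config.error_mix,
            strand_fraction=config.strand_fraction,
            seed=config.sample_seed(i), catalog=config.catalog,
            anchor_len=config.anchor_len,
            max_edit_fraction=config.max_edit_fraction,
            min_tract_bp=config.min_tract_bp)
        fq = run_dir / "reads" / f"{sc.sample_id}.fastq"
        write_fastq(fq, sample.reads)
        write_truth_tsv(run_dir / "truth" / f"{sc.sample_id}.tsv",
                        sample.reads)
        paths[sc.sample_id] = fq
        logger.info("simulated %s: %d reads", sc.sample_id, len(sample.reads))
    return paths


def stage_build_ref(config: RunConfig) -> dict[str, Path]:
    """Native/expanded reference pair over the run's flanks."""
    run_dir = _run_dir(config)
    left, right = load_flanks(run_dir)
    pair = build_reference_pair(left, right, core=config.catalog.core,
                                n_native=config.n_native,
                                n_insert=config.n_insert)
    return pair.write(run_dir / "reference")


def _sample_ids(run_dir: Path) -> list[str]:
    reads_dir = run_dir / "reads"
    if not reads_dir.is_dir():
        raise DataError(f"no reads directory at {reads_dir}")
    ids = sorted(p.stem for p in reads_dir.glob("*.fastq"))
    if not ids:
        raise DataError(f"no FASTQ files under {reads_dir}")
    return ids


def stage_classify(config: RunConfig) -> dict[str, Path]:
    """Anchor-classify each sample's reads; write class TSV + tract FASTA."""
    run_dir = _run_dir(config)
    left, right = load_flanks(run_dir)
    paths: dict[str, Path] = {}
    for sample_id in _sample_ids(run_dir):
        reads = read_sequences(run_dir / "reads" / f"{sample_id}.fastq")
        classified = classify_sequences(
            reads, left, right, anchor_len=config.anchor_len,
            max_edit_fraction=config.max_edit_fraction,
            min_tract_bp=config.min_tract_bp)
        rows = []
        tract_entries = []
        for c in classified:
            anchors = {f"{h.which}_{k}": v for h in c.anchors
                       if h.strand == (c.strand or "+")
                       for k, v in (("start", h.read_start),
                                    ("end", h.read_end),
                                    ("edits", h.edit_distance))}
            rows.append({
                "read_id": c.read_id, "span_class": c.span_class,
                "strand": c.strand or "",
                "tract_length": len(c.tract) if c.tract is not None else "",
                "left_start": anchors.get("left_start", ""),
                "left_end": anchors.get("left_end", ""),
                "left_edits": anchors.get("left_edits", ""),
                "right_start": anchors.get("right_start", ""),
                "right_end": anchors.get("right_end", ""),
                "right_edits": anchors.get("right_edits", ""),
            })
            if c.tract:
                tract_entries.append((f"{c.read_id} class={c.span_class}",
                                      c.tract))
        out = run_dir / "classify" / f"{sample_id}.tsv"
        write_tsv(out, pd.DataFrame(rows))
        write_fasta(run_dir / "tracts" / f"{sample_id}.fa", tract_entries)
        paths[sample_id] = out
    return paths


def _load_classified_tracts(run_dir: Path, sample_id: str
                            ) -> tuple[pd.DataFrame, dict[str, str]]:
    cls = read_tsv(run_dir / "classify" / f"{sample_id}.tsv")
    tract_path = run_dir / "tracts" / f"{sample_id}.fa"
    tracts = dict(read_sequences(tract_path)) if tract_path.exists() else {}
    return cls, tracts


def stage_quantify(config: RunConfig) -> Path:
    """Per-read core counts and the per-sample summary table."""
    run_dir = _run_dir(config)
    summaries = []
    per_read_rows = []
    for sample_id in _sample_ids(run_dir):
        cls, tracts = _load_classified_tracts(run_dir, sample_id)
        records = []
        for row in cls.itertuples():
            if row.span_class == NON_SPANNING:
                continue
            tract = tracts.get(row.read_id, "")
            count = count_core_repeats(tract, config.catalog.core,
                                       config.catalog,
                                       mode=config.count_mode)
            records.append(ClassifiedTract(
                read_id=row.read_id, span_class=row.span_class,
                tract_length_bp=len(tract), core_count=count))
            per_read_rows.append({
                "sample_id": sample_id, "read_id": row.read_id,
                "span_class": row.span_class, "tract_length_bp": len(tract),
                "core_count": count,
                "pathogenic": count > config.pathogenic_threshold})
        summaries.append(summarize_sample(records, sample_id,
                                          config.pathogenic_threshold))
    frame = summaries_frame(summaries)
    write_tsv(run_dir / "quantify" / "summary.tsv", frame)
    write_tsv(run_dir / "quantify" / "per_read.tsv",
              pd.DataFrame(per_read_rows))
    (run_dir / "quantify" / "summary.json").write_text(
        json.dumps([dataclasses.asdict(s) for s in summaries], indent=2,
                   sort_keys=True) + "\n")
    return run_dir / "quantify" / "summary.tsv"


def stage_motifs(config: RunConfig) -> dict[str, Path]:
    """Tokenize full-length tracts; write ratio and token tables."""
    run_dir = _run_dir(config)
    paths: dict[str, Path] = {}
    for sample_id in _sample_ids(run_dir):
        cls, tracts = _load_classified_tracts(run_dir, sample_id)
        full = cls[cls.span_class.isin(FULL_CLASSES)]
        read_ids = [r for r in full.read_id if tracts.get(r)]
        seqs = [tracts[r] for r in read_ids]
        tokenized, promoted = tokenize_sample(seqs, config.catalog)
        pooled = motif_ratios(tokenized, scope="pooled")
        rare = rare_motif_labels(pooled, config.rare_threshold_pct)
        rframe = ratio_frame(pooled)
        rframe.insert(0, "sample_id", sample_id)
        rframe["rare"] = rframe["label"].isin(rare)
        p = run_dir / "motifs" / f"{sample_id}_ratios.tsv"
        write_tsv(p, rframe)
        write_tsv(run_dir / "motifs" / f"{sample_id}_tokens.tsv",
                  tokens_frame(tokenized, read_ids))
        if promoted:
            logger.info("sample %s: promoted de-novo motifs %s", sample_id,
                        ",".join(promoted))
        paths[sample_id] = p
    return paths


def stage_report(config: RunConfig) -> Path:
    """Figures (class counts, distributions, waterfalls) + HTML index."""
    run_dir = _run_dir(config)
    fig_dir = run_dir / "figures"
    per_read = read_tsv(run_dir / "quantify" / "per_read.tsv")
    class_counts: dict[str, dict[str, int]] = {}
    for sample_id in _sample_ids(run_dir):
        cls, _ = _load_classified_tracts(run_dir, sample_id)
        counts = cls.span_class.value_counts().to_dict()
        class_counts[sample_id] = {c: int(counts.get(c, 0))
                                   for c in SPAN_CLASSES}
    figures = [plot_class_counts(class_counts, fig_dir / "class_counts.svg")]
    full = per_read[per_read.span_class.isin(FULL_CLASSES)]
    if len(full):
        figures.extend(plot_full_length_distributions(full, fig_dir).values())
    # waterfall of the highest-repeat full-length subread per sample
    for sample_id in _sample_ids(run_dir):
        sub = full[full.sample_id == sample_id]
        if not len(sub):
            continue
        top = sub.sort_values(["core_count", "read_id"],
                              ascending=[False, True]).iloc[0]
        _, tracts = _load_classified_tracts(run_dir, sample_id)
        seqs = [tracts[top.read_id]]
        tokenized, promoted = tokenize_sample(seqs, config.catalog)
        pooled_frame = read_tsv(run_dir / "motifs" / f"{sample_id}_ratios.tsv")
        rare = set(pooled_frame[pooled_frame.rare].label)
        svg = render_waterfall(tokenized[0], config.catalog, rare_labels=rare,
                               row_width=config.row_width,
                               title=f"{sample_id} {top.read_id} "
                                     f"({top.core_count} core units)")
        path = fig_dir / f"waterfall_{sample_id}.svg"
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(svg)
        figures.append(path)
    tables = sorted((run_dir / "quantify").glob("*.tsv")) + \
        sorted((run_dir / "motifs").glob("*.tsv"))
    return write_html_report(run_dir, {"Tables": tables, "Figures": figures})


STAGES = ("simulate", "build-ref", "classify", "quantify", "motifs", "report")


def run_pipeline(config: RunConfig, skip_simulate: bool = False) -> Path:
    """Execute the full pipeline; returns the run directory."""
    run_dir = _run_dir(config)
    write_manifest(config)
    if not skip_simulate:
        stage_simulate(config)
    stage_build_ref(config)
    stage_classify(config)
    stage_quantify(config)
    stage_motifs(config)
    stage_report(config)
    return run_dir
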