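"""Waterfall motif schematics and distribution plots.

The waterfall renders one rectangle per motif token, row-wrapped at
``row_width`` units, reading 5' (upper left) to 3' (lower right).  Motifs
whose pooled nucleotide share is below the rarity threshold are blacked
out.  SVG is assembled by hand so re-rendering identical inputs yields
byte-identical text.

Distribution plots (class-count bars, full-length tract length and repeat
number histograms) go through matplotlib with a fixed hash salt and no
date metadata, so they are also deterministic functions of their inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .catalog import DEFAULT_CATALOG, MotifCatalog
from .motifs import TokenizedTract
from .spanclasses import SPAN_CLASSES

logger = logging.getLogger(__name__)

plt.rcParams["svg.hashsalt"] = "repeatspan"

RARE_COLOR = "#000000"


def render_waterfall(tokenized: TokenizedTract,
                     catalog: MotifCatalog = DEFAULT_CATALOG,
                     rare_labels: Iterable[str] = (),
                     row_width: int = 50,
                     cell_w: int = 9, cell_h: int = 12,
                     pad: int = 2, title: str | None = None) -> str:
    """SVG schematic of one tract: one rectangle per token, row-major."""
    rare = set(rare_labels)
    tokens = tokenized.tokens
    if not tokens:
        logger.warning("empty tract: rendering empty waterfall canvas")
        return ('<svg xmlns="http://www.w3.org/2000/svg" width="10" '
                'height="10"></svg>')
    n_rows = (len(tokens) + row_width - 1) // row_width
    top = 18 if title else 2
    width = pad * 2 + min(len(tokens), row_width) * cell_w
    height = top + pad + n_rows * cell_h
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
             f'height="{height}">']
    if title:
        parts.append(f'<text x="{pad}" y="13" font-size="11" '
                     f'font-family="sans-serif">{title}</text>')
    for i, tok in enumerate(tokens):
        row, col = divmod(i, row_width)
        color = RARE_COLOR if tok.label in rare else catalog.color_for(tok.label)
        x = pad + col * cell_w
        y = top + pad + row * cell_h
        parts.append(f'<rect x="{x}" y="{y}" width="{cell_w - 1}" '
                     f'height="{cell_h - 1}" fill="{color}">'
                     f'<title>{tok.label} [{tok.start},{tok.end})</title>'
                     f'</rect>')
    parts.append("</svg>")
    return "\n".join(parts)


def _savefig(fig, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
    return path


def plot_class_counts(class_counts: Mapping[str, Mapping[str, int]],
                      path: str | Path) -> Path:
    """Grouped bars of span-class counts per sample."""
    samples = list(class_counts)
    fig, ax = plt.subplots(figsize=(7, 4))
    width = 0.8 / max(1, len(samples))
    for si, sample in enumerate(samples):
        counts = [class_counts[sample].get(c, 0) for c in SPAN_CLASSES]
        xs = [i + si * width for i in range(len(SPAN_CLASSES))]
        ax.bar(xs, counts, width=width, label=sample)
    ax.set_xticks([i + 0.4 - width / 2 for i in range(len(SPAN_CLASSES))])
    ax.set_xticklabels(SPAN_CLASSES, rotation=20, ha="right", fontsize=8)
    ax.set_ylabel("subreads")
    ax.set_title("Spanning-read classification")
    ax.legend()
    fig.tight_layout()
    return _savefig(fig, Path(path))


def plot_full_length_distributions(per_read: pd.DataFrame,
                                   outdir: str | Path,
                                   ) -> dict[str, Path]:
    """Histograms of full-length tract length (bp) and repeat number.

    ``per_read`` needs columns sample_id, tract_length_bp, core_count.
    """
    outdir = Path(outdir)
    paths: dict[str, Path] = {}
    for column, fname, xlabel in (
            ("tract_length_bp", "full_length_lengths.svg", "tract length (bp)"),
            ("core_count", "full_length_repeats.svg", "core repeat number")):
        fig, ax = plt.subplots(figsize=(7, 4))
        for sample, grp in per_read.groupby("sample_id"):
            ax.hist(grp[column], bins=20, alpha=0.5, label=str(sample))
        ax.set_xlabel(xlabel)
        ax.set_ylabel("full-length subreads")
        ax.legend()
        fig.tight_layout()
        paths[column] = _savefig(fig, outdir / fname)
    return paths


def write_html_report(run_dir: str | Path,
                      sections: Mapping[str, Sequence[Path]]) -> Path:
    """Minimal index page linking the run's tables and figures."""
    run_dir = Path(run_dir)
    lines = ["<html><head><title>repeatspan run</title></head><body>",
             "<h1>repeatspan run report</h1>"]
    for heading, paths in sections.items():
        lines.append(f"<h2>{heading}</h2><ul>")
        for p in paths:
            rel = Path(p).relative_to(run_dir)
            lines.append(f'<li><a href="{rel}">{rel}</a></li>')
        lines.append("</ul>")
    lines.append("</body></html>")
    out = run_dir / "report.html"
    out.write_text("\n".join(lines))
    return out
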