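"""Circular repeat-map rendering (SVG) and the end-to-end pipeline driver.

The repeat map draws the circular genome with its feature arcs and one chord
per repeat above a length cutoff; chord thickness is linear in repeat length
and DR/IR are distinguished by color (orange/red). Output is plain SVG text,
deterministic for identical input, so maps can be diffed and asserted on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .comparative import clade_report, log_transform
from .genome_io import MitoGenome, gene_region_union, write_repeat_table, write_species_table
from .repeat_scan import RepeatSet, ScanParams, find_repeats, scan_gene_regions
from .scoring import ScoreParams, profile
from .synthetic import PanelSpec, synthesize_panel

logger = logging.getLogger("mitorepeats")

_FEATURE_COLORS = {
    "gene": "#4daf4a", "CDS": "#377eb8", "tRNA": "#984ea3",
    "rRNA": "#a65628", "D-loop": "#999999", "other": "#dddddd",
}
_KIND_COLORS = {"DR": "#ff7f00", "IR": "#e41a1c"}


def _angle(pos: int, L: int) -> float:
    return 2.0 * math.pi * (pos - 1) / L - math.pi / 2.0


def _xy(pos: int, L: int, r: float, cx: float = 300.0, cy: float = 300.0) -> tuple[float, float]:
    a = _angle(pos, L)
    return cx + r * math.cos(a), cy + r * math.sin(a)


def chord_width(length: int, min_length: int, per_bp: float = 0.35) -> float:
    """Stroke width linear in repeat length; the cutoff length is thinnest."""
    return per_bp * (length - min_length + 1)


def render_repeat_map(genome: MitoGenome, repeats: RepeatSet | list, min_length: int = 11,
                      path: str | Path | None = None) -> str:
    """Render a circular repeat map as SVG text (optionally written to ``path``).

    Features are drawn as arcs on the genome circle; every repeat with
    ``length >= min_length`` becomes a chord between its two arm midpoints,
    with stroke width growing linearly with repeat length.
    """
    L = genome.length
    reps = sorted(repeats, key=lambda r: (r.kind, r.arm1_start, r.arm2_start, r.length))
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<svg xmlns="http://www.w3.org/2000/svg" width="600" height="600" viewBox="0 0 600 600">',
        f'<title>{genome.accession or "genome"} repeat map</title>',
        '<circle cx="300" cy="300" r="250" fill="none" stroke="#333333" stroke-width="1.5"/>',
    ]
    for f in genome.features:
        color = _FEATURE_COLORS.get(f.kind, "#dddddd")
        end = f.end if f.end >= f.start else f.end + L
        x1, y1 = _xy(f.start, L, 258.0)
        x2, y2 = _xy(end, L, 258.0)
        span = end - f.start + 1
        large = 1 if span > L / 2 else 0
        out.append(
            f'<path d="M {x1:.2f} {y1:.2f} A 258 258 0 {large} 1 {x2:.2f} {y2:.2f}" '
            f'fill="none" stroke="{color}" stroke-width="6"><title>{f.name}</title></path>'
        )
    for r in reps:
        if r.length < min_length:
            continue
        mid1 = (r.arm1_start - 1 + (r.length - 1) // 2) % L + 1
        mid2 = (r.arm2_start - 1 + (r.length - 1) // 2) % L + 1
        x1, y1 = _xy(mid1, L, 250.0)
        x2, y2 = _xy(mid2, L, 250.0)
        w = chord_width(r.length, min_length)
        color = _KIND_COLORS.get(r.kind, "#000000")
        out.append(
            f'<line x1="{x1:.2f}" y1="{y1:.2f}" x2="{x2:.2f}" y2="{y2:.2f}" '
            f'stroke="{color}" stroke-width="{w:.2f}" stroke-opacity="0.6"/>'
        )
    out.append("</svg>")
    svg = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(svg, encoding="utf-8")
    return svg


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (logged for reproducibility)."""

    outdir: str = "mitorepeats_out"
    seed: int = 0
    preset: str = "default"
    min_length: int = 2
    kinds: tuple[str, ...] = ("DR", "IR")
    clades: tuple[str, ...] = ("Root",)
    panel: PanelSpec = field(default_factory=PanelSpec)


def pipeline_run(config: RunConfig) -> dict[str, str]:
    """Synthetic end-to-end run: simulate panel, scan, score, correlate.

    Chains genome generation, repeat scanning (gene-region filtered),
    mutagenic scoring, and the clade-level comparative analysis, keeping the
    intermediate TSVs. Returns a mapping of artifact names to paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("mitorepeats %s pipeline run: %s", __version__, config)
    params = (ScanParams.relaxed() if config.preset == "relaxed"
              else ScanParams.default())
    if config.min_length != params.min_length:
        params = ScanParams(min_length=config.min_length, stringency=params.stringency)
    try:
        spec = PanelSpec(**{**config.panel.__dict__, "seed": config.seed})
        syn = synthesize_panel(spec)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'simulate': {err}") from err

    records = []
    try:
        for rec in syn.panel.records:
            genome = syn.genomes[rec.species]
            regions = gene_region_union(genome)
            totals = {}
            for kind in config.kinds:
                rs = find_repeats(genome, kind, params)
                filtered = scan_gene_regions(rs, regions)
                prof = profile(rs, filtered, ScoreParams())
                totals[kind] = prof.total_excl_dloop
                write_repeat_table(filtered, outdir / f"{rec.species}.{kind.lower()}.tsv")
            records.append(rec.__class__(
                species=rec.species, mls_years=rec.mls_years, lineage=rec.lineage,
                dr_total=totals.get("DR", rec.dr_total),
                ir_total=totals.get("IR", rec.ir_total),
            ))
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'scan/score': {err}") from err

    species_path = outdir / "species_scores.tsv"
    write_species_table(records, species_path)
    try:
        panel = log_transform(syn.panel.__class__(records=records))
        table = clade_report(panel, list(config.clades),
                             kinds=tuple(k.lower() for k in config.kinds), seed=config.seed)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'correlate': {err}") from err
    corr_path = outdir / "correlations.tsv"
    table.to_csv(corr_path, sep="\t", index=False)
    logger.info("pipeline finished: %d species, artifacts in %s", len(records), outdir)
    return {"species_scores": str(species_path), "correlations": str(corr_path)}
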