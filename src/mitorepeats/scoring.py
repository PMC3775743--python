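"""Mutagenic scoring of repeat sets.

Each repeat with ``i`` identical matches in an ``l`` bp arm alignment gets
the weight ``(i^2 / (25 * l)) ** 6``. The normalization constant 25 bp is
roughly the longest near-perfect repeat length seen in mammalian mtDNA, so a
perfect 25-bp repeat scores 1; the exponent 6 comes from the empirical
power-law between direct-repeat length and deletion rate in yeast
mitochondria (recoverable here via :func:`fit_power_exponent`). Summing the
weights over all repeats of a genome gives a single mutagenic score; the
headline comparative statistic excludes the D-loop by using only repeats
whose arms both lie in gene regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .repeat_scan import Repeat, RepeatSet


@dataclass(frozen=True)
class ScoreParams:
    """Normalization length (bp) and exponent of the per-repeat weight."""

    normalization_length: float = 25.0
    exponent: float = 6.0

    def __post_init__(self) -> None:
        if self.normalization_length <= 0:
            raise ValueError("normalization_length must be positive")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")


@dataclass
class MutagenicProfile:
    """Per-genome mutagenic score totals and per-length / per-matches spectra."""

    accession: str
    total: float
    total_excl_dloop: float
    by_length: dict[int, float] = field(default_factory=dict)
    by_matches: dict[int, float] = field(default_factory=dict)
    by_length_excl_dloop: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class PowerFit:
    exponent: float
    scale: float
    weights: tuple[float, ...]


def repeat_score(i: int, l: int, params: ScoreParams | None = None) -> float:
    """Mutagenic weight (i^2/(25*l))^6 of a repeat with i matches in l bp."""
    params = params or ScoreParams()
    if i < 1 or i > l:
        raise ValueError(f"matches i={i} must satisfy 1 <= i <= l={l}")
    return (i * i / (params.normalization_length * l)) ** params.exponent


def _spectrum(repeats, params: ScoreParams):
    by_length: dict[int, float] = {}
    by_matches: dict[int, float] = {}
    total = 0.0
    for r in repeats:
        sc = repeat_score(r.matches, r.length, params)
        total += sc
        by_length[r.length] = by_length.get(r.length, 0.0) + sc
        by_matches[r.matches] = by_matches.get(r.matches, 0.0) + sc
    return total, by_length, by_matches


def profile(repeats: RepeatSet, gene_filtered: RepeatSet | None = None,
            params: ScoreParams | None = None) -> MutagenicProfile:
    """Totals and spectra for a genome; additive over disjoint repeat sets.

    ``repeats`` covers all regions; ``gene_filtered`` is the same scan
    restricted to the gene-region union (D-loop excluded). When omitted, the
    D-loop-excluded total falls back to the all-regions total.
    """
    params = params or ScoreParams()
    if gene_filtered is not None and gene_filtered.accession != repeats.accession:
        raise ValueError(
            f"repeat sets come from different genomes: {repeats.accession!r} vs {gene_filtered.accession!r}")
    total, by_length, by_matches = _spectrum(repeats, params)
    if gene_filtered is None:
        excl, by_length_excl = total, dict(by_length)
    else:
        excl, by_length_excl, _ = _spectrum(gene_filtered, params)
    return MutagenicProfile(
        accession=repeats.accession, total=total, total_excl_dloop=excl,
        by_length=by_length, by_matches=by_matches,
        by_length_excl_dloop=by_length_excl,
    )


def subsample_to_reference_length(repeats: RepeatSet, ref_matches: int = 12,
                                  base: float = 3.0, seed: int = 0) -> RepeatSet:
    """Randomly discard short repeats down to the abundance of the reference class.

    A repeat with ``i`` identical matches is kept with probability
    ``base ** (i - ref_matches)``, clamped into [0, 1], so classes shorter
    than the reference end up with roughly equal expected counts (the base 3
    rather than 4 accounts for the quarter of shorter repeats hidden inside
    longer ones and never counted separately).
    """
    if base <= 1:
        raise ValueError("base must be > 1")
    rng = np.random.default_rng(seed)
    kept = []
    for r in repeats:
        p = min(1.0, base ** (r.matches - ref_matches))
        if rng.random() < p:
            kept.append(r)
    from .repeat_scan import replace_repeats

    return replace_repeats(repeats, kept)


def spacer_stratified_scores(repeats: RepeatSet, bin_edges: Sequence[float],
                             params: ScoreParams | None = None) -> dict[tuple[float, float], float]:
    """Sum per-repeat scores into bins of circular spacer distance.

    Bins are ``[e_k, e_{k+1})`` with the last bin closed; every repeat's
    spacer must fall inside the binned range so that the bin totals conserve
    the profile total.
    """
    params = params or ScoreParams()
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing with >= 2 entries")
    out = {(a, b): 0.0 for a, b in zip(edges, edges[1:])}
    keys = list(out)
    for r in repeats:
        sc = repeat_score(r.matches, r.length, params)
        if r.spacer < edges[0] or r.spacer > edges[-1]:
            raise ValueError(f"spacer {r.spacer} outside bin range [{edges[0]}, {edges[-1]}]")
        idx = min(int(np.searchsorted(edges, r.spacer, side="right")) - 1, len(keys) - 1)
        out[keys[idx]] += sc
    return out


def positional_scores(repeats: RepeatSet, genome, window: int = 500,
                      origin_feature: str = "tRNA-Phe",
                      params: ScoreParams | None = None) -> dict[int, float]:
    """Window -> summed score, with coordinates re-based to an origin feature.

    Coordinates are shifted so the origin feature (tRNA-Phe by convention,
    making positions comparable across mammals) starts at position 1. Each
    arm contributes half the repeat's score to the window containing its
    midpoint. Windows are numbered from 1.
    """
    params = params or ScoreParams()
    origin = None
    for f in genome.features:
        if origin_feature.lower() in f.name.lower():
            origin = f.start
            break
    if origin is None:
        raise ValueError(f"origin feature {origin_feature!r} not found in annotation")
    L = genome.length
    out: dict[int, float] = {}
    for r in repeats:
        sc = repeat_score(r.matches, r.length, params)
        for arm_start in (r.arm1_start, r.arm2_start):
            mid0 = (arm_start - 1 + (r.length - 1) // 2) % L
            rebased = (mid0 - (origin - 1)) % L + 1
            w = (rebased - 1) // window + 1
            out[w] = out.get(w, 0.0) + sc / 2.0
    return out


def fit_power_exponent(lengths: Sequence[float], rates: Sequence[float],
                       weights: Sequence[float] | None = None) -> PowerFit:
    """Weighted least-squares fit of rate = c * l**n in log-log space.

    Default weights are 1/l, emphasizing the short repeats for which the
    underlying deletion-rate data are most reliable.
    """
    lengths = np.asarray(lengths, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if lengths.size < 3:
        raise ValueError("need at least 3 points for a power fit")
    if (rates <= 0).any() or (lengths <= 0).any():
        raise ValueError("lengths and rates must be positive")
    if weights is None:
        w = 1.0 / lengths
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != lengths.shape or (w < 0).any() or not (w > 0).sum() >= 2:
            raise ValueError("weights must be non-negative with >= 2 positive entries")
    slope, intercept = np.polyfit(np.log(lengths), np.log(rates), 1, w=np.sqrt(w))
    return PowerFit(exponent=float(slope), scale=float(math.exp(intercept)),
                    weights=tuple(w.tolist()))


def score_vs_deletion_table(profile_by_length: Mapping[int, float],
                            deletions: Mapping[int, int]) -> tuple[pd.DataFrame, float, float]:
    """Align per-length scores with observed deletion counts and correlate.

    Returns the aligned table plus Pearson r and its two-tailed p-value over
    the lengths present in both inputs.
    """
    common = sorted(set(profile_by_length) & set(deletions))
    if not common:
        raise ValueError("no overlapping repeat lengths between score and deletion tables")
    df = pd.DataFrame({
        "length": common,
        "score": [profile_by_length[l] for l in common],
        "deletions": [deletions[l] for l in common],
    })
    if len(common) < 3:
        return df, float("nan"), float("nan")
    r, p = stats.pearsonr(df["score"], df["deletions"])
    return df, float(r), float(p)


def write_profile_table(prof: MutagenicProfile, path) -> None:
    """TSV spectrum (length, matches column key, score_sum) of a profile."""
    rows = [{"key": "length", "value": k, "score_sum": v} for k, v in sorted(prof.by_length.items())]
    rows += [{"key": "matches", "value": k, "score_sum": v} for k, v in sorted(prof.by_matches.items())]
    pd.DataFrame(rows, columns=["key", "value", "score_sum"]).to_csv(path, sep="\t", index=False)
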