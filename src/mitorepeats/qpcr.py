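"""qPCR quantification arithmetic for mtDNA inversions.

Covers the dilution-series estimate of per-cycle amplification efficiency
(f = 2**(1/slope), slope in cycles per two-fold concentration change), the
relative concentration of an inversion against total mtDNA, the nested
LR-PCR/qPCR delta-Ct comparison of two-primer (B), single-primer (S) and
no-primer (N) groups that separates replication-origin head-to-head dimers
from recombination-origin simple inversions, and the extrapolation of a
single measured inversion frequency to a genome-wide inversion burden via
the mutagenic-score ratio.

Inputs are final instrument Ct values; thresholding, baseline correction
and passive-reference normalization are upstream instrument concerns.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mitorepeats")


@dataclass(frozen=True)
class DilutionSeries:
    """Relative concentrations (fold factors, strictly decreasing) with Ct values."""

    concentrations: tuple[float, ...]
    cts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.concentrations) < 3:
            raise ValueError("need at least 3 dilution points")
        if len(self.concentrations) != len(self.cts):
            raise ValueError("concentrations and Ct values differ in length")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if any(b >= a for a, b in zip(self.concentrations, self.concentrations[1:])):
            raise ValueError("concentrations must be strictly decreasing")


@dataclass(frozen=True)
class Efficiency:
    """slope: cycles per 2-fold concentration change; f = 2**(1/slope) per cycle."""

    slope: float
    f: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not (1 < self.f <= 2 or self.slope < 1):
            raise ValueError("per-cycle efficiency f must lie in (1, 2] for slope >= 1")


@dataclass(frozen=True)
class NestedExperiment:
    """Per-reaction median Ct values of the three LR-PCR groups and the efficiency."""

    ct_b: tuple[float, ...]  # two-primer reactions
    ct_s: tuple[float, ...]  # single-primer reactions
    ct_n: tuple[float, ...]  # no-primer controls
    efficiency: Efficiency

    def __post_init__(self) -> None:
        if not self.ct_b or not self.ct_s or not self.ct_n:
            raise ValueError("all three reaction groups must be non-empty")


@dataclass(frozen=True)
class ReplicationFraction:
    delta_ct: float
    s_delta_ct: float
    m: float  # upper 95% bound of delta Ct
    mean_fraction: float
    min_fraction: float


def amplification_efficiency(series: DilutionSeries) -> Efficiency:
    """Efficiency from a dilution series: slope of Ct on log2 relative concentration.

    The slope is sign-normalized to cycles per two-fold change; a
    non-monotone Ct trend only logs a warning (noise on a shallow series).
    """
    logc = np.log2(np.asarray(series.concentrations, dtype=float))
    cts = np.asarray(series.cts, dtype=float)
    if np.ptp(logc) == 0:
        raise ValueError("zero variance in concentrations")
    if not (np.diff(cts) >= 0).all():
        logger.warning("dilution series Ct values are not monotone in dilution")
    slope = float(np.polyfit(logc, cts, 1)[0])
    slope = abs(slope)
    if slope == 0:
        raise ValueError("flat dilution series: cannot estimate efficiency")
    return Efficiency(slope=slope, f=2.0 ** (1.0 / slope))


def relative_concentration(f_m: Efficiency, ct_m: float, f_i: Efficiency, ct_i: float,
                           dilution: float = 20.0) -> float:
    """Relative concentration c = f_m**Ctm / (dilution * f_i**Cti).

    ``f_m``/``ct_m`` quantify total mtDNA measured on a ``dilution``-fold
    diluted template; ``f_i``/``ct_i`` quantify the inversion.
    """
    if dilution <= 0:
        raise ValueError("dilution factor must be positive")
    return (f_m.f ** ct_m) / (dilution * (f_i.f ** ct_i))


def replicate_median_ct(replicates: Sequence[float]) -> float:
    """Median Ct of one reaction's qPCR replicates (even counts average the middle two)."""
    if len(replicates) == 0:
        raise ValueError("no replicates")
    return float(statistics.median(replicates))


def replication_fraction(exp: NestedExperiment, confidence: float = 0.95,
                         use_t: bool = False) -> ReplicationFraction:
    """Fraction of inversions explained by replication (head-to-head dimers).

    delta_Ct = mean Ct(S) - mean Ct(B); its standard error combines the two
    group variances, s = (s_S^2/n_S + s_B^2/n_B)**0.5. The upper confidence
    bound m is the normal quantile (a t quantile with Welch-style pooled df
    when ``use_t``), and the mean / minimum replication fractions are
    f**(-delta_Ct) and f**(-m).
    """
    b = np.asarray(exp.ct_b, dtype=float)
    s = np.asarray(exp.ct_s, dtype=float)
    n_ctrl = np.asarray(exp.ct_n, dtype=float)
    mb, ms = float(b.mean()), float(s.mean())
    if n_ctrl.mean() <= max(mb, ms):
        logger.warning("no-primer control Ct (%.2f) does not exceed both group means", n_ctrl.mean())
    delta = ms - mb
    var_b = float(b.var(ddof=1)) if b.size > 1 else 0.0
    var_s = float(s.var(ddof=1)) if s.size > 1 else 0.0
    s_delta = (var_s / s.size + var_b / b.size) ** 0.5
    if s_delta > 0:
        if use_t:
            df = b.size + s.size - 2
            m = delta + float(stats.t.ppf(confidence, df)) * s_delta
        else:
            m = float(stats.norm.ppf(confidence, loc=delta, scale=s_delta))
    else:
        m = delta
    f = exp.efficiency.f
    return ReplicationFraction(
        delta_ct=delta, s_delta_ct=s_delta, m=m,
        mean_fraction=f ** (-delta), min_fraction=f ** (-m),
    )


def genomewide_inversion_burden(copies_per_event: float, event_repeat_score: float,
                                total_score: float) -> float:
    """mtDNA genomes per inversion, genome-wide.

    A single inversion observed once per ``copies_per_event`` genomes, caused
    by a repeat of mutagenic score ``event_repeat_score``, extrapolates to
    one inversion (of any kind) per
    ``copies_per_event * event_repeat_score / total_score`` genomes when the
    whole genome carries ``total_score`` worth of repeats.
    """
    if copies_per_event <= 0 or event_repeat_score <= 0 or total_score <= 0:
        raise ValueError("all inputs must be positive")
    if event_repeat_score > total_score:
        raise ValueError("a single repeat's score cannot exceed the genome total")
    return copies_per_event * event_repeat_score / total_score


# ---------------------------------------------------------------------------
# Plate I/O
# ---------------------------------------------------------------------------

def read_plate_table(path) -> pd.DataFrame:
    """TSV with columns reaction_group (B/S/N), reaction_id, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"reaction_group", "reaction_id", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table {path} is missing columns {sorted(missing)}")
    return df


def nested_experiment_from_plate(df: pd.DataFrame, efficiency: Efficiency) -> NestedExperiment:
    """Collapse a plate table to per-reaction median Cts grouped as B/S/N."""
    groups: dict[str, list[float]] = {"B": [], "S": [], "N": []}
    for (grp, _rid), sub in df.groupby(["reaction_group", "reaction_id"], sort=True):
        if grp not in groups:
            raise ValueError(f"unknown reaction group {grp!r} (expected B, S or N)")
        groups[grp].append(replicate_median_ct(sub["ct"].tolist()))
    return NestedExperiment(
        ct_b=tuple(groups["B"]), ct_s=tuple(groups["S"]), ct_n=tuple(groups["N"]),
        efficiency=efficiency,
    )


def dilution_series_from_table(df: pd.DataFrame | Mapping) -> DilutionSeries:
    """Build a dilution series from a table with rel_conc and ct columns.

    Replicates at the same concentration are averaged.
    """
    frame = pd.DataFrame(df)
    if not {"rel_conc", "ct"} <= set(frame.columns):
        raise ValueError("dilution table needs rel_conc and ct columns")
    agg = frame.groupby("rel_conc", sort=False)["ct"].mean().reset_index()
    agg = agg.sort_values("rel_conc", ascending=False)
    return DilutionSeries(concentrations=tuple(agg["rel_conc"]), cts=tuple(agg["ct"]))
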