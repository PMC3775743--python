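"""Seeded generators for every input the pipeline consumes.

Random circular genomes with a synthetic gene/D-loop annotation; planted
direct or inverted repeats with known ground truth (guaranteed findable by
the brute-force enumerator, and blocked from accidental extension by forced
flank mismatches); species panels whose planted inverted-repeat content
realizes a log-linear score-lifespan relation on a clade-structured
taxonomy; and simulated qPCR plates. Every generator is a pure function of
its seed and spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .comparative import SpeciesPanel, TaxonomyTree, build_tree_from_lineages
from .genome_io import GenomeFeature, MitoGenome, SpeciesRecord
from .qpcr import Efficiency, NestedExperiment
from .repeat_scan import Repeat
from .scoring import repeat_score

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_BASES = "ACGT"


@dataclass(frozen=True)
class PlantSpec:
    """One repeat to plant: kind, arm length, mismatch count, optional positions."""

    kind: str
    length: int
    mismatches: int = 0
    arm1_start: int | None = None  # 1-based; None = random placement
    arm2_start: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("DR", "IR"):
            raise ValueError("kind must be DR or IR")
        if self.length < 2:
            raise ValueError("planted repeats must be at least 2 bp")
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")
        if self.mismatches >= 1 and self.length < 4 * (self.mismatches + 1):
            raise ValueError(
                f"length {self.length} violates the l >= 4*(m+1) budget for m={self.mismatches}")


@dataclass(frozen=True)
class PanelSpec:
    """Species panel with planted relation log10(score) = alpha - beta*log10(MLS) + noise."""

    n_species: int = 60
    n_clades: int = 4
    alpha: float = 0.5
    beta: float = 1.0
    sigma: float = 0.15
    mls_range: tuple[float, float] = (2.0, 100.0)
    genome_length: int = 1600
    gc: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 6:
            raise ValueError("need at least 6 species")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not (0 < self.mls_range[0] < self.mls_range[1]):
            raise ValueError("MLS range must be positive and increasing")


@dataclass
class SyntheticPanel:
    panel: SpeciesPanel
    tree: TaxonomyTree
    genomes: dict[str, MitoGenome]
    planted: dict[str, list[Repeat]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

def random_circular_genome(length: int, gc: float = 0.4, seed: int = 0,
                           accession: str | None = None,
                           dloop_fraction: float = 0.1) -> MitoGenome:
    """Seeded random circular genome with one synthetic gene and one D-loop.

    The gene feature covers everything except a trailing D-loop segment of
    about ``dloop_fraction`` of the genome, so gene-region filtering has a
    non-trivial effect on every synthetic genome.
    """
    if length < 10:
        raise ValueError("genome length must be >= 10")
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(np.array(list(_BASES))[rng.choice(4, size=length, p=p)])
    dloop_len = max(5, int(round(length * dloop_fraction)))
    gene_end = length - dloop_len
    features = [
        GenomeFeature(kind="gene", start=1, end=gene_end, strand="+", name="synth-gene"),
        GenomeFeature(kind="D-loop", start=gene_end + 1, end=length, strand="+", name="D-loop"),
    ]
    return MitoGenome(sequence=seq, accession=accession or f"SYN{seed}",
                      organism="synthetic", features=features)


def _mismatch_offsets(length: int, m: int, rng: np.random.Generator) -> list[int]:
    """Interior 0-based arm offsets for planted mismatches: away from the arm
    ends (>=4 bp where possible, else >=3) and pairwise non-adjacent, so each
    mismatch is a crossable run of one."""
    if m == 0:
        return []
    for margin in (4, 3):
        slots = list(range(margin, length - margin))
        if len(slots) >= 2 * m - 1:
            chosen: list[int] = []
            pool = slots[:]
            while len(chosen) < m:
                c = int(rng.choice(pool))
                chosen.append(c)
                pool = [p for p in pool if abs(p - c) > 1]
                if not pool and len(chosen) < m:
                    break
            if len(chosen) == m:
                return sorted(chosen)
    raise ValueError(f"cannot place {m} spaced interior mismatches in a {length} bp arm")


def _random_base(rng: np.random.Generator, excluding: str) -> str:
    options = [b for b in _BASES if b != excluding]
    return options[int(rng.integers(0, len(options)))]


def _spacer_of(a1s0: int, a2s0: int, l: int, L: int) -> int:
    e1 = (a1s0 + l - 1) % L
    e2 = (a2s0 + l - 1) % L
    return int(min((a2s0 - e1 - 1) % L, (a1s0 - e2 - 1) % L))


def plant_repeat(genome: MitoGenome, spec: PlantSpec,
                 region: tuple[int, int] | None = None,
                 avoid: Sequence[tuple[int, int]] = ()) -> tuple[MitoGenome, Repeat]:
    """Plant one repeat and return the modified genome plus its ground truth.

    The second arm is written as a (mismatched) copy or reverse complement of
    the first; the bases just outside both arm pairings are forced to
    mismatch so the planted repeat is exactly maximal. Placement is uniform
    inside ``region`` (1-based, defaults to the whole genome), rejecting
    arm positions that collide with each other, the flank buffer, or the
    ``avoid`` intervals.
    """
    rng = np.random.default_rng(spec.seed)
    L = genome.length
    l = spec.length
    lo, hi = region if region is not None else (1, L)
    if hi - lo + 1 < 2 * l + 6:
        raise ValueError("placement region too small for the requested repeat")
    seq = list(genome.sequence)

    pad = 8  # room for the extension-blocking flank pattern

    if spec.arm1_start is not None and spec.arm2_start is not None:
        a1s0, a2s0 = spec.arm1_start - 1, spec.arm2_start - 1
    else:
        # occupancy mask of avoided intervals (incl. blocker padding), circular
        occ = np.zeros(L, dtype=bool)
        for a, b in avoid:
            span = (b - a) % L + 1 + 2 * pad
            occ[(np.arange(a - 1 - pad, a - 1 - pad + span)) % L] = True
        occ3 = np.concatenate([occ, occ, occ])
        window = l + 2 * pad
        csum = np.concatenate([[0], np.cumsum(occ3)])
        starts = np.arange(lo - 1, hi - l + 1)
        base = starts - pad + L  # window spans s0-pad .. s0+l-1+pad, kept in-range
        free = (csum[base + window] - csum[base]) == 0
        valid = starts[free]
        placement = None
        if valid.size >= 2:
            for a1 in rng.permutation(valid)[:50]:
                options = valid[np.abs(valid - a1) >= l + 2]
                if options.size:
                    a2 = int(options[int(rng.integers(0, options.size))])
                    placement = (min(int(a1), a2), max(int(a1), a2))
                    break
        if placement is None:
            raise ValueError("could not place the repeat without collision")
        a1s0, a2s0 = placement
    if a1s0 == a2s0:
        raise ValueError("arm positions collide")
    offsets = set(_mismatch_offsets(l, spec.mismatches, rng))

    def block_side(pairs: list[tuple[int, int]], inverted: bool) -> None:
        """Force the diagonal continuation beyond an arm end to be unextendable.

        ``pairs`` are (reference, write) positions at offsets 1, 2, ... past
        the arm ends. With six or more slots the pattern is four mismatches,
        one match, one mismatch — a mismatch run of four not followed by four
        matches, which the valley rule can never cross; with fewer slots the
        arm-overlap cap already bounds the extension and every slot is simply
        made a mismatch.
        """
        full = len(pairs) >= 6
        for t, (p_ref, p_w) in enumerate(pairs, start=1):
            want = _COMP[seq[p_ref]] if inverted else seq[p_ref]
            if full and t == 5:
                seq[p_w] = want
            else:
                if seq[p_w] == want:
                    seq[p_w] = _random_base(rng, want)

    spacer = _spacer_of(a1s0, a2s0, l, L)
    a1e0 = a1s0 + l - 1
    a2e0 = a2s0 + l - 1
    if spec.kind == "DR":
        for k in range(l):
            src = seq[(a1s0 + k) % L]
            seq[(a2s0 + k) % L] = _random_base(rng, src) if k in offsets else src
        inner = min(6, (a2s0 - a1e0 - 1) % L)   # writes fall in the inter-arm gap
        outer = min(6, (a1s0 - a2e0 - 1) % L)
        block_side([((a1s0 - t) % L, (a2s0 - t) % L) for t in range(1, inner + 1)],
                   inverted=False)
        block_side([((a1e0 + t) % L, (a2e0 + t) % L) for t in range(1, outer + 1)],
                   inverted=False)
    else:
        for k in range(l):
            src = seq[(a1s0 + k) % L]
            want = _COMP[src]
            seq[(a2e0 - k) % L] = _random_base(rng, want) if k in offsets else want
        inner = min(6, ((a2s0 - a1e0 - 1) % L) // 2)  # both sides of the pair sit in the gap
        outer = min(6, ((a1s0 - a2e0 - 1) % L) // 2)
        block_side([((a1e0 + t) % L, (a2s0 - t) % L) for t in range(1, inner + 1)],
                   inverted=True)
        block_side([((a1s0 - t) % L, (a2e0 + t) % L) for t in range(1, outer + 1)],
                   inverted=True)

    matches = l - spec.mismatches
    truth = Repeat(
        kind=spec.kind,
        arm1_start=a1s0 + 1, arm1_end=(a1s0 + l - 1) % L + 1,
        arm2_start=a2s0 + 1, arm2_end=(a2s0 + l - 1) % L + 1,
        length=l, matches=matches, mismatches=spec.mismatches,
        spacer=_spacer_of(a1s0, a2s0, l, L),
    )
    new_genome = MitoGenome(sequence="".join(seq), accession=genome.accession,
                            organism=genome.organism, features=list(genome.features))
    return new_genome, truth


# ---------------------------------------------------------------------------
# Species panels
# ---------------------------------------------------------------------------

def _plant_score_target(genome: MitoGenome, target: float, kind: str,
                        region: tuple[int, int], rng: np.random.Generator,
                        avoid: list[tuple[int, int]]) -> tuple[MitoGenome, list[Repeat]]:
    """Greedily plant perfect repeats (lengths 25 down to 8) summing to ~target."""
    planted: list[Repeat] = []
    remaining = target
    for l in range(25, 7, -1):
        unit = repeat_score(l, l)
        while unit <= remaining:
            spec = PlantSpec(kind=kind, length=l, mismatches=0,
                             seed=int(rng.integers(0, 2**31 - 1)))
            genome, rep = plant_repeat(genome, spec, region=region, avoid=avoid)
            for s, e in ((rep.arm1_start, rep.arm1_end), (rep.arm2_start, rep.arm2_end)):
                avoid.append((s, e))
            planted.append(rep)
            remaining -= unit
    return genome, planted


def synthesize_panel(spec: PanelSpec) -> SyntheticPanel:
    """Generate a clade-structured species panel with a planted score-MLS relation.

    Per species, maximum lifespan is log-uniform over ``mls_range`` and the
    inverted-repeat content is planted so the realized log10 total IR score
    equals alpha - beta*log10(MLS) plus Gaussian noise (up to the small
    quantization of planting discrete repeats). A couple of direct repeats
    of random length give every species a non-zero DR score. The lineage
    template Root > Clade > Genus > species induces a polytomous taxonomy.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SpeciesRecord] = []
    genomes: dict[str, MitoGenome] = {}
    planted_all: dict[str, list[Repeat]] = {}
    log_lo, log_hi = (math.log10(spec.mls_range[0]), math.log10(spec.mls_range[1]))
    per_clade = -(-spec.n_species // spec.n_clades)
    for i in range(spec.n_species):
        clade = i % spec.n_clades
        j = i // spec.n_clades
        genus = j // 3
        name = f"Species_{clade}_{j}"
        lineage = ("Root", f"Clade_{clade}", f"Genus_{clade}_{genus}")
        mls = 10 ** rng.uniform(log_lo, log_hi)
        log_target = spec.alpha - spec.beta * math.log10(mls) + rng.normal(0.0, spec.sigma)
        target = 10 ** log_target
        genome = random_circular_genome(spec.genome_length, spec.gc,
                                        seed=int(rng.integers(0, 2**31 - 1)),
                                        accession=name)
        gene_region = (1, next(f.end for f in genome.features if f.kind == "gene"))
        avoid: list[tuple[int, int]] = []
        genome, irs = _plant_score_target(genome, target, "IR", gene_region, rng, avoid)
        dr_total = 0.0
        drs: list[Repeat] = []
        for _ in range(2):
            dl = int(rng.integers(10, 16))
            genome, rep = plant_repeat(
                genome, PlantSpec(kind="DR", length=dl, seed=int(rng.integers(0, 2**31 - 1))),
                region=gene_region, avoid=avoid)
            for s, e in ((rep.arm1_start, rep.arm1_end), (rep.arm2_start, rep.arm2_end)):
                avoid.append((s, e))
            drs.append(rep)
            dr_total += repeat_score(dl, dl)
        ir_total = sum(repeat_score(r.matches, r.length) for r in irs)
        if ir_total <= 0:  # tiny target below the smallest plantable repeat
            genome, rep = plant_repeat(
                genome, PlantSpec(kind="IR", length=8, seed=int(rng.integers(0, 2**31 - 1))),
                region=gene_region, avoid=avoid)
            irs.append(rep)
            ir_total = repeat_score(8, 8)
        records.append(SpeciesRecord(species=name, mls_years=mls, lineage=lineage,
                                     dr_total=dr_total, ir_total=ir_total))
        genomes[name] = genome
        planted_all[name] = irs + drs
    panel = SpeciesPanel(records=records)
    tree = build_tree_from_lineages(records)
    _ = per_clade
    return SyntheticPanel(panel=panel, tree=tree, genomes=genomes, planted=planted_all)


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def simulate_qpcr(true_concentrations: Sequence[float], f: float = 1.67,
                  ct_noise: float = 0.1, seed: int = 0, offset: float = 10.0,
                  replicates: int = 3) -> pd.DataFrame:
    """Simulated dilution-series plate: Ct = -log_f(conc) + offset + N(0, sigma)."""
    if not 1 < f <= 2:
        raise ValueError("efficiency f must lie in (1, 2]")
    concs = list(true_concentrations)
    if any(c <= 0 for c in concs):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for c in concs:
        base = -math.log(c, f) + offset
        for rep in range(replicates):
            rows.append({"rel_conc": c, "replicate": rep + 1,
                         "ct": base + rng.normal(0.0, ct_noise)})
    return pd.DataFrame(rows)


def simulate_nested_experiment(true_delta_ct: float = 0.0, f: float = 1.67,
                               ct_noise: float = 0.3, n_b: int = 12, n_s: int = 12,
                               n_n: int = 6, seed: int = 0, base_ct: float = 20.0,
                               ctrl_offset: float = 12.0) -> NestedExperiment:
    """Simulated nested LR-PCR/qPCR experiment with known group separation."""
    rng = np.random.default_rng(seed)
    eff = Efficiency(slope=1.0 / math.log2(f), f=f)
    ct_b = tuple(base_ct + rng.normal(0.0, ct_noise) for _ in range(n_b))
    ct_s = tuple(base_ct + true_delta_ct + rng.normal(0.0, ct_noise) for _ in range(n_s))
    ct_n = tuple(base_ct + ctrl_offset + rng.normal(0.0, ct_noise) for _ in range(n_n))
    return NestedExperiment(ct_b=ct_b, ct_s=ct_s, ct_n=ct_n, efficiency=eff)
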