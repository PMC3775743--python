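"""Input/output for mitochondrial genomes, annotations and tabular data.

All public coordinates are 1-based and inclusive. Mitochondrial genomes are
circular; a feature or repeat arm that wraps the replication origin is
represented with ``end < start``.

GenBank and FASTA parsing is delegated to Biopython; tab-separated tables go
through pandas. Feature kinds are collapsed onto the five classes used for
gene-region masking: ``gene``, ``tRNA``, ``rRNA``, ``CDS`` and ``D-loop``
(anything else becomes ``other``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("mitorepeats")

GENE_KINDS = ("gene", "tRNA", "rRNA", "CDS")
FEATURE_KINDS = GENE_KINDS + ("D-loop", "other")

#: Column order of the repeat-table TSV schema.
REPEAT_TABLE_COLUMNS = [
    "kind", "arm1_start", "arm1_end", "arm2_start", "arm2_end",
    "length", "matches", "mismatches", "spacer", "score",
]


@dataclass(frozen=True)
class GenomeFeature:
    """One annotated feature; ``start > end`` means the feature wraps the origin."""

    kind: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError("feature coordinates are 1-based and must be >= 1")


@dataclass
class MitoGenome:
    """A circular mitochondrial genome with its annotated features."""

    sequence: str
    accession: str = ""
    organism: str = ""
    features: list[GenomeFeature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        if not self.circular:
            raise ValueError("mitochondrial genomes are treated as circular")
        for f in self.features:
            if f.start > len(self.sequence) or f.end > len(self.sequence):
                raise ValueError(f"feature {f.name!r} outside genome of length {len(self.sequence)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def dloop(self) -> GenomeFeature | None:
        """The D-loop/control-region feature, or None (with a logged warning)."""
        for f in self.features:
            if f.kind == "D-loop":
                return f
            lowered = f.name.lower()
            if "d-loop" in lowered or "control region" in lowered:
                return f
        logger.warning("genome %s: no D-loop/control-region annotation found", self.accession or "<unnamed>")
        return None


@dataclass(frozen=True)
class SpeciesRecord:
    """One species row: binomial, maximum lifespan (years), lineage, repeat scores.

    Lifespan positivity is enforced where raw panels are assembled (table
    reading, panel construction), so that the same record type can carry
    log10-transformed values.
    """

    species: str
    mls_years: float
    lineage: tuple[str, ...]
    dr_total: float = 0.0
    ir_total: float = 0.0

    def __post_init__(self) -> None:
        if not self.lineage:
            raise ValueError("lineage must be non-empty")


# ---------------------------------------------------------------------------
# GenBank / FASTA
# ---------------------------------------------------------------------------

def _classify_feature(feat: SeqFeature) -> str:
    ftype = feat.type
    if ftype in GENE_KINDS:
        return ftype
    note = " ".join(feat.qualifiers.get("note", []) + feat.qualifiers.get("standard_name", []))
    if ftype.lower() in ("d-loop", "d_loop") or "d-loop" in note.lower() or "control region" in note.lower():
        return "D-loop"
    return "other"


def _feature_name(feat: SeqFeature) -> str:
    for key in ("gene", "product", "standard_name", "note"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return feat.type


def _location_to_interval(loc, genome_length: int) -> tuple[int, int]:
    """Biopython 0-based half-open location -> 1-based inclusive (start, end).

    A two-part compound location whose first part ends at the sequence end and
    whose second part starts at 1 is folded into a single origin-wrapping
    interval with end < start.
    """
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if (
            len(parts) == 2
            and int(parts[1].end) == genome_length
            and int(parts[0].start) == 0
        ):
            return int(parts[1].start) + 1, int(parts[0].end)
        return int(loc.start) + 1, int(loc.end)
    return int(loc.start) + 1, int(loc.end)


def read_mito_genbank(path: str | Path) -> MitoGenome:
    """Read a single-record GenBank flat file into a :class:`MitoGenome`."""
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one GenBank record in {path}, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError(f"GenBank record {rec.id} has no sequence")
    features: list[GenomeFeature] = []
    for feat in rec.features:
        if feat.type == "source":
            continue
        kind = _classify_feature(feat)
        start, end = _location_to_interval(feat.location, len(seq))
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(GenomeFeature(kind=kind, start=start, end=end, strand=strand, name=_feature_name(feat)))
    organism = rec.annotations.get("organism", "") or rec.annotations.get("source", "")
    return MitoGenome(sequence=seq, accession=rec.id, organism=organism, features=features)


def write_genbank(genome: MitoGenome, path: str | Path) -> None:
    """Write a :class:`MitoGenome` back to a GenBank flat file."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession or "UNKNOWN",
        name=(genome.accession or "UNKNOWN").split(".")[0][:16],
        description=f"{genome.organism} mitochondrion".strip(),
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "organism": genome.organism,
        },
    )
    L = genome.length
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.start <= f.end:
            loc = FeatureLocation(f.start - 1, f.end, strand=strand)
        else:  # wraps the origin: join(start..L, 1..end)
            loc = CompoundLocation([
                FeatureLocation(f.start - 1, L, strand=strand),
                FeatureLocation(0, f.end, strand=strand),
            ])
        qualifiers = {"note": [f.name]} if f.kind in ("D-loop", "other") else {"gene": [f.name]}
        ftype = "D_loop" if f.kind == "D-loop" else ("misc_feature" if f.kind == "other" else f.kind)
        if f.kind == "D-loop":
            ftype = "D-loop"
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers=qualifiers))
    SeqIO.write([rec], str(path), "genbank")


def read_fasta(path: str | Path) -> MitoGenome:
    """Read a single-record FASTA file; no features are attached."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record in {path}, found {len(records)}")
    rec = records[0]
    return MitoGenome(sequence=str(rec.seq).upper(), accession=rec.id, organism=rec.description)


# ---------------------------------------------------------------------------
# Gene-region mask
# ---------------------------------------------------------------------------

def _merge_linear(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def gene_region_union(genome: MitoGenome) -> list[tuple[int, int]]:
    """Union of all gene/tRNA/rRNA/CDS intervals, circular-aware.

    Returns a list of 1-based inclusive intervals; a wrapping interval has
    ``end < start``. D-loop and ``other`` features never contribute.
    """
    L = genome.length
    pieces: list[tuple[int, int]] = []
    for f in genome.features:
        if f.kind not in GENE_KINDS:
            continue
        if f.start <= f.end:
            pieces.append((f.start, f.end))
        else:
            pieces.append((f.start, L))
            pieces.append((1, f.end))
    if not pieces:
        raise ValueError("no gene regions: genome has no gene/tRNA/rRNA/CDS features")
    merged = _merge_linear(pieces)
    if len(merged) == 1 and merged[0] == (1, L):
        return [(1, L)]
    # stitch across the origin when both ends of the line are covered
    if len(merged) >= 2 and merged[0][0] == 1 and merged[-1][1] == L:
        first, last = merged[0], merged[-1]
        merged = merged[1:-1] + [(last[0], first[1])]
        merged.sort()
    return merged


def interval_contains(regions: Sequence[tuple[int, int]], start: int, end: int, genome_length: int) -> bool:
    """True if the (possibly wrapping) arm [start, end] lies fully inside one region."""
    arm = _unroll(start, end, genome_length)
    for s, e in regions:
        for rs, re in (_unroll(s, e, genome_length), ):
            for shift in (0, genome_length):
                if rs <= arm[0] + shift and arm[1] + shift <= re:
                    return True
    return False


def _unroll(start: int, end: int, L: int) -> tuple[int, int]:
    """Map a circular 1-based interval to a linear one on [1, 2L]."""
    if start <= end:
        return start, end
    return start, end + L


# ---------------------------------------------------------------------------
# Species table
# ---------------------------------------------------------------------------

def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read a TSV with columns species, mls_years, lineage (semicolon-joined).

    Rows with missing or non-positive lifespan are skipped with a warning.
    Optional dr_total / ir_total columns are carried through.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("species", "mls_years", "lineage"):
        if col not in df.columns:
            raise ValueError(f"species table {path} is missing mandatory column {col!r}")
    records: list[SpeciesRecord] = []
    for _, row in df.iterrows():
        raw_mls = row["mls_years"]
        try:
            mls = float(raw_mls)
        except (TypeError, ValueError):
            mls = float("nan")
        if not mls > 0:
            logger.warning("species %s skipped: lifespan %r is missing or non-positive", row["species"], raw_mls)
            continue
        lineage = tuple(t.strip() for t in str(row["lineage"]).split(";") if t.strip())
        records.append(SpeciesRecord(
            species=str(row["species"]),
            mls_years=mls,
            lineage=lineage,
            dr_total=float(row.get("dr_total", 0.0) or 0.0),
            ir_total=float(row.get("ir_total", 0.0) or 0.0),
        ))
    return records


def write_species_table(records: Iterable[SpeciesRecord], path: str | Path) -> None:
    df = pd.DataFrame([
        {
            "species": r.species,
            "mls_years": r.mls_years,
            "lineage": ";".join(r.lineage),
            "dr_total": r.dr_total,
            "ir_total": r.ir_total,
        }
        for r in records
    ], columns=["species", "mls_years", "lineage", "dr_total", "ir_total"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Repeat table
# ---------------------------------------------------------------------------

def write_repeat_table(repeats, path: str | Path, scores: Sequence[float] | None = None) -> None:
    """Write repeats to the TSV schema; ``scores`` defaults to zeros."""
    rows = []
    repeats = list(repeats)
    if scores is None:
        scores = [0.0] * len(repeats)
    for r, sc in zip(repeats, scores):
        rows.append({
            "kind": r.kind,
            "arm1_start": r.arm1_start, "arm1_end": r.arm1_end,
            "arm2_start": r.arm2_start, "arm2_end": r.arm2_end,
            "length": r.length, "matches": r.matches, "mismatches": r.mismatches,
            "spacer": r.spacer, "score": sc,
        })
    pd.DataFrame(rows, columns=REPEAT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_repeat_table(path: str | Path):
    """Read a repeat-table TSV back into a list of Repeat objects."""
    from .repeat_scan import Repeat  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REPEAT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"repeat table {path} is missing columns {missing}")
    return [
        Repeat(
            kind=row["kind"],
            arm1_start=int(row["arm1_start"]), arm1_end=int(row["arm1_end"]),
            arm2_start=int(row["arm2_start"]), arm2_end=int(row["arm2_end"]),
            length=int(row["length"]), matches=int(row["matches"]),
            mismatches=int(row["mismatches"]), spacer=int(row["spacer"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Newick interop
# ---------------------------------------------------------------------------

def read_newick(path: str | Path):
    """Read a Newick tree (dendropy) and return a comparative.TaxonomyTree."""
    import dendropy

    from .comparative import TaxonomyTree, TreeNode

    dtree = dendropy.Tree.get(path=str(path), schema="newick")

    def convert(dnode) -> TreeNode:
        name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
        node = TreeNode(name=name)
        for child in dnode.child_nodes():
            node.children.append(convert(child))
        return node

    return TaxonomyTree(root=convert(dtree.seed_node))
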