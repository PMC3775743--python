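"""Comparative analysis: mutagenic score versus maximum lifespan (MLS).

Per-species repeat-score totals are log10-transformed and correlated with
log10 maximum lifespan (Pearson and Spearman, two-tailed; Shapiro-Wilk on
the regression residuals as a normality diagnostic). Because species share
ancestry, raw cross-species correlations overstate the effective sample
size; phylogenetically independent contrasts on a taxonomy-derived tree with
equal branch lengths provide the corrected association. Taxonomy trees are
typically polytomous, and each polytomy is reduced to a single contrast by
splitting its daughters at the median of the independent variable (MLS) —
the CAIC-style rule — with an optional seeded random bifurcation as a
sensitivity check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import SpeciesRecord

logger = logging.getLogger("mitorepeats")


@dataclass
class SpeciesPanel:
    """The unit of comparative analysis: one row per species."""

    records: list[SpeciesRecord]
    clade_filter: str = ""
    log10: bool = False

    def __post_init__(self) -> None:
        names = [r.species for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique in a panel")
        if not self.log10 and any(r.mls_years <= 0 for r in self.records):
            raise ValueError("all maximum lifespans must be positive")

    def __len__(self) -> int:
        return len(self.records)

    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def column(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.species(),
            "mls_years": self.column("mls_years"),
            "dr_total": self.column("dr_total"),
            "ir_total": self.column("ir_total"),
            "lineage": [";".join(r.lineage) for r in self.records],
        })


@dataclass
class TreeNode:
    name: str
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class TaxonomyTree:
    """Rooted tree with species at the tips and implicit unit branch lengths."""

    root: TreeNode

    def tip_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    shapiro_w: float = float("nan")
    shapiro_p: float = float("nan")


@dataclass
class ContrastSet:
    """Standardized contrasts, sign-polarized so the MLS contrast is >= 0."""

    x: np.ndarray  # independent variable (log MLS)
    y: np.ndarray  # dependent variable (log score)
    node_ids: list[str]

    def __len__(self) -> int:
        return len(self.node_ids)


# ---------------------------------------------------------------------------
# Transform & correlation
# ---------------------------------------------------------------------------

def log_transform(panel: SpeciesPanel, kinds: Sequence[str] = ("dr", "ir")) -> SpeciesPanel:
    """log10-transform lifespan and score columns, dropping zero-score species.

    A species whose total score is 0 for any requested repeat kind has no
    defined log score and is dropped with a warning.
    """
    if panel.log10:
        raise ValueError("panel is already log10-transformed")
    kept: list[SpeciesRecord] = []
    dropped = 0
    for r in panel.records:
        vals = {"dr": r.dr_total, "ir": r.ir_total}
        if any(vals[k] <= 0 for k in kinds):
            dropped += 1
            continue
        kept.append(SpeciesRecord(
            species=r.species,
            mls_years=math.log10(r.mls_years),
            lineage=r.lineage,
            dr_total=math.log10(r.dr_total) if r.dr_total > 0 else float("nan"),
            ir_total=math.log10(r.ir_total) if r.ir_total > 0 else float("nan"),
        ))
    if dropped:
        logger.warning("log_transform: dropped %d species with zero repeat score", dropped)
    out = SpeciesPanel(records=kept, clade_filter=panel.clade_filter, log10=True)
    return out


def correlate(panel: SpeciesPanel, y: str = "ir_total", x: str = "mls_years") -> CorrelationResult:
    """Pearson + Spearman of a score column on MLS, with a residual normality check."""
    xv = panel.column(x)
    yv = panel.column(y)
    n = len(xv)
    if n < 3:
        raise ValueError(f"need at least 3 species, got {n}")
    if np.allclose(xv.std(), 0) or np.allclose(yv.std(), 0):
        raise ValueError("zero variance in x or y")
    pr, pp = stats.pearsonr(xv, yv)
    sr, sp = stats.spearmanr(xv, yv)
    slope, intercept = np.polyfit(xv, yv, 1)
    resid = yv - (slope * xv + intercept)
    if n >= 3 and np.ptp(resid) > 0:
        w, wp = stats.shapiro(resid)
    else:
        w, wp = float("nan"), float("nan")
    return CorrelationResult(n=n, pearson_r=float(pr), pearson_p=float(pp),
                             spearman_rho=float(sr), spearman_p=float(sp),
                             shapiro_w=float(w), shapiro_p=float(wp))


def per_length_correlation(panels: dict[int, SpeciesPanel], y: str = "ir_total",
                           ) -> dict[int, CorrelationResult | None]:
    """Correlate each repeat-length class separately.

    Species without repeats of a given length (score 0, or NaN after log
    transform) are excluded from that length's panel; classes left with
    fewer than 3 species are flagged with None rather than raising.
    """
    out: dict[int, CorrelationResult | None] = {}
    for length, panel in sorted(panels.items()):
        usable = [r for r in panel.records
                  if np.isfinite(getattr(r, y)) and (panel.log10 or getattr(r, y) > 0)]
        if len(usable) < 3:
            out[length] = None
            continue
        sub = SpeciesPanel(records=usable, clade_filter=panel.clade_filter, log10=panel.log10)
        out[length] = correlate(sub, y=y)
    return out


# ---------------------------------------------------------------------------
# Taxonomy tree
# ---------------------------------------------------------------------------

def build_tree_from_lineages(records: Iterable[SpeciesRecord]) -> TaxonomyTree:
    """Merge root-to-species lineage paths into a (polytomous) taxonomy tree.

    Unit branch lengths are implicit; internal nodes with a single child are
    collapsed so every retained edge separates actual splits. Inconsistent
    lineages (the same taxon under two different parents) are an error.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    roots = {r.lineage[0] for r in records}
    if len(roots) > 1:
        raise ValueError(f"lineages do not share a root: {sorted(roots)}")
    parent_of: dict[str, str] = {}
    children: dict[str, list[str]] = {}

    def add_edge(parent: str, child: str) -> None:
        if child in parent_of and parent_of[child] != parent:
            raise ValueError(f"taxon {child!r} appears under both {parent_of[child]!r} and {parent!r}")
        if child not in parent_of:
            parent_of[child] = parent
            children.setdefault(parent, []).append(child)

    root_name = roots.pop()
    for r in records:
        path = list(r.lineage) + [r.species]
        for a, b in zip(path, path[1:]):
            add_edge(a, b)

    def build(name: str) -> TreeNode:
        node = TreeNode(name=name)
        for ch in children.get(name, []):
            node.children.append(build(ch))
        return node

    root = build(root_name)

    def collapse(node: TreeNode) -> TreeNode:
        while len(node.children) == 1:
            node = node.children[0]
        node.children = [collapse(c) for c in node.children]
        return node

    return TaxonomyTree(root=collapse(root))


# ---------------------------------------------------------------------------
# Independent contrasts
# ---------------------------------------------------------------------------

def independent_contrasts(tree: TaxonomyTree, panel: SpeciesPanel, y: str = "ir_total",
                          x: str = "mls_years", polytomy: str = "median_split",
                          seed: int = 0) -> ContrastSet:
    """Felsenstein contrasts with unit branch lengths on a (polytomous) tree.

    Every bifurcation yields one standardized contrast. Under the default
    ``median_split`` rule, a polytomy also yields exactly one contrast: its
    daughters are split into two groups at the median of the independent
    variable and the weighted group means are contrasted. ``polytomy="random"``
    instead resolves each polytomy into random cherries (seeded), yielding
    d-1 contrasts per degree-d polytomy, as a sensitivity check.

    Contrast pairs are polarized so the x (MLS) contrast is non-negative.
    """
    if polytomy not in ("median_split", "random"):
        raise ValueError(f"unknown polytomy rule {polytomy!r}")
    values = {r.species: (getattr(r, x), getattr(r, y)) for r in panel.records}
    rng = np.random.default_rng(seed)
    cx: list[float] = []
    cy: list[float] = []
    ids: list[str] = []

    def combine(items, node_name):
        """items: list of (x, y, v); returns combined (x, y, v) for the parent edge."""
        if len(items) == 1:
            xv, yv, v = items[0]
            return xv, yv, v + 1.0
        if len(items) == 2:
            (x1, y1, v1), (x2, y2, v2) = items
            sd = math.sqrt(v1 + v2)
            _emit((x1 - x2) / sd, (y1 - y2) / sd, node_name)
            xm = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
            ym = (y1 / v1 + y2 / v2) / (1 / v1 + 1 / v2)
            return xm, ym, 1.0 + v1 * v2 / (v1 + v2)
        if polytomy == "random":
            items = list(items)
            order = rng.permutation(len(items))
            items = [items[i] for i in order]
            while len(items) > 2:
                a = items.pop()
                b = items.pop()
                merged = combine([a, b], node_name)
                # undo the extra unit edge added for cherry-internal nodes:
                merged = (merged[0], merged[1], merged[2] - 1.0)
                items.append(merged)
            return combine(items, node_name)
        # CAIC-style median split on the independent variable
        items = sorted(items, key=lambda t: t[0])
        half = (len(items) + 1) // 2
        lo, hi = items[:half], items[half:]

        def group(sub):
            wsum = sum(1 / v for _, _, v in sub)
            gx = sum(xv / v for xv, _, v in sub) / wsum
            gy = sum(yv / v for _, yv, v in sub) / wsum
            return gx, gy, 1 / wsum
        (gx1, gy1, gv1), (gx2, gy2, gv2) = group(lo), group(hi)
        sd = math.sqrt(gv1 + gv2)
        _emit((gx1 - gx2) / sd, (gy1 - gy2) / sd, node_name)
        wsum = sum(1 / v for _, _, v in items)
        xm = sum(xv / v for xv, _, v in items) / wsum
        ym = sum(yv / v for _, yv, v in items) / wsum
        return xm, ym, 1.0 + 1 / wsum

    def _emit(dx, dy, name):
        if dx < 0 or (dx == 0 and dy < 0):
            dx, dy = -dx, -dy
        cx.append(dx)
        cy.append(dy)
        ids.append(name)

    def walk(node: TreeNode):
        if node.is_leaf():
            if node.name not in values:
                raise ValueError(f"tree tip {node.name!r} is not in the panel")
            xv, yv = values[node.name]
            return xv, yv, 1.0
        items = [walk(c) for c in node.children]
        return combine(items, node.name)

    walk(tree.root)
    if len(cx) < 1:
        raise ValueError("fewer than 2 usable nodes: no contrast can be formed")
    return ContrastSet(x=np.array(cx), y=np.array(cy), node_ids=ids)


def contrast_correlation(contrasts: ContrastSet) -> CorrelationResult:
    """Association of the contrast pairs: Spearman headline, Pearson through the origin."""
    n = len(contrasts)
    if n < 3:
        raise ValueError(f"need at least 3 contrasts, got {n}")
    x, y = contrasts.x, contrasts.y
    sr, sp = stats.spearmanr(x, y)
    denom = math.sqrt(float(np.sum(x * x)) * float(np.sum(y * y)))
    r0 = float(np.sum(x * y)) / denom if denom > 0 else float("nan")
    df = n - 1  # regression through the origin spends no intercept
    if abs(r0) < 1 and df > 0:
        t = r0 * math.sqrt(df / (1 - r0 * r0))
        p0 = 2 * stats.t.sf(abs(t), df)
    else:
        p0 = 0.0 if abs(r0) >= 1 else float("nan")
    return CorrelationResult(n=n, pearson_r=r0, pearson_p=float(p0),
                             spearman_rho=float(sr), spearman_p=float(sp))


# ---------------------------------------------------------------------------
# Clade report
# ---------------------------------------------------------------------------

def filter_clade(panel: SpeciesPanel, clade: str, exclude: str | None = None) -> SpeciesPanel:
    """Panel restricted to species whose lineage contains ``clade`` (minus ``exclude``)."""
    in_clade = [r for r in panel.records if clade in r.lineage or clade == r.species]
    if not in_clade:
        raise ValueError(f"unknown clade {clade!r}: no species lineage contains it")
    if exclude is not None:
        if not any(exclude in r.lineage for r in panel.records):
            raise ValueError(f"unknown exclusion clade {exclude!r}")
        in_clade = [r for r in in_clade if exclude not in r.lineage]
    label = clade if exclude is None else f"{clade} - {exclude}"
    return SpeciesPanel(records=in_clade, clade_filter=label, log10=panel.log10)


def clade_report(panel: SpeciesPanel, clades: Sequence[str | tuple[str, str | None]],
                 kinds: Sequence[str] = ("dr", "ir"), polytomy: str = "median_split",
                 seed: int = 0) -> pd.DataFrame:
    """Raw and contrast correlations per clade and repeat kind, Table-1 shaped.

    ``panel`` must already be log-transformed. Each entry of ``clades`` is a
    clade name or a (clade, exclude) pair.
    """
    if not panel.log10:
        raise ValueError("clade_report expects a log-transformed panel")
    rows = []
    for entry in clades:
        clade, exclude = entry if isinstance(entry, tuple) else (entry, None)
        sub = filter_clade(panel, clade, exclude)
        for kind in kinds:
            col = f"{kind}_total"
            res = correlate(sub, y=col)
            tree = build_tree_from_lineages(sub.records)
            try:
                cs = independent_contrasts(tree, sub, y=col, polytomy=polytomy, seed=seed)
                cres = contrast_correlation(cs)
                crho, cp, nc = cres.spearman_rho, cres.spearman_p, cres.n
            except ValueError:
                crho, cp, nc = float("nan"), float("nan"), 0
            rows.append({
                "clade": sub.clade_filter, "kind": kind.upper(), "n": res.n,
                "pearson_r": res.pearson_r, "pearson_p": res.pearson_p,
                "spearman_rho": res.spearman_rho, "spearman_p": res.spearman_p,
                "n_contrasts": nc, "contrast_rho": crho, "contrast_p": cp,
            })
    return pd.DataFrame(rows)
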