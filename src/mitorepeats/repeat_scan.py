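"""Enumeration of direct (DR) and inverted (IR) repeats on circular genomes.

The scanner aligns the genome against a second copy of itself (reverse
complemented for IRs) and rolls the two copies past each other one base at a
time; each relative offset is one *rotation state*, i.e. one (anti-)diagonal
of the self-comparison matrix. Local matched stretches along a diagonal are
candidate repeats. A candidate is accepted or rejected by a single acceptance
rule shared by the fast scanner and the exhaustive brute-force enumerator, so
the two can be compared as set-level oracles of each other.

Acceptance rule for a candidate arm alignment of length ``l`` with ``m``
mismatches (``i = l - m`` identical matches), under +1 match / -3 mismatch
local scoring:

* both arm ends must be matches;
* ``l >= min_length`` (default 2);
* default stringency: ``l >= 4*(m+1)`` for ``m >= 1`` (so 3 mismatches need
  at least 16 bp, one notch stricter than "a mismatch every three matches");
* relaxed stringency: ``m <= 2*i`` (two mismatches per match) with no length
  budget;
* a run of consecutive mismatches may be crossed only if it is at most
  ``low_match_extension`` (20) bp long, and a run of 4+ mismatches only if it
  is flanked by at least 4 consecutive matches on both sides (the break-even
  run under +1/-3 scoring).

Arms of a single repeat may not overlap each other. Reported repeats are
maximal: no acceptable candidate strictly contains another reported repeat's
arm pair, and within one diagonal only the best member of a family of
mutually overlapping candidates is kept (this collapses tandem/homopolymer
self-overlap families). Every repeat is canonically oriented
(``arm1_start <= arm2_start``) and reported exactly once even though the
rotation scan meets each DR in two rotation states and each IR in one state
that covers both arms simultaneously.

All public coordinates are 1-based inclusive; an arm wrapping the origin has
``end < start``.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .genome_io import MitoGenome, interval_contains

Kind = Literal["DR", "IR"]

_BASE_ORDER = "ACGTN"
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASE_ORDER):
    _ENC[ord(_b)] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N
_N = 4

BRUTE_FORCE_MAX_LENGTH = 2000


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the repeat acceptance rule.

    ``budget_factor`` is the per-mismatch length requirement of the default
    stringency (``l >= budget_factor * (m + 1)``); ``stringency="relaxed"``
    replaces the budget with the two-mismatches-per-match density cap.
    """

    match_reward: int = 1
    mismatch_penalty: int = 3
    min_length: int = 2
    budget_factor: int = 4
    low_match_extension: int = 20
    stringency: str = "default"

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if self.mismatch_penalty < 0:
            raise ValueError("mismatch_penalty must be non-negative")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.stringency not in ("default", "relaxed"):
            raise ValueError(f"unknown stringency preset {self.stringency!r}")

    @classmethod
    def default(cls, **kw) -> "ScanParams":
        return cls(**kw)

    @classmethod
    def relaxed(cls, **kw) -> "ScanParams":
        kw.setdefault("stringency", "relaxed")
        return cls(**kw)


@dataclass(frozen=True, order=True)
class Repeat:
    """One direct or inverted repeat occurrence (canonically oriented)."""

    kind: str
    arm1_start: int
    arm1_end: int
    arm2_start: int
    arm2_end: int
    length: int
    matches: int
    mismatches: int
    spacer: int

    def __post_init__(self) -> None:
        if self.matches + self.mismatches != self.length:
            raise ValueError("matches + mismatches must equal length")
        if self.matches < 1:
            raise ValueError("a repeat needs at least one match")


@dataclass
class RepeatSet:
    """A canonical, duplicate-free, maximality-filtered collection of repeats."""

    accession: str
    kind: str
    params: ScanParams
    genome_length: int
    repeats: list[Repeat] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.repeats)

    def __iter__(self):
        return iter(self.repeats)

    def signature_multiset(self) -> list[tuple[str, int, int, int]]:
        """Rotation-invariant multiset of (kind, length, matches, spacer)."""
        return sorted((r.kind, r.length, r.matches, r.spacer) for r in self.repeats)

    def coordinate_keys(self) -> set[tuple]:
        return {(r.kind, r.arm1_start, r.arm1_end, r.arm2_start, r.arm2_end) for r in self.repeats}


# ---------------------------------------------------------------------------
# Shared acceptance-rule machinery
# ---------------------------------------------------------------------------

def _encode(sequence: str) -> np.ndarray:
    arr = _ENC[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGTN")
    return arr


class _DiagonalContext:
    """Precomputed per-diagonal arrays used by the acceptance rule.

    ``M`` is the circular match profile of one rotation state (True = the two
    aligned bases match and neither is N).
    """

    __slots__ = ("L", "M2", "cum", "mism2", "ucum", "upos", "lastmatch2")

    def __init__(self, M: np.ndarray, params: ScanParams):
        L = M.size
        self.L = L
        M2 = np.concatenate([M, M])
        self.M2 = M2
        self.cum = np.concatenate([[0], np.cumsum(M2)])
        self.mism2 = np.flatnonzero(~M2).tolist()
        # mismatch runs on the circle and their crossability
        U2lin = np.zeros(2 * L, dtype=bool)
        if not M.all():
            if M.any():
                mm = ~M
                starts = np.flatnonzero(mm & ~np.roll(mm, 1))
                ends = np.flatnonzero(mm & ~np.roll(mm, -1))
                if ends.size and starts.size and ends[0] < starts[0]:
                    ends = np.roll(ends, -1)
                rl = (ends - starts) % L + 1
                bad = rl > params.low_match_extension
                need4 = (rl >= 4) & ~bad
                if need4.any():
                    cm3 = np.concatenate([[0], np.cumsum(np.concatenate([M, M, M]))])
                    before = cm3[starts + L] - cm3[starts + L - 4]
                    after = cm3[ends + L + 5] - cm3[ends + L + 1]
                    bad |= need4 & ((before < 4) | (after < 4))
                if bad.any():
                    diff = np.zeros(2 * L + 1, dtype=np.int64)
                    np.add.at(diff, starts[bad], 1)
                    np.add.at(diff, starts[bad] + rl[bad], -1)
                    cov = np.cumsum(diff[:-1]) > 0
                    U2lin = cov | np.concatenate([cov[L:], cov[:L]])
            else:
                U2lin[:] = True  # no matches at all: nothing is crossable
        self.ucum = np.concatenate([[0], np.cumsum(U2lin)])
        self.upos = np.flatnonzero(U2lin).tolist()  # sorted uncrossable positions
        self.lastmatch2 = np.maximum.accumulate(np.where(M2, np.arange(2 * L), -1)).tolist()

    def first_uncrossable_at_or_after(self, p: int) -> int:
        j = bisect_left(self.upos, p)
        return self.upos[j] if j < len(self.upos) else 2 * self.L

    def window_ok(self, s: int, e: int, cap: int, params: ScanParams) -> bool:
        """Full acceptance check for the window [s, e] on this diagonal."""
        l = e - s + 1
        if l < params.min_length or l > cap:
            return False
        if not (self.M2[s] and self.M2[e]):
            return False
        i = int(self.cum[e + 1] - self.cum[s])
        m = l - i
        if m > 0:
            if params.stringency == "default":
                if l < params.budget_factor * (m + 1):
                    return False
            else:
                if 3 * m > 2 * l:
                    return False
        return self.ucum[e + 1] - self.ucum[s] == 0


def _arith_mask(l: np.ndarray, m: np.ndarray, params: ScanParams) -> np.ndarray:
    ok = l >= params.min_length
    if params.stringency == "default":
        ok &= (m == 0) | (l >= params.budget_factor * (m + 1))
    else:
        ok &= 3 * m <= 2 * l
    return ok


# ---------------------------------------------------------------------------
# Window discovery: fast rolling scan
# ---------------------------------------------------------------------------

def _scan_diagonal(ctx: _DiagonalContext, caps: np.ndarray, extra_starts: Iterable[int],
                   params: ScanParams) -> set[tuple[int, int]]:
    """All per-diagonal-maximal acceptable windows (s, e) of one rotation state.

    Walks from the first match of every match run (plus any explicitly
    supplied starts) to the farthest acceptable end; full-cap windows whose
    start lies mid-run (possible only where the arm-overlap cap binds) are
    swept separately in vectorized form.
    """
    L = ctx.L
    M = ctx.M2[:L]
    windows: set[tuple[int, int]] = set()
    minlen = params.min_length
    bf = params.budget_factor
    default = params.stringency == "default"
    mism2 = ctx.mism2
    lastmatch2 = ctx.lastmatch2
    n_mism = len(mism2)

    if M.any():
        run_starts = set(np.flatnonzero(M & ~np.roll(M, 1)).tolist())
        run_starts.update(int(s) for s in extra_starts if M[s])
        for s in sorted(run_starts):
            cap = int(caps[s])
            if cap < minlen:
                continue
            hi = s + cap - 1
            fu = ctx.first_uncrossable_at_or_after(s)
            if fu - 1 < hi:
                hi = fu - 1
            if hi - s + 1 < minlen:
                continue
            j0 = bisect_left(mism2, s)
            first_mm = mism2[j0] if j0 < n_mism else 2 * L
            best = -1
            e0 = lastmatch2[min(first_mm - 1, hi)]
            if e0 - s + 1 >= minlen:
                best = e0
            k = 1
            span = hi - s + 1
            while True:
                if default:
                    if bf * (k + 1) > span:
                        break
                else:
                    if 3 * k > 2 * span:
                        break
                if j0 + k - 1 >= n_mism:
                    break
                qk = mism2[j0 + k - 1]
                if qk > hi:
                    break
                next_mm = mism2[j0 + k] if j0 + k < n_mism else 2 * L
                e_k = lastmatch2[min(next_mm - 1, hi)]
                if e_k > qk:
                    l = e_k - s + 1
                    if l >= minlen and ((bf * (k + 1) <= l) if default else (3 * k <= 2 * l)):
                        if e_k > best:
                            best = e_k
                k += 1
            if best >= s:
                windows.add((s, best))

    # full-cap sliding windows (cap-bound maxima whose start is mid-run)
    s_arr = np.arange(L)
    e_arr = s_arr + caps - 1
    valid = (caps >= minlen) & ctx.M2[s_arr] & ctx.M2[np.minimum(e_arr, 2 * L - 1)]
    if valid.any():
        ss = s_arr[valid]
        ee = e_arr[valid]
        ll = ee - ss + 1
        mm = ll - (ctx.cum[ee + 1] - ctx.cum[ss])
        ok = _arith_mask(ll, mm, params)
        ok &= (ctx.ucum[ee + 1] - ctx.ucum[ss]) == 0
        for s, e in zip(ss[ok].tolist(), ee[ok].tolist()):
            windows.add((s, e))
    return windows


# ---------------------------------------------------------------------------
# Window discovery: exhaustive brute force
# ---------------------------------------------------------------------------

def _brute_diagonal(ctx: _DiagonalContext, caps: np.ndarray, params: ScanParams) -> set[tuple[int, int]]:
    """Every acceptable window (s, e) of one rotation state, by enumeration."""
    L = ctx.L
    M = ctx.M2[:L]
    starts = np.flatnonzero(M)
    if starts.size == 0:
        return set()
    max_cap = int(caps.max())
    if max_cap < params.min_length:
        return set()
    offsets = np.arange(params.min_length - 1, max_cap)
    e_mat = starts[:, None] + offsets[None, :]
    l_mat = e_mat - starts[:, None] + 1
    mask = l_mat <= caps[starts][:, None]
    mask &= ctx.M2[np.minimum(e_mat, 2 * L - 1)]
    i_mat = ctx.cum[np.minimum(e_mat + 1, 2 * L)] - ctx.cum[starts][:, None]
    m_mat = l_mat - i_mat
    mask &= _arith_mask(l_mat, m_mat, params)
    mask &= (ctx.ucum[np.minimum(e_mat + 1, 2 * L)] - ctx.ucum[starts][:, None]) == 0
    si, oi = np.nonzero(mask)
    return set(zip(starts[si].tolist(), e_mat[si, oi].tolist()))


# ---------------------------------------------------------------------------
# Shared post-processing
# ---------------------------------------------------------------------------

def _remove_contained(windows: set[tuple[int, int]], L: int) -> list[tuple[int, int]]:
    """Drop windows strictly contained in another window of the same diagonal."""
    if len(windows) <= 1:
        return sorted(windows)
    entries = []
    for idx, (s, e) in enumerate(sorted(windows)):
        entries.append((s, e, idx))
        entries.append((s + L, e + L, idx))
    entries.sort(key=lambda t: (t[0], -t[1]))
    wlist = sorted(windows)
    dominated = [False] * len(wlist)
    max_e = -1
    for s, e, idx in entries:
        if e <= max_e:
            dominated[idx] = True
        if e > max_e:
            max_e = e
    return [w for w, d in zip(wlist, dominated) if not d]


def _suppress_families(windows: list[tuple[int, int]], L: int) -> list[tuple[int, int]]:
    """Keep one window per connected component of mutually overlapping windows.

    The survivor is the longest window of the component; ties go to the
    smallest start measured circularly from the component's own first start,
    which keeps the choice covariant under genome rotation.
    """
    if len(windows) <= 1:
        return list(windows)
    ws = sorted(windows)
    components: list[list[tuple[int, int]]] = []
    cur = [ws[0]]
    cur_end = ws[0][1]
    for w in ws[1:]:
        if w[0] <= cur_end:
            cur.append(w)
            cur_end = max(cur_end, w[1])
        else:
            components.append(cur)
            cur = [w]
            cur_end = w[1]
    components.append(cur)
    # merge across the origin: the final component may wrap past L and absorb
    # leading components; keep its own first window as the circular arc start
    if len(components) > 1:
        wrap_end = max(e for _, e in components[-1])
        if wrap_end >= L:
            wrapped = components.pop()
            while components and min(s for s, _ in components[0]) <= wrap_end - L:
                absorbed = components.pop(0)
                wrapped += absorbed
                wrap_end = max(wrap_end, max(e for _, e in absorbed) + L)
            components.insert(0, wrapped)
    out = []
    for comp in components:
        hull_start = comp[0][0]
        rel_end = max((w[0] - hull_start) % L + (w[1] - w[0]) for w in comp)
        if rel_end + 1 >= L:  # component covers the full circle
            hull_start = 0
        best = min(comp, key=lambda w: (-(w[1] - w[0] + 1), (w[0] - hull_start) % L))
        out.append(best)
    return out


def _pair_contains(xs: np.ndarray, xe: np.ndarray, ys: np.ndarray, ye: np.ndarray,
                   L: int) -> np.ndarray:
    """Boolean [candidate, container] matrix: container arm [ys,ye] contains [xs,xe].

    Arms are unrolled circular intervals with start in [0, L); a container
    wrapping the origin reaches candidates near the origin via the +L image.
    """
    c1 = (ys[None, :] <= xs[:, None]) & (xe[:, None] <= ye[None, :])
    c2 = (ys[None, :] <= xs[:, None] + L) & (xe[:, None] + L <= ye[None, :])
    return c1 | c2


def _nested_filter(repeats: list[Repeat], L: int) -> list[Repeat]:
    """Remove repeats whose arm pair is strictly nested in a longer repeat's."""
    if len(repeats) <= 1:
        return list(repeats)
    reps = sorted(repeats, key=lambda r: -r.length)
    lengths = np.array([r.length for r in reps])
    a1s = np.array([r.arm1_start - 1 for r in reps])
    a2s = np.array([r.arm2_start - 1 for r in reps])
    a1e = a1s + lengths - 1
    a2e = a2s + lengths - 1
    kept: list[Repeat] = []
    for length in np.unique(lengths)[::-1].tolist():
        grp = np.flatnonzero(lengths == length)
        nb = int(np.searchsorted(-lengths, -length))  # containers: strictly longer
        if nb == 0:
            kept.extend(reps[i] for i in grp.tolist())
            continue
        bs1, be1 = a1s[:nb], a1e[:nb]
        bs2, be2 = a2s[:nb], a2e[:nb]
        in11 = _pair_contains(a1s[grp], a1e[grp], bs1, be1, L)
        in22 = _pair_contains(a2s[grp], a2e[grp], bs2, be2, L)
        in12 = _pair_contains(a1s[grp], a1e[grp], bs2, be2, L)
        in21 = _pair_contains(a2s[grp], a2e[grp], bs1, be1, L)
        nested = ((in11 & in22) | (in12 & in21)).any(axis=1)
        kept.extend(reps[i] for i, n in zip(grp.tolist(), nested.tolist()) if not n)
    return kept


def _spacer(a1s0: int, a2s0: int, length: int, L: int) -> int:
    e1 = (a1s0 + length - 1) % L
    e2 = (a2s0 + length - 1) % L
    gap_cw = (a2s0 - e1 - 1) % L
    gap_ccw = (a1s0 - e2 - 1) % L
    return int(min(gap_cw, gap_ccw))


def _build_repeat(kind: str, s: int, e: int, ctx: _DiagonalContext,
                  arm2_start0_of, L: int) -> Repeat:
    l = e - s + 1
    i = int(ctx.cum[e + 1] - ctx.cum[s])
    a1s0 = s % L
    a2s0 = arm2_start0_of(s, e) % L
    if (a2s0, (a2s0 + l - 1) % L) < (a1s0, (a1s0 + l - 1) % L):
        a1s0, a2s0 = a2s0, a1s0
    return Repeat(
        kind=kind,
        arm1_start=a1s0 + 1, arm1_end=(a1s0 + l - 1) % L + 1,
        arm2_start=a2s0 + 1, arm2_end=(a2s0 + l - 1) % L + 1,
        length=l, matches=i, mismatches=l - i,
        spacer=_spacer(a1s0, a2s0, l, L),
    )


# ---------------------------------------------------------------------------
# Diagonal iteration
# ---------------------------------------------------------------------------

def _iter_diagonals(arr: np.ndarray, kind: str):
    """Yield (match_profile, caps_per_start, extra_starts, arm2_locator) per rotation state."""
    L = arr.size
    idx = np.arange(L)
    if kind == "DR":
        for d in range(1, L // 2 + 1):
            partner = arr[(idx + d) % L]
            M = (arr == partner) & (arr != _N) & (partner != _N)
            caps = np.full(L, min(d, L - d), dtype=np.int64)

            def arm2(s, e, d=d):
                return s + d

            yield M, caps, (), arm2
    else:
        for c in range(L):
            pidx = (c - idx) % L
            partner = arr[pidx]
            M = (arr == _COMP[partner]) & (arr != _N) & (partner != _N)
            T = (c - 2 * idx) % L
            caps = (T + 1) // 2
            # starts whose left extension is blocked by the reflection fixed point
            extra = np.flatnonzero(T >= L - 2)

            def arm2(s, e, c=c):
                return c - e

            yield M, caps, extra.tolist(), arm2


def _finalize(all_repeats: list[Repeat], accession: str, kind: str,
              params: ScanParams, L: int) -> RepeatSet:
    seen: dict[tuple, Repeat] = {}
    for r in all_repeats:
        key = (r.kind, r.arm1_start, r.arm1_end, r.arm2_start, r.arm2_end)
        seen.setdefault(key, r)
    kept = _nested_filter(list(seen.values()), L)
    kept.sort()
    return RepeatSet(accession=accession, kind=kind, params=params,
                     genome_length=L, repeats=kept)


def _validate_genome(genome: MitoGenome, params: ScanParams) -> np.ndarray:
    if genome.length < 2 * params.min_length:
        raise ValueError(
            f"genome of length {genome.length} is shorter than 2*min_length={2 * params.min_length}")
    return _encode(genome.sequence)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def find_repeats(genome: MitoGenome, kind: Kind, params: ScanParams | None = None) -> RepeatSet:
    """Enumerate all maximal direct or inverted repeats of a circular genome."""
    params = params or ScanParams()
    arr = _validate_genome(genome, params)
    L = arr.size
    out: list[Repeat] = []
    for M, caps, extra, arm2 in _iter_diagonals(arr, kind):
        if not M.any():
            continue
        ctx = _DiagonalContext(M, params)
        windows = _scan_diagonal(ctx, caps, extra, params)
        windows = _remove_contained(windows, L)
        windows = _suppress_families(windows, L)
        for s, e in windows:
            out.append(_build_repeat(kind, s, e, ctx, arm2, L))
    return _finalize(out, genome.accession, kind, params, L)


def brute_force_repeats(genome: MitoGenome, kind: Kind, params: ScanParams | None = None) -> RepeatSet:
    """Exhaustive reference enumerator; the semantics find_repeats must match.

    Enumerates every candidate arm pair of every rotation state, applies the
    same acceptance rule, and then the same canonicalization, family
    suppression and maximality filtering. Guarded to genomes <= 2000 bp.
    """
    params = params or ScanParams()
    if genome.length > BRUTE_FORCE_MAX_LENGTH:
        raise ValueError(f"brute-force oracle is limited to genomes <= {BRUTE_FORCE_MAX_LENGTH} bp")
    arr = _validate_genome(genome, params)
    L = arr.size
    out: list[Repeat] = []
    for M, caps, _extra, arm2 in _iter_diagonals(arr, kind):
        if not M.any():
            continue
        ctx = _DiagonalContext(M, params)
        windows = _brute_diagonal(ctx, caps, params)
        windows = _remove_contained(windows, L)
        windows = _suppress_families(windows, L)
        for s, e in windows:
            out.append(_build_repeat(kind, s, e, ctx, arm2, L))
    return _finalize(out, genome.accession, kind, params, L)


def locate_junction_repeat(genome: MitoGenome, j1: int, j2: int,
                           params: ScanParams | None = None) -> Repeat | None:
    """The maximal IR whose arms terminate at j1 (plus strand) and j2 (minus strand).

    Extends outward from the junction under +1/-3 local scoring and keeps the
    match-terminated extension with the highest running score (ties go to the
    longer one). Returns None when the junction bases themselves mismatch or
    no extension of at least ``min_length`` scores positively — junctions with
    no repeat at all are a real observation, not an error.
    """
    params = params or ScanParams()
    arr = _validate_genome(genome, params)
    L = arr.size
    if not (1 <= j1 <= L and 1 <= j2 <= L):
        raise ValueError(f"junction coordinates ({j1}, {j2}) out of range 1..{L}")
    p1 = j1 - 1
    p2 = j2 - 1
    D = (p1 - p2) % L
    if D == 0:
        return None
    t_max = (D - 1) // 2
    best_score = 0
    best_t = -1
    score = 0
    max_seen = 0
    for t in range(t_max + 1):
        b1 = arr[(p1 - t) % L]
        b2 = arr[(p2 + t) % L]
        if b1 != _N and b2 != _N and b1 == _COMP[b2]:
            score += params.match_reward
            if score >= best_score:
                best_score = score
                best_t = t
        else:
            score -= params.mismatch_penalty
        max_seen = max(max_seen, score)
        if score <= max_seen - params.mismatch_penalty * params.low_match_extension:
            break
    if best_t < 0 or best_score <= 0:
        return None
    l = best_t + 1
    if l < params.min_length:
        return None
    matches = 0
    for t in range(l):
        b1 = arr[(p1 - t) % L]
        b2 = arr[(p2 + t) % L]
        if b1 != _N and b2 != _N and b1 == _COMP[b2]:
            matches += 1
    a1s0 = (p1 - best_t) % L
    a2s0 = p2
    if (a2s0, (a2s0 + l - 1) % L) < (a1s0, (a1s0 + l - 1) % L):
        a1s0, a2s0 = a2s0, a1s0
    return Repeat(
        kind="IR",
        arm1_start=a1s0 + 1, arm1_end=(a1s0 + l - 1) % L + 1,
        arm2_start=a2s0 + 1, arm2_end=(a2s0 + l - 1) % L + 1,
        length=l, matches=matches, mismatches=l - matches,
        spacer=_spacer(a1s0, a2s0, l, L),
    )


def scan_gene_regions(repeats: RepeatSet, regions: Sequence[tuple[int, int]]) -> RepeatSet:
    """Keep only repeats with both arms fully inside the gene-region union."""
    L = repeats.genome_length
    kept = [
        r for r in repeats.repeats
        if interval_contains(regions, r.arm1_start, r.arm1_end, L)
        and interval_contains(regions, r.arm2_start, r.arm2_end, L)
    ]
    return replace_repeats(repeats, kept)


def replace_repeats(rs: RepeatSet, repeats: list[Repeat]) -> RepeatSet:
    return RepeatSet(accession=rs.accession, kind=rs.kind, params=rs.params,
                     genome_length=rs.genome_length, repeats=list(repeats))
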