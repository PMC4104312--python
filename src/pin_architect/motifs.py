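"""Ordered loop-motif scanning and clade-level presence matrices.

The canonical PIN loop is modular: a series of conserved motifs that always
occur in the same order, including the four highly conserved regions
HC1-HC4 and phosphorylation motifs such as ``TPRXS[SN]`` (the PINOID
target).  Scanning assigns each motif of an ordered library its best
gapless window subject to the order constraint (windows non-overlapping and
increasing with rank), via a maximum-total-identity dynamic program, and
then calls one of six presence states per motif:

``present``        identity >= 0.70 over non-wildcard columns
``divergent``      similarity >= 0.40, identity < 0.70, both rank
                   neighbours located in order
``partial``        >= 50% of the motif's columns overlap a truncated loop
                   edge and match at >= 0.70 identity
``absent``         none of the above, loop observed over the expected span
``no_data``        the loop is truncated over the motif's expected span
``no_consensus``   clade level only: no state reaches a strict majority

Pattern syntax: plain residues, ``X`` wildcard (matches anything, excluded
from denominators), ``[..]`` alternatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio.Align import substitution_matrices

MOTIF_STATES = ("present", "partial", "divergent", "no_consensus", "absent", "no_data")

MotifState = str


@lru_cache(maxsize=1)
def _blosum62():
    return substitution_matrices.load("BLOSUM62")


def _positive(a: str, b: str) -> bool:
    """Identical residue or positive log-odds substitution score."""
    if a == b:
        return True
    mat = _blosum62()
    try:
        return mat[a, b] > 0
    except (KeyError, IndexError):
        return False


@dataclass(frozen=True)
class MotifDef:
    """One loop motif: a residue pattern with a fixed rank in the loop order."""

    name: str
    pattern: str
    rank: int
    hc_group: Optional[str] = None
    phospho: bool = False

    def __post_init__(self) -> None:
        if len(self.columns()) < 4:
            raise ValueError(f"motif {self.name!r}: pattern shorter than 4 columns")
        if self.hc_group is not None and self.hc_group not in {"HC1", "HC2", "HC3", "HC4"}:
            raise ValueError(f"motif {self.name!r}: bad hc_group {self.hc_group!r}")

    def columns(self) -> Tuple[Optional[frozenset], ...]:
        """Parse the pattern into per-column residue sets (None = wildcard X)."""
        cols: List[Optional[frozenset]] = []
        i = 0
        pat = self.pattern
        while i < len(pat):
            ch = pat[i]
            if ch == "[":
                j = pat.index("]", i)
                cols.append(frozenset(pat[i + 1 : j]))
                i = j + 1
            elif ch == "X":
                cols.append(None)
                i += 1
            else:
                cols.append(frozenset(ch))
                i += 1
        return tuple(cols)

    def __len__(self) -> int:
        return len(self.columns())


@dataclass(frozen=True)
class ScanThresholds:
    present_identity: float = 0.70
    divergent_similarity: float = 0.40
    partial_coverage: float = 0.50


@dataclass
class MotifHit:
    """Scan result for one motif of the library."""

    name: str
    start: Optional[int]  # 0-based window start in the loop, None if unassigned
    end: Optional[int]
    identity: float
    similarity: float
    state: MotifState


def _window_scores(loop: str, cols: Sequence[Optional[frozenset]], start: int
                   ) -> Tuple[float, float]:
    """(identity, similarity) of a gapless window; wildcards excluded from denominators."""
    ident = simil = denom = 0
    for k, col in enumerate(cols):
        if col is None:
            continue
        denom += 1
        res = loop[start + k]
        if res in col:
            ident += 1
            simil += 1
        elif any(_positive(res, c) for c in col):
            simil += 1
    if denom == 0:
        return 0.0, 0.0
    return ident / denom, simil / denom


def _best_assignment(loop: str, library: Sequence[MotifDef]
                     ) -> Tuple[float, List[Optional[int]]]:
    """Maximum-total-identity order-respecting window assignment.

    Returns the optimal total identity and one start per motif (None =
    skipped, e.g. infeasible for lack of room).  Ties prefer assigning a
    window over skipping, then smaller starts.
    """
    L = len(loop)
    cols_list = [m.columns() for m in library]
    lens = [len(c) for c in cols_list]
    n = len(library)

    # identity of motif i's window at each feasible start
    ident = [
        [_window_scores(loop, cols_list[i], s)[0] for s in range(L - lens[i] + 1)]
        for i in range(n)
    ]

    from functools import lru_cache as _lru

    @_lru(maxsize=None)
    def dp(i: int, p: int) -> Tuple[float, int]:
        """Best (score, assigned_count) using motifs i.. with windows starting >= p."""
        if i == n:
            return 0.0, 0
        best = dp(i + 1, p)  # skip motif i
        for s in range(p, L - lens[i] + 1):
            sub_score, sub_cnt = dp(i + 1, s + lens[i])
            cand = (ident[i][s] + sub_score, sub_cnt + 1)
            if cand > best:
                best = cand
        return best

    starts: List[Optional[int]] = []
    score, _ = dp(0, 0) if n else (0.0, 0)
    p = 0
    for i in range(n):
        target = dp(i, p)
        chosen: Optional[int] = None
        if dp(i + 1, p) != target:
            for s in range(p, L - lens[i] + 1):
                sub_score, sub_cnt = dp(i + 1, s + lens[i])
                if (ident[i][s] + sub_score, sub_cnt + 1) == target:
                    chosen = s
                    break
        else:
            # skipping is optimal only if no assignment matches the target
            assign_possible = False
            for s in range(p, L - lens[i] + 1):
                sub_score, sub_cnt = dp(i + 1, s + lens[i])
                if (ident[i][s] + sub_score, sub_cnt + 1) == target:
                    assign_possible = True
                    chosen = s
                    break
            if not assign_possible:
                chosen = None
        starts.append(chosen)
        if chosen is not None:
            p = chosen + lens[i]
    dp.cache_clear()
    return score, starts


def _edge_partial(loop: str, motif: MotifDef, side: str,
                  thresholds: ScanThresholds) -> bool:
    """Does >= partial_coverage of the motif match a truncated loop edge at >= 0.70 identity?"""
    cols = motif.columns()
    m = len(cols)
    min_overlap = max(1, int(-(-m * thresholds.partial_coverage // 1)))  # ceil
    for k in range(min_overlap, m):
        if k > len(loop):
            break
        if side == "left":
            sub = cols[m - k :]
            window = loop[:k]
        else:
            sub = cols[:k]
            window = loop[-k:]
        ident = denom = 0
        for c, res in zip(sub, window):
            if c is None:
                continue
            denom += 1
            if res in c:
                ident += 1
        if denom > 0 and ident / denom >= thresholds.present_identity:
            return True
    return False


def scan_loop(
    loop: Optional[str],
    library: Sequence[MotifDef],
    thresholds: ScanThresholds = ScanThresholds(),
    complete_left: bool = True,
    complete_right: bool = True,
) -> List[MotifHit]:
    """Scan a loop against an ordered motif library and call presence states.

    ``complete_left`` / ``complete_right`` say whether the loop's N-side and
    C-side ends are fully observed; truncated ends enable the ``partial``
    and ``no_data`` states.
    """
    if not library:
        raise ValueError("empty motif library")
    ranks = [m.rank for m in library]
    if any(b <= a for a, b in zip(ranks, ranks[1:])):
        raise ValueError("motif library must be ordered by strictly increasing rank")
    if loop is None or not loop:
        return [MotifHit(m.name, None, None, 0.0, 0.0, "no_data") for m in library]

    _, starts = _best_assignment(loop, library)

    hits: List[MotifHit] = []
    located = []  # index -> bool (has a window)
    idents, simils = [], []
    for i, motif in enumerate(library):
        s = starts[i]
        if s is None:
            idents.append(0.0)
            simils.append(0.0)
            located.append(False)
        else:
            ident, simil = _window_scores(loop, motif.columns(), s)
            idents.append(ident)
            simils.append(simil)
            located.append(True)

    # ranks located confidently, used for the no_data span heuristic
    present_idx = [i for i in range(len(library))
                   if located[i] and idents[i] >= thresholds.present_identity]
    first_present = min(present_idx) if present_idx else len(library)
    last_present = max(present_idx) if present_idx else -1

    for i, motif in enumerate(library):
        s = starts[i]
        ident, simil = idents[i], simils[i]
        if located[i] and ident >= thresholds.present_identity:
            state = "present"
        else:
            neighbours_ok = True
            if i > 0:
                neighbours_ok &= located[i - 1]
            if i < len(library) - 1:
                neighbours_ok &= located[i + 1]
            if (located[i] and simil >= thresholds.divergent_similarity
                    and neighbours_ok):
                state = "divergent"
            elif not complete_left and _edge_partial(loop, motif, "left", thresholds):
                state = "partial"
            elif not complete_right and _edge_partial(loop, motif, "right", thresholds):
                state = "partial"
            elif not complete_left and i < first_present:
                state = "no_data"
            elif not complete_right and i > last_present:
                state = "no_data"
            else:
                state = "absent"
        end = s + len(motif) if s is not None else None
        hits.append(MotifHit(motif.name, s, end, ident, simil, state))
    return hits


def detect_repeats(
    loop: str,
    unit: Sequence[MotifDef],
    max_copies: int = 10,
    thresholds: ScanThresholds = ScanThresholds(),
    max_gap: int = 12,
) -> Tuple[int, List[Tuple[int, int]], Optional[Tuple[int, int]]]:
    """Greedy left-to-right count of consecutive occurrences of a motif unit.

    Each copy is anchored at the next present-level occurrence (identity >=
    0.70) of the first unit motif; the remaining unit motifs must follow in
    order within ``max_gap`` residues, each present or at least divergent
    (similarity >= 0.40), taking the best-scoring window in the
    neighbourhood.  Returns (copy count, full-copy spans, partial trailing
    span or None).
    """
    if not unit:
        raise ValueError("empty repeat unit")
    pos = 0
    copies: List[Tuple[int, int]] = []
    partial_span: Optional[Tuple[int, int]] = None

    def find_anchor_window(motif: MotifDef, lo: int, hi: Optional[int]) -> Optional[int]:
        """Earliest present-level window for the copy's first motif."""
        cols = motif.columns()
        last = len(loop) - len(cols)
        if hi is not None:
            last = min(last, hi)
        for s in range(lo, last + 1):
            ident, _ = _window_scores(loop, cols, s)
            if ident >= thresholds.present_identity:
                return s
        return None

    def find_follower(motif: MotifDef, lo: int, hi: int) -> Optional[int]:
        """Best present-or-divergent window in [lo, hi]."""
        cols = motif.columns()
        last = min(len(loop) - len(cols), hi)
        best, best_key = None, None
        for s in range(lo, last + 1):
            ident, simil = _window_scores(loop, cols, s)
            if ident >= thresholds.present_identity or \
                    simil >= thresholds.divergent_similarity:
                key = (ident, simil, -s)
                if best_key is None or key > best_key:
                    best, best_key = s, key
        return best

    first_copy = True
    while len(copies) < max_copies:
        span_start = None
        cur = pos
        matched = 0
        for k, motif in enumerate(unit):
            if k == 0:
                hi = None if first_copy else cur + max_gap
                s = find_anchor_window(motif, cur, hi)
            else:
                s = find_follower(motif, cur, cur + max_gap)
            if s is None:
                break
            if span_start is None:
                span_start = s
            cur = s + len(motif)
            matched += 1
        if matched == len(unit):
            copies.append((span_start, cur))
            pos = cur
            first_copy = False
        else:
            if matched > 0 and span_start is not None:
                partial_span = (span_start, cur)
            break
    return len(copies), copies, partial_span


def motif_matrix(
    scans: Mapping[str, Sequence[MotifHit]],
    clade_map,
) -> pd.DataFrame:
    """Aggregate per-sequence scans into a clade x motif state matrix.

    A clade's state for a motif is the strict-majority state over members
    with data (state != no_data); ``no_consensus`` when no state exceeds
    half of those members; ``no_data`` when no member covers the motif.
    Sequences missing from the clade map are excluded with a warning.
    """
    motif_names: List[str] = []
    for hits in scans.values():
        motif_names = [h.name for h in hits]
        break
    by_clade: Dict[str, List[Sequence[MotifHit]]] = {}
    for sid, hits in scans.items():
        clade = clade_map.sequence_to_clade.get(sid)
        if clade is None:
            warnings.warn(f"sequence {sid!r} has no clade assignment; excluded")
            continue
        by_clade.setdefault(clade, []).append(hits)

    rows = {}
    for clade in sorted(by_clade):
        states = {}
        for j, name in enumerate(motif_names):
            member_states = [hits[j].state for hits in by_clade[clade]]
            with_data = [s for s in member_states if s != "no_data"]
            if not with_data:
                states[name] = "no_data"
                continue
            best, best_n = None, 0
            for s in MOTIF_STATES:
                n = with_data.count(s)
                if n > best_n:
                    best, best_n = s, n
            if best_n * 2 > len(with_data):
                states[name] = best
            else:
                states[name] = "no_consensus"
        rows[clade] = states
    return pd.DataFrame.from_dict(rows, orient="index", columns=motif_names)


# ---------------------------------------------------------------------------
# Library I/O and the shipped default library


def default_motif_library() -> List[MotifDef]:
    """The shipped default loop-motif library.

    The published motif inventory exists only as a figure; this library is
    seeded with the explicitly documented elements (the four HC regions and
    the ``TPRXS[SN]`` phosphorylation motif that forms the thrice-motif
    repeat unit around HC2) completed with synthetic motifs matching the
    generator's canonical loop template.  Real-data users should supply
    their own library file.
    """
    return [
        MotifDef("m1", "GEDKFSQ", rank=1),
        MotifDef("hc1", "DYSERNDEFVE", rank=2, hc_group="HC1"),
        MotifDef("rptA", "TPRXS[SN]", rank=3, phospho=True),
        MotifDef("rptB", "KFDEGA", rank=4),
        MotifDef("rptC", "SMELYP", rank=5),
        MotifDef("hc2", "SNAWDKLGREQM", rank=6, hc_group="HC2"),
        MotifDef("m7", "PKNSDAG", rank=7),
        MotifDef("hc3", "WFSPASSENRLY", rank=8, hc_group="HC3"),
        MotifDef("m9", "QNFAGED", rank=9),
        MotifDef("hc4", "YTPANPDEFSSV", rank=10, hc_group="HC4"),
    ]


#: The unit of three consecutive motifs repeated four times around HC2.
REPEAT_UNIT_NAMES = ("rptA", "rptB", "rptC")


def repeat_unit(library: Sequence[MotifDef]) -> List[MotifDef]:
    by_name = {m.name: m for m in library}
    return [by_name[n] for n in REPEAT_UNIT_NAMES if n in by_name]


def read_motif_library(path: str | Path) -> List[MotifDef]:
    """Read a motif library TSV (columns: name, pattern, rank, hc_group, phospho)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        out.append(
            MotifDef(
                name=row["name"],
                pattern=row["pattern"],
                rank=int(row["rank"]),
                hc_group=row["hc_group"] or None,
                phospho=str(row["phospho"]).lower() in {"true", "1", "yes"},
            )
        )
    out.sort(key=lambda m: m.rank)
    return out


def write_motif_library(library: Sequence[MotifDef], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("name\tpattern\trank\thc_group\tphospho\n")
        for m in library:
            fh.write(f"{m.name}\t{m.pattern}\t{m.rank}\t{m.hc_group or ''}\t{m.phospho}\n")
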