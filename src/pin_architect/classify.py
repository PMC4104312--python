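"""Canonical / semicanonical / noncanonical classification.

A PIN protein is canonical when its loop matches the consensus of the four
highly conserved regions HC1-HC4 at >= 50% pooled identity or >= 70% pooled
similarity, with every observable region located in order.  A clade is
canonical when >= 90% of its members (with data) are canonical, or by a
clear majority in clades with fewer than ten members; the symmetric rule
yields noncanonical clades, everything else is mixed.  Semicanonical
proteins (the PIN6/PIN12 situation) retain clear homology to the canonical
loop but lack at least one HC region.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from pin_architect.motifs import MotifDef, _best_assignment, _window_scores

HC_NAMES = ("HC1", "HC2", "HC3", "HC4")


@dataclass(frozen=True)
class HCConsensus:
    """Consensus strings for the four highly conserved loop regions."""

    hc1: str
    hc2: str
    hc3: str
    hc4: str

    def __post_init__(self) -> None:
        for name, pat in zip(HC_NAMES, self.patterns()):
            cols = MotifDef(name.lower(), pat, rank=1).columns()
            if len(cols) < 8:
                raise ValueError(f"{name} consensus shorter than 8 columns")

    def patterns(self) -> Tuple[str, str, str, str]:
        return (self.hc1, self.hc2, self.hc3, self.hc4)

    def as_motifs(self) -> List[MotifDef]:
        return [
            MotifDef(name.lower(), pat, rank=i + 1, hc_group=name)
            for i, (name, pat) in enumerate(zip(HC_NAMES, self.patterns()))
        ]

    @classmethod
    def from_library(cls, library: Sequence[MotifDef]) -> "HCConsensus":
        by_group = {m.hc_group: m.pattern for m in library if m.hc_group}
        missing = [n for n in HC_NAMES if n not in by_group]
        if missing:
            raise ValueError(f"library lacks HC regions: {missing}")
        return cls(*(by_group[n] for n in HC_NAMES))


@dataclass(frozen=True)
class ClassifyThresholds:
    pooled_identity: float = 0.50
    pooled_similarity: float = 0.70
    locate_identity: float = 0.40
    locate_similarity: float = 0.60
    min_observable: float = 0.50  # fraction of consensus columns that must be observed
    per_region_strict: bool = False  # require every region to pass individually


@dataclass
class RegionScore:
    name: str
    located: bool
    observable: bool
    start: Optional[int]
    identity: float
    similarity: float
    n_columns: int  # non-wildcard consensus columns


@dataclass
class HCScores:
    regions: List[RegionScore]
    identity: float  # pooled over observable regions
    similarity: float
    observable_fraction: float

    @property
    def regions_located(self) -> List[str]:
        return [r.name for r in self.regions if r.located]


@dataclass
class ProteinClassification:
    id: str
    hc_identity: float
    hc_similarity: float
    regions_located: List[str]
    label: str  # canonical | semicanonical | noncanonical | insufficient_data


def hc_score(
    loop: Optional[str],
    consensus: HCConsensus,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
    complete_left: bool = True,
    complete_right: bool = True,
) -> HCScores:
    """Locate HC1-HC4 in a loop and pool identity/similarity over them.

    Regions are located by best gapless window subject to the order
    constraint HC1 < HC2 < HC3 < HC4 (maximum-total-identity assignment).
    Identity = identical columns / non-wildcard consensus columns, pooled
    over the observable regions; similarity additionally counts positive
    BLOSUM62 substitutions.  Regions overlapping a truncated loop end are
    excluded from the denominator (unobservable).
    """
    motifs = consensus.as_motifs()
    ncols = [sum(1 for c in m.columns() if c is not None) for m in motifs]
    total_cols = sum(ncols)

    if loop is None or not loop:
        regions = [
            RegionScore(n, False, False, None, 0.0, 0.0, k)
            for n, k in zip(HC_NAMES, ncols)
        ]
        return HCScores(regions, 0.0, 0.0, 0.0)

    _, starts = _best_assignment(loop, motifs)

    region_scores: List[RegionScore] = []
    for i, motif in enumerate(motifs):
        s = starts[i]
        if s is None:
            region_scores.append(
                RegionScore(HC_NAMES[i], False, True, None, 0.0, 0.0, ncols[i])
            )
            continue
        ident, simil = _window_scores(loop, motif.columns(), s)
        located = (
            ident >= thresholds.locate_identity
            or simil >= thresholds.locate_similarity
        )
        region_scores.append(
            RegionScore(HC_NAMES[i], located, True, s, ident, simil, ncols[i])
        )

    # A truncated loop end renders flanking unlocated regions unobservable:
    # regions ranked before the first located one (left truncation) or after
    # the last located one (right truncation) are presumed lost to truncation.
    located_idx = [i for i, r in enumerate(region_scores) if r.located]
    first = min(located_idx) if located_idx else len(region_scores)
    last = max(located_idx) if located_idx else -1
    for i, r in enumerate(region_scores):
        if r.located:
            continue
        if (not complete_left and i < first) or (not complete_right and i > last):
            r.observable = False

    obs = [r for r in region_scores if r.observable]
    obs_cols = sum(r.n_columns for r in obs)
    if obs_cols == 0:
        pooled_ident = pooled_simil = 0.0
    else:
        pooled_ident = sum(r.identity * r.n_columns for r in obs) / obs_cols
        pooled_simil = sum(r.similarity * r.n_columns for r in obs) / obs_cols
    return HCScores(
        regions=region_scores,
        identity=pooled_ident,
        similarity=pooled_simil,
        observable_fraction=obs_cols / total_cols if total_cols else 0.0,
    )


def classify_protein(
    scores: HCScores,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
    id: str = "",
) -> ProteinClassification:
    """Apply the canonical rule to pooled HC scores.

    canonical: every observable region located and pooled identity >= 0.50
    or pooled similarity >= 0.70 (thresholds inclusive, configurable);
    semicanonical: >= 2 regions pass individually but >= 1 observable
    region is unlocated or failing; insufficient_data: less than half of
    the consensus columns observable; noncanonical otherwise.  In strict
    mode every region must pass individually for the canonical label.
    """

    def region_pass(r: RegionScore) -> bool:
        return r.located and (
            r.identity >= thresholds.pooled_identity
            or r.similarity >= thresholds.pooled_similarity
        )

    label: str
    if scores.observable_fraction < thresholds.min_observable:
        label = "insufficient_data"
    else:
        observable = [r for r in scores.regions if r.observable]
        all_located = all(r.located for r in observable) and observable
        pooled_ok = (
            scores.identity >= thresholds.pooled_identity
            or scores.similarity >= thresholds.pooled_similarity
        )
        if thresholds.per_region_strict:
            canonical = bool(observable) and all(region_pass(r) for r in observable)
        else:
            canonical = bool(all_located and pooled_ok)
        if canonical:
            label = "canonical"
        else:
            n_pass = sum(1 for r in observable if region_pass(r))
            n_fail = sum(1 for r in observable if not region_pass(r))
            if n_pass >= 2 and n_fail >= 1:
                label = "semicanonical"
            else:
                label = "noncanonical"
    return ProteinClassification(
        id=id,
        hc_identity=scores.identity,
        hc_similarity=scores.similarity,
        regions_located=scores.regions_located,
        label=label,
    )


def classify_clade(members: Sequence[ProteinClassification],
                   large_clade: int = 10,
                   canonical_fraction: float = 0.90) -> str:
    """Clade-level label from member labels.

    Clades with >= 10 informative members: canonical iff >= 90% of members
    with data are canonical (semicanonical members count against); the
    symmetric rule gives noncanonical; otherwise mixed.  Smaller clades use
    a strict majority.  All-insufficient clades are ``insufficient``.
    """
    labels = [m.label for m in members if m.label != "insufficient_data"]
    if not labels:
        return "insufficient"
    n = len(labels)
    counts = Counter(labels)
    n_can = counts.get("canonical", 0)
    n_noncan = counts.get("noncanonical", 0)
    if n >= large_clade:
        if n_can / n >= canonical_fraction:
            return "canonical"
        if n_noncan / n >= canonical_fraction:
            return "noncanonical"
        return "mixed"
    if n_can > n - n_can:
        return "canonical"
    if n_noncan > n - n_noncan:
        return "noncanonical"
    return "mixed"
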