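"""Per-position conservation profiles, consensus and banding on canonical coordinates.

Profiles are computed over canonical position labels so that partial,
EST-derived sequences contribute only to the positions they cover.
Identity denominators count only covering sequences; insertion residues
(labels like ``N97+2``) never contribute to canonical positions.  Band
schemes reproduce the printed band layouts used for the family-wide
analysis (100%, >99%, >95%, >90%) and the within-clade self-identity
analysis (100%, 95-99, 90-95, 70-90, 50-70, <50).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from pin_architect.domains import DomainPartition
from pin_architect.seqio import AMINO_ACIDS, MISSING_CELLS, AlignmentMatrix

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_EPS = 1e-9


@dataclass
class ConservationProfile:
    """Residue frequencies per canonical position.

    ``counts`` has one row per position (ordered as ``labels``) and one
    column per residue in the 20-letter alphabet.  Frequencies are counts
    normalised over covering sequences only; positions with zero coverage
    carry empty (all-zero) vectors.
    """

    labels: List[str]
    counts: np.ndarray  # (n_positions, 20) integer counts

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.labels), len(AMINO_ACIDS)):
            raise ValueError("counts shape does not match labels/alphabet")

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = self.counts / cov[:, None]
        freq[cov == 0] = 0.0
        return freq

    @property
    def modal_identity(self) -> np.ndarray:
        return self.frequencies.max(axis=1)

    @property
    def modal_residue(self) -> List[Optional[str]]:
        out: List[Optional[str]] = []
        cov = self.coverage
        arg = self.counts.argmax(axis=1)
        for i in range(len(self.labels)):
            out.append(AMINO_ACIDS[arg[i]] if cov[i] > 0 else None)
        return out

    def position_index(self) -> Dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}


@dataclass(frozen=True)
class Band:
    """One identity interval.  ``lo < x <= hi`` with configurable closures."""

    label: str
    lo: float
    hi: float
    lo_inclusive: bool = False
    hi_inclusive: bool = True

    def contains(self, x: float) -> bool:
        above = x > self.lo - _EPS if self.lo_inclusive else x > self.lo + _EPS
        below = x < self.hi + _EPS if self.hi_inclusive else x < self.hi - _EPS
        return above and below


@dataclass(frozen=True)
class BandScheme:
    """Ordered, disjoint identity bands (highest first)."""

    name: str
    bands: Tuple[Band, ...]

    def classify(self, identity: float) -> Optional[str]:
        for band in self.bands:
            if band.contains(identity):
                return band.label
        return None

    @property
    def labels(self) -> List[str]:
        return [b.label for b in self.bands]


#: Family-wide banding of highly conserved positions: 100% its own band,
#: then >99%, >95%, >90% as disjoint intervals (covers (0.90, 1]).
TABLE2_BANDS = BandScheme(
    "family",
    (
        Band("100%", 1.0, 1.0, lo_inclusive=True, hi_inclusive=True),
        Band(">99%", 0.99, 1.0, hi_inclusive=False),
        Band(">95%", 0.95, 0.99),
        Band(">90%", 0.90, 0.95),
    ),
)

#: Within-clade self-identity banding over all 312 positions (covers (0, 1]).
TABLE3_BANDS = BandScheme(
    "self_identity",
    (
        Band("100%", 1.0, 1.0, lo_inclusive=True, hi_inclusive=True),
        Band("95-99%", 0.95, 1.0, hi_inclusive=False),
        Band("90-95%", 0.90, 0.95),
        Band("70-90%", 0.70, 0.90),
        Band("50-70%", 0.50, 0.70),
        Band("<50%", 0.0, 0.50),
    ),
)


def _canonical_labels(region: str, n_len: int = 158, c_len: int = 154,
                      loop_max: int = 0) -> List[str]:
    if region == "n_domain":
        return [f"N{i}" for i in range(1, n_len + 1)]
    if region == "c_domain":
        return [f"C{i}" for i in range(1, c_len + 1)]
    if region == "tm":
        return [f"N{i}" for i in range(1, n_len + 1)] + [
            f"C{i}" for i in range(1, c_len + 1)
        ]
    if region == "loop":
        return [f"L{i}" for i in range(1, loop_max + 1)]
    raise ValueError(f"unknown region {region!r}")


def _iter_region(partition: DomainPartition, region: str):
    pairs = []
    if region in ("n_domain", "tm") and partition.n_domain is not None:
        pairs += list(zip(partition.n_labels, partition.n_domain))
    if region == "loop" and partition.loop is not None:
        pairs += list(zip(partition.loop_labels, partition.loop))
    if region in ("c_domain", "tm") and partition.c_domain is not None:
        pairs += list(zip(partition.c_labels, partition.c_domain))
    return pairs


def build_profile(
    partitions: Sequence[DomainPartition],
    region: str,
    n_len: int = 158,
    c_len: int = 154,
) -> ConservationProfile:
    """Count residues per canonical position over a set of partitions.

    ``region`` is one of ``n_domain``, ``c_domain``, ``loop`` or ``tm``
    (both transmembrane domains, 312 canonical positions).  Insertion
    residues and unknown residues (X) are excluded.  Raises if no partition
    has the region present.
    """
    loop_max = 0
    any_present = False
    for part in partitions:
        pairs = _iter_region(part, region)
        if pairs:
            any_present = True
        if region == "loop":
            for lab, _ in pairs:
                if lab and lab.startswith("L"):
                    loop_max = max(loop_max, int(lab[1:]))
    if not any_present:
        raise ValueError(f"no observations: region {region!r} absent in all inputs")

    labels = _canonical_labels(region, n_len=n_len, c_len=c_len, loop_max=loop_max)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(AMINO_ACIDS)), dtype=float)
    for part in partitions:
        for lab, res in _iter_region(part, region):
            if lab is None or "+" in lab:
                continue  # unlabeled or insertion residue
            if res not in _AA_INDEX:
                continue  # X: unknown residue, no observation
            pos = index.get(lab)
            if pos is not None:
                counts[pos, _AA_INDEX[res]] += 1
    return ConservationProfile(labels=labels, counts=counts)


def consensus(profile: ConservationProfile, floor: float = 0.5) -> str:
    """Modal residue per position; '.' where modal identity falls below ``floor``."""
    if not profile.labels:
        raise ValueError("empty profile")
    out = []
    ident = profile.modal_identity
    for i, res in enumerate(profile.modal_residue):
        if res is not None and ident[i] >= floor - _EPS:
            out.append(res)
        else:
            out.append(".")
    return "".join(out)


def band_counts(
    profile: ConservationProfile,
    scheme: BandScheme,
    min_coverage: int = 1,
) -> Tuple[Dict[str, int], int]:
    """Count positions per identity band.

    Positions with coverage below ``min_coverage`` are excluded from the
    banding and returned separately as the second element (insufficient
    data).  Positions whose identity falls outside the scheme's range are
    also counted as excluded.  The in-band counts partition the banded
    positions.
    """
    counts = {label: 0 for label in scheme.labels}
    excluded = 0
    cov = profile.coverage
    ident = profile.modal_identity
    for i in range(len(profile.labels)):
        if cov[i] < min_coverage:
            excluded += 1
            continue
        label = scheme.classify(float(ident[i]))
        if label is None:
            excluded += 1
        else:
            counts[label] += 1
    return counts, excluded


def conserved_positions(
    profile: ConservationProfile,
    scheme: BandScheme,
    min_coverage: int = 1,
) -> Dict[str, Set[str]]:
    """Canonical position labels per band (the reference sets for cross-conservation)."""
    out: Dict[str, Set[str]] = {label: set() for label in scheme.labels}
    cov = profile.coverage
    ident = profile.modal_identity
    for i, lab in enumerate(profile.labels):
        if cov[i] < min_coverage:
            continue
        band = scheme.classify(float(ident[i]))
        if band is not None:
            out[band].add(lab)
    return out


def cross_conservation(
    reference_positions: Mapping[str, Set[str]] | Set[str],
    query_profile: ConservationProfile,
    threshold: float = 0.90,
    min_coverage: int = 1,
) -> Dict[str, int] | int:
    """How many reference-conserved positions are also conserved in a query set.

    ``reference_positions`` is either a mapping band label -> set of
    canonical positions (one count returned per band) or a bare set (a
    single count returned).  A reference position missing from the query
    profile's coordinate system is a hard error.
    """
    index = query_profile.position_index()
    ident = query_profile.modal_identity
    cov = query_profile.coverage

    def count(posset: Set[str]) -> int:
        n = 0
        for lab in posset:
            if lab not in index:
                raise ValueError(f"coordinate mismatch: {lab!r} not in query profile")
            i = index[lab]
            if cov[i] >= min_coverage and ident[i] >= threshold - _EPS:
                n += 1
        return n

    if isinstance(reference_positions, Mapping):
        return {band: count(posset) for band, posset in reference_positions.items()}
    return count(set(reference_positions))


def alignment_stats(aln: AlignmentMatrix) -> Dict[str, float]:
    """Row/column counts, parsimony-informative columns and missing fraction.

    A column is parsimony-informative iff at least two distinct non-missing
    states each occur in at least two rows.  Missing cells are gaps ('-')
    and unsequenced cells ('?').
    """
    n_rows, n_cols = aln.n_rows, aln.n_cols
    if n_rows == 0 or n_cols == 0:
        return {"n_rows": n_rows, "n_cols": n_cols,
                "parsimony_informative": 0, "missing_fraction": 1.0 if n_rows else 0.0}
    mat = np.array([list(row) for _, row in aln.rows])
    missing_mask = (mat == "-") | (mat == "?")
    missing_fraction = float(missing_mask.mean())
    informative = 0
    for j in range(n_cols):
        col = mat[:, j][~missing_mask[:, j]]
        if col.size < 4:
            continue
        _, cnts = np.unique(col, return_counts=True)
        if (cnts >= 2).sum() >= 2:
            informative += 1
    return {
        "n_rows": n_rows,
        "n_cols": n_cols,
        "parsimony_informative": int(informative),
        "missing_fraction": missing_fraction,
    }
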