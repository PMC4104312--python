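"""Anchor-based delineation of the tripartite PIN architecture.

Canonical PIN proteins consist of an N-terminal transmembrane domain that
runs from the initiator methionine to the anchor motif ``FLFEFRAAR`` (or a
close variant), a central hydrophilic loop, and a C-terminal transmembrane
domain that runs from the anchor motif ``VWRKLIRN`` (or variant) to the
stop.  With the N-anchor counted as part of the N-domain and the C-anchor
opening the C-domain, complete canonical domains have the modal lengths 158
(positions N1..N158) and 154 (positions C1..C154).  Rare longer N-domains
carry an insertion of up to 18 extra residues between N97 and N98.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from pin_architect.seqio import SequenceRecord

N_ANCHOR = "FLFEFRAAR"
C_ANCHOR = "VWRKLIRN"

CANONICAL_N_LEN = 158
CANONICAL_C_LEN = 154

#: Insertions are placed after this canonical N position (1-based).
INSERTION_AFTER = 97


@dataclass(frozen=True)
class AnchorConfig:
    """Anchor motifs and matching tolerances for delineation."""

    n_motif: str = N_ANCHOR
    c_motif: str = C_ANCHOR
    max_subs: int = 3
    max_insertion: int = 18
    canonical_n_len: int = CANONICAL_N_LEN
    canonical_c_len: int = CANONICAL_C_LEN


@dataclass(frozen=True)
class AnchorHit:
    """A window matching an anchor motif; coordinates 0-based half-open."""

    start: int
    end: int
    substitutions: int


@dataclass
class DomainPartition:
    """The N-domain / loop / C-domain split of one sequence.

    The concatenation of the present parts, in order, always equals the
    input residues.  ``n_labels`` / ``c_labels`` / ``loop_labels`` carry one
    canonical label per residue of the corresponding part (``None`` where no
    label applies); insertion residues between N97 and N98 are labelled
    ``N97+1`` .. ``N97+k``.
    """

    id: str
    n_domain: Optional[str]
    loop: Optional[str]
    c_domain: Optional[str]
    n_labels: List[Optional[str]] = field(default_factory=list)
    c_labels: List[Optional[str]] = field(default_factory=list)
    loop_labels: List[Optional[str]] = field(default_factory=list)
    flags: set = field(default_factory=set)
    n_hit: Optional[AnchorHit] = None
    c_hit: Optional[AnchorHit] = None
    n_complete: bool = True
    c_complete: bool = True

    def sequence(self) -> str:
        """Reassemble the input residues from the present parts."""
        return "".join(p for p in (self.n_domain, self.loop, self.c_domain) if p)

    @property
    def insertion_length(self) -> int:
        return sum(1 for lab in self.n_labels if lab and "+" in lab)

    @property
    def loop_complete_left(self) -> bool:
        """The loop's N-side end is observed iff the N-anchor was found
        (a truncation reaching into the loop removes the anchor first)."""
        return self.n_hit is not None

    @property
    def loop_complete_right(self) -> bool:
        """The loop's C-side end is observed iff the C-anchor was found."""
        return self.c_hit is not None


def _window_substitutions(seq: str, start: int, motif: str) -> int:
    subs = 0
    for i, m in enumerate(motif):
        if seq[start + i] != m:
            subs += 1
    return subs


def find_anchor(
    seq: str,
    motif: str,
    max_subs: int,
    expected_start: Optional[int] = None,
) -> Optional[AnchorHit]:
    """Locate the best-matching window for an anchor motif.

    Returns the window minimising substitution count; ties are broken by
    proximity of the window start to ``expected_start`` (then by the
    leftmost window).  Returns ``None`` when the best window still exceeds
    ``max_subs`` or when the sequence is shorter than the motif.
    """
    if len(motif) < 6:
        raise ValueError("anchor motif must have length >= 6")
    if max_subs >= len(motif) / 2:
        raise ValueError("max_subs must be < motif length / 2")
    if len(seq) < len(motif):
        return None
    best: Optional[tuple] = None
    for start in range(len(seq) - len(motif) + 1):
        subs = _window_substitutions(seq, start, motif)
        if subs > max_subs:
            continue
        dist = abs(start - expected_start) if expected_start is not None else start
        key = (subs, dist, start)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    subs, _, start = best
    return AnchorHit(start=start, end=start + len(motif), substitutions=subs)


def _label_n_domain(
    n_domain: str, n_complete: bool, config: AnchorConfig, flags: set
) -> List[Optional[str]]:
    """Assign canonical N labels, counting back from the anchor end.

    The last residue of the domain is N158 by construction (the anchor ends
    the domain).  A complete domain longer than 158 places the surplus as an
    insertion between N97 and N98 when it fits the configured maximum;
    otherwise the domain is flagged ``atypical_n``.  Incomplete N-termini
    never receive the label N1..: labels count backward from the anchor.
    """
    L = len(n_domain)
    k = config.canonical_n_len
    labels: List[Optional[str]] = [None] * L
    if n_complete and L > k:
        surplus = L - k
        if surplus <= config.max_insertion:
            tail = k - INSERTION_AFTER  # residues N98..N158
            for i in range(INSERTION_AFTER):
                labels[i] = f"N{i + 1}"
            for j in range(surplus):
                labels[INSERTION_AFTER + j] = f"N{INSERTION_AFTER}+{j + 1}"
            for j in range(tail):
                labels[INSERTION_AFTER + surplus + j] = f"N{INSERTION_AFTER + 1 + j}"
            return labels
        flags.add("atypical_n")
    # count backward from the anchor end: last residue is N158
    for offset in range(min(L, k)):
        labels[L - 1 - offset] = f"N{k - offset}"
    return labels


def _label_c_domain(c_domain: str, config: AnchorConfig, flags: set) -> List[Optional[str]]:
    """Assign canonical C labels forward from the anchor start (C1..)."""
    L = len(c_domain)
    k = config.canonical_c_len
    labels: List[Optional[str]] = [None] * L
    for i in range(L):
        if i < k:
            labels[i] = f"C{i + 1}"
        else:
            labels[i] = f"C{k}+{i - k + 1}"
    if L > k:
        flags.add("atypical_c")
    return labels


def delineate(record: SequenceRecord, config: AnchorConfig = AnchorConfig()) -> DomainPartition:
    """Split a sequence into N-domain, loop and C-domain by the anchors.

    The N-domain includes its anchor; the C-domain starts at its anchor.
    A missing anchor leaves the corresponding domain absent (flagged); the
    unattributable residues stay in the ``loop`` part so that the
    concatenation identity holds, and the loop is flagged unreliable.
    Finding the C-anchor before the N-anchor rejects both (a scrambled or
    non-PIN input).
    """
    seq = record.residues
    flags: set = set()
    if not record.n_complete:
        flags.add("n_partial")
    if not record.c_complete:
        flags.add("c_partial")

    n_hit = find_anchor(
        seq, config.n_motif, config.max_subs,
        expected_start=config.canonical_n_len - len(config.n_motif),
    )
    c_hit = find_anchor(
        seq, config.c_motif, config.max_subs,
        expected_start=len(seq) - config.canonical_c_len,
    )

    if n_hit is not None and c_hit is not None and c_hit.start < n_hit.end:
        n_hit = c_hit = None
        flags |= {"no_n_anchor", "no_c_anchor"}
    if n_hit is None:
        flags.add("no_n_anchor")
    if c_hit is None:
        flags.add("no_c_anchor")

    n_dom = seq[: n_hit.end] if n_hit else None
    c_dom = seq[c_hit.start :] if c_hit else None
    loop_start = n_hit.end if n_hit else 0
    loop_end = c_hit.start if c_hit else len(seq)
    loop = seq[loop_start:loop_end]
    loop_part: Optional[str] = loop if loop else None

    part = DomainPartition(
        id=record.id,
        n_domain=n_dom,
        loop=loop_part,
        c_domain=c_dom,
        flags=flags,
        n_hit=n_hit,
        c_hit=c_hit,
        n_complete=record.n_complete,
        c_complete=record.c_complete,
    )
    if n_dom is not None:
        part.n_labels = _label_n_domain(n_dom, record.n_complete, config, part.flags)
    if c_dom is not None:
        part.c_labels = _label_c_domain(c_dom, config, part.flags)
    if loop_part is not None and n_hit is not None:
        part.loop_labels = [f"L{i + 1}" for i in range(len(loop_part))]
    elif loop_part is not None:
        part.loop_labels = [None] * len(loop_part)
    return part


def loop_length_class(partition: DomainPartition) -> str:
    """Classify the loop as short (32-120 aa), long (>150), intermediate, or unknown.

    Noncanonical PINs carry short loops with no homology to the canonical
    modular loop; canonical loops are long.  The class is ``unknown`` when
    the loop is absent or one of its flanking anchors was not found.
    """
    if partition.loop is None:
        return "unknown"
    if "no_n_anchor" in partition.flags or "no_c_anchor" in partition.flags:
        return "unknown"
    n = len(partition.loop)
    if 32 <= n <= 120:
        return "short"
    if n > 150:
        return "long"
    if 120 < n <= 150:
        return "intermediate"
    return "unknown"  # below 32: outside both stated ranges
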