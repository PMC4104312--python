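"""Readers and writers for the formats the pipeline touches.

Conventions enforced here and used throughout the package:

* internal coordinates are 0-based half-open; user-facing canonical
  position labels (``N1``..``N158``, ``C1``..``C154``) are 1-based and are
  produced only at the boundary (see :mod:`pin_architect.domains`);
* alignment cells ``-`` (gap) and ``?`` (missing/unsequenced) are
  equivalent for statistics but preserved distinctly on write;
* sequence completeness travels in FASTA headers as the plain tokens
  ``n_partial`` / ``c_partial`` so files stay standard FASTA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import dendropy
from Bio import SeqIO

#: The 20 canonical residues plus X for an unknown residue.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS) | {"X"}

#: Alignment cells treated as missing for all statistics.
MISSING_CELLS = {"-", "?"}

LINEAGES = {"Eu1", "Eu2", "Eu3", "Lyco1", "Lyco2", "BC", "BNC", "other"}


@dataclass
class SequenceRecord:
    """One protein sequence with completeness flags.

    ``n_complete`` means the sequence starts at the initiator methionine;
    ``c_complete`` means it runs to the stop.  EST-derived fragments are
    typically partial at one or both ends.
    """

    id: str
    residues: str
    species: str | None = None
    n_complete: bool = True
    c_complete: bool = True

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for i, ch in enumerate(self.residues):
            if ch not in ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: non-alphabet character {ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignmentMatrix:
    """A rectangular multiple sequence alignment with '-' gaps and '?' missing."""

    rows: List[Tuple[str, str]]
    n_cols: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            self.n_cols = 0
            return
        self.n_cols = len(self.rows[0][1])
        seen = set()
        for rid, row in self.rows:
            if len(row) != self.n_cols:
                raise ValueError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, "
                    f"expected {self.n_cols}"
                )
            if rid in seen:
                raise ValueError(f"duplicate alignment row id {rid!r}")
            seen.add(rid)

    @property
    def ids(self) -> List[str]:
        return [rid for rid, _ in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class CladeMap:
    """Mapping of sequences to clades and clades to major lineages."""

    sequence_to_clade: Dict[str, str]
    clade_to_lineage: Dict[str, str]

    def __post_init__(self) -> None:
        for clade in set(self.sequence_to_clade.values()):
            if not clade:
                raise ValueError("empty clade name in sequence_to_clade")
            if clade not in self.clade_to_lineage:
                raise ValueError(f"clade {clade!r} has no lineage assignment")
        for clade, lineage in self.clade_to_lineage.items():
            if lineage not in LINEAGES:
                raise ValueError(
                    f"clade {clade!r}: unknown lineage {lineage!r} "
                    f"(expected one of {sorted(LINEAGES)})"
                )

    def clades(self) -> List[str]:
        return sorted(self.clade_to_lineage)

    def members(self, clade: str) -> List[str]:
        return sorted(s for s, c in self.sequence_to_clade.items() if c == clade)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> List[SequenceRecord]:
    """Read protein FASTA into :class:`SequenceRecord` objects.

    The header token before the first whitespace becomes the id; the tokens
    ``n_partial`` and ``c_partial`` anywhere later in the header clear the
    corresponding completeness flag.  Duplicate ids and non-alphabet
    characters are hard errors; an empty file yields an empty list with a
    warning.
    """
    path = Path(path)
    records: List[SequenceRecord] = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        tokens = entry.description.split()
        rid = entry.id
        if rid in seen:
            raise ValueError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
        flags = set(tokens[1:])
        species = None
        for tok in tokens[1:]:
            if tok.startswith("species="):
                species = tok[len("species="):]
        records.append(
            SequenceRecord(
                id=rid,
                residues=str(entry.seq).upper(),
                species=species,
                n_complete="n_partial" not in flags,
                c_complete="c_partial" not in flags,
            )
        )
    if not records:
        warnings.warn(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records, encoding completeness flags as header tokens."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id
            if rec.species:
                header += f" species={rec.species}"
            if not rec.n_complete:
                header += " n_partial"
            if not rec.c_complete:
                header += " c_partial"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Aligned FASTA


def read_alignment(path: str | Path) -> AlignmentMatrix:
    """Read an aligned FASTA file ('-' gaps, '?' missing) into a matrix.

    Rows of unequal length are a hard error naming the offending row.
    """
    path = Path(path)
    rows: List[Tuple[str, str]] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        rows.append((entry.id, str(entry.seq).strip().upper()))
    if not rows:
        warnings.warn(f"no alignment rows found in {path}")
    return AlignmentMatrix(rows=rows)


def write_alignment(aln: AlignmentMatrix, path: str | Path, width: int = 80) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rid, row in aln.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree.

    Tip labels are preserved verbatim; absent branch lengths stay ``None``
    (never coerced to zero).  Duplicate tip labels are a hard error.
    """
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"could not parse Newick tree in {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise ValueError(f"duplicate tip label(s) in {path}: {sorted(dupes)}")
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(Path(path)), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


# ---------------------------------------------------------------------------
# Clade-map TSV


def read_clade_map(path: str | Path) -> CladeMap:
    """Read a clade map from a two-section TSV.

    The file holds two header-introduced sections: rows with columns
    ``sequence_id<TAB>clade`` and rows with columns ``clade<TAB>lineage``.
    Sections may appear in either order.
    """
    path = Path(path)
    seq_to_clade: Dict[str, str] = {}
    clade_to_lineage: Dict[str, str] = {}
    mode = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        a, b = parts
        if (a, b) == ("sequence_id", "clade"):
            mode = "seq"
            continue
        if (a, b) == ("clade", "lineage"):
            mode = "clade"
            continue
        if mode == "seq":
            seq_to_clade[a] = b
        elif mode == "clade":
            clade_to_lineage[a] = b
        else:
            raise ValueError(f"{path}:{lineno}: data row before a section header")
    return CladeMap(sequence_to_clade=seq_to_clade, clade_to_lineage=clade_to_lineage)


def write_clade_map(clade_map: CladeMap, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sequence_id\tclade\n")
        for sid in sorted(clade_map.sequence_to_clade):
            fh.write(f"{sid}\t{clade_map.sequence_to_clade[sid]}\n")
        fh.write("clade\tlineage\n")
        for clade in sorted(clade_map.clade_to_lineage):
            fh.write(f"{clade}\t{clade_map.clade_to_lineage[clade]}\n")
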