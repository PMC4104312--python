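"""Synthetic PIN-like families with full ground truth.

The generator emulates the statistical structure the analysis assumes so
that every pipeline stage is testable offline:

* a canonical template with the anchor motifs planted verbatim, ten
  hydrophobic helix segments (one deliberately weak, to exercise
  cryptic-peak recovery), the invariant tyrosine at C123, and a modular
  loop assembled from the ordered motif library;
* per-position conservation bands over the 312 canonical transmembrane
  positions, with fractions mirroring the published family-wide band
  counts (56 / 49 / 58 / 30 over 312, remainder below 90%); members draw
  i.i.d. substitutions at the band rate so realized band fractions
  concentrate on the configured ones;
* clade-specific loss patterns of loop motifs (HC regions always kept in
  canonical clades);
* noncanonical clades with replacement loops of 32-120 residues, a
  retained invariant core of transmembrane positions and elevated
  substitution elsewhere;
* rare insertions of up to 18 residues between N97 and N98;
* EST-style truncation (geometric prefix/suffix removal) calibrated to a
  target alignment missing-data fraction, with sequences shorter than 100
  residues redrawn;
* a clade-level tree in which every noncanonical clade is sister to a
  canonical clade (so true origin count = number of noncanonical clades)
  on a long branch.

All randomness flows from one integer-seeded NumPy generator: identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from pin_architect import seqio
from pin_architect.motifs import MotifDef, default_motif_library
from pin_architect.seqio import AlignmentMatrix, CladeMap, SequenceRecord

N_LEN, C_LEN = 158, 154
N_ANCHOR, C_ANCHOR = "FLFEFRAAR", "VWRKLIRN"
INSERTION_AFTER = 97  # 1-based N position

HYDROPHOBIC = "AILMFV"
HYDROPHILIC = "DEKNQRSTG"
NC_LOOP_ALPHABET = "ADEFGHIKLMNPQRSTVY"

#: 1-based inclusive helix segments within each domain.  h3 is the weak
#: (cryptic) helix: a low-amplitude hydrophobic repeat.
N_HELICES = [(6, 26), (35, 55), (64, 84), (99, 119), (128, 148)]
C_HELICES = [(12, 32), (41, 61), (70, 90), (99, 119), (128, 148)]
WEAK_HELIX_INDEX = 2  # third helix of the N domain
WEAK_HELIX_PATTERN = "ILSTA"  # mean Kyte-Doolittle ~1.7; smoothing against the
# hydrophilic flanks usually pulls its peak under the primary cutoff, so the
# helix is typically recovered as a cryptic peak but never lost at the floor


@dataclass(frozen=True)
class BandSpec:
    """One conservation band: fraction of TM positions and substitution rate."""

    label: str
    fraction: float
    sub_prob: float


DEFAULT_BANDS = (
    BandSpec("100%", 56 / 312, 0.0),
    BandSpec(">99%", 49 / 312, 0.005),
    BandSpec(">95%", 58 / 312, 0.03),
    BandSpec(">90%", 30 / 312, 0.075),
    BandSpec("<=90%", 119 / 312, 0.2),
)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_clades: int = 8
    members_per_clade: int = 25
    n_noncanonical_clades: int = 2
    bands: Tuple[BandSpec, ...] = DEFAULT_BANDS
    # loop substitution rates per column class
    hc_col_sub: float = 0.02
    motif_col_sub: float = 0.06
    spacer_col_sub: float = 0.25
    # clade-specific motif loss
    droppable_motifs: Tuple[str, ...] = ("m1", "m7", "m9")
    drop_prob: float = 0.4
    # noncanonical clades
    noncanonical_loop_range: Tuple[int, int] = (32, 120)
    noncanonical_tm_sub: float = 0.30
    noncanonical_loop_sub: float = 0.20
    noncanonical_core_size: int = 50
    # insertions between N97/N98 (canonical members only)
    insertion_prob: float = 0.08
    max_insertion: int = 18
    # EST-style truncation; a fraction of members always stays full length
    truncate: bool = True
    truncation_prob: float = 0.85
    target_missing: float = 0.45
    min_seq_len: int = 100
    # tree
    branch_length_range: Tuple[float, float] = (0.08, 0.15)
    long_branch_factor: float = 5.0

    def validate(self) -> None:
        total = sum(b.fraction for b in self.bands)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"band fractions must sum to 1 (got {total})")
        if self.n_noncanonical_clades >= self.n_clades:
            raise ValueError("need at least one canonical clade")
        if not (0 < self.target_missing < 1):
            raise ValueError("target_missing must be in (0,1)")


def study_scale_config(seed: int = 0) -> GeneratorConfig:
    """A configuration at the scale of the analyzed study alignment:
    11 clades x 43 members = 473 rows, 3 noncanonical clades."""
    return GeneratorConfig(seed=seed, n_clades=11, members_per_clade=43,
                           n_noncanonical_clades=3)


@dataclass
class FamilyData:
    """Generator output plus complete ground truth."""

    config: GeneratorConfig
    records: List[SequenceRecord]
    alignment: AlignmentMatrix
    tree_newick: str
    clade_map: CladeMap
    members: pd.DataFrame            # per-member truth
    band_of_position: Dict[str, str]  # canonical label -> band label
    retention: pd.DataFrame          # clade x motif: bool retained
    helix_segments: Dict[str, List[Tuple[int, int]]]  # 0-based half-open, per domain
    noncanonical_clades: Set[str]
    true_origins: int
    template: Dict[str, str]         # n_domain / loop / c_domain templates
    motif_library: List[MotifDef]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seqio.write_fasta(self.records, outdir / "sequences.fasta")
        seqio.write_alignment(self.alignment, outdir / "alignment.fasta")
        (outdir / "clades.nwk").write_text(self.tree_newick + "\n")
        seqio.write_clade_map(self.clade_map, outdir / "clade_map.tsv")
        self.members.to_csv(outdir / "truth_members.tsv", sep="\t", index=False)
        self.retention.to_csv(outdir / "truth_retention.tsv", sep="\t")
        pd.Series(self.band_of_position, name="band").rename_axis("position") \
            .to_csv(outdir / "truth_bands.tsv", sep="\t")


# ---------------------------------------------------------------------------


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """Concrete residue string for a pattern: wildcards drawn, alternatives first."""
    out = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            out.append(pattern[i + 1])
            i = j + 1
        elif ch == "X":
            out.append(rng.choice(list(HYDROPHILIC)))
            i += 1
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def _build_tm_templates(rng: np.random.Generator) -> Tuple[str, str]:
    def fill(length: int, helices, anchor: str, anchor_at_start: bool,
             weak_index: Optional[int]) -> List[str]:
        res = [str(rng.choice(list(HYDROPHILIC))) for _ in range(length)]
        for h, (a, b) in enumerate(helices):
            if h == weak_index:
                pat = (WEAK_HELIX_PATTERN * 10)[: b - a + 1]
                for k, ch in enumerate(pat):
                    res[a - 1 + k] = ch
            else:
                for k in range(a - 1, b):
                    res[k] = str(rng.choice(list(HYDROPHOBIC)))
        if anchor_at_start:
            res[: len(anchor)] = list(anchor)
        else:
            res[length - len(anchor):] = list(anchor)
        return res

    n = fill(N_LEN, N_HELICES, N_ANCHOR, False, WEAK_HELIX_INDEX)
    n[0] = "M"
    c = fill(C_LEN, C_HELICES, C_ANCHOR, True, None)
    c[122] = "Y"  # the invariant tyrosine at C123
    return "".join(n), "".join(c)


def _build_loop_template(library: Sequence[MotifDef], rng: np.random.Generator
                         ) -> Tuple[str, List[Tuple[str, int, int]], List[float]]:
    """Assemble the canonical loop; returns (loop, motif spans, per-column rate codes)."""
    # layout: each motif once, except the repeat unit planted four times
    repeat_names = {"rptA", "rptB", "rptC"}
    spans: List[Tuple[str, int, int]] = []
    cols: List[str] = []
    rates: List[float] = []

    def add_spacer(n: int) -> None:
        for _ in range(n):
            cols.append(str(rng.choice(list(HYDROPHILIC))))
            rates.append(-1.0)  # placeholder, set to spacer rate later

    def add_motif(m: MotifDef, rate: float) -> None:
        s = len(cols)
        inst = _instantiate(m.pattern, rng)
        cols.extend(inst)
        rates.extend([rate] * len(inst))
        spans.append((m.name, s, len(cols)))

    by_rank = sorted(library, key=lambda m: m.rank)
    add_spacer(4)
    for m in by_rank:
        if m.name == "rptA":
            # the unit of three consecutive motifs repeated four times
            unit = [x for x in by_rank if x.name in repeat_names]
            for copy in range(4):
                for u in unit:
                    add_motif(u, -2.0)
                    add_spacer(2)
            continue
        if m.name in repeat_names:
            continue
        add_motif(m, -3.0 if m.hc_group else -2.0)
        add_spacer(6)
    return "".join(cols), spans, rates


def _assign_bands(config: GeneratorConfig, rng: np.random.Generator
                  ) -> Tuple[Dict[str, str], Dict[str, float], List[str]]:
    """Band per canonical TM label; helices and anchors take the high bands."""
    labels = [f"N{i}" for i in range(1, N_LEN + 1)] + [f"C{i}" for i in range(1, C_LEN + 1)]
    n_total = len(labels)
    counts = [int(round(b.fraction * n_total)) for b in config.bands]
    while sum(counts) > n_total:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n_total:
        counts[int(np.argmax([b.fraction for b in config.bands]))] += 1

    forced = (
        [f"N{i}" for i in range(N_LEN - len(N_ANCHOR) + 1, N_LEN + 1)]
        + [f"C{i}" for i in range(1, len(C_ANCHOR) + 1)]
        + ["N1", "C123"]
    )
    if counts[0] < len(forced):
        raise ValueError("infeasible band fractions: 100% band smaller than the "
                         "forced invariant set (anchors, N1, C123)")

    helix_labels = [f"N{i}" for a, b in N_HELICES for i in range(a, b + 1)] + \
                   [f"C{i}" for a, b in C_HELICES for i in range(a, b + 1)]
    helix_pool = [lab for lab in helix_labels if lab not in set(forced)]
    other_pool = [lab for lab in labels if lab not in set(forced) and lab not in set(helix_pool)]
    rng.shuffle(helix_pool)
    rng.shuffle(other_pool)
    pool = helix_pool + other_pool  # high bands drawn from helices first

    band_of: Dict[str, str] = {}
    rate_of_band = {b.label: b.sub_prob for b in config.bands}
    it = iter(pool)
    for lab in forced:
        band_of[lab] = config.bands[0].label
    remaining_first = counts[0] - len(forced)
    for b, cnt in zip(config.bands, counts):
        take = remaining_first if b is config.bands[0] else cnt
        for _ in range(take):
            band_of[next(it)] = b.label
    return band_of, rate_of_band, labels


def _substitute(residue: str, rng: np.random.Generator) -> str:
    """Category-preserving substitution to a different residue."""
    pool = HYDROPHOBIC if residue in HYDROPHOBIC else HYDROPHILIC
    choices = [r for r in pool if r != residue]
    if residue not in pool:
        choices = [r for r in HYDROPHILIC if r != residue]
    return str(rng.choice(choices))


def _mutate(seq: str, probs: Sequence[float], rng: np.random.Generator) -> str:
    draws = rng.random(len(seq))
    out = list(seq)
    for i, (p, u) in enumerate(zip(probs, draws)):
        if u < p:
            out[i] = _substitute(out[i], rng)
    return "".join(out)


def generate_family(config: GeneratorConfig = GeneratorConfig()) -> FamilyData:
    """Generate one PIN-like family with sequences, alignment, tree and truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_tmpl, c_tmpl = _build_tm_templates(rng)
    library = default_motif_library()
    loop_tmpl, motif_spans, loop_rate_codes = _build_loop_template(library, rng)

    hc_names = {m.name for m in library if m.hc_group}
    loop_rates = []
    for code in loop_rate_codes:
        if code == -3.0:
            loop_rates.append(config.hc_col_sub)
        elif code == -2.0:
            loop_rates.append(config.motif_col_sub)
        else:
            loop_rates.append(config.spacer_col_sub)
    # HC motif columns get the HC rate even inside the generic span bookkeeping
    for name, s, e in motif_spans:
        rate = config.hc_col_sub if name in hc_names else config.motif_col_sub
        for i in range(s, e):
            loop_rates[i] = rate

    band_of, rate_of_band, tm_labels = _assign_bands(config, rng)
    n_rates = [rate_of_band[band_of[f"N{i}"]] for i in range(1, N_LEN + 1)]
    c_rates = [rate_of_band[band_of[f"C{i}"]] for i in range(1, C_LEN + 1)]

    # invariant core retained by noncanonical clades (anchors always included)
    forced_core = [f"N{i}" for i in range(N_LEN - len(N_ANCHOR) + 1, N_LEN + 1)] \
        + [f"C{i}" for i in range(1, len(C_ANCHOR) + 1)] + ["N1", "C123"]
    invariant = [lab for lab, b in band_of.items() if b == config.bands[0].label
                 and lab not in set(forced_core)]
    rng.shuffle(invariant)
    extra = max(0, config.noncanonical_core_size - len(forced_core))
    core = set(forced_core) | set(invariant[:extra])

    n_canonical = config.n_clades - config.n_noncanonical_clades
    canonical_clades = [f"can{chr(65 + i)}" for i in range(n_canonical)]
    noncanonical_clades = [f"nc{chr(65 + i)}" for i in range(config.n_noncanonical_clades)]
    clades = canonical_clades + noncanonical_clades

    # clade-specific motif retention (canonical clades keep all HC regions)
    motif_names = [m.name for m in sorted(library, key=lambda m: m.rank)]
    retention = pd.DataFrame(True, index=clades, columns=motif_names)
    for clade in canonical_clades:
        for name in config.droppable_motifs:
            if rng.random() < config.drop_prob:
                retention.loc[clade, name] = False
    for clade in noncanonical_clades:
        retention.loc[clade, :] = False

    # per-clade loop templates and retained template-loop columns
    clade_loop: Dict[str, str] = {}
    clade_loop_cols: Dict[str, Optional[List[int]]] = {}
    clade_loop_rates: Dict[str, List[float]] = {}
    lo, hi = config.noncanonical_loop_range
    for clade in clades:
        if clade in noncanonical_clades:
            length = int(rng.integers(lo, hi + 1))
            clade_loop[clade] = "".join(
                str(rng.choice(list(NC_LOOP_ALPHABET))) for _ in range(length))
            clade_loop_cols[clade] = None
            clade_loop_rates[clade] = [config.noncanonical_loop_sub] * length
        else:
            dropped = {name for name in motif_names if not retention.loc[clade, name]}
            drop_cols = set()
            for name, s, e in motif_spans:
                if name in dropped:
                    drop_cols.update(range(s, e))
            keep = [i for i in range(len(loop_tmpl)) if i not in drop_cols]
            clade_loop[clade] = "".join(loop_tmpl[i] for i in keep)
            clade_loop_cols[clade] = keep
            clade_loop_rates[clade] = [loop_rates[i] for i in keep]

    # per-clade TM substitution rates
    tm_rates: Dict[str, Tuple[List[float], List[float]]] = {}
    for clade in clades:
        if clade in noncanonical_clades:
            nr = [0.0 if f"N{i}" in core else config.noncanonical_tm_sub
                  for i in range(1, N_LEN + 1)]
            cr = [0.0 if f"C{i}" in core else config.noncanonical_tm_sub
                  for i in range(1, C_LEN + 1)]
        else:
            nr, cr = n_rates, c_rates
        tm_rates[clade] = (nr, cr)

    # --- members -----------------------------------------------------------
    records: List[SequenceRecord] = []
    rows: List[dict] = []
    seq_to_clade: Dict[str, str] = {}
    aln_loop_cols = len(loop_tmpl)
    n_cols_total = N_LEN + aln_loop_cols + C_LEN
    aln_rows: List[Tuple[str, List[str]]] = []

    for clade in clades:
        nr, cr = tm_rates[clade]
        is_nc = clade in noncanonical_clades
        for k in range(config.members_per_clade):
            sid = f"{clade}_{k:03d}"
            n_part = _mutate(n_tmpl, nr, rng)
            c_part = _mutate(c_tmpl, cr, rng)
            loop_part = _mutate(clade_loop[clade], clade_loop_rates[clade], rng)
            ins_len = 0
            if not is_nc and rng.random() < config.insertion_prob:
                ins_len = int(rng.integers(1, config.max_insertion + 1))
                ins = "".join(str(rng.choice(list(HYDROPHILIC))) for _ in range(ins_len))
                n_part = n_part[:INSERTION_AFTER] + ins + n_part[INSERTION_AFTER:]
            full = n_part + loop_part + c_part

            # residue index -> alignment column (None for insertion / nc loop)
            col_map: List[Optional[int]] = []
            for i in range(len(n_part)):
                if i < INSERTION_AFTER:
                    col_map.append(i)
                elif i < INSERTION_AFTER + ins_len:
                    col_map.append(None)
                else:
                    col_map.append(i - ins_len)
            keep_cols = clade_loop_cols[clade]
            for i in range(len(loop_part)):
                col_map.append(None if keep_cols is None else N_LEN + keep_cols[i])
            for i in range(len(c_part)):
                col_map.append(N_LEN + aln_loop_cols + i)

            row_cells = ["-"] * n_cols_total
            for i, col in enumerate(col_map):
                if col is not None:
                    row_cells[col] = full[i]

            records.append(SequenceRecord(id=sid, residues=full))
            aln_rows.append((sid, row_cells))
            seq_to_clade[sid] = clade
            rows.append({
                "id": sid, "clade": clade,
                "label": "noncanonical" if is_nc else "canonical",
                "insertion_len": ins_len,
                "full_len": len(full),
                "n_end_full": len(n_part),
                "c_start_full": len(n_part) + len(loop_part),
                "loop_len_full": len(loop_part),
                "trunc_prefix": 0, "trunc_suffix": 0,
                "col_map": col_map,
            })

    # --- EST-style truncation ---------------------------------------------
    # Prefix/suffix removals with geometric lengths, calibrated in a few
    # deficit-correction rounds because residues without an alignment column
    # (insertions, noncanonical loops) mark no cells when removed.
    if config.truncate:
        total_cells = len(records) * n_cols_total
        pfx_of = [0] * len(records)
        sfx_of = [0] * len(records)
        truncatable = [bool(rng.random() < config.truncation_prob)
                       for _ in records]

        def missing_cells() -> int:
            return sum(cells.count("-") + cells.count("?") for _, cells in aln_rows)

        n_truncatable = max(1, sum(truncatable))
        for _ in range(4):
            deficit = config.target_missing * total_cells - missing_cells()
            if deficit <= 0.005 * total_cells:
                break
            mu = deficit / n_truncatable
            p_geom = 2.0 / (mu + 2.0)
            for idx, r in enumerate(rows):
                if not truncatable[idx]:
                    continue
                full_len = r["full_len"]
                slack = full_len - pfx_of[idx] - sfx_of[idx] - config.min_seq_len
                if slack <= 0:
                    continue
                add_p = int(rng.geometric(p_geom)) - 1
                add_s = int(rng.geometric(p_geom)) - 1
                # mimic the discard-and-resample of overly short fragments
                tries = 0
                while add_p + add_s > slack and tries < 25:
                    add_p = int(rng.geometric(p_geom)) - 1
                    add_s = int(rng.geometric(p_geom)) - 1
                    tries += 1
                if add_p + add_s > slack or (add_p == 0 and add_s == 0):
                    continue
                col_map = r["col_map"]
                cells = aln_rows[idx][1]
                new_p, new_s = pfx_of[idx] + add_p, sfx_of[idx] + add_s
                for i in list(range(pfx_of[idx], new_p)) + \
                        list(range(full_len - new_s, full_len - sfx_of[idx])):
                    if col_map[i] is not None:
                        cells[col_map[i]] = "?"
                pfx_of[idx], sfx_of[idx] = new_p, new_s

        for idx, rec in enumerate(records):
            pfx, sfx = pfx_of[idx], sfx_of[idx]
            if pfx == 0 and sfx == 0:
                continue
            L = rows[idx]["full_len"]
            records[idx] = SequenceRecord(
                id=rec.id,
                residues=rec.residues[pfx: L - sfx],
                n_complete=pfx == 0,
                c_complete=sfx == 0,
            )
            rows[idx]["trunc_prefix"] = pfx
            rows[idx]["trunc_suffix"] = sfx

    members = pd.DataFrame(rows)
    # anchor survival and truncated-coordinate boundaries
    n_end_t, c_start_t, n_ok, c_ok = [], [], [], []
    for _, r in members.iterrows():
        pfx, sfx = r["trunc_prefix"], r["trunc_suffix"]
        L = r["full_len"]
        ne, cs = r["n_end_full"], r["c_start_full"]
        ok_n = pfx <= ne - len(N_ANCHOR) and (L - sfx) >= ne
        ok_c = pfx <= cs and (L - sfx) >= cs + len(C_ANCHOR)
        n_ok.append(bool(ok_n))
        c_ok.append(bool(ok_c))
        n_end_t.append(ne - pfx if ok_n else -1)
        c_start_t.append(cs - pfx if ok_c else -1)
    members["n_anchor_intact"] = n_ok
    members["c_anchor_intact"] = c_ok
    members["n_end_trunc"] = n_end_t
    members["c_start_trunc"] = c_start_t
    members = members.drop(columns=["col_map"])

    alignment = AlignmentMatrix(rows=[(sid, "".join(cells)) for sid, cells in aln_rows])

    # --- clade tree --------------------------------------------------------
    blr = config.branch_length_range

    def blen(scale: float = 1.0) -> float:
        return round(float(rng.uniform(*blr)) * scale, 6)

    units: List[str] = []
    for i, clade in enumerate(canonical_clades):
        if i < len(noncanonical_clades):
            nc = noncanonical_clades[i]
            units.append(f"({clade}:{blen()},{nc}:{blen(config.long_branch_factor)}):{blen()}")
        else:
            units.append(f"{clade}:{blen()}")
    tree = units[0]
    for unit in units[1:]:
        tree = f"({tree},{unit}):{blen()}"
    newick = tree.rsplit(":", 1)[0] + ";"

    lineages = ["Eu1", "Eu2", "Eu3", "Lyco1", "Lyco2", "BC", "BNC"]
    clade_map = CladeMap(
        sequence_to_clade=seq_to_clade,
        clade_to_lineage={c: lineages[i % len(lineages)] for i, c in enumerate(clades)},
    )

    return FamilyData(
        config=config,
        records=records,
        alignment=alignment,
        tree_newick=newick,
        clade_map=clade_map,
        members=members,
        band_of_position=band_of,
        retention=retention,
        helix_segments={
            "n_domain": [(a - 1, b) for a, b in N_HELICES],
            "c_domain": [(a - 1, b) for a, b in C_HELICES],
        },
        noncanonical_clades=set(noncanonical_clades),
        true_origins=len(noncanonical_clades),
        template={"n_domain": n_tmpl, "loop": loop_tmpl, "c_domain": c_tmpl},
        motif_library=library,
    )
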