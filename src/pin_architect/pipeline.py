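"""End-to-end orchestration: delineate -> profile -> scan -> classify ->
topology -> origins, with report files styled after the published tables.

``run_all`` is deterministic given identical inputs and configuration and
writes a manifest recording every parameter left open by the method
description (thresholds, scales, seeds, input checksums) so results are
auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set

import pandas as pd

from pin_architect import seqio
from pin_architect.charevol import CladeTree, long_branch_clades, min_origins
from pin_architect.classify import (
    ClassifyThresholds, HCConsensus, classify_clade, classify_protein, hc_score,
)
from pin_architect.conservation import (
    TABLE2_BANDS, TABLE3_BANDS, band_counts, build_profile, conserved_positions,
    cross_conservation,
)
from pin_architect.domains import AnchorConfig, delineate, loop_length_class
from pin_architect.motifs import (
    ScanThresholds, default_motif_library, motif_matrix, read_motif_library, scan_loop,
)
from pin_architect.topology import HelixParams, detect_helices, hydropathy_profile

log = logging.getLogger("pin_architect")


class ValidationError(ValueError):
    """Bad run configuration or missing input."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    sequences: str
    clade_map: str
    out_dir: str
    tree: Optional[str] = None
    motif_library: Optional[str] = None
    anchors: AnchorConfig = field(default_factory=AnchorConfig)
    scan: ScanThresholds = field(default_factory=ScanThresholds)
    classify: ClassifyThresholds = field(default_factory=ClassifyThresholds)
    helix: HelixParams = field(default_factory=HelixParams)
    long_branch_ratio: float = 2.0
    min_coverage: int = 10
    exclude_clades: Sequence[str] = ()
    seed: int = 0

    def validate(self) -> None:
        for label, path in [("sequences", self.sequences), ("clade_map", self.clade_map),
                            ("tree", self.tree), ("motif_library", self.motif_library)]:
            if path is not None and not Path(path).exists():
                raise ValidationError(f"{label} file not found: {path}")


def _checksum(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> Dict[str, object]:
    """Execute every stage and write the report bundle.

    Emits: partitions.tsv, profile_tm.tsv, cross_conservation.tsv
    (family-band style), self_identity.tsv (within-clade style),
    motif_matrix.tsv, classes.tsv, classes_clade.tsv, helices.tsv,
    origins.json and manifest.json in ``out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {}
    warnings_summary: List[str] = []

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("read")
        records = seqio.read_fasta(config.sequences)
        clade_map = seqio.read_clade_map(config.clade_map)
        library = (read_motif_library(config.motif_library)
                   if config.motif_library else default_motif_library())
        consensus = HCConsensus.from_library(library)
    except Exception as exc:
        raise StageError("read", exc) from exc

    excluded = set(config.exclude_clades)
    if excluded:
        keep_ids = {r.id for r in records
                    if clade_map.sequence_to_clade.get(r.id) not in excluded}
        records = [r for r in records if r.id in keep_ids]

    # --- delineate ---------------------------------------------------------
    try:
        stage("delineate")
        partitions = {r.id: delineate(r, config.anchors) for r in records}
        rows = []
        for r in records:
            p = partitions[r.id]
            rows.append({
                "id": r.id,
                "n_len": len(p.n_domain) if p.n_domain else 0,
                "loop_len": len(p.loop) if p.loop else 0,
                "c_len": len(p.c_domain) if p.c_domain else 0,
                "loop_class": loop_length_class(p),
                "flags": ",".join(sorted(p.flags)),
                "anchor_subs_n": p.n_hit.substitutions if p.n_hit else "",
                "anchor_subs_c": p.c_hit.substitutions if p.c_hit else "",
            })
        pd.DataFrame(rows).to_csv(out / "partitions.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("delineate", exc) from exc

    # --- scan + classify (needed to know which clades are canonical) -------
    try:
        stage("scan")
        scans = {}
        for r in records:
            p = partitions[r.id]
            scans[r.id] = scan_loop(
                p.loop, library, config.scan,
                complete_left=p.loop_complete_left,
                complete_right=p.loop_complete_right,
            )
        matrix = motif_matrix(scans, clade_map)
        matrix.to_csv(out / "motif_matrix.tsv", sep="\t")
    except Exception as exc:
        raise StageError("scan", exc) from exc

    try:
        stage("classify")
        classifications = {}
        rows = []
        for r in records:
            p = partitions[r.id]
            scores = hc_score(
                p.loop, consensus, config.classify,
                complete_left=p.loop_complete_left,
                complete_right=p.loop_complete_right,
            )
            cls = classify_protein(scores, config.classify, id=r.id)
            classifications[r.id] = cls
            rows.append({
                "id": r.id,
                "identity": round(cls.hc_identity, 4),
                "similarity": round(cls.hc_similarity, 4),
                "regions": ",".join(cls.regions_located),
                "label": cls.label,
            })
        pd.DataFrame(rows).to_csv(out / "classes.tsv", sep="\t", index=False)

        clade_rows = []
        clade_labels = {}
        for clade in clade_map.clades():
            if clade in excluded:
                continue
            members = [classifications[s] for s in clade_map.members(clade)
                       if s in classifications]
            if not members:
                continue
            label = classify_clade(members)
            clade_labels[clade] = label
            clade_rows.append({
                "clade": clade,
                "n": len(members),
                "n_canonical": sum(1 for m in members if m.label == "canonical"),
                "label": label,
            })
        pd.DataFrame(clade_rows).to_csv(out / "classes_clade.tsv", sep="\t", index=False)
        results["clade_labels"] = clade_labels
    except Exception as exc:
        raise StageError("classify", exc) from exc

    # --- conservation profiles --------------------------------------------
    try:
        stage("profile")
        canonical_ids = [sid for sid, cls in classifications.items()
                         if cls.label == "canonical"]
        canonical_parts = [partitions[s] for s in canonical_ids]
        profile = build_profile(canonical_parts, "tm")
        pd.DataFrame({
            "position": profile.labels,
            "modal_residue": profile.modal_residue,
            "modal_identity": profile.modal_identity.round(4),
            "coverage": profile.coverage.astype(int),
        }).to_csv(out / "profile_tm.tsv", sep="\t", index=False)

        reference = conserved_positions(profile, TABLE2_BANDS,
                                        min_coverage=config.min_coverage)
        cross_rows = []
        nc_clades = [c for c, lab in clade_labels.items()
                     if lab in ("noncanonical", "mixed")]
        nc_ids_all = [s for c in nc_clades for s in clade_map.members(c)
                      if s in partitions]
        queries = {}
        if nc_ids_all:
            queries["NC"] = nc_ids_all
        for clade in nc_clades:
            queries[clade] = [s for s in clade_map.members(clade) if s in partitions]
        for name, ids in queries.items():
            qprofile = build_profile([partitions[s] for s in ids], "tm")
            counts = cross_conservation(reference, qprofile,
                                        min_coverage=config.min_coverage)
            for band, n in counts.items():
                cross_rows.append({
                    "band": band, "n_reference": len(reference[band]),
                    "group": name, "n_conserved": n,
                })
        pd.DataFrame(cross_rows).to_csv(out / "cross_conservation.tsv",
                                        sep="\t", index=False)

        self_rows = []
        for clade in clade_map.clades():
            ids = [s for s in clade_map.members(clade) if s in partitions]
            if len(ids) < 2:
                continue
            cprofile = build_profile([partitions[s] for s in ids], "tm")
            counts, excluded_n = band_counts(cprofile, TABLE3_BANDS,
                                             min_coverage=config.min_coverage)
            row = {"clade": clade, "n_members": len(ids),
                   "insufficient": excluded_n}
            row.update(counts)
            self_rows.append(row)
        pd.DataFrame(self_rows).to_csv(out / "self_identity.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("profile", exc) from exc

    # --- topology ----------------------------------------------------------
    try:
        stage("topology")
        helix_rows = []
        for r in records:
            p = partitions[r.id]
            for region, dom in [("n_domain", p.n_domain), ("c_domain", p.c_domain)]:
                if dom is None or len(dom) < config.helix.window:
                    continue
                pred = detect_helices(hydropathy_profile(dom, config.helix.window),
                                      config.helix)
                for i, h in enumerate(pred.helices):
                    helix_rows.append({
                        "id": r.id, "domain": region, "helix": i + 1,
                        "start": h.start + 1, "end": h.end,
                        "peak": round(h.peak, 3), "cryptic": h.cryptic,
                    })
        pd.DataFrame(helix_rows).to_csv(out / "helices.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("topology", exc) from exc

    # --- origins -----------------------------------------------------------
    origins_payload = None
    if config.tree:
        try:
            stage("origins")
            tree = seqio.read_tree(config.tree)
            states = {}
            for clade, label in clade_labels.items():
                states[clade] = 0 if label == "canonical" else 1
            ctree = CladeTree(tree=tree, states=states)
            if excluded:
                ctree = ctree.prune(excluded)
            origins, labeling = min_origins(ctree)
            flagged: Set[str] = set()
            has_lengths = all(e.length is not None
                              for e in tree.preorder_edge_iter()
                              if e.head_node is not tree.seed_node)
            if has_lengths:
                flagged = long_branch_clades(ctree.tree, ratio=config.long_branch_ratio)
            origins_payload = {
                "origins": origins,
                "labeling": labeling,
                "long_branch_clades": sorted(flagged),
            }
            (out / "origins.json").write_text(json.dumps(origins_payload, indent=2))
        except Exception as exc:
            raise StageError("origins", exc) from exc

    # --- manifest ----------------------------------------------------------
    manifest = {
        "inputs": {
            "sequences": {"path": config.sequences, "sha256": _checksum(config.sequences)},
            "clade_map": {"path": config.clade_map, "sha256": _checksum(config.clade_map)},
            "tree": ({"path": config.tree, "sha256": _checksum(config.tree)}
                     if config.tree else None),
        },
        "parameters": {
            "anchors": asdict(config.anchors),
            "scan": asdict(config.scan),
            "classify": asdict(config.classify),
            "helix": asdict(config.helix),
            "long_branch_ratio": config.long_branch_ratio,
            "min_coverage": config.min_coverage,
            "exclude_clades": sorted(excluded),
            "seed": config.seed,
        },
        "n_sequences": len(records),
        "warnings": warnings_summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    results.update({
        "n_sequences": len(records),
        "origins": origins_payload,
        "out_dir": str(out),
    })
    return results
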