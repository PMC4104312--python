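# Methods

This note documents the models, parameter choices and numerical conventions
behind `pin_architect`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and formats

Internally every coordinate is 0-based half-open; canonical position labels
(`N1`…`N158`, `C1`…`C154`, loop-relative `L1`…) are 1-based and produced
only at the interface, because that is how positions in this family are
conventionally cited (N97/N98, C123). In alignments `-` (gap) and `?`
(unsequenced) are both missing for statistics but preserved on write, since
EST-derived alignments mix the two meaningfully. Sequence completeness
travels in FASTA headers as the plain tokens `n_partial` / `c_partial`,
keeping files standard-compliant.

## Domain delineation

The two anchors (`FLFEFRAAR`, `VWRKLIRN`) are located by exhaustive-window
substitution counting (ties broken toward the expected position: anchor
start near position 150 for the N-anchor, 154 from the C-terminus for the
C-anchor; then leftmost). The default tolerance is 3 substitutions per
anchor — the variant spellings in real data are not quantified anywhere, so
this is a package default, configurable per run and recorded in the
manifest. The N-domain *includes* its anchor and the C-domain *starts* at
its anchor; the sources describing the family say the domains run "to" and
"from" the anchors without fixing inclusivity, and this choice is the one
under which complete canonical domains have the modal lengths 158 and 154.

Complete N-domains longer than 158 place the surplus (≤18 residues,
configurable) between N97 and N98, which is where essentially all known
insertions sit; larger surpluses are flagged `atypical_n` rather than
force-fitted. Sequences with an incomplete N-terminus are labelled by
counting backward from the anchor (N158 at the anchor's last residue), so
they contribute to the right canonical columns without claiming an N1.
Known limitation: an N-partial sequence that *also* carries an N97/N98
insertion cannot be recognised as such (there is no N1 reference), so its
pre-insertion residues are labelled shifted by the insertion length. Such
sequences are rare under realistic insertion rates (~8%) and the effect on
profiles is a small downward identity bias at N1–N97.

A loop edge counts as observed exactly when its flanking anchor was found:
a truncation that reaches into the loop necessarily removes the anchor
first. Loop-length classes follow the published ranges: short 32–120,
long >150, the forced-in-between (120, 150] reported as `intermediate`.

## Conservation profiles and bands

Frequencies at each canonical position are computed over the sequences that
cover it (insertion residues and unknown `X` excluded); a per-position
minimum coverage (default 10) marks positions as "insufficient data" in
band tables. Band edges are lower-open and upper-closed with 100% its own
band, matching how the printed band tables partition their counts; exact
identities are compared with a 1e-9 tolerance so rational frequencies like
199/200 land deterministically. Two named schemes are shipped: the
family-wide scheme (100%, >99%, >95%, >90%) and the within-clade
self-identity scheme (100%, 95–99, 90–95, 70–90, 50–70, <50). A column is
parsimony-informative iff at least two distinct non-missing states each
occur in at least two rows.

## Loop-motif scanning

Motif patterns use literal residues, `X` wildcards (match anything,
excluded from denominators) and `[..]` alternatives. Scanning solves a
maximum-weight increasing assignment: every motif gets its best gapless
window subject to windows being non-overlapping and ordered by rank,
maximised by total identity (dynamic program, exact; ties prefer assigning
over skipping, then smaller starts). The six presence states follow fixed
default thresholds — present at identity ≥0.70; divergent at similarity
≥0.40 (BLOSUM62-positive columns) with both rank-neighbours located;
partially present when ≥50% of the motif's columns overlap a truncated
loop edge at ≥0.70 identity; `no_data` when the motif's expected span lies
beyond a truncated edge (operationalised as: ranked outside the located
range on the truncated side). These thresholds are package defaults, not
values inherited from any source, and are recorded in run manifests. The
distinction between "partially present" and "present but divergent" is
inherently verbal in the field; this operationalisation is a recorded
design choice.

Repeat detection (the three-motif unit repeated around HC2) is greedy
left-to-right: each copy anchors at the next present-level occurrence of
the first unit motif and the remaining motifs must follow within a 12-residue
gap, present-or-divergent, taking the best-scoring window; an incomplete
trailing copy is reported as a partial span. Anchoring on a present-level
match is deliberate: similarity-only matches are too easy to find by
chance to start a copy.

Clade matrices use a strict majority over members with data (>50%), with
`no_consensus` otherwise and `no_data` when no member covers the motif.

## Classification

Identity is pooled over the non-wildcard columns of the four HC-region
consensi, with each region located by the same order-respecting assignment;
similarity adds BLOSUM62-positive substitutions. The canonical rule is
read as pooled ("≥50% identity or ≥70% similarity across all of HC1–HC4"),
with a per-region strict mode behind a flag, because the published usage
applies an identity percentage to a single region in at least one place and
both readings are defensible. A region counts as located at identity ≥0.40
or similarity ≥0.60 (defaults, configurable).

Regions rendered unobservable by loop truncation are excluded from both the
pooled denominator and the "all regions located" requirement; a protein
with less than half of the consensus columns observable is
`insufficient_data`. This deviates from a literal all-four-located rule on
purpose: a fragment whose observable regions all match well is evidence
*for* canonical structure, and the alternative would misclassify partially
sequenced canonical proteins as noncanonical. Clade labels use the 90%
rule at ≥10 informative members and a strict majority below;
semicanonical members count against the canonical fraction, a choice
surfaced in output metadata.

## Hydropathy topology

The per-residue scale is Kyte–Doolittle (X scored 0.0), smoothed by a
centred moving average (default window 19, ends truncated). Helices are
maximal runs of ≥7 window-centres above the cutoff, merged across gaps of
<3 centres. Detection starts at cutoff 1.6; while fewer than the expected
five helices per domain are found, the cutoff drops in steps of 0.1 to a
floor of 0.5, and newly appearing runs that do not overlap an existing
helix are added as *cryptic*. Because existing peaks are never removed or
re-segmented during relaxation, the recovered count is monotone in the
floor — that is the recovery guarantee; independent runs at different
starting cutoffs can disagree in count because separate runs can merge at
low cutoffs. Reported intervals are runs of window centres, so interval
edges depend on the cutoff-to-contrast ratio; they are guaranteed to lie
inside the delineated domain, which is the consistency check that matters
for validating delineation. All parameters are configurable; the defaults
replace an external HMM predictor plus manual reanalysis with a
transparent, reproducible procedure implementing the same cryptic-peak
logic.

## Origin counting

Tip states are binary: canonical 0, noncanonical or semicanonical 1 (both
depart from the canonical template). The root is fixed canonical, because a
single canonical ancestor for land plants is the inferred starting point.
By default the gain of noncanonical structure is irreversible: once the
modular loop is lost, regaining it wholesale is not considered a credible
event, and the statistic is the minimum number of 0→1 edges with 1→0
forbidden (Sankoff-style DP, exact). An `allow_reversals=True` mode
implements equal-cost reversals with the 0→1 count minimised secondarily
among minimum-change labelings; note that under that rule a single gain
plus a reversal can undercut two independent gains whenever two
noncanonical tips share a sparsely populated subtree, which is why it is
not the default. Long-branch clades are flagged when the median distance
from the clade root (MRCA, or the parent node for single-tip clades) to its
tips exceeds a ratio (default 2.0) times the tip-level median of the same
measure — the published observation is qualitative, so the statistic and
threshold are package choices.

The bundled reference cladogram encodes the major-clade arrangement — a
bryophyte canonical outgroup, the two independently derived bryophyte
noncanonical lineages, the lycophyte pair, and the three euphyllophyte
lineages with each noncanonical angiosperm clade sister to a canonical
clade (PIN9 inside the PIN1 group) — with the seven noncanonical lineages
(PIN5, PIN6, PIN8, PIN9, PIN12, PIND, the Marchantia W/X/Y group as one)
as an interpretation of the published clade set, recorded in the fixture
header. On it the default statistic is 7.

## Synthetic families

The generator builds a canonical template — anchors verbatim, ten
hydrophobic helix segments (21 residues each, ≥8-residue hydrophilic
spacers so the smoothing window can resolve them; the third N-domain helix
is a low-amplitude `ILSTA` repeat whose smoothed peak falls between the
detection floor and the primary cutoff, exercising cryptic recovery), the
invariant tyrosine at C123, and a modular loop assembled from the default
motif library with the three-motif unit planted four times. The 312
transmembrane positions are assigned to conservation bands with fractions
mirroring the published family-wide band counts (56/49/58/30 over 312,
remainder below 90%), high bands placed preferentially in helices and
anchors (helices are the most conserved parts of the domains); members draw
i.i.d. per-position substitutions at the band rate, category-preserving
(hydrophobic↔hydrophobic) so hydropathy structure survives. Loop columns
substitute at 0.02 (HC regions), 0.06 (other motifs) and 0.25 (spacers).

Noncanonical clades replace the loop with a random 32–120 residue sequence
and elevate transmembrane substitution to 0.30 outside a retained invariant
core of 50 positions (anchors and C123 always included), which makes the
within-clade invariant fraction of a noncanonical clade ≈16% of 312.
Canonical members carry an N97/N98 insertion of 1–18 hydrophilic residues
with probability 0.08. Each canonical clade drops a random subset of the
non-HC motifs (probability 0.4 per droppable motif), emulating
clade-specific motif loss.

EST-style truncation removes geometric-length prefixes/suffixes from ~85%
of members (the rest stay full length), calibrated over a few
deficit-correction rounds to hit a target alignment missing fraction
(default 0.45 ± 0.03 realized); fragments shorter than 100 residues are
resampled, mimicking the discard of very short sequences. The alignment
covers the template's canonical columns (insertions excluded, noncanonical
loops unalignable hence gapped), which is how such alignments treat those
regions in practice. One integer-seeded NumPy generator drives everything;
identical configurations give byte-identical files. The study-scale preset
(11 clades × 43 members = 473 rows, 3 noncanonical clades) matches the
scale of the analysed real alignment.

What the generator does *not* emulate: phylogenetic correlation of
substitutions (noise is i.i.d. given the template, so family-wide band
fractions concentrate, but within-clade self-identity of canonical clades
is lower than in real data, where most variation is between clades);
realistic substitution processes (no rate matrix); codon structure; and
alignment error. Tests passing on generator data therefore demonstrate the
correctness of the *operations* (delineation, scoring, counting, recovery
under noise and truncation), not field performance on real families.

## Problem sizes and determinism

Default test families are 8 clades × 25 members (200 sequences); the
acceptance script uses the 473-row study-scale preset, 200 sequences for
helix recovery, and 500 random ≤12-tip trees for verifying the origin DP
against exhaustive enumeration — sizes chosen so the whole suite runs in a
few minutes on one core. All stochastic tests are fixed-seed; every
threshold left open by the method description is a recorded default in
`RunConfig` and appears in the run manifest.
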