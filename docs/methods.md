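# Methods

This note records the models, conventions and numerical choices behind
`structgroups`, and what the synthetic fixtures do and do not establish.

## Data model and coordinate conventions

Structures follow the archival hierarchy: an *entry* (one deposited
structure or one computed model), its *entities* (distinct polymer
sequences), and *instances* (chains). All sequence positions are 1-based
and inclusive, following the mmCIF `label_seq_id` convention; alignment
columns and every positional track inherit this coordinate system.
Residues present in an entity sequence but absent from the coordinates
are kept as `modeled=False` records, which is what lets tracks
distinguish an unmodeled loop (no density) from a deletion (no residue).
Provenance (experimental vs computed) is always declared by the caller —
sidecar metadata or a CLI flag — never inferred from the coordinate
content; heuristics on B-factor ranges are fragile, and real corpora
carry provenance as metadata. For computed models the B-factor column is
interpreted as per-residue pLDDT in [0, 100]. Modified or non-standard
residues map to `X`. Insertion-coded residues in legacy PDB input are
renumbered sequentially with a logged mapping, because downstream tracks
need a single integer coordinate per chain.

Water and the twenty standard amino acids are never ligands; every other
non-polymer component is.

## Pairwise alignment

Global alignment uses the Gotoh three-state dynamic program with a
substitution matrix (BLOSUM62 default, includes `X`) and affine gaps: a
gap run of length k costs `gap_open + k·gap_extend`, defaults 11 and 1.
Terminal gaps are penalized (true global alignment). Traceback ties are
broken deterministically — diagonal, then up, then left — so identical
inputs always give identical alignments. The test suite checks score
equality against an independently written memoized-recursion scorer on
hundreds of seeded random pairs; the two implementations share only the
scoring model.

## Sequence-identity clustering

Identity is `(# identical aligned columns) / min(|a|, |b|)`. Min-length
normalization is a deliberate choice: it makes a full-length chain and an
exact fragment of it identical at 100%, which matches how same-sequence
groups are used in practice. Clustering is greedy centroid assignment:
entities sorted by (length descending, uid ascending); each joins the
first existing representative meeting the threshold, else founds a new
cluster. Only entity-vs-representative comparisons are made. This is
transparent and exactly testable at desk scale; it is *not* a
reimplementation of any production cascaded-clustering pipeline, and a
file-import path exists for users who cluster externally. Incremental
updates scan existing representatives in cluster-id order and never
disturb existing memberships; cluster ids are `<pct>_<ordinal>`
zero-padded so lexicographic order equals founding order.

## Group alignment (star topology)

A group alignment is reference-anchored: columns are positions 1..L of
one reference sequence (the accession's reference sequence, or the
cluster representative), and every member is aligned to it pairwise.
Member insertions relative to the reference get no column — they cannot
be displayed against reference coordinates — but are preserved in the
data model. The consequence, accepted deliberately, is that insertions
are not aligned member-vs-member; a progressive MSA would do that at the
cost of an unstable column system.

Consensus counts the modal symbol per column, where members whose aligned
span covers the column but lack a residue count as *gap*, and members
whose span does not reach the column (terminal truncation) are excluded
from the tally. Ties break residue-over-gap, then alphabetically.
Variation is `1 − (modal residue count / members with a residue)`,
in [0, 1], undefined (None) at depth-0 columns. Alignments paginate in
blocks of 50 member tracks.

When no external accession→sequence mapping is supplied, the reference
for an accession group defaults to its longest member sequence (ties by
uid); this keeps the tool usable fully offline.

## Tracks

Three denominators are used, on purpose:

- structural-feature frequencies (helix, strand, domain) divide by the
  members with a *modeled* residue at the column;
- per-ligand binding frequencies divide by the members contacting that
  ligand *anywhere*, so rarely-present ligands are not diluted to
  near-zero by the group size;
- the global binding histogram is a raw count of (member, ligand)
  contact events per column.

Contacts are heavy-atom minimum distance ≤ 4.5 Å (a common literature
convention; configurable), hydrogens ignored, computed by plain all-pairs
distances — structures here are desk-scale. Secondary structure is
assigned from CA geometry with P-SEA criteria (via biotite's
implementation), chosen over hydrogen-bond methods because the fixtures
carry ideal backbones without hydrogens and CA-only rules are
self-contained; contiguous modeled segments shorter than 5 residues are
all-coil. pLDDT categories use the 90/70/50 bin edges, half-open on the
lower side (69.9 is "low", 70.0 is "confident"). Mutation markers are
substitution columns only; gaps are not markers.

## Superposition

Correspondences are residue pairs sharing an alignment column, restricted
to residues modeled (with a CA) in both structures and optionally to a
column range; at least 3 pairs are required. The fit is Kabsch/SVD over
CA atoms — the alignment yields residue-level, not atom-level,
correspondence — with the reflection corrected by flipping the smallest
singular vector, and the resulting rigid transformation applied to the
entire entry, ligands included. No outlier trimming is performed: a
single rigid fit is reported, and column-range restriction is the user's
tool for conformational substructure. Collinear point sets are rejected
as degenerate. RMSD can additionally be evaluated over any column range
after fitting, which is how the hinge analysis reports the moving-domain
separation. The rotation is validated to be orthonormal with determinant
+1 to 1e-9.

## Synthetic fixtures: what they emulate, and what they do not

The generator emulates, deterministically from one seed per spec: ideal
backbone geometry from standard bond lengths/angles and torsions (helix
−57/−47, strand −139/+135, coil seeded-random), point-mutation families
with replacement drawn uniformly from all 20 residues (expected identity
1 − rate·19/20), a shared backbone per group plus per-member Gaussian
coordinate jitter (default 0.3 Å) so members behave like independent
determinations of one fold, hinge pairs rotated rigidly about an axis
through a pivot CA built from the fixed side of the chain (so hinge
applications compose exactly), interior unmodeled loops in experimental
members, region-wise pLDDT profiles on computed members
(low-confidence tails, high-confidence core), and single-heavy-atom
ligands placed at a fixed distance from an anchor CA, pointing away from
the chain centroid.

The default spec — nine ~100-residue variants, five experimental and
four computed, 5% mutation rate, one sugar-like ligand — mirrors the
archival situation the group tools target: a small family where
experimental entries and models of the same protein must be summarized
and compared together.

Not emulated: sidechains, chemistry or energies, crystallographic
artifacts, real pLDDT error structure, multi-chain assemblies beyond
simple instancing, or real evolutionary substitution patterns (mutations
are uniform, not BLOSUM-distributed). Passing tests therefore establish
the *bookkeeping and numerics* — coordinate systems, denominators,
determinism, fit optimality — not performance on real archival data, for
which clustering parameters and contact cutoffs may warrant tuning.

## Serialization and pipeline

Export documents (group alignment, group annotations, grouping
provenance) are pydantic models; the JSON Schemas shipped under
`structgroups/schemas/` are generated from those models and a test keeps
them in sync. JSON is dumped with sorted keys, so export → import →
export is byte-stable. The pipeline runs cluster → group → align →
tracks → superpose → export in dependency order, logs each stage with
its parameters, writes a run summary with the software version, a
config hash (excluding the output location) and the seed, and produces
byte-identical output trees for identical configs. Sequence-only runs
mark coordinate-dependent stages as "skipped: no coordinates"; any stage
failure aborts with a stage-named error and leaves a `FAILED` marker.

Problem sizes used by the shipped checks — 10-point clouds for the
superposition oracle, 200 alignment pairs of length ≤ 40, 10-member
mutant families at mutation rates {0, 0.05, 0.3}, a 20-entity set for
the end-to-end run — were chosen as the smallest sizes at which the
properties under test are non-trivial.

## Known limitations

- Star alignment cannot represent member-vs-member insertions.
- Greedy clustering is order-dependent by construction (the order is
  fixed and documented); it does not promise to match any external
  clustering tool's memberships.
- Member ranking uses reference coverage with date/uid tie-breaks only;
  no quality or resolution criteria.
- Deposition groups are taken from metadata as-is; no deposition-system
  integration exists.
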