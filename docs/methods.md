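# Methods

## Structural model

Structures are parsed with gemmi into a minimal chain → residue → atom
hierarchy. Only the first coordinate model of multi-model files is kept
(deposited cryo-EM/crystal structures present one conformation per entry),
hydrogens are dropped (all criteria are heavy-atom), and alternate locations
are collapsed to the highest-occupancy conformer with ties broken by altloc
letter ('A' first). Residue numbering is author numbering throughout, so
motif positions in structures and sequences line up. Waters are retained but
flagged and never participate in contacts. The deposited asymmetric unit is
used as-is; no symmetry mates or biological-assembly expansion are
generated, so "different subunits" means different chain identifiers in the
coordinate file.

## The geometric screen

Two anchor-atom distance criteria define a candidate site, both with a 5 Å
cutoff, inclusive: adenine C5 to the CG γ-carbon of aromatic residues
(Tyr/Trp/Phe/His), and γ-phosphate PG to arginine CZ. The C5 and CG anchors
make criterion 1 cheap and ligand-pose-insensitive; a full stacking test is
applied only on top of it.

**Stacking.** π–π stacking is not defined by the distance criteria alone, so
the screen uses standard literature geometry: ring-centroid separation
≤ 5.0 Å and interplanar angle ≤ 30°, with planes fit by least squares (SVD)
to the 9-atom purine system and to the side-chain ring (6-ring for Tyr/Phe,
5-ring for His, the full 9-atom bicyclic system for Trp). The angle between
plane normals is folded into [0°, 90°] so ring flip is irrelevant. Both
thresholds are parameters of `ScreenCriteria`.

**Tiers and pair selection.** Sites are triaged into T1 (≥ 2 aromatic
contacts), T2 (pair spans two chains), T3 (both members stacked), T4 (plus
an Arg–γ-phosphate contact; requires a triphosphate ligand). "Paired" is
read as at least two distinct aromatic residues each satisfying criterion 1.
When more than two contacts exist, every pair is evaluated and the site's
tier is the best tier any pair achieves; among pairs achieving it, the one
with the smallest summed C5–CG distance is reported. Choosing purely by
summed distance was considered and rejected: a close same-chain pair could
then mask a genuine cross-subunit pair, and the tier would no longer be
monotone under cutoff changes (tightening a cutoff could *raise* a tier by
removing the masking pair). With best-tier selection, tightening any cutoff
only removes candidate pairs and can never raise the tier — a property the
test suite asserts directly.

Each ligand copy is screened independently; a structure's tier, when
summarised per entry, is the maximum over its ligands. ADP/AMP are admitted
only in `criterion1_only` mode, which also skips the arginine criterion, so
that mode can never report T4. All orderings (contacts, arginines, rows) are
deterministic: distance first, then chain and residue number.

## Superposition

Cα atoms are paired across models by identical (chain, residue number,
insertion code, component) — the intended comparison is between bound and
free forms of the same construct, so sequence-alignment-driven pairing is
out of scope. The optimal rotation is the Kabsch SVD solution with the
determinant sign corrected to exclude reflections; RMSD is the root mean
square residual after applying the transform. Degenerate (collinear) point
sets and correspondences under 3 pairs raise typed errors. A single pass is
used — no outlier-rejection iteration — matching how a plain Cα RMSD is
reported. The allosteric-to-catalytic separation is operationalised as the
centroid distance from the nucleotide's heavy atoms to the nearest instance
of the cofactor component (e.g. TPP).

## Motif scanning and identity

The scanner checks the eight anchors at exact offsets (0, 1, 4, 8, 9, 17,
19, 51) from each candidate start, left to right; `X` never matches an
anchor. Exact spacing is stricter than checking residue identity inside a
multiple alignment (which tolerates indels between anchors); an optional
per-gap `spacer_slack` lets each inter-anchor gap stretch by up to that many
residues, with the leftmost placement reported. The default is 0: the
intended inputs are high-identity families where anchor spacing is
conserved, and exactness is what makes prevalence recovery deterministic.

Percent identity is computed by global Needleman–Wunsch alignment
(Biopython's PairwiseAligner) with unit match score, zero mismatch and
affine gap penalties of 10 (open) and 0.5 (extend), as identical columns
over all alignment columns including gap columns. End gaps are penalised
like internal ones and the argument order is canonicalised before aligning;
both choices exist to make the measure exactly symmetric even when
co-optimal alignments exist, at the cost of punishing length differences —
appropriate for a ≥ 60 % same-family filter, not for domain extraction.

## Logo data

Anchor-centred windows (default flank 3, merged where windows overlap) are
indexed by offset from the leading proline. Per-column information content
is log2(20) − H with frequencies over the 20 residues, a uniform background
and no small-sample correction — the intended inputs have hundreds of
sequences, where the correction is negligible. Gaps (window truncation at
sequence ends, non-standard letters) are counted separately and excluded
from the entropy rather than treated as a 21st symbol; all-gap columns are
reported as missing.

## Distances and trees

Pairwise distances over an alignment are uncorrected p-distances
(mismatches over columns where neither sequence has a gap) — the simplest
defensible model at the high identities the survey targets, and the one
whose additive-recovery behaviour is easiest to verify. Neighbor joining
follows Saitou–Nei: join the pair minimising the Q-criterion, branch lengths
from the standard formulas, new distances by the reduction formula, and a
closed-form three-taxon star at the end. Ties in Q are broken by the lowest
(i, j) index pair so output is deterministic; negative branch lengths are
clamped to zero with the deficit moved to the sibling branch (standard
practice), and pre-clamp lengths are retained for diagnostics. The
implementation is in-package because the tie-break and clamping behaviour
are part of the contract; dendropy and scikit-bio serve as independent
cross-checks in the tests, never as the implementation. Multiple sequence
alignment itself is out of scope: callers supply an alignment, and the
synthetic generator emits gap-free families that are trivially aligned.

## Synthetic fixtures

**Structures.** Each fixture is an idealised adenine nucleotide (planar
purine with standard 1.39 Å ring bonds, correct atom names, a PA/PB/PG
chain) plus aromatic side chains and an arginine placed by construction:
the ring is tilted by the requested interplanar angle, its centroid held at
the requested height above (or below, for the second ring of the sandwich)
the purine plane, and slid until the C5–CG distance matches the request to
better than 0.01 Å; of the two possible positions the one keeping the ring
centroid nearest the purine centroid is used, so genuinely close placements
also stack. Arginine CZ is placed at the exact requested distance from PG.
Scaffold residues are glycine — no CG atom — so no accidental aromatic
contacts can arise. Six decoy modes each violate exactly one criterion
(far aromatics, a single aromatic, same-chain pair, no stacking, no
arginine), so the intended tier is known by construction; the sidecar label
records it alongside every planted and realised measurement, and the
default full-sandwich design mirrors the characterised site: His 706 on one
chain and Tyr 710 on the other stacking the adenine, Arg 711 at the
γ-phosphate.

What the structural fixtures do *not* emulate: real backbone geometry,
rotamers, crystal contacts, occupancy/disorder, or chemically accurate
nucleotides. Passing tests therefore demonstrate the screen's geometric
logic, not its robustness to real-world coordinate noise.

**Sequences.** Families are derived from a random 800-residue reference
with the motif planted at position 702 (the reference numbering). Members
are mutated at non-anchor columns to a per-sequence identity drawn from a
band (default 70–90 %, comfortably above the 60 % survey filter);
motif-positive members keep every anchor, negatives have the leading P
destroyed, and every emitted sequence is verified free of accidental motif
occurrences, so surveyed prevalence equals the planted fraction exactly.
Fungal-variant members substitute K at the R_a anchor. Real families differ
in having indels, phylogenetic correlation between members, and non-uniform
residue composition; none of these affect what the fixtures are for —
deterministic ground truth.

All generation is driven by a single explicitly seeded NumPy generator;
identical seeds give byte-identical FASTA/PDB/mmCIF output.

## Pipeline and reproducibility

`run_pipeline` executes the stages in dependency order, echoes its config
verbatim into the output directory, and writes a manifest with a SHA-256
hash per artifact. Stage timings go to the log only, so manifests from
identical config + seed are byte-identical. Unknown config keys are
rejected rather than ignored.

## Problem sizes

The bundled checks use sizes chosen to exercise every code path at desk
scale: 100 structure fixtures for screen-vs-ground-truth scoring, 200
sequences for the prevalence survey, 4–8-taxon additive matrices for NJ
recovery, and ≤ 50-point sets for the numerical superposition oracle. These
are the package's own verification sizes, not limits of the methods.

## Known limitations

- The screen trusts deposited coordinates: no occupancy weighting, no
  handling of alternative ligand poses beyond altloc collapse, no symmetry
  expansion (a cross-subunit site split across asymmetric-unit boundaries
  would be missed).
- Exact-spacing motif scanning misses occurrences with indels between
  anchors unless `spacer_slack` is raised.
- Global-alignment identity penalises length differences; fragment
  sequences score low even when their overlap is identical.
- NJ output is a single tree without support values; it is a survey
  visualisation aid, not a phylogenetic inference tool.
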