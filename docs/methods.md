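# Methods

`riboframe` reimplements, as a reusable pipeline, a structural survey of
how 16S rRNA base A1503 engages the mRNA in bacterial 70S ribosome
complexes, together with the quantification arithmetic of the in-vitro
−1 frameshifting assay used to test A1503's role in reading-frame
maintenance. This note records the models, the tunable parameters and the
design choices that were genuinely open.

## Coordinate model and the mRNA register

Structures are parsed (via gemmi, mmCIF or legacy PDB) into a flat atom
table; the first model is used unless configured otherwise, coordinates
are in Å throughout, and insertion codes are kept as part of residue
identity, ordered after their base number. Functional chains are assigned
by length heuristics — 16S rRNA 1400–1700 residues, 23S 2700–3100, tRNAs
55–110, mRNA < 55 — with explicit per-structure configuration overriding
everything; ambiguous cases fail loudly rather than guess. 16S numbering
is assumed E. coli-aligned (true for most bacterial 70S depositions);
a per-structure integer offset covers other numbering schemes, and no
sequence alignment is attempted.

mRNA positions follow the register convention in which **+1 is the first
base of the P-site codon** and negative positions run 5′ (E-site side);
there is no position 0, so positions −1 and +1 are adjacent residues. The
P codon is located geometrically: the mRNA triplet whose three bases each
make a Watson–Crick-edge heavy-atom contact ≤ 3.5 Å (configurable; the
canonical H-bond distance) with residues 34–36 of a tRNA anticodon,
paired antiparallel. When one tRNA admits several windows the
tightest-pairing window is used; when several tRNAs qualify the codon
nearest the 5′ end is chosen, because in intermediate (chimeric) states
the site labels of the tRNAs blur. An explicit `p_codon_start` in the
configuration short-circuits detection — this is the intended route for
chimeric complexes whose tRNAs occupy pe/E-like positions. If no triplet
pairs within the cutoff the structure is reported *unresolved*, never
silently guessed.

## Contact geometry

Each base is reduced to the centroid of its canonical ring atoms (purine
N1,C2,N3,C4,C5,C6,N7,C8,N9; pyrimidine N1–C6) and a least-squares plane
normal (smallest-variance axis of the ring-atom cloud). Fewer than 5 ring
atoms — including engineered abasic sites — makes that base unresolvable.

An mRNA base *j* is a **stacking partner** of the query base when all
three hold:

| parameter | default | meaning |
|---|---|---|
| `d_stack` | 4.5 Å | max centroid–centroid distance |
| `alpha_max` | 30° | max acute angle between base planes |
| `omega_max` | 40° | max angle between the centroid–centroid vector and the query normal |
| `d_retract` | 6.0 Å | beyond this the query is out of range entirely |

The ω-test demands genuine face-on stacking; a coplanar edge-on approach
at small distance is rejected. The original screen used centroid
distances plus visual inspection without printed cutoffs; these values
are standard π-stacking geometry ranges, they are configurable, and the
full threshold set is stamped (as a hash and as columns) into every
report so any count is reproducible from the report alone. Whether the
original "stacked" category admitted edge contacts is unknowable from the
publication; face-on was chosen here and is recorded as such.

Calls: **intercalated** = exactly two partners at *adjacent* register
positions with the query centroid between their planes (signed
projections onto the partners' mean normal have opposite signs — robust
to partner-plane disagreement up to `alpha_max`); **stacked** = exactly
one partner, or two partners at non-adjacent positions (nearer partner
kept, warning recorded — intercalation is strictly between neighbouring
bases); **retracted** = no partner; **unresolved** = missing geometry.
Distance ties within 0.01 Å break toward the more 5′ position for
reproducibility. The four calls are mutually exclusive and exhaustive,
invariant under rigid motion, and monotone under a `d_stack` sweep
(retracted → stacked → intercalated only).

## Rotation measurement and state windows

Body and head rotation are measured against a classical-state
(non-rotated) reference structure by a two-stage scheme: (1) superpose
the structure onto the reference on the 23S rRNA core (phosphorus atoms,
excluding the mobile L1 stalk ~2093–2196 and A-site finger ~880–898); if
no 23S is present the 16S body serves as the frame, flagged in the
output; (2) the residual least-squares rotation of the 30S body domain,
decomposed to axis–angle (Euler–Rodrigues, i.e. unit-quaternion
parameters with stable branch selection near 0° and 180°), gives the body
angle; (3) after aligning body frames, the residual head-domain rotation
gives the head angle — head swivel is thus measured against the body, not
the 50S, which is the convention behind the published windows. The head
domain defaults to 16S residues 930–1381 and the body to the remainder;
these community-standard boundaries are configurable because any
reproduction of the rotation scatter depends on them. Superposition is
the Kabsch algorithm (SVD with determinant correction); degenerate
(n < 3 or collinear) sets are rejected.

Angles are reported as magnitudes with a sign flag relative to an
optional recorded forward-rotation axis, because the state windows are
defined on magnitudes. State call, precedence chimeric > hybrid >
classical:

* **chimeric-hybrid**: head rotation in [15°, 21°]
* **hybrid**: body rotation in [6°, 10°] (forward sense when a reference
  handedness is recorded)
* **classical**: body ≤ 3° and head ≤ 6° (the published definition is
  only "non-rotated"; these cutoffs are this package's declared
  operationalisation, stamped into outputs)
* **unassigned**: anything else, including the window gaps (e.g. body 4°)
  that the original classification leaves unspecified.

## Survey batch and confidence filter

The per-structure pipeline (read → chains → register → A1503 contact
against positions −4…+4, optionally C1397 against +7…+10 → rotation →
state) never aborts the batch: failures become records with a reason. The
original census kept 209 of 672 deposited structures "with reasonable
confidence, based on local resolution and/or map quality" — a partly
subjective step that a coordinates-only pipeline cannot replay. The
declared stand-in filter passes a structure iff its reported resolution
is ≤ `r_max` (default 4.0 Å), the register resolved, and A1503 plus mRNA
positions −4…+1 each retain ≥ 5 ring atoms; a missing reported resolution
fails conservatively. Counts produced under this filter are expected to
approximate, not equal, the published census, and any deviation is
traceable through the per-structure report.

Aggregation yields one row per state — total, intercalated (with the
modal partner pair, written codon-proximal first, e.g. "−1|−2"), stacked,
retracted, percentages — with unresolved contacts, unassigned states and
failed records tallied separately, so each row satisfies
total = intercalated + stacked + retracted exactly.

## Frameshift-assay arithmetic

Products are [35S]-Met labeled, so band intensity scales with methionine
content: each band is divided by the number of **internal** methionines
of its predicted product before any comparison. "Internal" excludes only
the initiator (position 1); the alternative (also discounting a retained
fMet) is not what the methods describe and was not adopted. Then, per
replicate: percent frameshift = 100·fs/(fs+full); −1/0-frame ratio =
fs/full, which is identically p/(100−p); activity = (full+fs) of the lane
over (full+fs) of the control lane of the same replicate. Replicates are
summarized as mean ± SEM (sample sd/√N, N ≥ 2), and ratios are averaged
per replicate — recomputing a ratio from the mean percent gives a
different number whenever replicates vary, and the published per-
construct pairs (e.g. 42.3% with ratio 0.75) are consistent only with
per-replicate averaging. All outputs are invariant under rescaling a
lane set's intensities. Background subtraction is assumed upstream;
inputs are already background-corrected. Display rounding is 2 decimals;
full precision is kept internally.

## Synthetic fixtures

The generator provides the labeled inputs for every test:

* **Contact scenes** — idealized planar base templates (regular 1.39 Å
  rings; a fused regular pentagon for purines) stacked single-strand at
  3.4 Å rise, positions −4…+3 with a configurable intercalation gap. The
  query base is inserted midway in a doubled gap (intercalated), face-on
  3.4 Å over the terminal base (stacked), or ≥ `d_retract` + margin away
  (retracted). Isotropic Gaussian noise is added per atom; the scene is
  redrawn until the construction label holds with ≥ 0.5 Å margin beyond
  the classifier thresholds (checked by direct centroid bookkeeping,
  never by the classifier under test), and raises rather than mislabel.
  A P-site tRNA anticodon (in-plane translated copies of the codon
  bases) makes the register detectable by the real code path.
* **Rotated subunits** — seeded Gaussian point clouds for body, head and
  23S core; the rotated copy applies the body rotation to body+head then
  the head rotation about the head centroid, so the injected angles are
  exact ground truth; noise perturbs the rotated copy only. Batches
  measured against one shared reference must share the `subunit_seed`
  that fixes the underlying clouds.

What the fixtures do *not* emulate: real RNA backbones and sugar
puckers, modified-nucleotide geometry, correlated (non-isotropic)
coordinate error, crystallographic disorder, and the map-quality
judgement behind the published confidence step. Passing tests therefore
demonstrate the correctness of the geometry, the measurement and the
bookkeeping — not the field-accuracy of the thresholds on deposited
structures, which remain configurable for exactly that reason.

## Problem sizes and numerics

The validation runs use a 6×6 grid of injected angles in [0°, 25°]
(noise-free recovery < 0.01°; observed ~1e-13) plus 200 noisy trials at
σ = 0.3 Å (≥ 95% within 0.5°; observed 100%), 200 scenes per contact
class (100% label agreement) and 100 random rigid motions (100%
invariance); the stand-in survey uses 209 structures in the published
per-state composition. Rotation matrices are validated orthogonal with
det +1 to 1e-6 before decomposition; axis recovery near 180° uses the
largest-diagonal quaternion branch; base planes come from SVD, with the
normal sign fixed toward the 5′ neighbour when available.

## Known limitations

* Chain heuristics target bacterial 70S complexes; eukaryotic or
  mitochondrial ribosomes need explicit chain hints.
* The confidence filter cannot see local map resolution; it is a
  declared proxy.
* Head/body domain boundaries are defaults, not assertions about the
  boundaries used in any particular published measurement.
* The fetch-by-accession helper requires network access and is never
  exercised in tests.
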