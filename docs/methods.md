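# Methods

## The model

`diffcontact` treats a protein conformation as the set of its
residue–residue contacts and a conformational change as the symmetric
difference of two such sets, restricted to changes large enough to
reflect a collective motion. The procedure for a pair of structure
models A and B of (nearly) the same protein:

1. **Parsing.** Each PDB file is reduced to one chain's eligible
   residues: ATOM records only (no HETATM), empty insertion code,
   hydrogens removed, and one conformer per atom name when alternate
   locations are present (highest occupancy wins; ties go to the
   smallest altloc identifier). Multi-model files contribute a single
   model (the first, by default). Each observed residue is assigned its
   position in the chain's SEQRES sequence.
2. **Residue pairing.** The two SEQRES sequences are aligned globally
   (Needleman–Wunsch, BLOSUM62, gap open 10, gap extend 0.5). Columns
   where either side is a gap, or where either side's SEQRES position
   has no observed coordinates, are removed; the surviving columns form
   a strictly monotone one-to-one residue map. At the ≥95% sequence
   identity this method assumes, the pairing is insensitive to the
   scoring parameters; they are fixed and recorded in the outputs for
   reproducibility.
3. **Skip rule.** If more than 5% of the paired residues have different
   3-letter names the pair is not comparable and the run stops with a
   dedicated status. The threshold is strict: exactly 5% passes.
   Comparing 3-letter names makes point mutations count as mismatches
   while identical nonstandard residues do not. Because the map is
   one-to-one, the number of extracted residues is equal on both sides
   by construction.
4. **Contacts.** For each mapped pair (i, j) with j − i ≥
   `min_seq_separation`, the inter-residue distance is the minimum
   Euclidean distance over all pairs of side-chain heavy atoms
   (non-hydrogen atoms excluding backbone N, Cα, C, O and terminal OXT);
   glycine contributes its Cα instead. A pair is in contact when this
   distance is strictly below `contact_threshold`. Residues without any
   side-chain heavy atoms form no contacts — inventing a position for an
   unresolved side chain would fabricate interactions.
5. **Difference and filter.** The difference contact map is the
   symmetric set difference of the two contact sets, each entry labelled
   with the conformation it belongs to and annotated with the distance
   in both models. An entry survives the filter iff its distance change
   |d_A − d_B| is strictly greater than `delta_threshold`; a change of
   exactly the threshold is removed. The filter uses the same
   minimum-side-chain-distance metric as the contact definition — the
   only inter-residue distance the method defines (a Cα–Cα variant would
   be a different, coarser notion of "moved apart"). Entries whose
   change cannot be evaluated because one side's side chain is
   unresolved are excluded from the filtered map with a logged warning.
6. **DSRs.** The differentially stabilizing residues are the union of
   residues over filtered entries, reported with both models' author
   numbering (which may disagree) and per-residue filtered-contact
   counts.

## Parameters

| parameter            | default | unit | meaning |
|----------------------|---------|------|---------|
| `contact_threshold`  | 5.0     | Å    | contact iff min side-chain heavy-atom distance < this; 5 Å is the upper end of the direct-interaction range, beyond which water-mediated contacts begin |
| `delta_threshold`    | 5.0     | Å    | difference entries with distance change ≤ this are treated as local fluctuations and removed |
| `mismatch_tolerance` | 0.05    | —    | maximum fraction of differing paired residues (strict >) |
| `min_seq_separation` | 1       | —    | minimum mapped-index separation for a contact; 1 means sequence neighbours are eligible, since the method defines no separation filter. A value of 2 excludes them; the option exists because trivially-adjacent side chains are a known source of uninformative contacts |

Summary metrics: the pair's RMSD is computed over the mapped Cα pairs
after least-squares optimal (Kabsch) superposition — the community
default when no superposition protocol is prescribed. The
changed-contact fraction divides the number of filtered entries by the
*total number of contacts*; "total" is taken as |contacts_A ∪
contacts_B| by default because the union is symmetric in A/B and bounds
the numerator (fraction ∈ [0, 1]); per-conformation mean and minimum are
available as alternatives and the choice is recorded in the output.

## Boundary and numerical choices

- All distance comparisons are made in double precision with no
  rounding. PDB coordinates carry three decimals; rounding distances
  would create artifacts exactly at the thresholds the method is defined
  by.
- Contact detection uses a k-d tree over side-chain atoms
  (`scipy.spatial.cKDTree.query_pairs`), followed by an exact per-pair
  minimum. Every atom pair within the threshold is enumerated, so the
  per-residue-pair minimum over those atom pairs equals the true minimum
  whenever it lies below the threshold; the strict `<` cut is applied to
  the recomputed exact distances.
- Contact boundary is strict (< 5 Å); filter removal is non-strict
  (≤ 5 Å); the mismatch rule is strict (> 5%).
- Superposition uses `scipy.spatial.transform.Rotation.align_vectors`
  (SVD-based Kabsch) on centered coordinates; rigid-motion invariance
  holds to ~1e-7 Å in memory and to ~1e-3 Å through a PDB write/read
  cycle (the file format's 3-decimal precision).

## The synthetic-data generator

Real conformational pairs cannot be bundled, so the `fixtures` module
generates them. The artificial protein is a poly-alanine hairpin: two
arms of Cα positions 3.8 Å apart, facing each other across a 5.2 Å gap
so their side chains form a contact interface; every seventh residue is
glycine to exercise the Cα rule; a small uniform jitter (±0.3 Å,
seed-driven) decorrelates fixtures across seeds. Conformation B applies
one of four motions to the residues past a hinge point: `none`, `rigid`
(whole-body rotation + translation — a negative control that must
produce an empty difference map and zero RMSD), `hinge` (rotation of the
second arm about an axis through the first moving residue, giving
distance changes that grow with lever arm so that near-hinge entries
fall below the delta filter and far ones above it), and `shear` (a
translation of the second arm).

Designated probe residues carry a single side-chain pseudo-atom placed
to realize *planted* inter-residue distances in each conformation. The
anchor residue's side-chain atom is snapped to integer coordinates and
the probe is placed axis-aligned at the requested distance, so that
after the file's 3-decimal rounding the measured distance equals the
planted value exactly — including values sitting exactly on a threshold
(a 5.000 Å planted contact is reliably *not* a contact under the strict
comparison, with no floating-point leakage). Unrealizable requests (e.g.
a residue serving as both probe and anchor, so that placing one breaks
the other) are detected by post-hoc measurement and rejected with the
offending pair named.

Ground truth is never trusted from construction: it is re-measured from
the emitted PDB texts by an independent brute-force pass — a minimal
column-sliced ATOM reader and an O(n²) all-pairs distance scan kept free
of the package's parser and contact code — so a writer bug cannot
propagate into the expected values.

What the generator does *not* emulate: physically realistic backbone
geometry, rotamers, missing density, alternate locations, nonstandard
residues, numbering offsets between depositions, or crystallographic
artifacts. Passing the fixture suite therefore demonstrates that the
set algebra, thresholds, boundary semantics and bookkeeping are correct,
not that real-PDB parsing corner cases are all covered; the worked
examples on downloaded PDB entries (see `tests/test_acceptance.py`)
cover the latter and require network access on first run.

## Problem sizes

The test suite and `scripts/acceptance.py` use fixtures of 20–40
residues and 20-fixture recovery sweeps; at these sizes the full
pipeline runs in milliseconds per pair and the brute-force oracle in
well under a second, while still exercising every rule (glycines,
planted boundaries, all four motions, the 5% mismatch boundary at
n = 100). Real kinase-sized chains (~300 residues) take well under a
second per pair.

## Known limitations

- Exact reproduction of published contact counts for real pairs can
  hinge on conventions the method leaves open (alignment end-gap
  handling, whether sequence-adjacent contacts are counted); the
  `min_seq_separation` option and the recorded alignment parameters
  document these degrees of freedom.
- The reference RMSD values attached to well-known conformational pairs
  come from an unpublished superposition protocol; the Cα/Kabsch value
  computed here may differ at the few-tenths-of-an-Ångström level.
- mmCIF input, biological assemblies, symmetry mates and
  occupancy-weighted multi-conformer geometry are out of scope; only
  MODEL 1 of multi-model files is used unless another index is given.
- Bound/unbound classification of the two models and survey-scale
  analyses over the whole PDB are out of scope; the `summarize` batch
  interface operates on user-supplied pair manifests instead.
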