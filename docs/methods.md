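# Methods

This note documents the models, parameters and design choices behind
`rnainterolog`, and what the synthetic validation does and does not
demonstrate.

## Contact definition and typing

A contact is an amino-acid/nucleotide pair with at least one heavy-atom pair
strictly below the cutoff (default **5.0 Å**); hydrogens are parsed but
excluded from all counts. `n_atomic` is the exact number of heavy-atom pairs
under the cutoff and `n_apolar` its carbon–carbon subset, both computed with
a k-d tree and verified in tests against a brute-force double loop.

The polar/stacking detectors are purely geometric, so the package has no
external annotation-binary dependency (a reader for saved third-party
annotation output can be substituted where available):

* **Hydrogen bonds** — donor and acceptor heavy atoms come from bundled
  per-residue tables (sidechain and backbone donors/acceptors for the 20
  amino acids; base, ribose 2′-OH and phosphate atoms for A/C/G/U). Criterion:
  D–A ≤ **3.5 Å**; when explicit hydrogens are present near the donor the
  D–H…A angle must be ≥ **120°**, otherwise the distance criterion alone
  decides (hydrogen positions are not inferable from heavy atoms in general,
  and most crystal structures at ≤ 2.5 Å deposit none). C–H…O interactions
  are not counted. Each bond records the amino-acid moiety
  (sidechain/backbone) and nucleotide moiety (base/sugar/phosphate).
* **Salt bridges** — a basic sidechain nitrogen (Lys NZ; Arg NE/NH1/NH2; His
  ND1/NE2) within **4.0 Å** of a phosphate oxygen (OP1/OP2/O5′/O3′).
  Detection is independent of the H-bond detector; the subtype relationship
  (salt bridges as short ionic H-bonds) is a reporting convention only.
* **π-stacking** — an aromatic sidechain ring (His/Phe/Tyr/Trp; both Trp
  rings) and a base ring (purines contribute both rings) with centroid
  distance ≤ **5.0 Å**, best-fit plane angle ≤ **30°**, and lateral offset of
  one centroid from the other ring's normal axis ≤ **2.0 Å**. Cation-π is out
  of scope.
* **Base pairs** — Watson–Crick-like geometry: the glycosidic-face atoms
  (purine N1, pyrimidine N3) 2.5–3.5 Å apart with base planes within 30°,
  excluding sequence neighbours; each base joins at most one pair, assigned
  greedily by a geometry-quality score (base triples therefore resolve to
  their best pairing — behaviour for triples is otherwise unspecified).

All detectors are invariant under rigid motion (property-tested with random
rotations). Because every typing criterion operates below 5 Å, a typed
interaction always sits on a stored atomic contact.

## Structure model and quality filters

PDB and mmCIF files are parsed with gemmi; only model 1 is read, altlocs are
reduced to the highest-occupancy conformer (ties: first encountered), and
non-standard residues are standardized through an editable parent-component
table (`data/residue_parents.tsv`); unmappable residues become `other` and
are excluded from typed chains. Chains are typed by the majority polymer
kind, a heuristic flagged with a warning on mixed-content chains. Biological
assemblies are not generated internally; the coordinates provided are the
coordinates analyzed.

Structure-level filters (all strict inequalities, so boundary values pass):
NMR excluded, resolution ≤ **2.5 Å** and present (a missing resolution fails,
since "worse than 2.5 Å" cannot be evaluated without a value), protein chains
≥ **30 aa** and not Cα-only, RNA chains ≥ **10 nt** and not P-only.
Interfaces keep ≥ **5** protein and ≥ **5** RNA interface residues.

Two RNA chains merge into one double-stranded partner when at least one
amino acid contacts two inter-chain base-paired nucleotides, one from each
chain; merged chains are not also emitted separately, and junctions of three
or more chains emit each qualifying two-chain merge with a warning.

Redundancy clustering is single-linkage at 100 % protein / ≥ 99 % RNA
identity on global pairwise alignments (matches / alignment columns). At
these near-duplicate thresholds an exact-plus-alignment implementation is
equivalent in intent to dedicated clustering tools and removes two binary
dependencies. Representatives take the numerically smallest resolution;
resolution ties and missing values fall back to lexicographic interface id.

## Structural correspondence and pair metrics

The TM-align family of aligners is wrapped (TM-align for proteins, RNA-align
for RNAs, MM-align for the joint interface), and their stdout is parsed for
the alignment columns and the dual TM-score report, keeping the score
normalized by the smaller molecule/interface. Outputs are cached so an
analysis can re-run parse-only. MM-align outputs lacking one molecule type
mark the correspondence failed and the pair is skipped. When no binaries are
available, a built-in fallback derives the correspondence from global
sequence alignment per molecule type, the superposition by least squares
(Kabsch) over mapped CA/P atoms, and TM-scores from the standard
length-normalized formula; this is adequate for close homologs only and is
not a substitute for structural alignment of remote pairs.

Pair metrics:

* **Interface overlap** (per molecule type): interface residues of A whose
  correspondent is itself an interface residue of B, over the smaller
  interface, ×100. The stricter "correspondent must be at the interface"
  reading is the default; a flag exposes the literal "has any correspondent"
  reading.
* **Interface RMSD**: over mapped interface CA (protein) and P (RNA) atoms
  after applying the stored superposition.
* **Structure-based identity**: identical residues over aligned positions,
  optionally restricted to interface positions; the pair's *minimum interface
  sequence identity* is the minimum over protein and RNA, binned into
  [0, 19), [19, 34), [34, 60), [60, 100] (half-open, last bin closed).
* **Sequence-based identity**: Smith–Waterman (BLOSUM62 for protein, +5/−4
  for RNA, affine gaps 10/0.5 — pinned for determinism) weighted by coverage
  (aligned positions / larger molecule length).

Acceptance: interface TM ≥ 0.5 ∧ protein TM ≥ 0.6 (inclusive; the source
thresholds are stated as cutoffs without strictness) ∧ both overlaps > 40 %
(strict: "exceed"), excluding same-entry pairs sharing a chain. The RNA
TM-score is deliberately not a criterion, since flexible RNAs can score low
while the interfaces superpose well. Groups are connected components of the
accepted-pair graph, labeled by the most-represented ECOD T-group/Rfam clan
tags, or "ambiguous".

## Conservation statistics

All statistics operate on the in-scope contact set: contacts whose amino
acid and nucleotide both have structural correspondents. A contact of A is
*matched* when the aligned position pair is a contact of B; otherwise it is
one-sided (`only_A`/`only_B`).

* **Weighted Jaccard** (atomic, apolar): matched contacts contribute the
  average of the two sides' counts; one-sided contacts their own count. A
  matched atomic contact whose apolar count is zero on one side is a
  *non-conserved* apolar contact (it exists on one side only under the apolar
  definition) and contributes its one-sided weight to the denominator.
  Zero-denominator values are absent, never imputed.
* **Unweighted Jaccard** (H-bond, salt bridge, π-stacking): conserved when
  the type is present on both sides of a matched pair, over position pairs
  with the type on at least one side.
* **Switching out** (direction A→B; a flag emits the symmetrized view): an
  interface residue of A switches out when its correspondent makes no
  contacts in B. Weighted fractions weigh each residue by its summed atomic
  contacts. Non-conserved contacts on either side are attributed to
  amino-acid-only, nucleotide-only or joint switching; the split sums to
  100 % over switch-linked contacts.
* **Compensation scenarios** (sidechain H-bonds; salt bridges, which are
  sidechain-mediated by construction): each in-scope bond of A is assigned
  the first matching category of **Cons → SwitchingOut → PropertyLost →
  OtherInter → OtherIntra → OtherNC**. The precedence places switching first
  as the stronger structural event (a switched-out partner makes the
  chemical nature of the correspondent moot). PropertyLost means the
  corresponding amino acid lost sidechain polarity (H-bonds) or is no longer
  Lys/Arg/His (salt bridges). OtherInter requires a same-kind sidechain bond
  with a nucleotide *not* aligned to the original partner; OtherIntra a
  same-kind intramolecular bond with a neighbouring amino acid, detected with
  the same geometric criteria within the 5 Å neighbourhood. Categories are
  exhaustive and mutually exclusive; scenario classification is directional
  (per-pair breakdowns), with a symmetrized average available.
* **Stratified summaries**: conservation is averaged per pair within strata
  (absent values excluded): pair-level strata by identity bin and ribosomal
  character; contact-level strata by secondary-structure pair (same-H /
  same-E / same-C / changed), base-pair status (paired-both / unpaired-both /
  changed), interface region (core-core / any-rim; rim = rASAc > 25 %), and
  evolutionary-conservation bins (0–30 / 30–50 / 50–70 / 70–100 on the
  minimum of the two aligned residues' scores). Per-pair averaging matches
  the distributional (violin-plot) presentation of such data; pooling
  contacts across pairs is the alternative reading and is not implemented.

## Residue annotations

* **Secondary structure**: an external DSSP run is wrapped when available,
  with the 8→3 mapping H/G/I→H, B/E→E, T/S/–(and P)→C; otherwise an internal
  φ/ψ classifier (helix: φ ∈ [−150°, −30°], ψ ∈ [−80°, 40°]; strand:
  φ ∈ [−170°, −45°], ψ ≥ 90° or ≤ −160°; else coil) with per-chain provenance
  recorded. The internal classifier ignores hydrogen-bond patterns and will
  disagree with DSSP at helix/strand termini; it exists so analyses run
  self-contained.
* **rASAc**: Shrake–Rupley SASA of the full complex (biotite, probe 1.4 Å,
  element radii, 500 sphere points per atom) summed per residue and divided
  by the Tien et al. (2013) theoretical maximum ASA, ×100. The reference
  table is pinned and shipped; tools with different normalization constants
  will shift rASAc values by a few percent near the 25 % core/rim boundary.
* **Evolutionary scores**: Rate4Site output is ingested and min–max rescaled
  to 0–100 oriented so higher = more conserved (Rate4Site's raw convention
  is lower = more conserved; a flag flips the orientation for other inputs).
  Degenerate inputs: a single position is an error; all-equal scores map to
  50 with a warning.
* **ECOD/Rfam/ribosomal labels** are ingested from TSVs; ECOD domains with
  residue ranges are filtered to those overlapping interface residues. Pairs
  with a missing annotation on either side are "unknown" and excluded from
  consistency denominators.

## Randomization baselines

Both baselines keep the scaffold — which positions are in the interface and
the backbone geometry — and re-assign identities per molecule type:
*shuffle* permutes the interface residue identities; *resample* keeps each
identity with probability `target_identity/100` and otherwise draws from the
interface's own type-frequency distribution excluding the original identity
(so empirical identity calibrates to the target; verified to 2 % at 500
replicates).

Contacts of all natures are then re-derived on the fixed scaffold:

* a contact survives relabeling iff the new residue pair can still span the
  stored backbone gap — contact kept when
  `reach(aa) + reach(nt) + 5 Å > d(CA, C3′)`, using a bundled table of
  approximate maximal sidechain/base reaches; contacts made through backbone
  atoms always survive (the backbone never changes);
* `n_atomic` and `n_apolar` are rescaled by the new/old residue pair's
  heavy-atom and carbon composition ratios (bundled composition table);
* H-bond/salt-bridge/π-stacking flags survive only if the new amino acid is
  chemically capable (polar / basic / aromatic sidechain); backbone-moiety
  H-bonds survive any amino-acid substitution.

This is a deliberate model of sidechain remodeling on a fixed backbone, not
a re-run of the geometric detectors (no sidechain coordinates exist after
relabeling). The three rules are isolated in `rederive_contacts` so an
alternative reconstruction can be plugged in; output metadata records the
rule set used. Replicate streams derive from `seed + replicate index`; the
same seed reproduces the same summary bit-for-bit.

## Synthetic data

The generator is constructive: given target Jaccard values, contact counts,
and switching fractions, it lays contacts on an amino-acid × nucleotide grid
(a covering diagonal anchors every non-switching residue with a conserved
contact, then unused cells host one-sided contacts), plants switching
residues whose correspondents make no contacts, and assigns typed flags to
disjoint cell sets with chemically capable residue names. Targets are met
exactly up to the nearest achievable rational (e.g. 3/8 for a 0.375 target on
8 cells); infeasible combinations raise errors naming the nearest achievable
value. Ground truth (per-type Jaccard, switching fractions, attribution
split) is recomputed by direct set enumeration over the constructed contact
lists, independent of the statistics code it validates. Planted switching
fractions require enough conserved contacts to anchor every non-switching
residue; the generator refuses otherwise.

Coordinate-level fixtures place minimal atom sets at exact geometries
(donor–acceptor distances, ring plane angles and offsets, standard planar
base frames for Watson–Crick pairing, an atom-shell for burial) so each
detector's outcome is analytically forced.

What the synthetic suite shows: the statistics implement their definitions
exactly, the detectors honour their thresholds, and the baselines order
below originals under realistic residue mixtures. What it does not show:
agreement with any external annotation tool's H-bond/stacking calls on real
coordinates, behaviour of the aligner wrappers beyond their parsers, or the
composition of a real interface dataset — those depend on a dated structure
snapshot and external binaries and are out of scope for the bundled
validation.

## Problem sizes and defaults

The bundled validation and the acceptance script use cohorts of up to 40
simulated pairs (interfaces of ~8–24 amino acids and 8–18 nucleotides,
22–60 atomic contacts) and 100 baseline replicates per pair; cohort defaults
emulate the study conditions (per-type conservation levels near 0.73 / 0.68 /
0.39 / 0.31 / 0.36, unweighted switching 21 % / 17 %, arginine/lysine-rich
interface composition). The full analysis of a real structure snapshot
(hundreds of interfaces, all-vs-all alignment) runs through the same code
path via `rnainterolog report` but requires the external aligners and hours
of alignment compute.

## Known limitations

* H-bond detection without hydrogens is distance-only; weak or bifurcated
  bonds and C–H…O bonds are not modelled.
* The internal secondary-structure fallback is φ/ψ-only.
* The sequence-alignment correspondence fallback cannot find remote
  structural homology; remote-pair analyses need the external aligners.
* The baseline contact-survival gate uses isotropic residue reach; it
  ignores sidechain packing and orientation.
* Base-pair assignment covers Watson–Crick-like geometry only; non-canonical
  pair families are not classified.
* Ribosomal/non-ribosomal labels are ingested, not derived.
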