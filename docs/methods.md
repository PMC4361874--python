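# Methods

## The 7TM frame

The analysis frame is a `BundleDefinition`: seven helices, each with an
inclusive Ballesteros–Weinstein index range and a partition into five
contiguous horizontal sections numbered 1 (extracellular) to 5
(intracellular).  Because the chain alternates direction through the
membrane, each helix records which end of its ascending index range faces
the extracellular side; section numbering always follows the membrane
axis, not the sequence.

The shipped default covers exactly 200 positions.  Helix III spans
3.22–3.55 (34 positions) with sections sized 8/8/4/7/7 — the unique
positive-integer solution to the pairwise products in its published
per-section pair table (8·8 = 64, 8·4 = 32, 4·7 = 28, C(7,2) = 21, …).
The extreme section sizes are likewise fixed: sections I-1 and VII-5 hold
3 positions each (smallest cross-product 9), VI-1 holds 10 and VII-1
holds 9 (largest cross-product 90).  Helix II ends at 2.67, helix IV
starts at 4.39 and helix VI ends at 6.60, so the documented gap patterns
(a missing 4.39; missing 2.66/2.67 and 6.59/6.60) reduce the pair universe
to 19,701 and 18,915 respectively.  The remaining boundaries are not fixed
by any printed constraint; the defaults place the conserved positions
1.52, 1.53, 2.46 and 3.43 in section 4 (the middle-to-intracellular band)
and are plain YAML, editable without touching code.  One published figure
states 581 intrahelical helix III distances with 220/581 = 37.9%; this is
inconsistent with C(34,2) = 561 and with the same table's total (220/561 =
0.39), so the combinatorial value 561 is used throughout.

Adjacency is defined as consecutive BW indices within one helix; the six
inter-helix junction pairs are not adjacent, giving 200 − 7 = 193 adjacent
pairs for the default frame.  BW numbering is serial in both directions
from each `*.50` anchor with no gap insertion.

## Scoring and ranking

For an ensemble, statistics are computed only over the positions present
in every member (the intersection rule above).  Per pair: mean, SD,
minimum, maximum of the Euclidean Cα–Cα distance across members, and the
conservation score mean/SD (the inverse coefficient of variation;
dimensionless, higher = more conserved spacing).

Conventions, all configurable:

* **SD** is the population SD (divide by n).  With tens of members the
  choice is near-immaterial, but it must be fixed: the 20 Å / 0.4 Å ↔ 50
  correspondence is exact only under this convention.
* **Zero SD** (possible for degenerate synthetic input, never observed on
  real ensembles whose scores span roughly 1.5–250) yields a capped
  sentinel score (default 10⁶) and a flag, never infinity.  Zero detection
  tolerates the ulp-sized SD that identical members can leave behind
  (threshold 10⁻⁹ relative to the mean).
* **Ranking** removes adjacent pairs first (they sit at ~3.8 Å in any
  helix and score highly for trivial reasons), then sorts by descending
  score with ties broken by canonical pair order, making the result
  independent of input row order.  Exactly `top_n` rows feed the
  classification; the full ranking stays available.
* **Histograms** default to 5 score units and 0.5 Å bins; capped rows are
  excluded from the score histogram.

## Classification and normalisation

Top-N pairs are binned into 28 unordered helix pairs and 630 unordered
section pairs (105 intrahelical = 7 × [C(5,2) + 5]; 525 interhelical =
21 × 25).  Each bin's count is normalised by the number of pairs the bin
could contribute over the common positions, so missing positions shrink
the denominators.

By default the denominators count *all* combinatorial pairs, including
adjacent ones, while the numerator comes from the adjacency-excluded
ranking.  This asymmetry is deliberate: it reproduces the conventional
reporting in which a 34-residue helix's intrahelical total is printed as
561 even though its 33 adjacent pairs can never be ranked.  Setting
`denominator_excludes_adjacent=True` gives fully consistent universes
(561 → 528 for helix III).

For an intrahelical helix filter the section table mirrors the
conventional layout: all ten cross-section bins individually, same-section
bins only for section 4 (`same_section_detail` parameter), the remaining
same-section bins pooled into an `others` row (28 + 28 + 6 + 21 = 83 for
helix III), and a closing `total` row.  Which same-section rows merit
individual listing is a reporting choice, not a mathematical one; the
default highlights the conserved intracellular band.

`compare_sets` joins two (or more) summaries on bin label and reports
per-bin ratio deltas sorted by magnitude — the tool for leave-one-
subfamily-out contrasts.

## Torsion analysis

φ(i) = C(i−1)–N(i)–Cα(i)–C(i) and ψ(i) = N(i)–Cα(i)–C(i)–N(i+1), computed
directly from coordinates under the IUPAC sign convention (verified in the
tests against an independent library implementation).  Helices are
isolated segments: angles needing a neighbour across a helix boundary or a
gap are undefined.  Cross-ensemble dispersion per position is the circular
standard deviation via the mean resultant length (so −179° and +179° are
2° apart); a minimal arc-range alternative is available.  Whether the
appropriate dispersion is an SD, a mean absolute deviation or a range
cannot be decided from published values alone; circular SD was chosen as
the analogue of the SD used for distances.  Section values are arithmetic
means of the per-position dispersions; positions defined in fewer than two
members are excluded and logged.

## The synthetic generator

The generator emulates the *statistical* structure of an ensemble of
inactive-state 7TM bundles, not their physical realism: no sequence, no
side chains, no membrane.  Each helix is grown by natural-extension
(NeRF) from internal coordinates — bonds N–Cα 1.458 Å, Cα–C 1.525 Å,
C–N 1.329 Å; angles 111.2°/116.2°/121.7°; φ = −57°, ψ = −47°, ω = 180° —
so the construction torsions are exact ground truth for torsion-recovery
tests.  The resulting geometry (rise ≈ 1.5 Å/residue, twist ≈ 100°/residue,
radius ≈ 2.3 Å, consecutive Cα ≈ 3.8 Å, i→i+4 ≈ 6.2 Å) is self-checked
against the declared targets at generation time.  Helix axes sit on an
ellipse of 11 Å nominal radius with alternating chain direction; a helix
can carry a kink (hinge position + bend angle).

Per member, in a fixed draw order from one seeded NumPy generator:

1. per-residue torsion noise (per-helix σ, degrees) — perturbs local
   backbone geometry;
2. per-atom isotropic coordinate noise (per-helix σ, Å) — the only term
   that degrades *intra*helical distance conservation;
3. per-helix rigid-body jitter (translation σ Å, rotation σ degrees about
   a random axis through the group centroid) — degrades *inter*helical
   conservation only.  Helices in a coupling group share one joint draw,
   so their mutual distances stay conserved while the group moves relative
   to the rest of the bundle.

Every noise array is always drawn and then scaled by its σ, so one seed
yields the same underlying perturbation field at any noise setting; this
makes noise-monotonicity comparisons paired rather than merely
distributional.  Exact coordinates are reproducible only within this
implementation; cross-implementation claims should therefore be about
statistics, not coordinates.

Preset conditions: `rhodopsin_like` (20 members; helix III residue noise
0.02 Å, helices IV/VII 0.45 Å with 1.0 Å translation jitter, others
0.12–0.15 Å; I–VI coupled) encodes a homogeneous-family ensemble whose
designed ground truth is the qualitative pattern reported for real
receptor sets — intrahelical conservation dominated by helix III,
interhelical by I–VI, helices IV and VII most variable.  `mixed_family`
inflates all jitter and kinks helix VI by 12° at 6.50, emulating a
heterogeneous multi-family set; `gapped` adds the two documented gap
patterns (universe 18,915).  Member counts of 20 match the scale of the
minimal curated receptor sets.  What passing tests show is that the
pipeline *recovers engineered conservation structure from backbone
coordinates*; they cannot show that real receptor families exhibit that
structure — that requires the original crystallographic ensembles, whose
data-dependent values (per-bin numerators and ratios, mean score, absolute
torsion deviations) are deliberately not asserted anywhere in this
package.

## Numerical and degenerate-input choices

* Distances via `scipy.spatial.distance.pdist` per member; statistics are
  vectorised over the full (members × pairs) matrix.
* Dihedrals raise on collinear triplets (cross-product norm < 10⁻⁸).
* Altloc handling: blank altloc wins, otherwise conformer A, independent
  of record order; residues whose Cα exists only in other conformers are
  treated as absent, exactly like unmodelled residues, so the intersection
  rule stays well-defined.  Only the first model of multi-model files is
  read.
* `top_n` larger than the ranked table returns everything with a warning;
  empty inputs raise.
* Helix layouts that bring Cα atoms of different helices within 2 Å
  trigger a warning, not an error (synthetic layouts may legitimately be
  driven into contact).

## Problem sizes

Default analyses run at 20 members × 200 positions (19,900 pairs); the
statistical acceptance checks repeat this over 10 seeds.  These sizes hold
the full test suite to well under a minute of compute while keeping
the sampling error of recovered noise parameters (≈ σ/√(2(n−1)) for an SD
at n = 20) comfortably inside the asserted tolerances.

## Known limitations

* No automatic BW assignment: alignment tables are inputs (a serial
  extension helper from `*.50` anchors is provided).
* Ratios are reported raw; no enrichment statistics are attached to bins.
* Insertion codes are supported in parsing but must appear verbatim in
  alignment-table keys.
* Active-state ensembles, molecular-dynamics trajectories and
  superposition/RMSD analyses are out of scope.
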