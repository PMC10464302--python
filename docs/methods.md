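# Methods

## Model

`parse2` classifies 25-residue windows of a protein sequence into three
classes — folded-like (F), disordered (D), phase-separating disordered
(P) — from three intrinsic property averages, then aggregates window
calls into residue annotations, regions, and a scalar phase-separation
(PS) potential.

The decision tree is deliberately minimal. Folded character is read from
a single scale: the window mean of the Bastolla contact-derived
hydrophobicity, φ, with F assigned when φ > 0.08 (the folded and
disordered training classes separate most strongly on this scale). The
remaining windows are placed in the (α, ν<sub>model</sub>) plane, where α
is the Tanaka–Scheraga α-helix propensity mean and ν<sub>model</sub> an
apparent polymer scaling exponent; the line
ν = −0.244·α + 0.789 bisects the disordered and phase-separating
training distributions, with the high-α, high-ν side labeled D and the
other side P. ν<sub>model</sub> is derived from a hydrodynamic-radius
model for disordered monomeric chains,

    R_h = 2.16 Å · N^(0.503 − 0.11·ln f_PPII) + 0.26·|Q_net| − 0.29·√N
    ν_model = log(R_h / 2.16 Å) / log N

with f<sub>PPII</sub> the window's mean experimental polyproline-II
propensity and Q<sub>net</sub> its integer net charge (K, R = +1;
D, E = −1; histidine neutral). Two readings of the typeset radius
formula are possible; this package uses the one above — a single
PPII-dependent power law plus additive charge and offset corrections —
which matches the radius-model literature the equation comes from, and
takes the magnitude of Q<sub>net</sub> since charge of either sign
expands a disordered chain. Logarithms are natural where a base matters
(ln f<sub>PPII</sub>); the ν ratio is base-independent. The radius model
is meaningful only for disordered chains; F windows never consult it.

### Classifier distance

Each window's label carries a *classifier distance*: for F, (φ −
0.08)/(0.1164 − 0.08), i.e. 1.0 at the folded training mean; for P/D,
the Euclidean distance in the (α, ν) plane to the foot of the
perpendicular on the boundary line, divided by 0.019 (the boundary-to-
training-mean distance). The foot is computed with the slope-form
projection formulas; tests verify it against the closed-form point-line
distance to 1e−9. Distances are continuous across boundaries and zero
exactly on them.

Tie rules (measure-zero but fixed for determinism): φ exactly at the
cutoff is *not* F; a point exactly on the P/D line is P with distance 0.

### Regions

Window labels and distances are assigned to the window's central residue
(window starting at s annotates residue s+12); the 12 residues at each
terminus inherit the first/last window's values. Regions are runs of
≥ 20 residues that are ≥ 90 % one label. Because the published ruleset
defines what qualifies but not an extraction order, the algorithm is
pinned down as:

1. per label, collect qualifying intervals (length ≥ 20, purity ≥ 0.9,
   both endpoint residues carrying the label — endpoints may not borrow
   foreign flanks) that are inclusion-maximal;
2. resolve same-label overlaps greedily, longest first, ties by leftmost
   start;
3. split overlaps between adjacent selected regions of different classes
   evenly, the N-terminal region receiving the extra residue when the
   overlap is odd; a region entirely inside its predecessor is dropped.

Length and purity are enforced before splitting; a split may leave a
region shorter than 20 residues and it is kept. Mixed-label stretches
are simply uncovered. Every rule is exercised against an exhaustive
interval-enumeration oracle on random label strings.

The efficient finder locates, for each label position, the rightmost
feasible region end by binary search on the suffix maximum of an
integer prefix score (+1 per matching label, −9 per other, so purity
≥ 0.9 ⇔ non-negative interval score). This is O(n log n) per sequence
and exact: no floating-point purity arithmetic is involved.

### PS potential and interaction extensions

The base PS potential is the summed classifier distance over P windows.
The expanded potential adds per-window interaction terms:

- U<sub>π</sub> = a·[3·T(Y,R) + 2·T(Y,K) + 2·T(F,R) + 1·T(F,K) +
  1·T(F,Y)] with T(A,B) = #A·#B / max(|#A − #B|, 1), encoding the
  experimental potency ranking of aromatic/cation-π pairs and rewarding
  balanced partner counts (the divisor is clamped at 1 where the counts
  tie, avoiding a divide-by-zero);
- U<sub>q</sub> = b·SCD + c·|NCPR|, with SCD the sequence charge
  decoration N⁻¹ ΣᵢΣ_{j>i} qᵢqⱼ|j−i|^½ and NCPR the net charge per
  residue.

Four published weight sets are shipped, keyed by the observable they
were fit against: `delta_h` (a=0.14, b=8.4, c=5.6), `delta_s` (0.08,
4.6, 7.0), `delta_g` (0.11, 5.2, 5.4) and `csat` (0.28, −16.0, 33).
`csat` (saturation concentration at 4 °C) is the default, being the one
most directly tied to phase-separation propensity.

In the expanded sum, P windows contribute distance + U and D windows are
*promoted* — contributing U − distance — when U exceeds their classifier
distance. Three points were genuinely open and are decided as follows:

- **Joint promotion.** When both extensions are enabled, one combined
  U = U<sub>π</sub> + U<sub>q</sub> drives a single promotion decision
  per window. A window has one label; promoting independently per term
  would be order-dependent.
- **No flooring.** U<sub>q</sub> can be negative and P-window
  contributions (distance + U) are used as-is, with no per-window floor;
  none is specified and flooring would hide charge-based suppression.
- **Segmentation uses base labels.** Promotion changes the potential
  sum only. Region calls default to the unpromoted classifier (the
  batch outputs are defined from it); `ScanConfig(segment_on_promoted=
  True)` opts into segmenting on promoted labels.

## Property tables

The four 20-entry tables are compiled in as versioned constants
(`parse2.scales`), each annotated with its primary citation:
hydrophobicity from Bastolla et al. (2005), α-helix propensity from
Tanaka & Scheraga (1977), PPII propensity from Elam et al. (2013),
formal charge at neutral pH. They were transcribed from the cited
literature; unit tests pin each table with a SHA-256 checksum so any
silent edit fails loudly, and each table can be exported as TSV for
audit against an independent copy.

## Numerical choices

- All property tables are exact 4-decimal values, so window sums are
  computed as scaled 64-bit integers and divided once. Window means are
  therefore independent of summation order, identical between the
  vectorized path and the naive oracle, and — the important case —
  windows whose mean is mathematically equal to a decimal cutoff (φ =
  0.08 occurs in practice) compare equal deterministically instead of
  falling on either side depending on float accumulation.
- Charge-dependent quantities (Q_net, SCD lag sums, residue counts for
  U_π) are integer arithmetic throughout; SCD is assembled per charge-
  pair lag d as √d times an exact sliding integer sum, giving ≤ 1e−12
  agreement with the brute-force double loop.
- The window size is configurable (the classification is fairly
  insensitive to it) but every published constant assumes 25, so other
  sizes emit a warning. Sequences must have N > window size; batch mode
  skips and logs shorter records rather than failing.
- Recall curves use the exact empirical threshold grid (all distinct
  observed values of both sets) with endpoint padding to (1,1) and
  (0,0), and trapezoidal AUC over the reference-fraction axis. A set
  against itself traces the diagonal and yields AUC 0.5 exactly, which
  pins the convention.

## Synthetic data

The fixture generator (`parse2.synthetic`) emulates proteins with
designed modular architecture: residues drawn from class-biased pools
(hydrophobic-rich for F; Pro/Gly/Ser-rich, low-helix for P;
Glu/Lys-rich, high-helix for D), with every generated single-class
sequence *verified against the classifier itself* and resampled until
all windows carry the target label. The pools are tuning details; the
contract is the post-verification. Multi-segment fixtures concatenate
pool-sampled blocks and carry an expected region layout with a ±12
residue junction tolerance — the smearing inherent in assigning a
25-residue window's label to its central residue.

These fixtures share none of the statistics of real proteomes: no
realistic composition mixture, no folded/disordered length
distributions, no mucin/collagen-style repeat families, no ambiguous
boundary windows beyond the junctions themselves. Passing tests
therefore demonstrate that the implementation computes the specified
quantities correctly and segments designed architectures as intended —
not that the classifier's biological error rates match any benchmark.
Quantities tied to external datasets (benchmark AUCs against curated
phase-separation sets, proteome percentages, throughput) are out of
scope here.

## Problem sizes

The test suite and the acceptance script size their ensembles for a
single desk-scale run: 100 random sequences of length 26–2000 for
window-oracle equivalence (integer fields exact, floats to 1e−12), 500
random label strings of length ≤ 200 for region-oracle equivalence, 10⁴
random points for the classifier-distance closed form, and a
1000-sequence synthetic proteome scanned twice for byte-identical
outputs. The scanner itself is vectorized per sequence (O(w·N) per
protein including SCD lags) and comfortably handles 10⁴-sequence
inputs.

## Known limitations

- The three propensity tables are transcribed constants; an independent
  audit against the primary sources is advised before publication-grade
  use (the TSV export exists for exactly that purpose).
- The region-extraction order (maximality, greedy selection,
  containment drop) is one deterministic reading of the published
  ruleset; it is isolated behind `find_regions` so an alternative
  convention can be swapped in without touching anything else.
- The radius model is for monomeric disordered chains; φ, not R_h,
  carries all information about folded regions.
- No attempt is made to model post-translational state (phosphorylation,
  methylation), ligands/RNA, or concentration dependence — the score is
  a sequence-intrinsic propensity, not a phase diagram.
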