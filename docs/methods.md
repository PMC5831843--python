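# Methods

This note documents the models behind `ggshuffle`, the defaults and why
they were chosen, and what the synthetic-data generators do and do not
emulate.

## Coordinates and sequence conventions

Internally every coordinate is 0-based, half-open; files and CLI reports
use 1-based inclusive positions and say so in a header field. Sequences
are canonicalized to uppercase A/C/G/T; circular sequences compare equal
under rotation (and products additionally under strand flip, since a
circular duplex has no preferred strand). Ambiguity codes are not stored:
the single-N spacers flanking each recognition site are concretized at
design time (default `A`, configurable per design).

## Mutation codons

A protein-level substitution is realized by the synonymous codon with the
fewest nucleotide edits from the wild-type codon; ties are broken by the
higher E. coli K-12 codon-usage frequency, then lexicographically, so codon
choice is deterministic. An explicit `codon_override` wins over the policy.
This mirrors common mutagenesis practice and keeps WT/mutant donors maximally
similar, which minimizes the chance that a mutation lands in an overhang
window.

## Assembly model

**Digestion.** The enzyme is a configurable type-IIS cutter, default BsaI:
motif GGTCTC, top-strand cut 1 nt downstream, bottom-strand cut 5 nt
downstream, leaving 4-nt 5′ overhangs. Cuts on both strands of a construct
are applied simultaneously; overlapping overhang windows raise an
"ambiguous digestion" error rather than guessing an order.

**Fragments.** A fragment is stored as the top-strand stretch beginning
with its left overhang; the right overhang is recorded as the top-strand
reading of the duplex it will form. Ligating A before B is legal iff
`A.right == B.left`, and the ligated top strand is the plain concatenation
— which makes scar accounting exact.

**Ligation.** Only exact Watson–Crick 4-nt matches ligate. Mismatch
ligation is reported as risk (the fidelity table lists overhang pairs
closer than 3/4, optionally against reverse complements too) but never
produces products: the design constraints exist precisely to make such
events negligible. Fragments keep their orientation; an inverted insertion
would need one overhang to equal another's reverse complement, which the
selection stage forbids outright.

**Products.** Enumeration returns *monomeric* circles: cycles in the
overhang graph that use each junction once. Concatemers (two inserts plus
two backbones, etc.) occur in real one-pot reactions at low rates but grow
combinatorially and are outside this model; the designed library size
2^k refers to monomers. A product is **stable** iff neither strand retains
a recognition motif — the sequence-level reading of the final digestion
step of the thermocycled restriction–ligation, which relinearizes
re-ligated donors, junction spacers and stuffer circles. Reversibility of
digestion is still available: `religate()` on the fragments in positional
order reconstructs the original construct (as an unstable product).

**Genotyping.** A stable product is genotyped by anchoring at the acceptor
backbone arm and comparing each module region, in order, to the WT and
mutant alternatives; any length or sequence mismatch is classified as an
invalid pattern (the quantity behind the percent-correct-pattern
statistic), with the offending module and offset reported.

## Design rules

**Partitioning.** Mutations whose codons lie closer than `min_module_len`
(default 60 nt, roughly the smallest fragment practical for synthesis and
reliable ligation) merge into one cluster; one module per cluster. Junction
windows are the boundary positions whose 4-nt overhang window (the last
four nucleotides of the upstream module) touches no mutated codon.
Boundaries may fall at any nucleotide inside a window — scarless overhangs
carry no reading-frame constraint — and the chosen boundary is written back
once overhang selection succeeds.

**Overhang selection.** The two acceptor junctions (default TGGT/CTTG) are
fixed; one native 4-mer is chosen per junction window such that every pair
of selected overhangs differs in at least 3 of 4 positions and none is
palindromic. The search is deterministic: windows left to right, candidate
positions leftmost first, chronological backtracking; failures report the
blocking window and the conflicting pairs.

A *strict* mode additionally applies the 3/4 rule between each overhang
and every other's reverse complement. It is off by default: with the fixed
TGGT/CTTG pair the largest mutually strict-compatible overhang set is about
five, so no 7-module design could ever satisfy it; the 8-overhang rule set a
7-module design needs is achievable only under the direct-distance rule. Even in default mode an overhang that
exactly equals another's reverse complement is rejected, since that pair
would cross-ligate perfectly.

**Donor layout.** Each donor insert reads

```
GGTCTCN O0 body1 [NGAGACC GGTCTCN Oi body_{i+1}]  (i = 1..k-1)  Ok NGAGACC
```

with O0/Ok the vector overhangs replicated at the ends and each internal
Oi the last 4 nt of body_i replicated at the next fragment's start. The
mirrored internal site pair cuts outward, so every recognition site is lost
on correct ligation. Construction verifies that neither allele's insert
carries recognition sites beyond the designed 2k (a mutation that creates
one is reported with a suggested synonymous recode), and the donor/acceptor
vector backbones are generated recognition-site-free, re-drawn if a motif
would span a junction.

## Library statistics

Screened clones that are invalid (wrong restriction pattern) or redundant
are treated as uniform, uninformative loss: n·efficiency effective draws
from N equiprobable variants (rounded to the nearest integer). This is an
approximation — it ignores ligation bias and treats redundancy as part of
a single efficiency number. Coverage uses the inclusion–exclusion
coupon-collector identity evaluated with exact `fractions` arithmetic, so
N = 128 poses no overflow or cancellation problem; the minimal clone count
for a target coverage is found by bisection (the probability is monotone
in n). "Shuffling efficiency" is not an algebraic quantity in common use;
here it is the first-occurrence non-redundant fraction — per 100 clones,
how many carry a valid genotype not seen earlier in the sample — with
distinct-over-valid available as an alternative mode.

## Screening analytics

**Tm extraction.** The derivative method smooths the fluorescence with a
centered Savitzky–Golay filter (window 5 points, order 2 — plate readers
step at 0.5 °C and are mildly noisy), takes the filter's own first
derivative, and refines the peak with a parabola fitted over ±4 grid
points; Tm is the vertex. The sigmoid method fits a two-state transition
with linear pre/post baselines by least squares and reports the midpoint.
Curves without a net fluorescence increase, or whose derivative peak does
not stand at least 5 robust σ above the derivative baseline, raise a
"no transition detected" error. ΔTm is reported on the 0.5 °C instrument
grid. Both extractors are invariant under positive affine rescaling of the
fluorescence. With sloped baselines the derivative peak sits slightly
below the two-state midpoint (≈0.2 °C for the default synthetic curve);
this is a property of the derivative definition, shared by the instruments
that use it.

**Concentration calibration.** Ordinary least squares through
(concentration, signal) pairs; inverse prediction with a delta-method
standard error from the slope/intercept covariance; queries outside the
calibrated signal range are flagged as extrapolation; a zero slope is an
error, not a number.

**Kinetics.** Rates come from absorbance slopes via rate = slope/(ε·l),
default ε = 26 mM⁻¹ cm⁻¹ at 515 nm and l = 1 cm. Michaelis–Menten
parameters are fitted by nonlinear least squares on v = k_cat·E·S/(K_m+S),
started from a Hanes–Woolf linearization; k_cat/K_m is reported to 3
significant figures. Non-convergence and a K_m outside the substrate span
are flags on the result, not silent failures.

**ΔΔG filtering.** Candidates with predicted ΔΔG^Fold above the threshold
(default −5 kJ mol⁻¹) are discarded; the boundary is kept. With several
predictors per mutation the combine rule is `any` by default (a single
predictor at/below threshold suffices), with `all` and `mean` available —
the choice is recorded in the output because published funnels rarely state
it. The downstream steps of such funnels (force-field ΔΔG computation, MD
inspection) are out of scope; the filter operates on user-supplied tables.

**Structure shell.** A residue is excluded iff its minimum distance to any
atom of the named cofactor group is ≤ cutoff (default 5.0 Å); remaining
positions contribute 19 substitutions each. The distance convention is
configurable (minimum heavy atom — the default, Cα-only, or all stored
atoms) because published counts rarely pin it down.

## Synthetic data

The generators are pure functions of their arguments: same seed, same
bytes. They emulate the *structure* of a campaign's inputs, not any real
dataset:

- `make_toy_cds` — a recognition-site-free, stop-free CDS (default 300
  codons) with k evenly spaced mutation clusters, optionally with one
  adjacent substitution pair merged into the first cluster; substitution
  targets are random non-synonymous residues. Real genes have codon-usage
  structure and less uniform mutation spacing; nothing downstream depends
  on either.
- `simulate_melt_curve` — two-state transition (default midpoint 48.5 °C,
  width 2 °C) with linear baselines and Gaussian noise (default 1% of
  amplitude) on a 25–90 °C grid at 0.5 °C. Real ThermoFAD curves can show
  aggregation tails and multi-phasic transitions; these are not modeled,
  so passing tests demonstrate estimator correctness on clean two-state
  data only.
- `simulate_clone_sample` — uniform multinomial genotype draws with
  independent invalid-pattern contamination; an exact-composition mode
  reproduces a stated (valid, distinct) count pair deterministically.
  Ligation bias (non-uniform variant abundance) is not modeled.
- `simulate_mm_data` — Michaelis–Menten rates with relative Gaussian
  noise on a substrate grid that must span K_m.

Generated designs always pass `validate_design`; demo designs retry a
bounded sequence of derived sub-seeds so that rare overhang-search
dead-ends never surface to callers, keeping the result a deterministic
function of the requested seed.

## Problem sizes

The bundled verification uses a 300-codon, 7-module design (the full
2⁷ = 128-product enumeration plus genotyping runs in a couple of seconds),
one hundred 90–120-codon designs with k ≤ 3 for the scarless round-trip
property, exhaustive coverage enumeration up to N = 6, and 2×10⁴
Monte-Carlo replicates for the library-scale coverage check. These sizes
make every exact claim checkable by brute force while keeping the whole
suite interactive.

## Known limitations

- Monomer-only ligation model; no concatemers, no mismatch products, no
  partial digestion, star activity or methylation sensitivity.
- Reaction kinetics (cycle counts, enzyme units, concentrations) are not
  simulated; the model is purely sequence-level.
- One type-IIS enzyme per design; no codon optimization, primer design or
  synthesis-complexity scoring.
- Coverage mathematics assumes equiprobable variants.
- The structural candidate count depends on the distance convention and on
  which residues a deposited structure resolves; on real structures the
  convention must be stated alongside the number.
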