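# Methods

This note documents the models behind `synidp`, the defaults chosen where
the design was genuinely open, and what the synthetic-data generators do
and do not emulate.

## Motif library

The repeat motif is `P-G-X1-X2-X3-X4` with X drawn from the 20 standard
amino acids minus Pro and Cys, at least one Gly among the X positions, and
Gly excluded from X4 (which abuts the next repeat's Pro, so an X4 Gly
would create a GP dipeptide). Motifs are identified with residue
*multisets*; the canonical arrangement sorts X1–X3 ascending and places
the largest admissible residue at X4, swapping X3/X4 when sorting would
leave Gly last. This convention is deterministic and invertible
(`realize_motif(multiset_key(m)) == m`), which is all that is required of
it — no claim is made that it reproduces any particular laboratory
arrangement.

Exhaustive enumeration over the 18-letter X alphabet yields 1139
admissible multisets (1140 containing at least one Gly, minus the
unrealizable all-Gly set). Externally curated libraries of different
sizes are reconciled through an explicit exclusion list
(`apply_curation`), not by adjusting the constraint system: the
constraints above are necessary conditions, and any further curation is
treated as data.

Every unit is exactly 1/6 proline by construction; glycine is at least
1/3 on average (scaffold Gly plus ≥1 required Gly per four X positions).

## Codon engineering

Each 24-residue unit maps to 72 nt. The junction geometry is fixed by the
requirement that circularization create exactly one SexAI site
(`ACCTGGT`) overlapping the Pro-Gly codons: position 0 = `CCT` (Pro),
position 1 = `GGT` (Gly), and the final codon must end in `A`. A
consequence worth stating plainly: residues with no A-ending codon
(F, Y, C, H, N, D, M, W) cannot occupy X4 of a designable unit. The
library surfaces this as a design failure with a diagnostic rather than
silently bending the junction; the pipeline records and skips such
motifs.

Codons are otherwise restricted to E. coli K-12 usage fractions ≥ 0.10
(configurable). Junction-forced codons bypass the cutoff — without this,
X4 = Ile would be undesignable solely because `ATA` is rare.

Repeat structure is scored as
`composite = w1·max(0, direct − k0) + w2·max(0, inverted − k0)` with
`k0 = 8` nt, `w1 = 1`, `w2 = 2`: hairpin stems (inverted repeats) are the
dominant failure mode for polymerase/ligase processing of repetitive
templates, hence the double weight. `direct` is the longest substring
occurring at two distinct start positions (overlap allowed); `inverted`
is the longest substring whose reverse complement also occurs at a
disjoint position, with an optional minimum loop gap for the hairpin
variant. Both are computed by diagonal run-length scans of the
self-match matrix and are verified in the tests against an O(n³)
exhaustive oracle.

The optimizer is seeded simulated annealing over synonymous codons
(geometric temperature ladder, best-so-far tracking, internal
`ACCWGGT` occurrences penalized prohibitively). It is deterministic for
a fixed seed, never returns a candidate worse than the best visited
state, and in practice reaches composite 0 for typical units. The
published objective of the original scrambling algorithm is preserved;
its internals are not reproduced.

`ACCWGGT` is its own reverse complement under the `W` degeneracy, so
single-strand scanning covers both strands; the scanner documents this
and a property test checks match-count symmetry under reverse
complement.

## RCA and methylation-protected digestion

A linear concatemer of `n` repeats carries `n − 1` junction sites. With a
fraction `f_mC` of dCTP replaced by 5-methyl-dCTP, and `c` cytosine
positions per site whose methylation blocks cleavage, each site is
independently protected with probability `q = 1 − (1 − f_mC)^c`. Complete
digestion cuts every unprotected site; runs of protected sites give
internal fragments of `k` units with `P(L = k) = q^(k−1)(1−q)`, mean
`1/(1−q)`. The two terminal fragments are censored by the molecule ends,
not bounded by two cuts, and are excluded from distribution comparisons.

Defaults: `f_mC = 0.25` (the bench substitution ratio) and `c = 4` (the
dcm-context cytosines on both synthesized strands of the `CCWGG` core),
giving `q ≈ 0.684` and mean spacing ≈ 3.2 repeats — a methyl block about
every four repeats. A 10 % preset (`FIG1_MODEL`) is provided because both
substitution levels appear in the source protocols; whether
hemimethylation suffices to block cleavage is not settled, so `c` is
configurable. The simulator assumes fully double-stranded product
(single-stranded regions are not digestible by this enzyme and are not
modeled).

Size selection keeps 360 ≤ ℓ ≤ 576 bp, i.e. 5–8 repeat units (the
alternative "400–600 nt" window quoted elsewhere in the source protocols
is not the default). The number-fraction of fragments in a window
`[k_lo, k_hi]` is `q^(k_lo−1) − q^k_hi`; maximizing gives
`q* = ((k_lo−1)/k_hi)^(1/(k_hi−k_lo+1))`, which for [5, 8] is
`2^(−1/4) ≈ 0.8409` with a maximal retained fraction of exactly 1/4. The
closed form is cross-checked against a grid search in the tests.

## Read QC

References are circular 72-mers, so alignment must be phase-free: the
read is aligned with edlib in infix mode against the unit tiled past the
read length, in both orientations; the optimal start modulo 72 is the
phase. This is exact (it equals a full dynamic program minimized over
all 72 phases, which the tests verify against a DP oracle for reads up
to 300 nt) and is a desk-scale stand-in for a production short-read
aligner, which is deliberately out of scope.

Filter thresholds, where the filtering rules are qualitative: reads
shorter than 100 nt fail `too_short`; > 0.10 edits per aligned base fail
`poor_alignment`; an in-frame stop codon in the design reading frame
(frame derived from the phase) fails `nonsense`; an indel region whose
net frame disruption persists beyond 24 nt fails `large_frameshift`; and
fewer than 3 perfect repeats fails `few_perfect_repeats`, where a
"perfect repeat" is an exact copy of the full 72-nt unit (any rotation),
not of the hexapeptide. All are configurable.

The read simulator plants provenance (reference, phase, orientation,
error count) in read names. It emulates substitution and indel errors at
uniform per-base rates and reverse-complement cloning orientation; it
does not emulate quality-score profiles, adapter read-through, chimeras,
or coverage bias. Passing its tests therefore demonstrates correctness
of the alignment and filtering logic, not robustness to every artifact
of real sequencing data. Reproducing published library-scale counts
would require the archived accession-scale read set and aligner parity,
and is out of scope; the pipeline computes the same four summary fields
(unique alignments, unique passing sequences, distinct forward and
reverse-complement references) on synthetic data with planted truth.

## Solubility

The packaged Urry scale uses the guest-residue inverse-transition-
temperature values from the elastin-like-polypeptide literature
(hydrophobic aromatics strongly negative, charged residues strongly
positive, Gly 55). Because several normalizations of this scale
circulate and the exact table behind the published integer thresholds
is not printed, the scale is injectable and the package asserts only the
*ordering* property: a fitted integer threshold strictly separates
labeled classes when they are separable (`separation_threshold` returns
the smallest such integer, or none). The default thresholds 42
(standalone) / 47 (fused) are carried as configurable metadata; scores
exactly on a threshold are reported `indeterminate` since the classes
are defined by strict inequalities.

Wilkinson–Harrison: `CV = 15.43·f_turn − 29.56·|charge/n − 0.03|` with
turn formers {N, G, P, S} and integer charges (+1 K/R, −1 D/E; His
optionally +0.5), `CV′ = 1.71`, and class probability
`clip(0.4934 + 0.276·|CV−CV′| − 0.0392·(CV−CV′)², 0, 1)`, which is
0.4934 at the boundary and saturates at 0 %/100 % for extreme CV. The
default sequence scope is the tag alone; no pKa model is used (the
integer-charge convention matches the published calculator family).

Masses use Biopython's residue tables (average and monoisotopic). The
assembled constructs of all five printed tag sequences fall in the
10–20 kDa design window.

## Scattering

Form factors, all normalized to 1 at q → 0:

* Debye: `I = 2(e^(−x) + x − 1)/x²`, `x = (qRg)²` (series below
  `x = 10⁻³` for numerical stability);
* thin rod: `I = 2 Si(qL)/qL − 4 sin²(qL/2)/(qL)²`;
* PEV: with `U = q²Rg²(2ν+1)(2ν+2)/6`,
  `I = γ(1/2ν, U)/(ν U^(1/2ν)) − γ(1/ν, U)/(ν U^(1/ν))` (lower
  incomplete gamma). This parameterization is pinned by two identities
  the tests enforce: it reduces exactly to the Debye function at ν = 1/2,
  and its high-q slope is −1/ν.

The Porod exponent is the negative least-squares slope of log I vs log q
over a window, default 0.03–0.2 Å⁻¹ (the mid-q range used for rigid
chains); the asymptotic windows qRg ∈ [4, 10] and qL ∈ [10, 60] are used
for the analytic ideal-chain/rod checks to avoid Guinier-crossover bias.
On those windows the fitted exponents are 1.94 and 0.97 — the crossover
still biases them slightly below the asymptotic 2 and 1, which is why
the claims are stated at integer rounding.

Kratky classification computes q²I(q): a well-defined interior maximum
exceeding the high-q tail by 1.3× ⇒ compact; otherwise a fitted relative
rise > 0.25 of the tail (top third of the q range) ⇒ extended (the rod
Kratky grows ~linearly without bound); otherwise the ideal-chain plateau
⇒ flexible-disordered. The rise is measured relative to the tail mean
because the Debye Kratky approaches its plateau from below and a small
absolute slope is always present at finite q.

`fit_pev` is σ-weighted nonlinear least squares with 8 multi-starts from
a seeded Latin hypercube over (Rg, ν) bounds — the surface is mildly
multimodal — with 1-σ uncertainties from the Jacobian and an explicit
convergence flag. On synthetic curves with 2 % Gaussian noise over the
experimental range 0.012 < q < 0.6 Å⁻¹ it recovers Rg within ±10 % and ν
within ±0.05 across seeds. The PEV model assumes chain flexibility and
is not applicable to rigid extended chains (Porod exponent ≈ 1); such
profiles should be characterized by their Kratky class and Porod slope
instead.

The bead-chain Monte-Carlo oracle evaluates the orientation-averaged
Debye double sum over seeded conformers (freely jointed chain or
collinear rod). It validates the closed forms; it is not a simulation of
real polypeptide chains (no excluded volume, no hydration shell, no
instrument smearing).

The terminal-transferase polymerization model takes mean degree of
polymerization `DP = ratio × conversion` (500 at 1:500 and full
conversion) with a Poisson length law — the simplest law consistent with
memoryless single-nucleotide addition — giving dispersity `1 + 1/DP`
(1.002 at DP 500). This is a model choice, not a measured distribution.

The CD random-coil test requires a negative global minimum within
195–200 nm and a positive local maximum within 212–218 nm, the
signature used to call the tags unstructured; the synthetic CD fixtures
are Gaussian-band cartoons for exercising the rule, not simulated
spectra.

## Problem sizes and determinism

Default simulation sizes (10⁴–5·10⁵ repeat units for digestion
statistics, ≤ 250 conformers × ≤ 300 beads for scattering oracles,
tens-to-hundreds of reads for QC) were chosen so the geometric-law,
form-factor and recovery checks are statistically decisive while the
whole suite runs in seconds on one CPU. One global seed is fanned out
into per-stage substreams (`numpy.random.SeedSequence.spawn`), so a
config + seed pair reproduces every pipeline output byte for byte while
stages remain independently reproducible.

## Known limitations

* No kinetic model of the polymerase (priming cascades, processivity) —
  the concatemer is idealized as uniform tandem repeats.
* Library-wide (cross-member) repeat minimization between different
  oligos is not attempted; scrambling is per-design.
* The junction constraint excludes eight residues from X4 (see above);
  designs requiring them would need a different junction chemistry.
* Absolute hydropathy thresholds depend on the injected scale table and
  are not asserted; only threshold ordering and recovery are.
* The aligner is exact but quadratic per read-reference pair; it is
  meant for library-verification scale, not genome scale.
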