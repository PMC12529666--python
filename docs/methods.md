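# Methods

## Seed-site classification

A target window of 8 nt is written 5′→3′, so its 3′-most base is t1,
opposite guide position g1.  Pairing is strict Watson–Crick (G:U wobbles
count as mismatches; canonical site definitions are Watson–Crick only).
Classes are mutually exclusive with priority 8mer > 7mer-m8 > 7mer-A1 >
6mer:

| class   | t2–t7 | t8  | t1   |
|---------|-------|-----|------|
| 8mer    | paired| paired | A  |
| 7mer-m8 | paired| paired | ≠A |
| 7mer-A1 | paired| unpaired | A |
| 6mer    | paired| unpaired | ≠A |

The internal alphabet is RNA; T on input is normalized to U, because
library designs are routinely written in DNA spelling while targets are
RNA.  Library classification defaults to *fixed-register* mode (classify
the 8-nt variable region at its known position).  A *full-scan* mode
classifies every 8-nt window of flank+variable+flank and reports the
highest-priority class, admitting sites that span the variable/flank
junction; whether junction-spanning matches should count is a design
choice with no single right answer, so both modes are provided and the
output records which was used.

## Equilibrium binding

Fraction of target bound versus total enzyme follows the ligand-depletion
(quadratic) isotherm; the discriminant is clamped at ≥ 0 against rounding.
As S_T → 0 it reduces to the hyperbola B_max·E_T/(E_T + K_D) (tested
analytically).  Fitting is bounded trust-region nonlinear least squares
(K_D > 0, 0 < B_max ≤ 1.2 by default — a soft allowance for normalization
error above 1).  Initialization is deterministic: K_D starts at the
enzyme concentration closest to half-maximal binding, B_max at the
maximal observed F.  Degenerate inputs (flat response) set
`converged=False` rather than raising.  Standard errors come from the
Jacobian at the solution.

## Dissociation

Two-phase decay with amplitude parameterization A_fast, k_fast, k_slow
and an optional plateau (fixed at 0 by default; freed by flag).  Rates
are initialized from log-linear fits of the early and late halves of the
time course.  Identifiability guard: two phases are reported only when
k_fast/k_slow ≥ 3 *and* both amplitudes exceed 0.01 *and* the biphasic
fit beats the single exponential in residual sum of squares; otherwise
the single-exponential fit is returned with `fallback=True`.  Below a
3-fold rate separation the two phases are statistically indistinguishable
at typical dot-blot point counts (≈ 8 time points).  A series trending
upward is flagged as non-converged (not a decay).  The fast-phase
amplitude is reported per fit and not modeled further; in the motivating
experiments it varies between trials for unknown reasons.

## Association

One-phase exponential per enzyme concentration, then ordinary least
squares of k_obs against [E]; the slope is the second-order k_on and the
intercept estimates k_off (an intercept-free fit is available by flag).
Concentrations are nM and rates carry the input time unit; K_D = k_off /
k_on converts explicitly (nM⁻¹s⁻¹ → M⁻¹s⁻¹ is a factor 10⁹).  The
synthetic default k_on is the *slow* (mutant-like) regime,
0.04 nM⁻¹s⁻¹: with sampling no finer than 15 s, a fast complex
(0.2 nM⁻¹s⁻¹, exposed as `ASSOC_WT_KON`) is ~90% bound by the first
time point at the upper concentrations, so k_obs is unconstrained there —
the same limitation the wet-lab design reports.  Parameter-recovery
claims therefore apply to the measurable regime.

## RBNS processing

Reads are demultiplexed on a leading fixed-length barcode (default
max_mismatch 0; a read within range of ≥ 2 barcodes is always
unassigned), adapter-trimmed at the first literal occurrence, and kept
only at the exact construct length.  Member assignment is exact-match on
the variable region: the library is small and fully enumerable, and a
read one error away from a member is biologically uninterpretable in this
assay, so error-tolerant mapping would only blur classes.  Read fractions
are computed over member-matched reads (unmatched reads are excluded from
denominators; output metadata says so).  Fold enrichment divides sample
by input fractions; zero-input members are flagged `undefined` rather
than dropped, and the default pseudocount is 0 (an optional count-level
pseudocount, suggested 1, stabilizes display of rare members).

## Synthetic RBNS occupancy model

Input pools are Dirichlet(α=5)-skewed multinomials over the 256 members
(synthesis bias).  A bound sample at incubation time t draws member m
with probability ∝ pool(m)·occ(m, t), where

    occ(m, t) = w_class(m)^φ · (1 − e^(−r·t)) + b

with class weights 400 / 120 / 80 / 20 for 8mer / 7mer-m8 / 7mer-A1 /
6mer (roughly the affinity ladder of canonical site types), weight 0 for
the no-seed class — all background binding enters through the constant
baseline b — a fidelity exponent φ ≤ 1, and a single scenario-wide
approach-to-equilibrium rate r.  The wild-type-like preset (φ=1, b=0.2,
r=0.05 s⁻¹) is near-saturated and seed-dominated by 30 s; the
mutant-like preset (φ=0.4, b=1.0, r=0.004 s⁻¹) starts
background-dominated and gains fidelity with incubation, reproducing the
two-timepoint mis-targeting pattern as an emergent property rather than
by construction.  This is a test harness: it has no kinetic competition
between members, no rebinding, no sequencing error (quality strings are
constant), and the absolute seed-match percentages it yields are not
calibrated to any experiment — only the orderings (WT > mutant early;
mutant late > mutant early; enrichment monotone in class weight) are
claimed and tested.

## isomiR classification

A read is aligned to each candidate canonical miRNA at every 5′ offset
within ±max_shift (default 3 nt); the 3′ offset follows from the length
difference and must also be within range.  Mismatches are counted on the
aligned overlap only (non-templated extensions cannot be checked against
the reference).  The best assignment minimizes (mismatches, |5′ offset| +
|3′ offset|) lexicographically, ties broken by canonical name.  The
category is a closed function of (5′ offset, 3′ offset, mismatches):
canonical, 5′-variant, 3′-trimmed(+exchange), 3′-extended(+exchange),
nucleotide-exchange, and mixed for anything combining a 5′ change with a
3′ change or exchange.  Genome-templated versus non-templated 3′
additions are not distinguished.

## Exclusivity, arm ratios, thresholds

"Exclusively bound" is operationalized as count ≥ min_count (default 1)
in *every* replicate of one condition and exactly 0 in every replicate of
all others — the strictest reading, with no published threshold to
follow.  Arm ratios are log2((count_3p + 1)/(count_5p + 1)) per sample;
groups are compared by a two-sided Welch t-test on these ratios and the
*raw* p-value is thresholded at 0.05 (the source analysis quotes a raw
P ≤ 0.05; alternatives are pluggable and the choice is recorded in
output).  Benjamini–Hochberg adjustment is the standard step-up with
monotonicity enforcement, written here because it is a primitive of the
pipeline, and tested against both a brute-force definition and
statsmodels.  DE threshold rules: FDR-adjusted p < 0.05 with
|log2FC| > 1 for small-RNA tables; FDR-adjusted p < 0.05 alone for mRNA
tables (min_abs_lfc = 0).  Upstream DE estimation (dispersion modeling,
Wald tests) is consumed from tables, not reimplemented.

## Network and GSEA

CWCS tiers: high iff CWCS < −0.4; moderate iff −0.4 ≤ CWCS ≤ −0.2 (both
boundaries inclusive into moderate — "between" is ambiguous, so the
convention is documented and configurable); else excluded.  Edges are
kept only for high/moderate predictions whose target is significantly
regulated *opposite* to the miRNA's RISC-loading direction.  Preranked
GSEA uses hit increments ∝ |stat|^p (p = 1 by default, normalized over
set members in the signature) and miss decrements 1/(N − n); the ES is
the running-sum extremum.  Because the signature is preranked, sample
permutation is impossible; significance uses gene-label permutations
(random same-size sets), one-sided in the observed direction, with
p = (1 + more-extreme) / (n_perm + 1) ∈ (0, 1] and a required seed.  No
normalized ES or multi-set FDR is computed (single-set use).  The
implementation is not asserted to match any particular GSEA package
bit-for-bit.

## Problem sizes and determinism

Every generator derives its random stream from (seed, scenario name), so
identical configurations give identical outputs and scenarios are
independently reproducible.  The test and acceptance runs use 10⁴–10⁵
reads per RBNS sample, 100 replicates for kinetic-recovery statistics,
and 1000 replicates for null-calibration checks — sizes at which the
Monte-Carlo error of each reported statistic is small relative to its
tolerance while the whole suite stays fast.

## Known limitations

- No thermodynamic scoring, 3′-supplementary pairing, or non-canonical
  (pivot/centered) site classes.
- The RBNS generator's occupancy model ignores member-member competition
  and depletion of the protein; absolute enrichment magnitudes are not
  comparable to experiments.
- The small-RNA generator plants effects at the count level and does not
  simulate miRNA biogenesis (DROSHA/DICER cleavage offsets).
- Welch's t on log2 ratios is approximate for very low counts; its size
  is verified by simulation at the default count scale only.
- Quality scores are ignored throughout; no UMI handling.
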