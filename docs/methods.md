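# Methods

## Scope and model overview

`dgscan` implements a structure-perturbation approach to 5'UTR analysis:
translation efficiency is treated as a monotone function of the 5'UTR
minimum folding free energy (MFE), so the positions whose substitution
perturbs the MFE the most are the positions most involved in the UTR's
structured, translation-regulating elements. The package computes MFE
folds, runs the saturation-substitution scan, calls elements, fits the
efficiency/energy relation and designs oligonucleotides; everything
wet-lab (translation assays, transfections, reporter measurements) is out
of scope by construction.

## Folding energy models

Two builtin models share one admissibility notion: pairs from
{AU, UA, CG, GC, GU, UG}, hairpin loops of at least `min_hairpin_loop`
(default 3) unpaired residues, non-crossing structures, no pseudoknots.

**PAIRMAX** assigns a fixed energy per pair class (defaults −3 GC/CG, −2
AU/UA, −1 GU/UG kcal/mol) and minimizes by a weighted Nussinov DP. It is
deliberately simple: every admissible structure of a short sequence can
be enumerated and scored, so the DP is certified *exactly* (not
approximately) against the enumeration minimum. Lone pairs are allowed by
default.

**NN** is a simplified Zuker-style nearest-neighbor model: stacking
energies for adjacent pairs (packaged Turner-like table, 37 °C free
energies, symmetric under strand reversal and checked on load),
size-dependent hairpin/bulge/internal initiation penalties with
logarithmic extrapolation E(n) = E(n_max) + 1.0785·ln(n/n_max) beyond the
table, and an affine multiloop cost (offset 3.4, 0.4 per branch including
the closing pair, 0.1 per unpaired residue, kcal/mol). Deliberate
simplifications, each standard in reduced nearest-neighbor treatments:
no dangling ends, no coaxial stacking, no terminal-AU penalty, no
internal-loop asymmetry term, no tetraloop bonuses, and internal loops
capped at 30 unpaired residues in the DP (the cap cannot bind at the
sequence lengths where the enumeration oracle certifies the DP). Lone
pairs are disallowed by default — exactly: every pair must be stacked on
an adjacent pair on at least one side, enforced identically in the DP
(via a split into internally-supported and outer-supported closing
matrices), in the structure validator and in the oracle. The packaged
table keeps all stacks stabilizing; the G:U-on-U:G stack, destabilizing
in full parameter sets, is set to a mildly stabilizing −0.3 kcal/mol for
uniformity.

No claim of numeric identity with any specific third-party folding
program is made: published ΔG values for real UTRs are treated as given
inputs, and the `external` engine adapter (RNAfold-style call contract)
exists for users who want a full-parameter engine.

**Determinism and tie-breaking.** Traceback candidates are examined in a
fixed order — 5' to 3', pairing preferred over leaving a position single,
nearest partner first; within a closed pair: helix extension, hairpin,
bulge/internal branches (5' arm ascending, 3' arm descending), multiloop
splits ascending. Identical inputs give identical structures. Every
traceback is re-scored with the shared structure-energy kernel and must
agree with the DP energy.

## Perturbation scan

Per position, the three non-wild-type substitutions are folded (mutant
energies are memoized by sequence string, so a scan costs at most 3L + 1
folds) and the score is the mean absolute ΔΔG. The absolute value is the
default because stabilizing and destabilizing changes both indicate
structural involvement; a signed mode exists for exploration. The score
is smoothed by a valid-window sliding mean (window 6 positions — the
6-position reading of "consecutive changes"; other readings are reachable
via the window flag) and min–max scaled to [0, 100] for display (scaling
is cosmetic and configurable: none | minmax | z-score; a constant signal
scales to all zeros).

Element calling groups windows with signal at or above the 90th
percentile into runs, merges runs separated by at most `merge_gap`
windows (default: the window length), maps each run to its raw-coordinate
footprint, merges any overlapping footprints, and returns the top 3 by
peak signal, labelled e1, e2, … The defaults (percentile 90, 3 elements)
mirror the three-element output style of the original analyses; both are
flags. Note that merging can legitimately span sub-threshold windows
between two runs; the guarantee kept is that element *boundaries* are
anchored on above-threshold windows. A constant signal yields no
elements.

## Efficiency model

ln(efficiency) is regressed on ΔG by plain OLS (no weights, no
intercept-free variant), matching the stated published analysis; a =
exp(intercept), b = slope, and r² is reported on the log-linear scale.
Properties tested: scale equivariance (y → k·y multiplies a by k), shift
equivariance (X → X + c multiplies a by e^(−bc)), strict monotonicity of
predictions for b > 0, exact recovery on noiseless data and 3-standard-
error recovery on log-normal noise (σ = 0.1, n = 50).

Two published parameterizations of the same panel are shipped as presets
(`fig1c`: a = 127.29, b = 0.0248; `results-text`: a = 140.46, b =
0.0307). The printed record does not say which is final, so neither is
hard-coded as *the* model; users pick explicitly. Regulatory potential is
defined as the efficiency ratio reference/variant (model-based form
e^(b·(X₁−X₂))); the published 5.96-fold figure reproduces to 5.98 from
the printed rounded efficiencies (24.09%/4.03%), a 0.3% discrepancy
attributable to rounding of the assay means.

## Oligo design

Sense = element subsequence; antisense = reverse complement; the
microRNA-like insertion goes after residue ⌊n/2⌋ of the parent (the
printed record does not fix the exact offset; this is the declared
convention) and uses a homopolymer of the base that cannot Watson–Crick
pair with the two partner residues flanking the junction (at most two of
the four bases are excluded, so a choice always exists; among the
remainder, the least wobble-prone base wins). Insertion length is 2 or 3
(default 3). Scrambled controls are seeded Fisher–Yates shuffles redrawn
until the longest perfect complementary run against the full target UTR
is below 7; composition and length are preserved and results are
reproducible from (parent, seed). Hybridization reports scan all gapless
antisense appositions: Watson–Crick appositions count as matches, G:U as
wobble (labelled as G:T apposition in TSV output when the chemistry is
DNA); the best apposition maximizes (Watson–Crick, wobble) with ties to
the 5'-most offset. Tm (Wallace rule) and GC% are rough annotations.

## Synthetic fixtures

The generator emulates the weakly/strongly folded UTR contrast: an i.i.d.
background with P(G) = P(C) = gc_bias/2 (default gc_bias 0.5) and perfect
planted hairpins (default one 10-bp stem with a 6-nt loop in an 80-nt
UTR, matching a realistic short structured 5'UTR domain), arms drawn from
the background composition, deterministic per seed. It does not emulate
non-i.i.d. real UTR composition, imperfect helices, pseudoknots or
sequence-level motifs (uAUGs, IRES consensus) — so passing localization
tests certify the scanning and calling machinery on a known structural
signal, not motif discovery on real UTRs. Planted fixtures fold strictly
below their arm-shuffled controls (paired over 20 seeds); stem-free
30-nt backgrounds have median MFE within [−5, 0] kcal/mol under the NN
model.

Localization checks run under the NN engine: stacking makes a contiguous
planted helix energetically meaningful, whereas pure pair maximization is
highly degenerate (a broken pair is often compensated by an alternative
partner, diluting the positional signal). In the two-stem check the
merge gap is widened to two windows so that the two arms of one hairpin
merge across the loop into a single element.

## Problem sizes and numerics

Oracle certification uses 200 random sequences of length 8–14 per engine
(exhaustive enumeration above that length is combinatorial; the
enumerator refuses sequences longer than 14 by default). Scans in the
tests use 80–120-nt fixtures; the DP kernels are JIT-compiled, and a full
scan of a 200-nt UTR (601 folds) completes in well under a minute with
the PAIRMAX engine on one core. Energy comparisons between DP and oracle
use an absolute tolerance of 1e-9 kcal/mol (the arithmetic is identical
table sums, so agreement is exact up to float association); traceback
self-checks use 1e-4. Model recovery asserts 10+ significant digits on
noiseless data.

## Known limitations

- The NN parameterization is reduced (see above); absolute ΔG values are
  not comparable to full Turner-2004 engines, though structure ranking on
  short sequences is similar in practice.
- No partition function: the scan uses MFE changes only, ignoring
  ensemble effects near degenerate optima.
- Element calling is percentile-based on a per-sequence signal; signals
  are not comparable across UTRs of very different structure content.
- Scanning 3'UTRs or coding regions is accepted but nothing specific to
  those contexts (codon structure, miRNA seeds) is modelled.
- The scrambled-control bound constrains perfect complementary runs, not
  thermodynamic duplex stability.
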