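# Methods

## Reference anchoring and coordinates

All residue and domain coordinates are 1-based inclusive (Pfam
convention). The reference model fixes the PctA ligand-binding domain
span (36–261), the active-pocket logo region (100–175), the five-position
signature [(126, R), (128, W), (144, Y), (146, D), (173, D)] and the
extended pocket {101, 111, 121, 126, 128, 144, 146, 147, 173}.

The packaged default reference sequence is a **synthetic stand-in**: a
deterministic, reproducibly seeded 629-residue chain that carries the
known pocket residues (Y101, M111, Y121, R126, W128, Y144, D146, A147,
D173) at their correct positions. Every analysis in the package is
coordinate- and signature-based, so the identity of the non-pocket
residues is immaterial to its correctness; users anchoring real family
data should supply the biological PctA sequence via
`ReferencePocketModel.with_reference`.

Column maps are built by walking the reference row of the MSA left to
right and assigning each non-gap column the next reference position,
starting from the row's `id/start-end` coordinate suffix when present,
else from the domain start. Columns outside the domain span are
dropped, which implements "remove alignment columns not represented in
the reference domain". Residue disagreement between the reference row
and the reference sequence is a hard error: a silent off-by-one here
would corrupt every downstream position. The alternative pairwise route
(global alignment, BLOSUM62, gap open 11 / extend 1 — standard
protein-search defaults) exists for sequences outside any family MSA;
reports derived from it should be labelled pairwise-anchored, because
the two routes are only guaranteed to agree when the MSA is the one the
pairwise alignments induce.

## Signature screening

Match is strict residue identity at the five signature positions; a gap
or `X` counts as a mismatch. The threshold k (default 5) is exposed
because the four-of-five case is biologically meaningful (the PctA
paralogs PctB and PctC carry four of the five residues and bind AI-2
weakly). Pass sets are nested in k, and the screen is invariant to row
order and to columns outside the retained set; both are property-tested.

## Conservation profiling

Position-frequency matrices count residues at retained columns only.
Gaps are excluded from the frequency denominator (the common
sequence-logo convention) and the gap fraction is reported alongside;
`X` is tallied separately and excluded. Information content is
log₂20 − H in bits, so an invariant column scores log₂20 ≈ 4.32 and a
uniform column scores 0. The small-sample correction
e(n) = 19/(2 ln 2 · n) is available but off by default: the families
this package targets have thousands of rows, where e(n) is negligible.
`top_conserved` ranks positions by peak single-residue frequency with
ties broken toward the lower position number; all-gap positions are
reported as missing and rank last.

## Domain-architecture classification

The class rule table maps Pfam output-domain names to functional
classes (see the module docstring for the full table). The rule table
is a design choice, not a published artifact: the source analysis names
classes, not Pfam accessions, so the default table uses the canonical
Pfam families for each output type and is editable YAML. Precedence for
multi-domain proteins is MCP > CSP > HK > SP > STK > AC/GC > CNB-only —
chemotaxis output is the least ambiguous annotation, and CNB-only by
definition requires the cyclic-nucleotide-binding domain to be the sole
output domain. Changing precedence only reassigns proteins whose
domains qualify for more than one class (property-tested).
Classification is total: qualifying evidence → class; non-qualifying
output domains → OTHER-annotated; no output domains → UNCHARACTERIZED.
Phylum is taken positionally from the lineage (second element after a
recognized superkingdom) with an explicit `unresolved` fallback.

## One-site ITC model

The forward model uses the exact displacement recursion (concentrations
diluted by `1 − v/V0` per injection, complex displaced out of the
active volume accounted for in the heat) rather than the linearized
`i·v/V0` approximation — exact and equally simple. The bound-complex
concentration is the physical root of the binding quadratic, computed
via the product-of-roots form `S·L / root₊` to avoid catastrophic
cancellation in the tight-binding limit; it is verified against an
independent Brent root-finder to 1e-12 relative error, and cumulative
heats are verified against a mole-balance oracle that tracks complex
remaining in the cell plus complex displaced out.

Fitting is unweighted nonlinear least squares over
(log₁₀Kd, n, ΔH, q₀) with `scipy.optimize.least_squares` (TRF,
bounds log₁₀Kd ∈ [−12, −1], n ∈ [0.05, 10]). Kd is log-parameterized
because it is a scale parameter spanning decades. Sixteen starts (eight
log-spaced Kd values × two ΔH scales, ΔH seeded from total heat under a
full-saturation assumption) guard against the local minima of low-c
isotherms; the lowest residual sum of squares wins. `fix_n` clamps
stoichiometry, the customary practice when c = n·M₀/Kd < 1 and n is not
identifiable; the fit then warns via the Wiseman-c flag rather than
failing. Non-convergence is flagged on the result, not raised. Standard
errors are asymptotic (Jacobian-based), with the log-Kd error
transformed to the Kd scale. The first injection is kept by default
(`discard_first` available; vendor conventions differ). Noise-free
fits recover generating parameters to better than four significant
figures across c from ~0.4 to 500.

ΔH defaults to −40 kJ/mol in simulations — a typical exothermic
protein–ligand enthalpy; the validated quantities are Kd and n
recovery, which are insensitive to this choice.

## Synthetic-data generators

The family generator emits the alignment directly (no aligner), with
columns equal to the reference domain positions, so screening tests are
aligner-independent. Exactly `round(f·n)` synthetic rows carry all five
signature residues (background rows that would match by chance are
perturbed at one signature position, partial rows carry exactly four),
and the reference row is always one additional full match — large-scale
counts in tests and examples are therefore `round(f·n) + 1`. Defaults
mirror the screened-cohort conditions: 25-injection titrations of
700 µM ligand into 70 µM protein at 20 °C, a full-match prevalence of
1535/18970, a class mix dominated by chemoreceptors with a ~3%
completely-uncharacterized tail, and gradient-plate distances of
6.5/3.5 mm (mean RI 0.65). The per-class split of the published cohort
is not printed in the extracted text, so the default class proportions
are a plausible choice, fixed once; tests only ever compare against the
generator's own ground truth, never against those proportions.

What the generator does *not* emulate: phylogenetic correlation between
rows (sequences are i.i.d. given their planted type), realistic indel
structure (insertion columns are i.i.d. with coin-flip gaps), residue
composition bias, or alignment error. Passing screens on synthetic
families therefore demonstrate the correctness of the bookkeeping
(column mapping, counting, joins) at scale — not robustness to
misalignment, which only the pairwise-vs-MSA agreement tests touch.
Optional stressors: `indel_rate` inserts reference-gap columns that any
correct column map must ignore; `shuffle_gap_columns` permutes them.

ITC replicates derive per-replicate generators from
`(master seed, replicate, stream)` tuples, so datasets are bit-stable
and replicates independent. Dilution controls are simulated as the
background offset plus noise, matching ligand-into-buffer control
injections.

## Problem sizes and determinism

The test suite screens synthetic families up to 20,000 rows (and one
18,970-row cohort mirroring the published family size) with exact
truth recovery, and checks ITC parameter recovery as the median fitted
Kd over 20 seeded replicates per regime at 2% heat noise — within 20%
of the generating value at c ≥ 50, within 30% in the two low-c regimes
(c ≈ 0.4, where single-replicate scatter is large and the median is the
right estimator). `scripts/acceptance.py` uses 50 replicates in the
well-conditioned regimes and 150 in the low-c regimes, where the
skewed per-replicate distribution makes the median estimator noisier.
All randomness flows from explicit seeds; reruns with the same config
are byte-identical, and run manifests record input checksums.

## Known limitations

- The real supplementary data of the source study (the 18,970-domain
  alignment and its metadata table) are not bundled; reproducing the
  published 1535 / 1482 / 52 / 1 counts requires downloading them and,
  likely, adjusting the class-rule YAML to the study's unstated
  Pfam-name mapping. The pipeline consumes such files through the
  documented aligned-FASTA/Stockholm and TSV dialects; a thin import
  shim may be needed for the exact supplementary column layout.
- The one-site model assumes a single class of independent sites;
  multi-site or sequential binding is out of scope, as is baseline
  integration of raw power traces (inputs are integrated heats).
- The fit's error model is i.i.d. Gaussian per injection; instrument
  heteroscedasticity is not modelled (a weights hook exists).
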