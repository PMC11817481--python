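# Methods

## Screening model

A protein is a wholly disordered protein (WDP) when

* length N ≥ `min_length` (default 50 residues, inclusive), and
* (disordered residues)/N ≥ `min_fraction` (default 0.90, inclusive),

where "disordered residues" is the size of the **union** of the
protein's disorder intervals — overlapping or duplicated intervals are
counted once. Intervals use 1-based inclusive coordinates (the UniProt
feature convention); intervals running past the chain are clamped to N
at load with a warning. The union is computed by a sorted sweep and is
verified in the test suite against a per-residue boolean-mask count on
random inputs.

Per-residue score tracks (e.g. AlphaFold pLDDT exported one value per
residue) are thresholded into intervals first: maximal runs with
score < `score_threshold` (default 50, the common pLDDT reading of
disorder) become intervals; the direction is configurable for score
conventions where high means disordered. When a protein carries both
an interval track and a score track, intervals win by default
(`prefer_intervals`). The package deliberately takes **one** track per
protein and leaves consensus-building across predictors to the user:
published screens combine annotation sources with unstated rules, and
we prefer an explicit input contract over a guessed merge.

Exact duplicate sequences are removed before screening (first
occurrence kept, input order preserved), mirroring standard practice
(`seqkit rmdup`-style) for redundant proteome entries.

## Physicochemical indices

All four indices are computed from pinned, published constant tables
(`wdpscan/constants.py`; dumped by `--show-constants`):

* **GRAVY** = mean Kyte–Doolittle (1982) hydropathy. Range
  [−4.5, 4.5]; negative ⇒ hydrophilic.
* **Instability index** II = (10/N) Σ_{i=1..N−1} DIWV(rᵢ, rᵢ₊₁) with
  the Guruprasad et al. (1990) dipeptide weights; pairs the original
  publication leaves unlisted weigh 1.0. II > 40 ⇒ predicted unstable
  in vivo (the threshold itself is "stable"). II is order-sensitive by
  construction — permuting a sequence changes it — which the tests
  assert, alongside GRAVY's permutation invariance.
* **Aliphatic index** AI = X(A) + 2.9·X(V) + 3.9·(X(I)+X(L)), mole
  percents; range [0, 390].
* **Theoretical pI**: the Henderson–Hasselbalch net charge over D, E,
  C, Y side chains, K, R, H side chains and both termini, with the
  Bjellqvist pKa set used by ExPASy ProtParam including its
  residue-specific terminal pKas. The charge is strictly decreasing in
  pH, so the root on [0, 14] is unique; bisection stops at
  |charge| < 1e-4 (≈ 1e-4 pH precision at typical slopes). A dense
  1e-3 grid scan of the same charge function is the test oracle.
  One subtlety the residue-specific terminal pKas introduce:
  *appending* an acidic residue changes the C-terminal pKa (4.55 for a
  terminal Asp vs 3.55 generic) and can slightly **raise** the pI of a
  very short acidic peptide; the monotonicity property ("adding D
  never raises pI") therefore holds for mid-chain insertion, which is
  how the tests state it.

Non-canonical residues (lenient input mode) contribute zero
hydropathy, zero aliphatic volume, the default DIWV weight and no
ionizable group, but still count toward N. Strict mode (default)
rejects them so data problems surface early. Outputs print 3 decimals;
full precision is kept internally. Biopython's ProtParam implements
the same published definitions and is used in the test suite as an
independent cross-check (never as the implementation).

## Diagram of states

Charge fractions are exact rationals of integer counts, and the region
thresholds are stored as `Fraction`s, so a protein with FCR of exactly
7/20 is classified by the printed inequalities (0.25 and 0.35 belong
to R2; NCPR = 0.35 belongs to R3) rather than by binary rounding —
with float thresholds, `Fraction(7,20) > 0.35` is true and boundary
compositions silently leak into R3/R4. Histidine is not counted as
charged: the classification follows the K/R vs D/E convention of the
charge-fraction literature (localCIDER counts H the same way).

Since NCPR ≤ FCR identically, R1 and R2 membership depends on FCR
alone; the NCPR clauses sometimes attached to them are vacuous and are
documented rather than coded. The R4-vs-R5 sign convention
(`negative_is_R4`, the Das–Pappu orientation) is configurable;
analyses that only need the strong-polyelectrolyte union are
insensitive to it. An exhaustive enumeration over all integer
compositions up to N = 20 verifies that the predicates partition the
reachable (FCR, NCPR) space.

## Families

Hits (12-column BLAST tabular) are filtered to E ≤ 1e-4 (inclusive)
and capped at 20 hits per query by descending bitscore (ties broken by
E-value then subject id, so the cap is independent of file order).
Edges are undirected — an asymmetric A→B hit still connects — and
families are the connected components (single linkage), computed with
networkx and verified against a hand-written union-find oracle.
Proteins without qualifying hits are singletons; the family label is
the lexicographically smallest member accession. Published category
counts additionally involve manual motif inspection after multiple
sequence alignment; optional `--min-identity` / `--min-coverage` edge
filters (off by default) approximate that step, and the family count
is therefore not treated as a reference quantity.

## Statistics

Both an unpaired Welch *t* (Welch–Satterthwaite df) and a two-sided
Mann–Whitney *U* (midranks for ties) are always reported. The MW
p-value is exact by full enumeration when both groups have ≤ 8
observations and the pooled data is tie-free, otherwise the normal
approximation with tie and continuity corrections is used (the
measured worst-case exact-vs-asymptotic gap at 8 vs 8 is ≈ 0.011).
Degenerate inputs are defined rather than NaN: identical constant
groups give p = 1. No multiple-testing adjustment is applied by
default — the per-metric questions are reported as-is, and the output
header says so — with Benjamini–Hochberg available behind `--bh`.

## Synthetic proteomes

The generator emulates the statistical structure of a real WDP screen,
not its biology:

* **Classes.** A `wdp_fraction` (default 0.10) minority of
  "WDP-like" proteins: lengths uniform on [99, 442] (the span of the
  published Arabidopsis WDP set, most 100–200 aa), hydrophilic-biased
  composition, per-protein charge fractions uniform on [0.02, 0.28]
  for each sign so the realized (FCR, NCPR) pairs spread over
  R1/R2/R3 with occasional R4/R5 — the qualitative layout reported
  for real WDP sets. Background proteins: lengths uniform on
  [100, 600] (matching the structured comparison sets used in such
  studies), low charge ([0.02, 0.10] per sign), mostly hydrophobic
  pool.
* **Composition is exact.** `round(N·f₊)` residues from {K, R} (split
  evenly) and `round(N·f₋)` from {D, E}; the remainder is drawn from
  the 16 non-charged residues with weights interpolated between
  uniform (bias 0) and a polar disorder-promoting pool {S,G,N,Q,T,P}
  (bias 1; WDP class default 0.8, background 0.15). Realized counts
  deviate from requested fractions only by rounding (≤ 1 residue per
  charge class).
* **Disorder tracks.** One contiguous interval per protein. WDP-class
  coverage is drawn uniform on [0.90, 1.0] and the covered count
  rounds **up**, so a planted WDP can never fall below the 0.90
  screen threshold through integer rounding; background coverage is
  uniform on [0, 0.60]. Ground truth (class, realized fraction,
  family) is emitted as a TSV.
* **Hit tables.** All ordered within-family pairs get E-values
  ≤ 1e-10; optional noise adds cross-family hits with E ≥ 1e-2, which
  must not survive the 1e-4 cutoff.
* **Determinism.** One `numpy.random.default_rng(seed)` instance
  threads through every draw; identical specs are byte-identical on
  disk, different seeds differ.

What the generator does **not** emulate: realistic disorder-predictor
noise, fragmented disorder tracks, evolutionary sequence divergence
within families (hits are planted, not aligned), or compositional
quirks like repeat expansions. Passing the recovery tests therefore
shows the pipeline's logic is correct under the stated conditions, not
that any particular predictor's output is trustworthy.

## Pipeline

`run_pipeline` is a pure function of (inputs, config): stage TSVs plus
a manifest with tool/table versions, config echo, input and output
SHA-256 checksums and per-stage row counts. All defaults equal the
screening criteria above (0.90, 50, E ≤ 1e-4, 20 hits, II > 40). Logs
go to stderr and `run.log`; TSVs never mix with logs.

## Problem sizes in the validation

The test suite and `scripts/acceptance.py` run on synthetic proteomes
of 100–300 proteins with 10% planted WDPs, 200-sequence random panels
for index-oracle agreement, exhaustive composition enumeration to
N = 20, and 200-replicate power checks at n = 56 per group (the size
of the published WDP and background sets); these sizes give exact or
tightly converged checks while keeping the whole validation inside a
few minutes on one CPU.

## Known limitations

* Real-data reference numbers (the published 20/15/19/2 region split,
  length extremes, per-protein II values) require the 56 UniProt
  sequences; the package ships the accession list and a fetch helper
  but no sequence data, so those numbers are reproducible only with
  network access.
* The homology stage consumes a hit table; running BLASTP itself is
  out of scope (docs show the expected `blastp -outfmt 6` invocation).
* No synteny/phylogenetics, expression, PPI/GO or phase-separation
  analysis — the package covers the sequence-level screen and
  characterization only.
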