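# Methods

## Sequence model

A genome is normalized to lowercase `{a, c, g, t}` and partitioned into
*runs*: maximal unambiguous stretches. Ambiguity symbols (`n`, IUPAC
degeneracies, gaps) and FASTA record boundaries terminate runs; they
contribute neither to the effective length `n` nor to any word. The
rationale is that words spanning unknown bases or chromosome-concatenation
junctions are not sequence that was ever read off a molecule, and counting
them would corrupt the entropies. Consequently the single-string occurrence
count `n − k + 1` generalizes to `W_k = Σ_runs max(0, |run| − k + 1)`, and
every formula uses `W_k`. Sequences are processed single-stranded, 5′→3′ as
written; no reverse-complement canonicalization is applied.

## k-mer machinery

Two exact backends implement the same contracts and are tested against
each other and against naive dictionary hashing:

- **Packed codes.** Each k-mer is a 2-bit-per-base integer (`uint64` up to
  k = 32, a lexicographically ordered pair up to k = 64, Python strings
  beyond). Codes are built by binary doubling (O(log k) vectorized passes)
  and counted by sorting. Spectra never materialize the 4^k space — only
  observed words.
- **Suffix structure.** A prefix-doubling suffix array with Kasai LCP over
  the runs joined by pairwise-distinct sentinels. Since sentinels never
  match anything, no common prefix spans a run boundary. The longest
  repeated substring is the LCP maximum; k-mer groups are maximal
  SA-adjacent blocks with LCP ≥ k.

The **maximal repeat length** (`mrl`) uses a fast path: sort the full
32-base codes of every position; the longest common prefix over all pairs
is realized by an adjacent sorted pair, and equals half the leading-zero
count of the minimal adjacent XOR. Windows shorter than 32 bases near run
ends are not covered by full codes and are checked explicitly (against the
sorted codes by range query, and against each other by hashing); when this
tail work would exceed a fixed budget, or when a repeat of length ≥ 32
exists, the suffix structure takes over. Overlapping occurrences count, and
the `mrl` of a repeat-free genome is defined as 0 (the degenerate case has
no canonical definition; 0 keeps `repeat_count(k) = 0 ⇔ k > mrl` exact).

## Entropies

`E_k` is computed from the multiplicity histogram:
`E = lg2(W_k) − (1/W_k) Σ_m count(m)·m·lg2(m)` — grouping words with equal
multiplicity is numerically stable (all terms non-negative) and fast. The
entropy at the non-integer double logarithmic length `2LG = lg2(n)` is the
linear interpolation `E_{k1} + (2LG − k1)(E_{k2} − E_{k1})` with
`k1 = ⌊2LG⌋`, `k2 = ⌈2LG⌉`; the same weight interpolates the lexical-index
ratio (evaluation at `round(2LG)` is available behind a flag). Theoretical
bounds: `max E_k = lg2(n − k + 1)` (equipartition, attained in the
all-hapax case) and, for random genomes at `k = ⌈lg2 n⌉`, a gap from
`lg2(n)` of order `lg2(n / (n − ⌈lg2 n⌉ + 1))`. Note the gap can never fall
strictly below that expression — equipartition makes it the exact value in
the all-hapax case and a lower bound otherwise — so it is an *envelope
scale*, not a strict dominance bound; the property suite asserts the gap
stays within twice the envelope.

## Indexes and the biobit measure

`EC = E_2LG − LG` and `AC = 2LG − E_2LG` satisfy `EC + AC = LG` to machine
precision by construction (`LG = 2LG/2` is exact in binary floating point).
`BB = scale · AF^γ (1 − 2·AF)^δ`. Defaults: δ = 3 (the cubic collapse of
super-ordered genomes), γ = 0.5 (weights the anti-entropic fraction below
linearity, placing the maximum at `AF* = γ/(2γ+2δ) = 1/14 ≈ 0.0714`), and
`scale = LG`, which keeps BB commensurate with logarithmic length; all
three are configurable (`BBParams`) because the functional family — not one
exponent pair — is the substantive claim. For `AF ≥ 1/2` the value is
non-positive and reported as such rather than raised.

Degenerate inputs: indexes are computed wherever the bracketing spectra
exist; an `E_2LG` outside the open interval `(LG, 2LG)` sets a flag instead
of raising, so perturbation scans can record law violations as data.

## Random-genome experiment

`mrl_trials` draws each trial genome iid uniform over the four bases with
numpy's PCG64; per-trial seeds are spawned deterministically from the
master seed, so any trial is independently regenerable. The reported
statistics are min, max, sample standard deviation (ddof = 1; at 100 trials
the ddof choice is below reporting precision) and mean of `mrl + 1`, with
`lg2(n)` alongside: the balance argument (occurrence probability
`(n−k+1)/4^k` against hapax probability `1/(n−k+1)`) predicts
`avg(mrl + 1) ≈ lg2(n)`, and the simulation shows the mean sitting slightly
above `lg2(n)` at every length. Default 100 trials per length; lengths up
to 10⁷ run in a few minutes on one CPU (about 2 s per 10⁷-base trial), and
a configurable length cap guards against accidental huge allocations.

## Laws and perturbations

`verify_laws` evaluates registered predicates on computed indexes and
returns pass/fail with margins; failures are data, never exceptions. The
built-in set L1–L5 covers the inequalities stated in the model section;
the registry accepts additional user-supplied laws so the set can be
extended without code changes. L5 (`lg2 LX ≤ AC` at integer k) is a
theorem — `E_k ≤ lg2|D_k|` and `W_k ≤ n` — and is asserted on every input
as an implementation self-check.

Edit plans operate in effective coordinates (0-based, half-open,
non-overlapping within a plan): `delete` removes a span, `shuffle-window`
permutes the bases of a span in place with the plan's seed. Run boundaries
persist through edits (ambiguity structure is outside the model).
`law_survival_scan` applies each plan, recomputes the indexes and the law
report, and emits one row per plan, recording per-plan errors without
aborting the scan. No search strategy over edit space is provided — the
operators and the scan harness are the supported surface.

## Synthetic fixtures

The fixture generator produces the test corpus: `random` (AF ≈ 0),
`periodic` (AF near its maximum for the length, BB ≈ 0), `block-mixture`
(a periodic block of `ordered_fraction · n` bases plus a random block,
sweeping AC monotonically between the two ends) and `literal`
hand-checkable strings. The mixture fraction is a generator knob for
spanning the order spectrum, not an estimate of any real genome's
composition. Real genomes differ from every fixture kind — they carry
repeat families, isochores, long-range correlation — so passing tests show
the indexes behave correctly across the order spectrum, not that any
biological conclusion holds for a particular species.

## Problem sizes and tolerances

The test suite exercises genomes up to 10⁶ bases and the repeat-length
experiment up to 10⁷ × 100 trials; brute-force oracle comparisons run on
strings up to 2,000 bases (200 mixed random/structured cases) where
exhaustive hashing is exact and fast. Stochastic assertions use fixed seeds
and tolerances of three standard errors; conservation identities are
asserted at 1e−9; exact-equivalence contracts (spectra, mrl) at equality.
Known limitations: ambiguity handling (run splitting) is a modelling
choice that cannot be validated against the indexes' original convention,
which is unstated for genomes with unknown nucleotides; plain-text FASTA
only (no gzip); and the strict random-gap inequality discussed above holds
only as an envelope.
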