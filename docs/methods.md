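# Methods

## Composition model

A soft-masked chromosome is a string over `{A,C,G,T,N}` plus IUPAC
ambiguity codes, with lowercase marking repeat-derived bases. For a window
`[s, e)` we count, at the byte level:

- `gc`, `at` — unambiguous bases, case-insensitively;
- `rep_gc`, `rep_at` — the lowercase subset of those;
- `n` — N and every ambiguity code ("unknown").

Derived percentages: `GC% = 100·gc/(gc+at)`, `rep% = 100·rep/(gc+at)` with
`rep = rep_gc + rep_at`, and GC% within the repeat and non-repeat fractions
from the split tallies. GC is defined over assayed bases only: unknown
bases appear in neither numerator nor denominator. Any percentage whose
denominator is zero is *undefined* (`None`, an empty TSV cell) — never a
sentinel zero, which would silently drag regressions.

Windows tile the chromosome without overlap (default 100 kb, last tile
short). Tiling rather than overlapped sliding makes the conservation
property exact: window counts sum to the whole-chromosome single-pass
counts for every window size, which the tests assert against an
independent per-character recount. Chromosome- and genome-level values are
always pooled from counts (weighted by assayed bases), never averaged over
percentages, so short terminal windows cannot bias them. Coordinates are
0-based half-open internally.

The per-chromosome repeat statistic used against chromosome size is the
*median* of defined window rep% values, which is robust to the strongly
asymmetric within-chromosome rep% distributions; the pooled mean rep% is
reported alongside.

Windows with fewer assayed bases than 20% of their span (gap-dominated)
are excluded from window-level regressions and heterogeneity scoring
(configurable threshold).

## Association models

Per species, chromosome GC% (or median rep%) `y` is modelled against
chromosome size `L` (Mb):

| kind | form | free parameters `k` |
|---|---|---|
| null | `y = μ` | 1 |
| linear | `y = β₀ + β₁L` | 2 |
| hyperbolic | `y = a + b/L` | 2 |
| segmented | continuous 2-slope piecewise linear | 4 (incl. breakpoint) |

Linear and hyperbolic fits are ordinary least squares (the hyperbola is
linear in `1/L`, so no nonlinear optimisation is needed and the fit is
deterministic). The segmented fit is an exhaustive grid search over
candidate breakpoints (midpoints of adjacent observed sizes by default,
≥3 points required on each side), solving the hinge design
`[1, L, max(0, L−c)]` at each candidate and keeping the RSS minimiser;
ties break toward the smaller breakpoint. Models are compared on a common
AIC convention, `AIC = n·ln(RSS/n) + 2k`, with the breakpoint counted as a
parameter. "Clearly better" means ΔAIC > 2 (the conventional evidence
margin); rankings always use raw AIC and both are reported.

The association label is derived from the AIC-best model: "none" if that
is the null model or its overall F-test has p ≥ 0.05 (threshold
configurable), otherwise the sign of the size dependence — the linear
slope, `−sign(b)` for the hyperbola (b > 0 means small chromosomes are
GC-enriched, a negative association), or the below-breakpoint slope for
the segmented model. Model-family discrimination between linear and
hyperbolic fits is intrinsically weak on narrow size ranges (both are
monotone and nearly collinear there), which is why the label, not the
family, is the primary call; family identification is reliable when
microchromosomes extend the size range.

A "fits the linear model well" style call corresponds to F-test p < 0.05
and R² ≥ 0.3 (both configurable and reported with the raw diagnostics).
Square-root size axes are used only for the combined overview figure,
never in fitting. No multiple-testing correction is applied across species
by default; a Benjamini–Hochberg helper is available for panel-wide
screens. Chromosomes are called micro below a 30 Mb threshold by default
(boundary value counts as macro); the threshold is a config knob and
deliberately distinct from the estimated breakpoint.

## Karyotype metrics

For arm lengths `p ≤ q`: CI = 100·p/(p+q) ∈ [0, 50]; arm ratio `q/p`
(infinite for telocentrics); THCL = Σ(p+q); FN counts one arm for
mono-armed and two for bi-armed chromosomes over the diploid complement,
hence FN ≤ 2×2n. Mono-armed is CI ≤ 12.5 (a Levan-style
acrocentric/telocentric cut); the literature uses several conventions, so
the cutoff is a parameter.

## Heterogeneity and grouping

AT/GC heterogeneity is scored as the standard deviation of defined window
GC% at a fixed window size (default 100 kb), reported together with that
window size. A genome of two equal-mass isochore classes at GC 35% and
55% has the two-point closed form SD = 10, which the acceptance checks
recover. Species grouping uses Ward agglomerative clustering on
standardized (log₁₀ assembly size, genome GC%); group ids are renumbered
by ascending mean genome size so the partition is deterministic and
input-order invariant. Clustering generalizes the narrative three-group
amphibian pattern instead of hard-coding its thresholds; recovering that
pattern is a test, not a rule.

## Synthetic genomes

Each chromosome gets a target GC from a size model (constant / linear /
hyperbolic / segmented) plus `N(0, σ)` chromosome-level scatter (σ = 0.5
for the linear presets, 0.4 hyperbolic, 0.3 segmented). Along the
chromosome, isochore-like segments have exponential lengths (mean 0.3 Mb)
and segment GC drawn `N(chromosome GC, isochore SD)`, or an explicit cyclic
GC list for exact constructions. Repeat tracts have geometric lengths
(mean 500 bp) and uniform starts; the placement intensity is
`−ln(1−d)·L/mean` so the expected masked fraction equals the requested
density `d` despite tract overlap. Repeat bases are lowercased and their
GC shifted by a configurable offset; N-gaps are Poisson-placed geometric
runs. Bases are i.i.d. within segments, so binomial error bounds apply to
every realized value; the emitted ground-truth table is recounted from the
final byte array, and a fixed seed yields a byte-identical FASTA.

What the generator does *not* emulate: dinucleotide/codon structure, real
transposable-element families, GC-dependent assembly gaps, or
phylogenetic covariance between species. Passing tests therefore
demonstrate correctness of the measurement and inference machinery under
controlled composition, not robustness to every artefact of real
assemblies (e.g. collapsed repeats or lineage-specific masking quality).

### Coordinate scale

`bases_per_mb` sets how much sequence represents one nominal megabase
(default 1e6). The end-to-end CLI demonstration runs the six-pattern
default panel at 10 kb per nominal Mb with 1 kb windows (the nominal
equivalent of 100 kb windows), keeping the full pipeline — including two
complete reruns for the byte-determinism check — to tens of megabases of
sequence while preserving the Mb size axis, the 50/20 Mb breakpoints and
the window-per-chromosome resolution. Statistical behaviour at this scale
differs from full scale only through the (smaller) binomial term, which is
dominated by the chromosome-level σ in every preset.

### Preset conditions

Linear recovery uses slope −0.05 %GC/Mb, σ = 0.5, 25 chromosomes of
20–60 Mb. Breakpoint panels use slope −0.8 below the breakpoint, 0 above,
σ = 0.3, sizes 5–200 Mb (breakpoint 50) and 5–100 Mb (breakpoint 20).
Pattern presets: positive (19 chromosomes, 17–35 Mb, +0.15 %GC/Mb),
negative (24, 20–35 Mb, −0.2), none (25, 37.5–59.6 Mb, constant GC
36.5%), hyperbolic (30, 5–200 Mb, GC = 41 + 120/L). The chromosome-count
and size ladders mirror the ranges typical of the lineages each pattern
represents.

## Numerical choices

- AIC uses `max(RSS, 1e-300)` to keep noise-free exact fits finite;
  exact fits still rank first.
- R² is clipped to [0, 1] and defined as 0 when the response is constant.
- OLS goes through statsmodels; rank deficiency (all sizes equal) raises a
  singular-fit error rather than returning garbage coefficients.
- All pipeline outputs embed the config hash and seed, carry no
  timestamps, and use a fixed float format, so reruns are byte-identical.
- Degenerate inputs fail loudly: empty FASTA records, out-of-range table
  rows (with their row number), out-of-bounds BED intervals, empty window
  lists, k exceeding the panel size.

## Known limitations

- Repeat annotation is taken from masking (or a BED override); no repeat
  detection or family breakdown is attempted, so rep% inherits the quality
  of the upstream masking.
- The hyperbolic fit is OLS on 1/L, which weights small chromosomes'
  residuals equally with large ones; a variance-weighted variant would
  differ slightly for very unbalanced panels.
- Breakpoint uncertainty is not reported (no Davies-type interval); the
  grid resolution is that of the observed sizes.
- No phylogenetic correction: species are treated as independent, as in
  panel-wide descriptive screens.
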