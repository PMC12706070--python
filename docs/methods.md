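# Methods

## The screen being modeled

A combinatorial activator screen fuses ordered tuples of 1–3 protein parts
(22 activation domains, ADs, plus 3 well-folding inert "protein folder"
domains, PFs) onto an MCP scaffold recruited by dCas9 to a target promoter.
Each part carries a fixed 8-nt DNA barcode; each cloned plasmid
additionally carries a random 6-nt UMI per cloning round, so a sequencing
read identifies both the construct (via the barcode tuple) and the clonal
lineage (via the UMI). Cells transduced at low MOI are selected, passaged,
stained for the target protein and sorted into four extreme expression
bins — two covering the bottom of the distribution and two the top, each
holding 12.5% of cells. Bins, the unsorted population, and the plasmid
pool are sequenced as barcode amplicons.

## Scoring model

**Activation.** Reads for each construct are split into UMI groups by UMI
prefix (prefix length 3 → 64 groups, 2 → 16, 0 → one aggregated group).
Group counts are normalized within each condition by a single scalar so the
mean over groups equals 100 (equalizing sequencing depth between bins), and
each sufficiently covered group is scored as

    score(group) = Σ_{bin=1..4} normalized_reads_bin × MFI_bin

with MFI the bin's mean fluorescence intensity, an external per-sort input
(supplied per target and replicate; the simulator emits it for synthetic
runs). A construct's score is the mean over its groups within a replicate,
then the mean over replicates. Groups whose summed normalized reads over
the four bins fall below `min_bin_sum` are not scored (defaults: 10 for
grouped UMIs, 40 when all UMIs are aggregated — aggregated counts pool more
reads, so the bar is proportionally higher). Constructs with no surviving
group are reported unscored, and a coverage report records the scored
fraction per target.

**Toxicity.** Before scoring, UMIs holding more than `umi_outlier_fraction`
(default 0.5) of their construct's reads within a condition are discarded
as PCR-jackpot/contamination artifacts; this filter is applied to
cell-derived counts but not to plasmid counts, whose clonal diversity is
too high to produce outlier UMIs. All UMIs are then pooled, both conditions
are normalized to a mean of 100 reads over constructs, and

    toxicity = −log2((reads_cells + 1) / (reads_plasmid + 1))

with one pseudoread guarding zeros. The sign is chosen so that higher =
more toxic (stronger depletion from cells); a `negate_toxicity` flag
restores the raw log-ratio for anyone preferring the opposite convention.
Toxicity is averaged over the endogenous-target populations × replicates;
reporter-derived populations are excluded by the caller (they reuse the
same physical cells and would double-count).

A consequence of the outlier filter worth knowing: a construct represented
by a single clone in a condition loses its only UMI (100% share > 50%) and
becomes unscoreable there. This mirrors the intent of the filter — a
single-clone construct's counts are indistinguishable from a jackpot — but
it means very low-coverage screens should lower `umi_outlier_fraction` or
accept reduced scoreable fractions.

## The synthetic screen generator

The generator's defaults are the study conditions it emulates:

| parameter | default | meaning |
|---|---|---|
| `moi` | 0.1 | mean lentiviral integrations per cell (Poisson) |
| `n_cells` | 1,000,000 | cells exposed per transduction (≈95,200 infected) |
| `passages` | 3 | growth rounds; clone mass × 2^(−cost·passages) |
| `bin_fractions` | 4 × 0.125 | extreme sort gates (bottom two, top two) |
| `umi_length` | 6 nt | clonal identifier |
| `read_depth` | 1,000,000 | reads per sequenced condition |
| `jackpot_prob`, `jackpot_factor` | 0.01, 10 | per-(construct, UMI) PCR jackpot |
| control spikes | 3.6% (single) / 1.5% (bi-/tri-partite) each | supernatant, multi-copy, mutant-scaffold |
| `targets`, `n_replicates` | EPCAM+CXCR4, 2 | independent transduction chains |

Latent ground truth: per-AD base strength ~ LogNormal(0, 1) in arbitrary
fluorescence-contribution units; per-AD fitness cost ~ Uniform(0, 0.4)
log2-units per passage; PFs contribute 0 to both. A construct's strength is
the sum of its parts' strengths plus optional adjacent-pair interaction
terms (zero by default; an `order_sensitivity` flag keys them on ordered
pairs to emulate tripartite order dependence), and its fitness cost is
always the sum of part costs. Per-cell fluorescence is
exp(log(1 + strength) + N(0, noise_sd)) with noise_sd 0.3 — a log-normal
expression model around an additive mean. The fluorescence-vs-potency form
is a stand-in used only for recovery testing; no claim is made that real
reporter response is additive on this scale.

Cells with ≥1 integration keep a single construct drawn proportional to
plasmid abundance (real protocols aim for single copy at MOI 0.1); each
transduction event gets a fresh UMI. Growth depletion is deterministic
exponential on expected clone mass, then re-discretized multinomially
before sorting. Sorting ranks cells by fluorescence with ties broken by
(construct_id, UMI) for determinism; bin sizes are ⌊n × fraction⌋, so
8,000 cells yield exactly 1,000 per bin. Sequencing draws reads
multinomially per condition; plasmid reads are spread over 32 random UMIs
per construct.

Controls: the supernatant control is never packaged into cells but
contaminates cell-derived sequencing at an attenuated rate (default 0.2 of
its plasmid share); the mutant-scaffold control is a zero-strength,
zero-cost construct; the multi-copy control rides in co-infected cells and
is emulated by assigning it the fluorescence of one randomly drawn library
construct (a deliberate simplification — full per-cell co-occupancy is not
tracked, and this control exists only to exercise control handling, not to
be scored).

What the generator does **not** emulate: sequencing base-call errors
(malformed reads are injected directly in tests instead), lentiviral
recombination between barcodes, UMI collisions beyond what 4⁶ = 4,096
random UMIs naturally produce, growth stochasticity beyond multinomial
resampling, and any nonlinearity between activator potency and
fluorescence. Passing recovery tests therefore demonstrates that the
scoring pipeline inverts *this* generative model faithfully — not that it
is robust to every artifact of real screens.

## Read layout and extraction

Reads are anchor + (barcode₈ + UMI₆) blocks separated by a cloning scar,
plus a terminal scar: each cloning round inserts the new domain between the
previous ORF and its barcode, so barcodes accumulate **innermost-last** —
the block read last belongs to position 1, the position closest to the
scaffold (configurable via `block_order`). The simulator stores one clonal
UMI per transduction event; in emitted reads it occupies the position-1
block while outer blocks carry random filler UMIs, and extraction keys
counts on the position-1 UMI — making the encode/decode round trip exact.
Anchor and scar matching is exact, case-insensitive, forward-strand only;
all offsets are 0-based half-open. Rejections (missing anchor/scar, short
block, N in a barcode) are returned as typed data and fully accounted:
accepted + control + rejected = total, always. N inside a UMI is kept as a
distinct symbol. Barcode correction at Hamming distance 1 is available but
off by default; the default library's barcodes are generated with pairwise
distance ≥ 3, which makes single-substitution correction unambiguous.

## Combinatorial analyses

Order effects report Pearson r over order-reversed pairs, one point per
unordered pair; palindromic constructs (their own reversal, including
A-B-A tripartites) are excluded since they would inflate r trivially. By
default only all-AD constructs are paired; `require_exact_n_ads=2` on
tripartite scores restricts to two-AD/one-PF fusions. Positional and
copy-number effects are medians over the relevant construct strata;
copy-number padding uses the two inert PFs (the third folder is excluded
from filler sets). Additivity predicts a multi-domain score as the sum of
its parts' single-domain scores and reports Pearson r. Pearson is used for
score-vs-score comparisons, Spearman for score-vs-ground-truth rank
comparisons.

## Sequence features

NCPR counts K/R positive and D/E negative; histidine is neutral
(physiological pH convention). Hydropathy is the mean Kyte–Doolittle value
rescaled linearly from [−4.5, 4.5] to [0, 9]. The disorder-promoting set is
{T,A,G,R,D,H,Q,K,S,E,P}. Kappa and omega are blob-patterning scores: per
blob size g ∈ {5, 6}, the local asymmetry σ = (f_A − f_B)²/(f_A + f_B) is
computed over sliding windows, δ(g) is the mean squared deviation of window
σ from the whole-sequence σ, and the score averages δ(g)/δ_max(g) where
δ_max comes from the deterministic maximally segregated arrangement (A
block, neutrals, B block). For two-group compositions this arrangement is
the exact maximizer (verified exhaustively in tests), so the segregated
sequence scores 1 and alternating arrangements score minimally. For
neutral-containing compositions certain interleaved arrangements can exceed
the block normalizer, so the score is clamped at 1; a Monte-Carlo
normalizer option (`mc_normalizer_draws`) cross-checks δ_max and can only
lower the score. Kappa shows no hit/miss signal in this screening context
but is provided for completeness alongside omega.

Native-position profiles use start = (N−1)/Lp and end = (N−1+Ld)/Lp for a
domain of length Ld starting at residue N of an Lp-residue protein; the
protein is divided into 20 equal sections and a section is flagged when the
domain overlaps it with positive measure (a domain ending exactly at a
section boundary does not touch the next section). Native coordinates are
taken as given input; discrepancies between screened and canonical
sequences must be resolved upstream.

Hits are records with fold activation ≥ 2 on at least one target
(boundary inclusive); group comparisons use an unpaired two-sided t-test
with pooled variance by default and a Welch option, excluding missing
feature values pairwise. Predictor confusion reports sensitivity
TP/(TP+FN) and precision TP/(TP+FP), flagging undefined denominators.

## Problem sizes and tolerances

The test suite and acceptance script run bipartite screens at 10⁶ cells and
10⁶ reads per condition (seconds per screen, single CPU), with a smaller
60,000-cell screen for plumbing tests; these sizes give recovery
correlations comfortably above the ρ ≥ 0.8 contract while keeping the
whole suite under ten seconds. Exact equalities (gate sizes, normalization
means, worked-example scores) are asserted to machine precision or 1e-9;
stochastic recovery properties use fixed seeds. Determinism is bit-exact:
identical configs (including seed) reproduce identical tables, and every
threshold a run applies is echoed into its manifest.

## Known limitations

- The fluorescence model and all latent-parameter distributions are
  choices, not measurements; recovery statistics quantify pipeline
  correctness, not biological effect sizes.
- Multi-copy cells are approximated, not tracked per cell.
- No paired-end merging, quality-aware correction, or base-call error
  model in extraction.
- Scores carry no uncertainty beyond replicate means; the analyses report
  point correlations only.
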