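# Methods

## Trio design and the additive baseline

The experimental unit is a trio: two parental lines (roles P1, P2) and
their hybrid (H), each sequenced in replicate (three libraries per
genotype in the emulated design, nine in total). All expression is
compared on a per-library reads-per-million (RPM) scale: each sample
column is scaled to sum to 10⁶. RPM was chosen because the original
normalization of small-RNA counts is tool-internal and unstated;
per-library scaling is the standard, assumption-light choice and keeps
the |log2FC| > 1 threshold interpretable. A pseudocount of 1 RPM is
added before any log2.

The additive expectation for a feature is the mid-parent value
MPV = ½(P1 + P2). The hybrid-vs-MPV test needs MPV "replicates": these
are built by pairing parental replicates by index,
MPVᵢ = ½(P1ᵢ + P2ᵢ), stopping at the smaller replicate count if they
differ. This is a testing contract, not a biological claim — parental
libraries are not actually paired — and it halves the MPV variance
relative to a single library, which is conservative in the direction of
calling more non-additivity.

### Tests and thresholds

All differential calls use a two-sided Welch t-test on log2(RPM + 1),
per feature, with Benjamini–Hochberg correction across all tested
features within a comparison. Features with zero counts in both groups
of a comparison are excluded from testing and from the BH denominator.
Degenerate rows (zero variance in both groups) return p = 1 when the
means agree — no evidence — and p = 0 when they differ.

* Non-additive: |log2(mean_H / MPV)| > `lfc` (default 1) **and**
  q < `alpha` (default 0.05) in the H-vs-MPV test.
* Pairwise significance (used by the pattern rules): p < alpha and
  |log2FC| > lfc in miRNA mode; gene mode additionally requires
  q < alpha. The switch exists because the emulated designs tested
  miRNAs at p and genes at q.

### Pattern classes

With ">" meaning significantly higher and "=" not significantly
different: HP = hybrid above both parents; LP = below both; CT44 =
equal to P1 and different from P2; CT45 symmetric; BP = strictly
between two parents with both hybrid–parent contrasts significant in
opposite directions. The published pattern list includes the
parent-equal case for LP ("H < P1 = P2") but omits it for HP; we
complete HP symmetrically (hybrid significantly above both parents
suffices, whatever the parents do between themselves). Non-additive
features matching no listed pattern are reported `unclassified` rather
than forced into a bucket. Raising `alpha` can only grow, and raising
`lfc` only shrink, the significant sets; swapping the parent labels
swaps CT44↔CT45 and fixes the other classes (both properties are
tested).

### Venn / FPU and the reduction statistic

For three DE sets A = DE(H vs P1), B = DE(H vs P2), C = DE(P1 vs P2),
the FPU set is (A ∪ B) \ C — features differential against a parent but
not between the parents — reported with its three-region decomposition
(A-only + B-only + (A∩B)\C). `percent_reduction(value, reference)` is
100·(reference − value)/reference to two decimals, used for comparing
abnormality rates (e.g. abnormal pollen-mother-cell frequencies per
meiotic stage) between genotypes.

## Degradome site calling

Tags are 1-based 5′-end positions of degradome reads on transcripts;
read length beyond the 5′ end is ignored. Around each tagged position p
with full support (p ≥ 14, p + 12 ≤ length) a 26-nt query window
covering p−13 … p+12 is extracted, the tagged nucleotide at window
offset 14. For each miRNA two anchorings are evaluated — the tag
opposite miRNA nucleotide 10 and opposite nucleotide 11, the canonical
cleavage registers — whenever the implied duplex fits inside the
window (miRNAs of 24–25 nt cannot fit the anchor-10 duplex in a 26-nt
window; such anchorings are skipped).

The pairing score is the standard plant scheme: ungapped antiparallel
duplex, mismatch 1.0, G:U wobble 0.5, penalties doubled at miRNA
positions 2–13; U and T are equivalent. Sites with score ≤ 4 are
retained; overlapping anchorings landing on the same (miRNA,
transcript, position) are deduplicated keeping the lower score (anchor
10 on ties). Gapped alignment (bulged duplexes) is out of scope; the
CLI reserves no flag for it.

Categories follow the tag count c at the site relative to the
transcript's tagged positions: c = 1 → category 4; c > 1 and c equal to
the maximum → 0 (unique maximum) or 1 (tied maximum); otherwise 2 if c
is above the median and 3 if at or below it. The median is computed
over tagged positions only — untagged positions are not zero
observations of degradation but absences from the tag table — and ties
at the median go to category 3 ("equal to or less than"). Categories
are always re-derivable from the stored per-site statistics.

Coverage is the percentage of input transcripts with ≥ 1 tag, to two
decimals. T-plot tables list every tagged position in ascending order
with exactly one row flagged as the cleavage site.

## Hairpin screening

Candidates carry their own dot-bracket structure and free energy (from
any folding tool; no internal thermodynamics). The structure must be a
single hairpin: pairs must nest around one terminal loop, multiloops
are rejected. A bulge is any maximal unpaired run between consecutive
stem pairs, counted across both arms (an internal loop is one bulge);
it is *biased* when its unpaired nucleotides lie on one arm only. An
*error* is an unpaired nucleotide. These readings of "biased errors in
one bulge" and "biased bulges" are this package's definitions — the
terms have no published formal definition — and are isolated in one
place (`hairpin.Bulge`) so they can be swapped.

The 11 inclusive thresholds: max nt in one stem bulge ≤ 12; stem pairs
≥ 16; free energy ≤ −15 kcal/mol; hairpin length (2·pairs + loop +
bulge nt) ≥ 50; loop ≤ 200; max nt in one mature-region bulge ≤ 4;
biased errors in one mature bulge ≤ 2; biased bulges in the mature
region ≤ 2; mature errors ≤ 4; mature base pairs ≥ 12; percent of the
mature sequence in the stem ≥ 80. "In the stem" counts paired
nucleotides and stem-bulge nucleotides (the plausible alternative —
paired only — would double-penalize bulges already bounded by criteria
6–9). G:U counts as a pair. Mature intervals must be 18–25 nt.

## Synthetic data: what it emulates and what it does not

### Trio counts

Counts are negative binomial with the mean/dispersion parameterization,
variance = μ + φμ² (φ = `dispersion`, default 0.1 — a typical
biological-replicate CV of ~32 %). Baseline relative abundances are
log-normal (σ = 1); each genotype column of means is scaled so its
expected library total equals `library_size` (default 10⁶), and planted
counts default to 50 HP, 50 LP, 50 CT44, 50 CT45 and 20 BP of 1,000
features, mirroring the proportions of non-additive categories reported
in the emulated study design.

Planted mean geometry, with e = `effect_log2fc` (default 2):

* HP / LP: parents equal at b, hybrid at b·2^±e.
* CT44 / CT45: parents at b·2^∓e (2e apart), hybrid exactly equal to
  the **lower** parent. Matching the lower parent is a geometric
  necessity, not a free choice: if the hybrid equals the higher of two
  parents, H/MPV < 2 always, so |log2FC| > 1 against the MPV is
  unreachable and the plant could never be non-additive.
* BP: parents 2e apart, hybrid displaced from the MPV by e toward the
  lower parent — the arithmetic MPV sits high between log-spaced
  parents, so the downward displacement keeps the hybrid strictly
  between them; its margin over the lower parent is small (~1.09 log2
  units at e = 2), which makes BP intrinsically the hardest class.
* Additive: parents get a mild random offset (±0.5 log2), hybrid at
  the MPV.

Centering planted features at b·2^±e keeps the genotype library totals
within ~0.2 log2 units of each other, so compositional RPM shift does
not masquerade as non-additivity.

The generator emulates mean structure and overdispersion only: no
adapter/length artefacts, no correlated features, no dosage or
ploidy-specific biology, no miRNA length distribution. A passing round
trip shows the caller recovers the planted mean structure under NB
noise — not that it would behave identically on real libraries.

**Power at the default design.** With three replicates the per-feature
Welch t-test estimates its variance on ~4 degrees of freedom; at φ = 0.1
a true 4-fold effect yields p-values spread over ~0.003–0.03, and BH
across 1,000 features (22 % of them truly non-additive) leaves the
q < 0.05 gate unmet for roughly a third of planted features.
Unconditional recovery of planted HP/LP/CT44/CT45 labels is therefore
~50–67 % across seeds, limited almost entirely by the q-gate: the
pairwise pattern gates pass at 0.9–1.0 and the category accuracy among
features recovered as non-additive exceeds 95 %. The false non-additive
rate on planted-additive features is ≈ 0.001. Tests borrowing variance
strength across features (edgeR/DESeq2-style moderation) would recover
> 95 %, but the per-feature t-test is the method this pipeline
implements, and the generator's conditions were fixed a priori rather
than tuned to the test's power.

### Degradome scenarios

Transcripts are uniform random RNA (default 30 transcripts of 200–400
nt); miRNAs uniform random (default 8 of 21 nt; 18–25 allowed). Each
planted site gets its own transcript: a perfect reverse complement of
one miRNA is embedded with the tagged position opposite miRNA
nucleotide 10, at least 13 nt from the 5′ end and 12 from the 3′ end so
the query window is complete. Tag piles are then built to realize the
requested category — e.g. a category-2 site receives a higher pile
elsewhere plus two low filler piles so the median stays below the site
count (with only two piles the median equals their mean and the site
would fall to category 3). Background decay is Poisson per position
(default rate 0 for closed-loop tests); piles are re-drawn up to 100
times if a background draw perturbs the intended category, then the
generator fails loudly.

### Hairpin fixtures

Twelve records built from declarative stem blueprints (paired runs,
one-arm bulges, internal loops, loop length): one passes all criteria,
and each criterion has a fixture violating exactly it — with one
documented exception: a mature region of ≥ 18 nt with < 12 base pairs
necessarily has ≥ 7 unpaired nucleotides, so `fail_mature_base_pairs`
also violates the mature-error bound. Free energies are assigned
(−45 kcal/mol, or −10 for the energy fixture); structures are authored,
not folded.

## Numerical and interface choices

* BH is applied within each comparison; q ∈ [0, 1] by construction.
* log2 fold changes use group mean RPM with pseudocount 1, so FC = 0
  exactly for identical groups.
* All coordinates are 1-based inclusive; TSV everywhere (see
  `docs/FORMATS.md`); one seed drives every stochastic stage.
* Determinism: equal seeds give byte-identical simulate/classify/
  targets outputs (tested).

## Problem sizes

Default analysis scales — 1,000 features × 9 samples for the trio,
30 transcripts / 8 miRNAs / 20 planted sites for the degradome, 12
hairpins — were chosen so a full planted-truth round trip of every
stage, including the exhaustive-scan oracle comparison, completes in
seconds while keeping BH corrections and median statistics
non-trivial.

## Known limitations

* Cleavage positions for anchor-11 hits are reported at the tagged
  coordinate with the anchor label; which coordinate the original
  pipelines print for that case is unstated.
* No gapped miRNA/target duplexes; no transcriptome mapping of raw
  reads (tag tables are the input); no miRBase annotation or GO/KEGG
  enrichment.
* The hairpin screen trusts the supplied structure; it does not fold.
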