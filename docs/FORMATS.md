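# File formats

All tabular files are TSV: tab-separated, one header row, UTF-8, LF
line endings. All positions are 1-based and inclusive. Sequences are
FASTA; miRNAs may use U or T (equivalent for pairing) and are emitted
as given, uppercased on read.

## Counts (`counts.tsv`)

| column       | content                                   |
|--------------|-------------------------------------------|
| `feature_id` | unique feature identifier                  |
| `<genotype>_<rep>` | non-negative integer counts, one column per library, e.g. `T44_1`, `H21_3` |

The genotype prefix is mapped to a role (P1/P2/H) at read time
(`--p1/--p2/--hybrid` on the CLI).

## Trio truth table (`truth.tsv`)

`feature_id`, `category` (HP/LP/CT44/CT45/BP/additive), `mean_P1`,
`mean_P2`, `mean_H` (relative concentration units).

## Expression calls (`calls.tsv`)

`feature_id`, `mpv`, `log2fc_mpv`, `p`, `q`, `additivity`
(additive/non-additive), `category`.

## Degradome tags (`tags.tsv`)

`transcript_id`, `position` (1-based 5′ end of the tag), `count`
(positive integer). Duplicate rows for one position are summed on read.

## Target sites (`sites.tsv`)

`mirna_id`, `transcript_id`, `cleavage_pos`, `anchor` (10 or 11),
`score`, `count_at_site`, `tx_max`, `n_max`, `tx_median`, `category`
(0–4), `alignment` (one mark per miRNA position 5′→3′: `|` pair,
`o` G:U, `x` mismatch).

## T-plot table

`position`, `count`, `is_cleavage_site` (exactly one `True` row),
positions ascending.

## Hairpins (`hairpins.tsv`)

`id`, `sequence`, `structure` (dot-bracket, same length),
`mature_start`, `mature_end`, `energy` (kcal/mol).

## Hairpin verdicts (`verdicts.tsv`)

`id`, then for each of the 11 criteria its measured value and a
`<criterion>_pass` boolean, then `overall_pass`.

## Venn regions

`region` (A_only, B_only, C_only, AB_not_C, AC_not_B, BC_not_A, ABC,
FPU), `size`.
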