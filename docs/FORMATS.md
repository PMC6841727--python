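# File formats

## Summary statistics (`.ma`)

Whitespace-delimited text with a header, one row per variant (the
COJO/GCTB 8-column dialect). Extra columns are ignored.

```
SNP A1 A2 freq b se p N
rs1001 A G 0.3173 0.0142 0.0093 0.1274 25100
```

* `A1` — effect (counted) allele; `A2` — other allele. Case-insensitive.
* `freq` — frequency of A1 in (0, 1).
* `b`, `se` — marginal least-squares effect per A1 copy and its standard
  error (se > 0).
* `p` — Wald p value in (0, 1]; `N` — per-SNP sample size (≥ 1).

Rows with non-numeric or invalid fields are rejected (counted in the log).
Duplicate `SNP` values are an error.

## Genotypes (PLINK 1 bed/bim/fam)

Standard SNP-major `.bed` (magic `6c 1b 01`, two bits per call:
00 = hom A1, 01 = missing, 10 = het, 11 = hom A2), with the usual 6-column
`.bim` (chrom, id, cM, bp, A1, A2) and `.fam`.

## Phenotypes

3+ columns, whitespace-delimited, no header: `FID IID value`. Matched to
panels by IID. The same layout is used for PRS files written by `score`.

## Genetic map

Per-chromosome whitespace-delimited files with columns
`position(bp) rate(cM/Mb) map(cM)`; a header line is detected
automatically. Map positions at arbitrary bp are obtained by piecewise-
linear interpolation; positions outside the map range are extrapolated at
the nearest interval's rate.

## Region exclusion lists

3 columns: `chrom start end`, 1-based inclusive start, half-open end
(`start ≤ bp < end`). `#` comments allowed.

## LD store (`.ldm`)

Little-endian binary, CRC-checked:

| field        | type            | content                                  |
|--------------|-----------------|------------------------------------------|
| magic        | 4 bytes         | `SPLD`                                   |
| version      | uint32          | 1                                        |
| p            | int64           | number of SNPs                           |
| nnz          | int64           | total stored values                      |
| info_len     | uint64          | byte length of the info block            |
| window_start | int64[p]        | first row index of each SNP's window     |
| indptr       | int64[p+1]      | CSC-style column delimiters into values  |
| values       | float64[nnz]    | stored correlations, column-concatenated |
| info         | utf-8 TSV       | snp_id, chrom, bp, cm, A1, A2, freq      |
| crc32        | uint32          | CRC-32 of everything above               |

Column j's stored rows are the contiguous range
`window_start[j] .. window_start[j] + (indptr[j+1]-indptr[j]) - 1`. The
matrix is symmetric with unit diagonal. `read_ld` verifies the magic,
lengths and checksum and raises a corrupt-file error otherwise.
`sbayesr.ldref.export_text` writes an `i j value` text dump for
inspection.

## Fit outputs

`<out>.snpRes.txt` — TSV: `SNP, A1, beta` (posterior mean, per-allele),
`PIP`, per-component posterior probabilities.
`<out>.parRes.txt` — TSV trace of thinned draws: iteration, σ²β, σ²ε, h²,
π per component.

## Run configuration

Every subcommand accepts `--config FILE` (YAML mapping of long option
names, dashes or underscores); explicit flags override config values,
which override defaults. The fully resolved configuration is logged at
the start of each run and round-trips through
`sbayesr.cli.RunConfig.to_yaml`/`from_yaml`.
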