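# mafscan

Motif detection and conservation scoring in Multiple Alignment Format (MAF)
files. `mafscan` searches the aligned blocks of a MAF file for motifs given
as **k-mers** (multi-pattern Aho–Corasick), **JASPAR position weight
matrices** (log2-odds scanning with an empirically calibrated p-value
threshold), or **regular expressions**, then scores each hit's conservation
against every other sequence aligned in the same block.

For each hit and each compared sequence a *similarity vector* over
`{1, 0, –}` is computed column by column over the hit's gapped span:
both-gap columns are ignored, a gap in the searched sequence against a
character records `–`, a (case-insensitive) character match records `1`,
and everything else — mismatch or a gap in the compared sequence —
records `0`. The conservation percentage is `100 · #1 / length` (with `0`
and `–` in the denominator), and the block-level conservation is the
unweighted mean over compared sequences.

Large files are split into block-aligned byte ranges processed by parallel
workers; blocks are independent (searches never cross block boundaries),
and results merge in file order, so output is byte-identical for any
process count.

## CLI

```sh
# k-mer search (one motif per line, optional "id<TAB>sequence")
mafscan alignment.maf --kmers motifs.txt --bed hits.bed --json hits.json --csv hits.csv

# PWM search: threshold auto-calibrated to p = 1e-4 against the background
mafscan alignment.maf --jaspar motifs.jaspar --pvalue 1e-4 --background 0.3 0.2 0.2 0.3 --bed hits.bed

# regex search, 8 worker processes, reverse complement included
mafscan alignment.maf --regexes "GA+T,TT[AC]G" --processes 8 --reverse-complement --bed hits.bed
```

Key options: `--search-genome ID` searches a specific source (default: each
block's reference, i.e. its first sequence); `--genome-ids FILE` restricts
conservation comparison to the listed genome IDs; `--seed N` fixes the PWM
calibration RNG (all runs are reproducible); `--bed` is the default output,
`--json`/`--csv` are optional and additionally carry similarity vectors,
conservation percentages, and — for PWM hits — score, empirical p-value,
and Benjamini–Hochberg FDR.

Coordinates: BED intervals are 0-based half-open on the forward strand;
JSON/CSV additionally report gapped (`g_start`/`g_end`) and ungapped
(`u_start`/`u_end`) offsets within the MAF block.

## Python API

```python
from mafscan import parse_maf, KmerSet, SearchOptions, search_block

blocks = list(parse_maf(open("alignment.maf")))
hits = search_block(blocks[0], KmerSet(kmers=(("m1", "GATTACA"),)), SearchOptions())
```

`mafscan.synthetic.generate_maf` builds synthetic MAF fixtures with motifs
planted at known coordinates and an exactly derivable expected hit set —
every pipeline stage is testable without external data.

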