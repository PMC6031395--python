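# markerdiv

Compare the taxon richness and phylogenetic diversity (PD) of taxonomic
groups — for instance a family of giant viruses against the bacterial and
archaeal domains — using a single conserved marker gene such as the two
largest RNA-polymerase subunits (Rpb1/Rpb2). The package implements the
complete analysis chain that such marker-gene surveys use on metagenomic
protein fragments, and ships a synthetic-community generator with full
ground truth so that every stage can be validated end to end.

## What it computes

Given reference alignments of the marker for each group (and a reference
tree), plus unaligned protein fragments:

1. **Homolog screening** — a light profile HMM ("Plan7-lite": match/insert/
   delete states, local Viterbi in log-odds, Gumbel-calibrated E-values) is
   built per group; fragments shorter than 150 aa are skipped, and hits are
   kept at E < 10⁻⁵.
2. **Alignment & placement** — accepted fragments are mapped onto reference
   alignment columns via their Viterbi path, then placed on the reference
   tree by maximum likelihood (Felsenstein pruning under a 20-state Poisson
   model; per-edge pendant branch optimized by golden-section search).
   Groups are assigned by strict monophyletic edge painting.
3. **Richness** — a 100-residue sliding window (step 10) over the reference
   alignment; members with gaps at more than 10% of window sites are
   discarded; greedy centroid clustering into OTUs at 70/80/90% amino-acid
   identity; rarefaction (mean OTUs over 10 resamplings without
   replacement); richness curves compared between groups with a two-sample
   log-rank test on OTU cluster sizes.
4. **PD** — per window and group, up to 1,000 members are subsampled, a
   neighbor-joining tree is built over Poisson-corrected distances
   d = −(19/20)·ln(1 − (20/19)·p), and PD is its total branch length.
5. **Paralog correction** — fragments of a group carrying an ancient gene
   duplication are split into the two paralog clades before rarefaction, so
   the duplication does not inflate apparent richness (~2-fold otherwise).
6. **Selection** — pairwise Ka/Ks (ω) by Nei–Gojobori counting with
   Jukes–Cantor correction and a codon-bootstrap standard error; pairs
   filtered at Ka > 0.01, Ks < 5 (or 10), SE% < 25; group ω distributions
   compared with a Mann–Whitney U test.

## Worked example

Run the whole pipeline on a synthetic community in which group `V` is built
with three times the lineages and twice the radiation depth of group `B`:

```python
from markerdiv import io, pipeline

cfg = io.RunConfig(
    groups=[["V", 12, 1.6, 0.05], ["B", 4, 0.8, 0.05]],
    fragment_count=200, alignment_len=300,
    resample_n=30, pd_subsample=50, n_null=300, seed=42,
)
manifest = pipeline.run_pipeline(cfg, "out")
print(manifest.n_fragments, manifest.n_hits, manifest.n_placed)
# 200 200 200   (all fragments pass the E<1e-5 screen and are placed)
```

`out/richness.tsv` then contains, for the window starting at column 100:

```
window_start group  cutoff  n_members  n_otus
         100     B     0.7         91     4.0
         100     B     0.8         91     4.0
         100     B     0.9         91    10.4
         100     V     0.7         91     7.9
         100     V     0.8         91     7.6
         100     V     0.9         91    15.1
```

and `out/pd.tsv`:

```
window_start group  n_subsampled       pd
         100     B            50  4.099748
         100     V            50  9.369406
```

The deeper, wider radiation of `V` is recovered as higher OTU richness at
every identity cutoff and higher PD (here 9.37 vs 4.10 expected
substitutions per site of total branch length). `out/logrank.tsv` holds the
per-window log-rank comparison of the OTU size distributions, and
`out/manifest.json` records counts, parameters and seeds; re-running with
the same config reproduces every output byte for byte.

The same stages are available from the shell:

```bash
markerdiv run --outdir out --seed 42
markerdiv simulate --outdir sim --seed 1
markerdiv kaks --pair pair.fasta
markerdiv logrank --sizes-a 1,1,1 --sizes-b 3,3,3
```

## Documentation

`docs/methods.md` describes the models and procedures, all tunable
parameters with their defaults, what the synthetic generator does and does
not emulate, and the package's numerical and design choices.
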