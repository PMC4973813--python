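# fabmap

Construction toolkit for a synteny-anchored SNP marker platform in a
diploid crop, built around six stages:

1. **homology anchoring** (`fabmap.homology`) — parse 12-column tabular
   homology hits, compute unique reciprocal best hits between two
   transcriptome assemblies (defaults: alignment ≥ 100 bp, E ≤ 1e-30)
   and anchor each contig pair to a single reference gene
   (`MtXgNNNNNN`-style identifiers carry the chromosome number).
2. **SNP mining** (`fabmap.mining`) — global affine-gap alignment of
   anchored contig pairs, candidate calling at substitution columns,
   then three filters: ≥ 50 bp flanks, no reference intron junction
   within 50 bp (flanks truncated at more distant junctions), and no
   extra matching contig/locus (paralog and multi-locus screens).
   Passing targets are named `Vf_<gene>_<serial>` and exported with a
   `[X/Y]` consensus flank.
3. **genotype QC** (`fabmap.qc`) — genotype matrices (lines × markers,
   calls AA/AB/BB/NC), iterative 6 % no-call filtering, gene diversity
   (2pq) and PIC, per-line heterozygosity, concordance audits against
   sequence predictions, segregation-distortion filters, cluster
   quality classes I–IV from 2-D fluorescence, and UPGMA trees.
4. **linkage mapping** (`fabmap.linkage`) — two-point recombination
   fractions by EM (F2 codominant, dominant-trait × codominant marker,
   and inbred designs with the RIL-by-selfing correction
   R = 2r/(1+2r)), LOD-based single-linkage grouping (LOD ≥ 5,
   r ≤ 0.3), SARF marker ordering (exhaustive for small groups, greedy
   + 2-opt beyond), Kosambi or Haldane spacing, and dominant-trait
   placement with flanking markers.
5. **consensus merging** (`fabmap.consensus`) — weighted DAG merge of
   per-population maps with greedy deletion of conflicting marker
   occurrences (logged), chromosome labelling by anchor-marker vote,
   and summary statistics (length, mean/max gap, loci vs markers).
6. **synteny candidates** (`fabmap.synteny`) — marker → reference-gene
   links (E ≤ 1e-37, name-derived fallback), colinear block detection
   by monotone chaining, and candidate-gene listing inside a trait
   interval with keyword filtering.

`fabmap.simulate` generates every input with known truth: a reference
genome with intron-containing gene models (GFF3 + FASTA), two parental
transcript sets with planted SNPs and diverged paralog decoys, F2 /
F5-SSD / RIL populations (Poisson crossovers, no interference,
optional error, missing data and viability distortion), and
three-cluster fluorescence readouts of tunable tightness.

> Note on the inbred distortion cut-offs (0.045 / 0.25): a
> homozygote:heterozygote ratio for F5 material has expectation ≈ 15
> and cannot fall inside those bounds, so the filter interprets them
> as heterozygote:homozygote bounds (expectation 1/15 ≈ 0.067 for F5),
> which they bracket.

## CLI

```sh
fabmap simulate reference --n-chrom 2 --genes-per-chrom 20 --seed 1 -o ref/
fabmap simulate transcriptomes --refdir ref/ --snp-rate 0.004 --seed 2 -o trans/
fabmap anchor --ab hits_ab.tsv --ba hits_ba.tsv --genes hits_genes.tsv -o anchors.csv
fabmap mine --fasta-a trans/line_a.fa --fasta-b trans/line_b.fa \
    --anchors anchors.csv --gff ref/reference.gff3 --ref-fasta ref/reference.fa -o targets.csv
fabmap qc --genotypes panel.csv --max-nc 0.06 -o qc_report/
fabmap map --genotypes pop1.csv --design f2 --min-lod 5 --max-r 0.3 -o pop1.map.csv
fabmap consensus --maps pop1.map.csv --maps pop2.map.csv --weights weights.json -o consensus.csv
fabmap synteny --map consensus.csv --gff ref/reference.gff3 -o synteny/
fabmap candidates --interval Vf_Mt3g092810_001,Vf_Mt3g094760_001 \
    --map consensus.csv --gff ref/reference.gff3 -o candidates.csv
```

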