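import pytest

from fabmap.simulate import make_parental_transcriptomes, make_reference


@pytest.fixture(scope="session")
def small_reference():
    return make_reference(n_chrom=2, genes_per_chrom=10, introns_per_gene=2, seed=3)


@pytest.fixture(scope="session")
def parental_transcriptomes(small_reference):
    return make_parental_transcriptomes(
        small_reference, snp_rate=0.004, paralog_fraction=0.3, seed=4
    )


@pytest.fixture(scope="session")
def mined(small_reference, parental_transcriptomes):
    """Full anchoring + mining run over the synthetic transcriptomes."""
    from fabmap.alignment import kmer_hits
    from fabmap.homology import anchor_to_ortholog, reciprocal_best_hits
    from fabmap.mining import mine

    ref = small_reference
    ta, tb, variants = parental_transcriptomes
    transcripts = {g.gene_id: g.spliced(ref.chromosomes[g.chrom]) for g in ref.genes}
    hits_ab = [h for q, s in ta.items() for h in kmer_hits(q, s, tb)]
    hits_ba = [h for q, s in tb.items() for h in kmer_hits(q, s, ta)]
    hits_genes = [
        h for q, s in {**ta, **tb}.items() for h in kmer_hits(q, s, transcripts)
    ]
    pairs = reciprocal_best_hits(hits_ab, hits_ba)
    anchors = [anchor_to_ortholog(p, hits_genes) for p in pairs]
    result = mine(
        ta,
        tb,
        anchors,
        {g.gene_id: g for g in ref.genes},
        chromosome_seqs=ref.chromosomes,
        reference_seqs=ref.chromosomes,
    )
    return result, variants
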