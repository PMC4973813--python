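"""Published summary inputs for the faba bean SNP marker platform.

These are the study's printed panel and map summaries, carried as data
so that summary arithmetic can be recomputed without the (unavailable)
raw genotype files.  Values are inputs, not expectations: nothing here
is asserted, only consumed.
"""

from __future__ import annotations

# % heterozygosity of the 37 validation-panel inbred lines
VALIDATION_PANEL_HETEROZYGOSITY: dict[str, float] = {
    "NV153-1": 1.27,
    "NV639-1": 1.39,
    "NV643-3": 2.15,
    "NV644-1": 7.44,
    "NV648-2": 1.13,
    "NV656-3": 0.63,
    "NV657-2": 0.89,
    "NV658-2": 0.76,
    "NV662-1": 2.78,
    "NV713-1": 1.64,
    "NV714-1": 0.75,
    "NV715-1": 0.90,
    "NV716-1": 0.64,
    "NV717-1": 0.50,
    "NV718-1": 0.25,
    "NV719-1": 0.38,
    "NV720-1": 0.76,
    "NV721-1": 1.01,
    "NV722-1": 1.01,
    "NV723-1": 0.88,
    "NV724-1": 0.76,
    "NV725-1": 0.64,
    "NV726-1": 0.89,
    "NV727-1": 1.14,
    "NV728-1": 0.89,
    "NV729-1": 1.42,
    "NV730-1": 0.76,
    "NV731-1": 0.50,
    "NV732-1": 2.17,
    "NV733-1": 0.88,
    "NV734-1": 0.38,
    "NV735-1": 1.01,
    "NV736-1": 1.78,
    "NV737-1": 2.89,
    "NV738-1": 0.79,
    "NV739-1": 5.37,
    "NV740-1": 0.40,
}

# consensus-map totals as printed
CONSENSUS_TOTAL_LENGTH_CM = 1403.8
CONSENSUS_UNIQUE_LOCI = 542
CONSENSUS_GROUPS = 6
CONSENSUS_MARKERS = 687
CONSENSUS_LARGEST_GAP_CM = 24.7

# concordance of genotyped vs predicted alleles (matching, total assays)
CONCORDANCE_COUNTS = (512, 757)

# mapping population sizes (progeny analysed), used as default merge weights
POPULATION_SIZES = {
    "pop1": 136,  # F2
    "pop2": 165,  # F2
    "pop3": 52,   # F2
    "pop4": 125,  # F2
    "pop5": 194,  # F5
    "pop6": 101,  # RIL
}
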