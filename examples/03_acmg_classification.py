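"""ACMG-AMP evidence combination.

Classifies a few evidence-tag sets with the combining engine: a null
truncating variant absent from population databases, a known missense
allele, contradictory evidence, and a benign profile.
"""

from hepadx import acmg_classify

examples = [
    ({"PVS1", "PM2"}, "novel high-confidence PTV, absent from gnomAD"),
    ({"PVS1", "PM2", "PP5"}, "same, plus a reputable-source report"),
    ({"PS1", "PM2"}, "missense matching a known pathogenic change"),
    ({"PM2", "PP3"}, "rare + in-silico support only"),
    ({"BA1", "PVS1"}, "truncating but too common to cause disease"),
    ({"BS1", "BP4"}, "frequency + computational benign evidence"),
]
for tags, note in examples:
    print(f"{sorted(tags)!s:<28} -> {acmg_classify(tags):<18} ({note})")
# Only pathogenic / likely_pathogenic classes count toward a diagnosis;
# contradictory evidence collapses to a VUS.
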