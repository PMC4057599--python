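"""Test whether a gene set is enriched for essential (lethal) genes.

Writes a small phenotype report, flags genes whose phenotype text mentions
"lethality", and computes the log2-odds enrichment of lethal genes in a test
set against the full background, with a hypergeometric p-value.
"""

from pathlib import Path
import tempfile

from gatewaynet import lethality_enrichment, read_mgi_lethality
from gatewaynet.io_formats import lethal_gene_set

REPORT = """Kl\tpreweaning lethality, incomplete penetrance
Igf1\tembryonic lethality
Aqp1\tabnormal water homeostasis
Ttr\tdecreased circulating thyroxine level
Cdkn1c\tneonatal lethality
Folr1\tembryonic lethality
Dio1\tabnormal hormone level
Fbp1\tdecreased gluconeogenesis
Actr10\tabnormal locomotion
Cldn1\tneonatal lethality
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "phenotypes.rpt"
    path.write_text(REPORT)
    lethal = lethal_gene_set(read_mgi_lethality(path))

background = {line.split("\t")[0] for line in REPORT.strip().splitlines()}
test_set = {"Kl", "Igf1", "Cdkn1c", "Aqp1"}

print(f"lethal genes: {sorted(lethal)}")
result = lethality_enrichment(test_set, background, lethal)
print(f"b/n = {result.b}/{result.n} in test, B/N = {result.B}/{result.N} in background")
print(f"log2 odds enrichment = {result.enrichment:.3f} ({result.direction})")
print(f"hypergeometric p = {result.p_value:.3f}")
# Positive enrichment means the test set carries a higher fraction of
# essential genes than the background; the p-value is the probability of
# drawing at least that many lethal genes by chance.
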