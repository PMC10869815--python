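"""Scan a coding region for codons convertible to premature stops.

Four codons can become stops through a single-strand C->T deamination:
CAG->TAG, CAA->TAA and CGA->TGA (sense-strand C), and TGG->TGA/TAG/TAA
(antisense-strand C, read as G->A on the sense strand).  Each target
cytosine is classified by the base 5' of it on its edited strand, because
the canonical double-strand deaminase only accepts 5'-TC (or 5'-TCC)
contexts while relaxed homologs also accept 5'-AC and 5'-GC.
"""

import numpy as np

import cbekit as ck

rng = np.random.default_rng(4)
cds = "ATG" + "".join(rng.choice(list("ACGT"), size=3 * 198)) + "TAA"
region = ck.CodingRegion("demo_cds", cds)

targets = ck.scan_stop_codons(region)
summary = ck.summarize_scan(targets)
counts = ", ".join(f"{n}x {c}" for c, n in sorted(summary.per_codon.items()))
print(f"{summary.total} stop-convertible codons in {region.n_residues} residues: {counts}")

strict = ck.summarize_scan(targets, ("5'-TC", "5'-TCC"))
relaxed = ck.summarize_scan(targets, ("5'-TC", "5'-TCC", "5'-AC", "5'-GC"))
print(f"targetable with a strict 5'-TC/TCC deaminase: {len(strict.qualifying)}")
print(f"targetable with a relaxed-context deaminase:  {len(relaxed.qualifying)}")
# The gap between these two numbers is the targeting density a relaxed
# deaminase buys: every extra codon is one more place a knockout stop
# could be installed.
for t in strict.qualifying[:5]:
    ctx = ", ".join(f"{c.context}" for c in t.cytosines)
    print(f"  residue {t.residue}: {t.codon} -> {'/'.join(t.achievable_stops)} "
          f"({t.edited_strand} strand; contexts: {ctx})")
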