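"""Seed-match site scanning and composite target scoring.

Scans a 3'-UTR for canonical seed sites of a mature miRNA and shows how the
per-site weights combine into the retention score (threshold 0.7).
"""

from exomirnet import find_seed_sites, score_target, seed_of

mirna = "UAAAGUGCUUAUAGUGCAGGUAG"   # mature miRNA, seed = nt 2-8
utr = (
    "CCAUGGUUAAGCUU"
    "GCACUUUA"       # 8mer site: reverse complement of the seed, then A
    "GGAUACGUCAUA"
    "CACUUU"         # bare 6mer (seed nt 2-7 match)
    "GGCC"
)

print(f"miRNA seed (nt 2-8): {seed_of(mirna)}")
sites = find_seed_sites(mirna, utr, mirna_id="miR-20a-5p", gene_id="CXCL8")
for s in sites:
    print(f"  {s.site_type:8s} at UTR[{s.utr_start}:{s.utr_end}] = "
          f"{utr[s.utr_start:s.utr_end]}")
score = score_target(sites)
print(f"composite score: {score:.4f} ({'retained' if score >= 0.7 else 'dropped'} at 0.7)")

# The 8mer site alone carries weight 0.9; sites combine as a noisy-OR
# (1 - prod(1 - w)), so additional weaker sites only raise the score.
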