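"""Estimate an admixture proportion with F4 Ratio Estimation.

Simulates a five-population phylogeny whose leaf X is an 80/20 mixture of
the W-side and S-side clades, then forms the ratio
f4(OUT, REF; X, S) / f4(OUT, REF; W, S), whose expectation is the W-side
ancestry fraction of X.  Standard errors come from a 5 cM block jackknife.
"""

import admixkit as ak

g = ak.simulate_admixture_graph(n_snps=30_000, alpha=0.8, t_admix=30, seed=11)
freqs = ak.allele_frequencies(g)

est = ak.f4_ratio_ancestry(freqs, "X", outgroup="OUT", reference="REF",
                           cladeW="W", cladeS="S")
print(f"true W-side ancestry of X : 0.800")
print(f"estimated proportion      : {est.estimate:.3f} +/- {est.std_err:.3f} "
      f"({est.n_blocks} jackknife blocks)")

# The 4-population test rejects treeness when a population is admixed:
res = ak.four_population_test(freqs, "OUT", "W", "X", "S")
print(f"treeness of ((OUT,W),(X,S)): Z = {res.z:.1f} "
      f"({'rejected' if res.tree_rejected else 'consistent'}) "
      f"- X is admixed, so |Z| > 3 is expected")

fst = ak.fst_pairwise(freqs, "W", "S")
print(f"pairwise Fst(W, S)        : {fst.estimate:.3f} +/- {fst.std_err:.3f}")
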