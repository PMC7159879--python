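"""Score-density clustering of a small protein set.

Two near-identical sequences pass the culling thresholds (both covered to
>= 90% of their length, >= 1.89 bits per aligned column) and form one
cluster; an unrelated sequence stays a singleton.
"""

from conflictscan import ProteinSeq, ScoringParams, align_pair, bit_score, cluster_proteins

a = ProteinSeq("a", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
b = ProteinSeq("b", "MKTAYIAKQRQISFVKSHFSRQLEDRLGLIEVQ")  # one substitution
c = ProteinSeq("c", "GWWNPEYGHHDDCCVVLLMMPPRRSSTTKKFFY")

raw, cols, cov_a, cov_b, ident = align_pair(a, b)
bits = bit_score(raw)
print(f"a vs b: raw={raw:.0f}  bits={bits:.2f}  density={bits/cols:.2f} bits/col  "
      f"coverage={cov_a:.2f}/{cov_b:.2f}  identity={ident:.2f}")

cs = cluster_proteins([a, b, c], ScoringParams(L=0.9, S=1.89))
for members, rep in zip(cs.clusters, cs.representatives):
    print(f"cluster (rep {rep}): {sorted(members)}")
# density well above 1.89 and full mutual coverage -> a and b co-cluster;
# c shares no significant local alignment and remains alone.
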