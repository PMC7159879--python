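"""Detect planted conflict systems and compare against the ground truth.

The scan extracts neighborhoods around anchor-domain genes, matches the
gene-order templates, and applies the three conservation filters: <= 70 nt
between consecutive run members, one strand per run, and presence of the
same cluster signature in at least two phyla.
"""

from conflictscan import SimConfig, generate, load_templates, scan_genomes

data = generate(SimConfig(seed=7, n_genomes=150, genes_per_genome=50, decoy_rate=0.3))
instances = scan_genomes(
    data.genomes, data.hits, load_templates(), proteins=data.proteins
)

def key(rec):
    comp = rec["component_genes"] if isinstance(rec, dict) else rec.component_genes
    gid = rec["genome_id"] if isinstance(rec, dict) else rec.genome_id
    return (gid, tuple(sorted(comp.items())))

truth = {key(r) for r in data.ground_truth.planted}
found = {key(i) for i in instances}
tp = len(truth & found)
print(f"planted: {len(truth)}  detected: {len(found)}  true positives: {tp}")
print(f"sensitivity: {tp/len(truth):.2f}  precision: {tp/len(found):.2f}")
for inst in instances[:3]:
    print(f"  {inst.system_type} in {inst.genome_id} ({inst.strand}) "
          f"effectors={inst.effectors}")
# every decoy violates one filter, so none should be detected:
decoys = {key(d) for d in data.ground_truth.decoys}
print(f"decoys detected: {len(decoys & found)}/{len(decoys)} (expected 0)")
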