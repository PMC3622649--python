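"""Bin anonymous fragments back to their source genomes.

Trains the naive-Bayes k-mer model on four composition-distinct genomes
and reports how often 870 bp fragments return to their source — the
assignment that later selects TIS parameters (genus) and SVM models
(domain).
"""

import metagun as mg

genomes = [
    mg.generate_genome(length=50_000, genome_id=f"genome{i}", genus=f"genus{i}",
                       domain="Bacteria" if i < 3 else "Archaea", seed=10 + i)
    for i in range(4)
]
model = mg.train_binning_model(genomes, k=8)

correct = total = 0
for g in genomes:
    frags, _ = mg.sample_fragments(g, coverage=0.3, length_spec=870, seed=5)
    assignments = mg.assign_groups(model, frags)
    for f in frags:
        gid, genus, domain = assignments[f.id]
        correct += gid == g.id
        total += 1
print(f"self-assignment: {correct}/{total} fragments "
      f"({100 * correct / total:.1f}%) binned to their source genome")
gid, post = mg.classify_fragment(model, frags[0])
print(f"example: {frags[0].id} -> {gid} with posterior {post:.4f}")
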