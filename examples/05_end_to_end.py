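"""Full three-stage prediction on a held-out genome.

Runs the packaged benchmark: universal module trained on two genomes per
domain, prediction on an unseen genome of the same family, scored with the
standard fragment metrics. Takes about a minute.
"""

from metagun.benchmarks import end_to_end_benchmark

result = end_to_end_benchmark(seed=1)
print(f"fragments: {result['n_fragments']}  truth genes: {result['n_truth_genes']}")
print(f"3' ends:  Sn {result['sn_pct']:.1f}%  Sp {result['sp_pct']:.1f}%  "
      f"Hm {result['hm_pct']:.1f}%  (TP {result['tp']}, FP {result['fp']}, FN {result['fn']})")
print(f"TIS:      internal {result['tis_internal_pct']:.1f}%  "
      f"external {result['tis_external_pct']:.1f}%  total {result['tis_total_pct']:.1f}%")
# Sn/Sp count exact 3'-end matches (frame matches for edge-truncated genes);
# TIS accuracy is scored over correctly identified genes only.
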