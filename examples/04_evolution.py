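"""A small NSGA-II run: evolve wiring patterns for TE up / cost down.

Uses the seconds-scale "smoke" sizes; swap in scale="desk" (Gen=10, P=Q=25,
~half a minute) for the configuration used by the acceptance runs.
"""

import wirevo as wv

manifest = wv.run_condition(condition_id=1, scale="smoke", seed=1,
                            characterize_entities=False)

cols = ["gen", "te_mean", "te_max", "cost_mean", "density_mean",
        "modularity_mean"]
print(manifest.summary[cols].round(3).to_string(index=False))
print()
print(f"objectives: {' + '.join(manifest.objectives)}")
print(f"patterns evaluated: {len(manifest.archive)}")
print(f"top-TE pattern ids: {manifest.top_ids[:3]} ...")
# Each row summarizes one generation's pool (survivors + offspring): the TE
# columns should drift upward and mean coupling cost downward across
# generations, while density stays near the initial sparsity of 0.2.

consensus = wv.consensus_connectivity(
    [manifest.history.patterns[i] for i in manifest.top_ids]
)
print(f"consensus connectivity of top patterns: range "
      f"[{consensus.min():.2f}, {consensus.max():.2f}] "
      f"(+1 = all excitatory, -1 = all inhibitory)")
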