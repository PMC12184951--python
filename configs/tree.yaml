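# Same protocol on the directed 17-node tree-with-return graph.
env: directed_graph
agents: [classical, symmetric]
n_reps: 40
episodes: 50
gen_episodes: 50
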