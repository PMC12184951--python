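# Two-phase navigation generalization on the open 11x11 room.
env: empty_room
agents: [classical, symmetric]
n_reps: 30
episodes: 400
gen_episodes: 100
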