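# Default side-chain physicochemical classes (P1-P6) used for the
# sequence-space maps. The six classes partition the 20 standard amino
# acids; edit and pass your own table to re-partition (every map output
# records the table it used).
P1: {name: small aliphatic,     members: [G, A, V, L, I, P]}
P2: {name: aromatic,            members: [F, Y, W]}
P3: {name: polar uncharged,     members: [S, T, N, Q, C, M]}
P4: {name: positively charged,  members: [K, R, H]}
P5: {name: negatively charged,  members: [D, E]}
P6: {name: special,             members: []}
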