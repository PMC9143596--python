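# Binary physicochemical property memberships of the 20 standard amino acids
# (Livingstone & Barton 1993 set, as used by common alignment viewers).
# Column conservation = number of properties whose membership status
# (all-have / all-lack) is uniform across the non-gap residues of a column;
# a column of identical residues scores 11.
hydrophobic: [A, C, F, G, H, I, K, L, M, T, V, W, Y]
polar:       [C, D, E, H, K, N, Q, R, S, T, W, Y]
small:       [A, C, D, G, N, P, S, T, V]
proline:     [P]
tiny:        [A, G, S]
aliphatic:   [I, L, V]
aromatic:    [F, H, W, Y]
positive:    [H, K, R]
negative:    [D, E]
charged:     [D, E, H, K, R]
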