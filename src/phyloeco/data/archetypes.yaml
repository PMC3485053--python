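# Default environment archetypes for the synthetic proteome generator.
#
# residue_weights are Dirichlet concentration parameters per canonical
# residue (total ~3000): a species' amino-acid composition is one draw
# from Dirichlet(intensity-adjusted weights), so expected composition =
# weights / sum(weights) and the total concentration sets the
# within-archetype species-to-species compositional spread.
#
# The three archetypes realize three pairwise habitat contrasts, each
# leaving the third archetype intermediate:
#   * acidity (D+E up, K+R down): halophile-like high, mesophile-like
#     low, hyperthermophile-like between — the halophile acidic-proteome
#     signature;
#   * hydrophobic/charged thermostability (I,V,L,Y and E,K up; N,Q,S,T
#     down): hyperthermophile-like high, halophile-like low;
#   * protein length and small-polar content: mesophile-like high,
#     hyperthermophile-like low (thermophilic proteome streamlining),
#     halophile-like between.
#
# intensity_law: per-species adaptation intensity u (normal, truncated);
# the species' expected composition is the archetype profile moved
# toward/away from the dataset baseline composition along the archetype's
# log-contrast by the factor u (u = 1 reproduces the profile exactly).
# This models species differing in how extreme their adaptation is.
#
# length_law: lognormal protein lengths (meanlog/sdlog in log-residues;
# expected mean lengths 240 / 290 / 340), truncated below at min_length.
# n_proteins_law: uniform integer range.
version: 2
baseline_weights: {A: 235.7, R: 161.5, N: 106.4, D: 203.9, C: 26.1, Q: 61.3,
                   E: 307.8, G: 218.8, H: 44.1, I: 231.5, L: 281.8, K: 179.4,
                   M: 68.0, F: 112.0, P: 126.1, S: 157.6, T: 126.5, W: 27.0,
                   Y: 107.0, V: 217.5}
archetypes:
  - name: hyperthermophile-like
    residue_weights: {A: 226.9, R: 170.1, N: 89.6, D: 149.3, C: 23.9, Q: 50.7,
                      E: 343.3, G: 179.1, H: 41.8, I: 265.7, L: 307.5, K: 211.9,
                      M: 59.7, F: 131.3, P: 104.5, S: 137.3, T: 98.5, W: 32.8,
                      Y: 125.4, V: 250.7}
    length_law: {family: lognormal, meanlog: 5.3773, sdlog: 0.45, min_length: 30}
    n_proteins_law: {min: 150, max: 220}
    intensity_law: {family: normal, mean: 1.0, sd: 0.04, min: 0.85, max: 1.15}
    phenotype: {temperature: hyperthermophile, salt: non-halophile,
                pH: acidophile, O2: aerobe, metabolism: non-methanogen,
                pressure: non-piezophile}
  - name: halophile-like
    residue_weights: {A: 241.7, R: 148.0, N: 108.8, D: 302.1, C: 24.2, Q: 63.4,
                      E: 362.5, G: 256.8, H: 39.3, I: 193.4, L: 250.8, K: 139.0,
                      M: 60.4, F: 90.6, P: 132.9, S: 160.1, T: 132.9, W: 21.1,
                      Y: 90.6, V: 181.3}
    length_law: {family: lognormal, meanlog: 5.5683, sdlog: 0.45, min_length: 30}
    n_proteins_law: {min: 150, max: 220}
    intensity_law: {family: normal, mean: 1.0, sd: 0.04, min: 0.85, max: 1.15}
    phenotype: {temperature: mesophile, salt: halophile, pH: neutrophile,
                O2: aerobe, metabolism: non-methanogen,
                pressure: non-piezophile}
  - name: mesophile-methanogen-like
    residue_weights: {A: 238.5, R: 166.2, N: 120.9, D: 160.2, C: 30.3, Q: 69.6,
                      E: 217.5, G: 220.5, H: 51.3, I: 235.5, L: 287.2, K: 187.2,
                      M: 84.0, F: 114.0, P: 141.0, S: 175.2, T: 147.9, W: 27.0,
                      Y: 105.0, V: 220.5}
    length_law: {family: lognormal, meanlog: 5.7279, sdlog: 0.45, min_length: 30}
    n_proteins_law: {min: 150, max: 220}
    intensity_law: {family: normal, mean: 1.0, sd: 0.04, min: 0.85, max: 1.15}
    phenotype: {temperature: mesophile, salt: non-halophile, pH: neutrophile,
                O2: anaerobe, metabolism: methanogen,
                pressure: non-piezophile}
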