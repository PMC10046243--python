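# African-American stratum generative profile (study summary statistics).
stratum: AA
n: 604
target_prevalence: 0.306
age_mean: 61.8
age_sd: 7.8
site_prob: 0.555          # P(Louisiana site)
ancestry_mean: 0.906      # African-ancestry proportion
ancestry_sd: 0.155
ld: null                  # all same-chromosome r2 < 0.2 in this stratum
variants:
  - {id: rs2274976, chromosome: "1", position: 11790870, gene: MTHFR, minor: A, major: G, maf: 0.03}
  - {id: rs1801131, chromosome: "1", position: 11794419, gene: MTHFR, minor: C, major: A, maf: 0.17}
  - {id: rs1801133, chromosome: "1", position: 11796321, gene: MTHFR, minor: A, major: G, maf: 0.13}
  - {id: rs1805087, chromosome: "1", position: 236885200, gene: MTR, minor: G, major: A, maf: 0.29}
  - {id: rs7587117, chromosome: "2", position: 74221528, gene: SLC4A5, minor: C, major: T, maf: 0.16}
  - {id: rs10380, chromosome: "5", position: 7897078, gene: MTRR, minor: T, major: C, maf: 0.34}
  - {id: rs4644, chromosome: "14", position: 55138217, gene: LGALS3, minor: A, major: C, maf: 0.26}
  # minor/major reversed relative to the EA stratum
  - {id: rs4652, chromosome: "14", position: 55138318, gene: LGALS3, minor: A, major: C, maf: 0.16}
  - {id: rs2236225, chromosome: "14", position: 64442127, gene: MTHFD1, minor: T, major: C, maf: 0.22}
  - {id: rs622506, chromosome: "15", position: 79846853, gene: MTHFS, minor: C, major: A, maf: 0.18}
  - {id: DHFR-19bp, chromosome: "19", position: null, gene: DHFR, minor: ins, major: del, maf: 0.45}
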