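# European-American stratum generative profile (study summary statistics).
stratum: EA
n: 690
target_prevalence: 0.214
age_mean: 64.0
age_sd: 7.7
site_prob: 0.538          # P(Louisiana site)
ancestry_mean: 0.967      # European-ancestry proportion
ancestry_sd: 0.073
ld:
  pair: [rs4644, rs4652]
  r2: 0.86
variants:
  - {id: rs2274976, chromosome: "1", position: 11790870, gene: MTHFR, minor: A, major: G, maf: 0.05}
  - {id: rs1801131, chromosome: "1", position: 11794419, gene: MTHFR, minor: C, major: A, maf: 0.33}
  - {id: rs1801133, chromosome: "1", position: 11796321, gene: MTHFR, minor: A, major: G, maf: 0.33}
  - {id: rs1805087, chromosome: "1", position: 236885200, gene: MTR, minor: G, major: A, maf: 0.20}
  - {id: rs7587117, chromosome: "2", position: 74221528, gene: SLC4A5, minor: C, major: T, maf: 0.32}
  - {id: rs10380, chromosome: "5", position: 7897078, gene: MTRR, minor: T, major: C, maf: 0.10}
  - {id: rs4644, chromosome: "14", position: 55138217, gene: LGALS3, minor: A, major: C, maf: 0.39}
  - {id: rs4652, chromosome: "14", position: 55138318, gene: LGALS3, minor: C, major: A, maf: 0.42}
  - {id: rs2236225, chromosome: "14", position: 64442127, gene: MTHFD1, minor: T, major: C, maf: 0.43}
  - {id: rs622506, chromosome: "15", position: 79846853, gene: MTHFS, minor: C, major: A, maf: 0.35}
  # chromosome recorded as printed in the source summary table, which
  # conflicts with the gene's cytogenetic band (5q14.1); kept as given.
  - {id: DHFR-19bp, chromosome: "19", position: null, gene: DHFR, minor: del, major: ins, maf: 0.43}
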