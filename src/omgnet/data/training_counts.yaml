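# Training-cohort sufficient statistics: 89 adults with ptosis and/or
# diplopia suspicious of ocular myasthenia gravis (39 OMG-positive,
# 50 OMG-negative) from a prospective diagnostic-accuracy study.
#
# Each row gives the observed state counts of one conditional-probability
# table, per parent configuration.  `missing` gives the number of cases in
# each disease stratum in which the test was not performed (NA); variables
# without a `missing` block were observed in every case.
#
# provenance: "printed" rows are published cross-tabulations; "derived" rows
# (the AChR-by-age split within disease strata) are reconstructed by integer
# inversion of the published posterior summaries against the published
# margins (48/2 seronegative-stratum and 6/33 seropositive-stratum totals,
# and the age-specific sensitivities 6/10 under age 50, 27/29 over 50) —
# the unique integer solution, but not itself a printed table.
variables:
  age:
    rows:
      - parents: {}
        counts: {"18-50": 25, "50-70": 30, "70+": 34}
        provenance: printed
  sex:
    rows:
      - parents: {}
        counts: {male: 41, female: 48}
        provenance: printed
  omg:
    rows:
      - parents: {sex: male}
        counts: {negative: 18, positive: 23}
        provenance: printed
      - parents: {sex: female}
        counts: {negative: 32, positive: 16}
        provenance: printed
  achr:
    rows:
      - parents: {omg: negative, age: "18-50"}
        counts: {negative: 15, positive: 0}
        provenance: derived
      - parents: {omg: negative, age: "50-70"}
        counts: {negative: 17, positive: 0}
        provenance: derived
      - parents: {omg: negative, age: "70+"}
        counts: {negative: 16, positive: 2}
        provenance: derived
      - parents: {omg: positive, age: "18-50"}
        counts: {negative: 4, positive: 6}
        provenance: derived
      - parents: {omg: positive, age: "50-70"}
        counts: {negative: 1, positive: 12}
        provenance: derived
      - parents: {omg: positive, age: "70+"}
        counts: {negative: 1, positive: 15}
        provenance: derived
  diplopia:
    rows:
      - parents: {omg: negative}
        counts: {negative: 14, positive: 36}
        provenance: printed
      - parents: {omg: positive}
        counts: {negative: 15, positive: 24}
        provenance: printed
  ptosis:
    rows:
      - parents: {omg: negative}
        counts: {negative: 19, positive: 31}
        provenance: printed
      - parents: {omg: positive}
        counts: {negative: 10, positive: 29}
        provenance: printed
  upgaze:
    rows:
      - parents: {omg: negative}
        counts: {negative: 32, positive: 14}
        provenance: printed
      - parents: {omg: positive}
        counts: {negative: 13, positive: 25}
        provenance: printed
    missing: {negative: 4, positive: 1}
  ice:
    rows:
      - parents: {omg: negative}
        counts: {negative: 21, positive: 9}
        provenance: printed
      - parents: {omg: positive}
        counts: {negative: 8, positive: 13}
        provenance: printed
    missing: {negative: 20, positive: 18}
  besinger:
    rows:
      - parents: {omg: negative}
        counts: {"-1-1": 5, "1-4": 25, "4-8": 18, "8-24": 2}
        provenance: printed
      - parents: {omg: positive}
        counts: {"-1-1": 5, "1-4": 14, "4-8": 16, "8-24": 4}
        provenance: printed
  edrophonium:
    rows:
      - parents: {omg: negative}
        counts: {negative: 36, positive: 4}
        provenance: printed
      - parents: {omg: positive}
        counts: {negative: 2, positive: 29}
        provenance: printed
    missing: {negative: 10, positive: 8}
  rns:
    rows:
      - parents: {omg: negative}
        counts: {negative: 42, positive: 8}
        provenance: printed
      - parents: {omg: positive}
        counts: {negative: 14, positive: 23}
        provenance: printed
    missing: {negative: 0, positive: 2}
  sfemg:
    rows:
      - parents: {omg: negative}
        counts: {negative: 28, positive: 22}
        provenance: printed
      - parents: {omg: positive}
        counts: {negative: 9, positive: 27}
        provenance: printed
    missing: {negative: 0, positive: 3}
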