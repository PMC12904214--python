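# Default suspected-OMG network.
#
# Variable declaration order doubles as the CSV column order. The edge set
# is the minimal conditioning structure of the model: age and sex are roots,
# disease status (omg) depends on sex, the AChR-antibody serology depends on
# disease status and age (seropositivity rises with age), and every other
# clinical sign or test depends on disease status alone.
variables:
  - name: age
    states: ["18-50", "50-70", "70+"]
    parents: []
  - name: sex
    states: [male, female]
    parents: []
  - name: diplopia
    states: [negative, positive]
    parents: [omg]
  - name: ptosis
    states: [negative, positive]
    parents: [omg]
  - name: achr
    states: [negative, positive]
    parents: [omg, age]
  - name: upgaze
    states: [negative, positive]
    parents: [omg]
  - name: ice
    states: [negative, positive]
    parents: [omg]
  - name: besinger
    states: ["-1-1", "1-4", "4-8", "8-24"]
    parents: [omg]
  - name: edrophonium
    states: [negative, positive]
    parents: [omg]
  - name: rns
    states: [negative, positive]
    parents: [omg]
  - name: sfemg
    states: [negative, positive]
    parents: [omg]
  - name: omg
    states: [negative, positive]
    parents: [sex]
outcome: omg
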