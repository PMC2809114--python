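# Approximate secondary-structure topology of bovine rhodopsin (348 aa):
# seven transmembrane helices, intradiscal (extracellular) N-terminus and
# loops, cytoplasmic loops and C-terminus.  Boundaries are round-number
# approximations to the classic topology model and are meant to be edited
# for other reference structures.
source: approximate bovine rhodopsin topology (editable)
intervals:
  - {start: 1,   end: 36,  label: intradiscal}
  - {start: 37,  end: 61,  label: transmembrane}   # TM1
  - {start: 62,  end: 72,  label: cytoplasmic}
  - {start: 73,  end: 97,  label: transmembrane}   # TM2
  - {start: 98,  end: 110, label: intradiscal}
  - {start: 111, end: 133, label: transmembrane}   # TM3
  - {start: 134, end: 152, label: cytoplasmic}
  - {start: 153, end: 173, label: transmembrane}   # TM4
  - {start: 174, end: 199, label: intradiscal}
  - {start: 200, end: 225, label: transmembrane}   # TM5
  - {start: 226, end: 252, label: cytoplasmic}
  - {start: 253, end: 276, label: transmembrane}   # TM6
  - {start: 277, end: 285, label: intradiscal}
  - {start: 286, end: 309, label: transmembrane}   # TM7
  - {start: 310, end: 348, label: cytoplasmic}
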