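# Example three-domain annotation for E. coli adenylate kinase (author
# numbering of 4AKE chain A / 4JZK chain B). Domain boundaries are not part
# of the method; these are commonly used literature values -- adjust to taste.
domains:
  NMP: [[30, 59]]
  LID: [[122, 159]]
  CORE: [[1, 29], [60, 121], [160, 214]]
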