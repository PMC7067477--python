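# BRAF kinase-domain activation segment, author numbering of the active
# conformation (4MNE chain B): DFG motif (594-596) through APE motif (621-623).
domains:
  activation_segment: [[594, 623]]
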