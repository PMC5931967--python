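# Direct ATP-equivalent cost of amino-acid biosynthesis from central-carbon
# precursors, counting only ATP/GTP-hydrolysing steps of the canonical
# bacterial pathways (PPi-releasing steps charged 2). Reducing equivalents
# and precursor opportunity costs are excluded, which is why several amino
# acids derived directly from TCA/glycolytic intermediates carry zero direct
# ATP cost. User-replaceable data, not a literature table.
#
# polymerisation_cost_per_residue: tRNA aminoacylation ATP -> AMP (2)
#   + EF-Tu GTP (1) + EF-G translocation GTP (1) = 4 per residue. Charged
#   per residue (length n), not per peptide bond (n - 1), because
#   aminoacylation applies to every residue.
provenance: >
  phagelight direct-ATP accounting of amino-acid biosynthesis
  (ATP/GTP-consuming steps only; NADPH and precursor costs excluded).
amino_acid_costs:
  A: 0.0
  R: 7.0
  N: 3.0
  D: 0.0
  C: 4.0
  E: 0.0
  Q: 1.0
  G: 0.0
  H: 5.0
  I: 2.0
  L: 0.0
  K: 2.0
  M: 7.0
  F: 1.0
  P: 1.0
  S: 0.0
  T: 2.0
  W: 5.0
  Y: 1.0
  V: 0.0
polymerisation_cost_per_residue: 4.0
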