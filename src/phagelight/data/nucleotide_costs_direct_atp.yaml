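# Direct ATP-equivalent cost of de novo deoxyribonucleoside-triphosphate
# biosynthesis from central-carbon precursors in a cyanobacterium, counting
# only ATP/GTP-hydrolysing steps. A step that releases PPi (ATP -> AMP) is
# charged 2 ATP equivalents. Reducing equivalents (NADPH for ribonucleotide
# reductase, thymidylate synthase's folate cycle) are NOT converted to ATP;
# pass atp_per_nadph to dna_replication_cost to add them.
#
# Accounting (per molecule):
#   shared purine route to IMP: PRPP synthetase (ATP->AMP, 2) + GAR, FGAM,
#     AIR, N5-CAIR, SAICAR synthetases (1 each) = 7
#   dATP: IMP->AMP (adenylosuccinate synthetase, GTP, 1) + AMP->ADP (1)
#         + dADP->dATP (1)                                   -> 7+3 = 10
#   dGTP: IMP->XMP (NAD) + GMP synthetase (ATP->AMP, 2) + GMP->GDP (1)
#         + dGDP->dGTP (1)                                   -> 7+4 = 11
#   shared pyrimidine route to UMP: carbamoyl-phosphate synthetase (2 ATP)
#     + PRPP for orotate phosphoribosyltransferase (2) = 4
#   dCTP: UMP->UDP (1) + UDP->UTP (1) + CTP synthetase (1) + dCDP->dCTP (1)
#                                                            -> 4+4 = 8
#   dTTP: UMP->UDP (1) + dUDP->dUTP (1) + dUTPase loses 2 ~P (2)
#         + dTMP->dTDP (1) + dTDP->dTTP (1)                  -> 4+6 = 10
provenance: >
  phagelight direct-ATP accounting of de novo dNTP biosynthesis
  (ATP/GTP-consuming steps only; PPi release charged as 2; NADPH excluded).
  User-replaceable; see file header for the per-step breakdown.
nucleotide_costs:
  dATP: 10.0
  dGTP: 11.0
  dCTP: 8.0
  dTTP: 10.0
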