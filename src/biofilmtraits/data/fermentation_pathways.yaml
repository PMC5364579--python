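# Editable gene-set configuration for the fermentation and hydrogenase traits.
#
# The fermentation trait is satisfied when a genome carries ALL genes of one
# of the acetate pathways, or at least TWO of the three genes of one of the
# ethanol pathways.  The lists enumerate the canonical pyruvate-to-acetate
# and pyruvate-to-ethanol routes; each entry names the reference pathway
# identifier (MetaCyc / KEGG module) the gene list was drawn from.  Edit or
# extend freely — the rule structure (ALL per acetate pathway, 2-of-3 per
# ethanol pathway) is fixed in code, the gene content is not.

fermentation:
  acetate_pathways:
    - name: pta_ackA
      source: "MetaCyc PWY0-1312 (acetate formation from acetyl-CoA I)"
      genes: [pta, ackA]
    - name: pyruvate_oxidase
      source: "MetaCyc PWY-5451 / EC 1.2.5.1 (pyruvate oxidase route)"
      genes: [poxB]
    - name: adp_acetyl_coa_synthetase
      source: "MetaCyc PWY-5482 (ADP-forming acetyl-CoA synthetase)"
      genes: [acdA, acdB]
    - name: pfl_pta_ackA
      source: "KEGG M00579 via pyruvate formate-lyase"
      genes: [pflB, pta, ackA]
    - name: pfor_pta_ackA
      source: "KEGG M00579 via pyruvate:ferredoxin oxidoreductase"
      genes: [porA, porB, pta, ackA]
    - name: acetaldehyde_dehydrogenase
      source: "MetaCyc PWY-6333 (acetaldehyde oxidation to acetate)"
      genes: [aldB]
    - name: amp_acetyl_coa_synthetase
      source: "EC 6.2.1.1 reversal (AMP-forming acetyl-CoA synthetase)"
      genes: [acs]
    - name: eutD_ackA
      source: "MetaCyc PWY0-1312 variant (EutD phosphotransacetylase)"
      genes: [eutD, ackA]
  ethanol_pathways:
    - name: pdc_adh
      source: "MetaCyc PWY-5480 (pyruvate decarboxylase + alcohol dehydrogenase)"
      genes: [pdc, adhA, adhB]
    - name: adhE_bifunctional
      source: "KEGG M00579 branch via bifunctional AdhE"
      genes: [pflB, adhE, mhpF]
    - name: pfor_ald_adh
      source: "MetaCyc PWY-6587 (PFOR + aldehyde/alcohol dehydrogenases)"
      genes: [porA, ald, adhP]

# Symbols accepted as evidence of anaerobic hydrogen oxidation in addition to
# EC 1.12.1.3 ([NiFe]/[FeFe] uptake hydrogenase subunits and the energy-
# converting Ech hydrogenase).
hydrogenase_symbols: [hydA, hydB, hyaA, hyaB, echE]
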