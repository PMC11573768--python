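# Default identifier sets.
#
# usicg_ids: 11 ribosomal/translation-machinery COGs used as a stand-in
# universal single-copy gene panel; override with the panel of your
# pipeline when known.
usicg_ids:
  - COG0048   # ribosomal protein S12
  - COG0049   # ribosomal protein S7
  - COG0052   # ribosomal protein S2
  - COG0080   # ribosomal protein L11
  - COG0081   # ribosomal protein L1
  - COG0087   # ribosomal protein L3
  - COG0088   # ribosomal protein L4
  - COG0090   # ribosomal protein L2
  - COG0091   # ribosomal protein L22
  - COG0092   # ribosomal protein S3
  - COG0093   # ribosomal protein L14

# Carbohydrate-related identifiers backing the consensus cazyme filter.
# A stand-in subset; the full CAZy-derived equivalence map is supplied
# by the user as a config of this same shape.
carb_related:
  pfam:
    - PF00128   # alpha-amylase, catalytic domain
    - PF00232   # glycosyl hydrolase family 1
    - PF00331   # glycosyl hydrolase family 10
    - PF00457   # glycosyl hydrolase family 11
    - PF00535   # glycosyl transferase family 2
    - PF00704   # glycosyl hydrolase family 18
    - PF00722   # glycosyl hydrolase family 16
    - PF00728   # glycosyl hydrolase family 20
    - PF00759   # glycosyl hydrolase family 9
    - PF01670   # glycosyl hydrolase family 12
    - PF01915   # glycosyl hydrolase family 3 C-terminal
    - PF02156   # glycosyl hydrolase family 26
    - PF02838   # glycosyl hydrolase family 39
  kegg:
    - K01176    # alpha-amylase
    - K01179    # endoglucanase
    - K01183    # chitinase
    - K01187    # alpha-glucosidase
    - K01190    # beta-galactosidase
    - K01206    # alpha-L-fucosidase
    - K05349    # beta-glucosidase
  cog:
    - COG0366   # glycosidase
    - COG1472   # beta-glucosidase-related glycosidase
    - COG1501   # alpha-glucosidase
    - COG2723   # beta-glucosidase/6-phospho-beta-glucosidase
    - COG3250   # beta-galactosidase/beta-glucuronidase

# SusC (TonB-dependent transporter) and SusD (glycan-binding) domains.
susc_domains:
  - PF00593   # TonB-dependent receptor
  - PF07715   # TonB-dependent receptor plug domain
  - PF13715   # Carboxy-pepD domain
  - TIGR04056 # SusC/RagA family
susd_domains:
  - PF07980   # SusD family
  - PF12741   # SusD and RagB
  - PF12771   # Starch-binding SusD-like
  - PF14322   # Starch-binding SusD-like N-terminal

sulfatase_ids:
  - PF00884   # sulfatase
  - K01130    # arylsulfatase
peptidase_ids:
  - PF00082   # subtilase family peptidase
  - PF01435   # peptidase family M48
regulator_ids:
  - PF00165   # AraC-type HTH regulator
  - PF04773   # HTH-containing anti-sigma factor
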