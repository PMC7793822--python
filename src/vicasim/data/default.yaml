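# Default parameterization for the vicagrel / clopidogrel minimal PBPK/PD model.
#
# Provenance key (per value):
#   [printed]    — printed in the source publications for these compounds
#   [anchor]     — chosen so that a printed constraint holds exactly
#   [literature] — standard literature/physiology value
#   [default]    — package default, documented in docs/methods.md
#
# Units are fixed by the schema: clearances in uL/min/mg protein (intrinsic) or
# L/h (organ-level), volumes in L, flows in L/h, doses in mg, times in h.

compounds:
  clopidogrel:
    molecular_weight: 321.8        # g/mol [literature]
    ka: 1.5                        # 1/h   [default]
    fa: 0.5                        # [literature] incomplete absorption
    fu_plasma: 0.02                # [literature] highly bound
    blood_plasma_ratio: 1.0        # [default]
    v_sys: 150.0                   # L [default]
    renal_cl: 0.0                  # L/h; esterase/CYP elimination only [printed]
    pathways:
      # CES1 hydrolysis to the inactive carboxylic acid dominates (85% of
      # clopidogrel-related material in plasma). 300 uL/min/mg is the wild-type
      # value whose 80% scaling gives the printed 240 uL/min/mg for 428 G/A.
      - {enzyme: CES1,    site: liver, clint: 300.0,              product: "",                 cv: 0.4}  # [anchor]
      # Hepatic CYPs form 2-oxo-clopidogrel; the pathway sum is fixed so that
      # CYP/(CYP+CES1) = 0.15, the oxidative fraction of clopidogrel.
      - {enzyme: CYP2C19, site: liver, clint: 31.764705882352942, product: "2-oxo-clopidogrel", cv: 0.4}  # [anchor] 60% of CYP sum
      - {enzyme: CYP1A2,  site: liver, clint: 10.588235294117647, product: "2-oxo-clopidogrel", cv: 0.4}  # [anchor] 20%
      - {enzyme: CYP2B6,  site: liver, clint: 10.588235294117647, product: "2-oxo-clopidogrel", cv: 0.4}  # [anchor] 20%

  vicagrel:
    molecular_weight: 363.9        # g/mol [literature]
    ka: 2.0                        # 1/h [default] rapid absorption
    fa: 0.9                        # [default]
    fu_plasma: 0.02                # [default] analogous to clopidogrel
    blood_plasma_ratio: 1.0        # [default]
    v_sys: 150.0                   # L [default]
    # The acetate ester is rapidly hydrolyzed by circulating/hepatic esterases;
    # the tiny systemically available fraction is cleared first-order. [default]
    renal_cl: 100.0                # L/h
    pathways:
      # Intestinal hydrolysis to 2-oxo-clopidogrel. 46,100 uL/min/mg is the
      # wild-type CES2 value whose 20-fold reduction gives the printed 2,305;
      # AADAC is set so its share of gut hydrolysis is 53%.
      - {enzyme: CES2,  site: gut, clint: 46100.0,            product: "2-oxo-clopidogrel", cv: 0.4}  # [anchor]
      - {enzyme: AADAC, site: gut, clint: 51985.106382978724, product: "2-oxo-clopidogrel", cv: 0.4}  # [anchor] 53/47 x CES2

  2-oxo-clopidogrel:
    molecular_weight: 337.8        # g/mol [literature]
    ka: null                       # metabolite: no oral absorption
    fa: 1.0
    fu_plasma: 0.1                 # [default]
    blood_plasma_ratio: 1.0
    v_sys: 80.0                    # L [default]
    renal_cl: 0.0
    pathways:
      # CES1 hydrolysis (inactivating): 20 uL/min/mg wild type -> 16 at 80%.
      - {enzyme: CES1,    site: liver, clint: 20.0, product: "",      cv: 0.4}  # [anchor]
      # CYP oxidation to AM-H4; pathway sum 16 uL/min/mg so the static
      # formation-fraction arithmetic (16+16)/(16+20) ~ 0.89 matches the
      # reported CES1 G/G / G/A AM-H4 exposure ratio.
      - {enzyme: CYP3A4,  site: liver, clint: 6.0,  product: "am-h4", cv: 0.4}  # [anchor]
      - {enzyme: CYP2C19, site: liver, clint: 4.0,  product: "am-h4", cv: 0.4}  # [anchor]
      - {enzyme: CYP2B6,  site: liver, clint: 3.0,  product: "am-h4", cv: 0.4}  # [anchor]
      - {enzyme: CYP2C9,  site: liver, clint: 3.0,  product: "am-h4", cv: 0.4}  # [anchor]

  am-h4:
    molecular_weight: 355.9        # g/mol [literature]
    ka: null
    fa: 1.0
    fu_plasma: 0.1                 # [default]
    blood_plasma_ratio: 1.0
    v_sys: 150.0                   # L [default]
    # The active thiol is chemically labile in plasma; its elimination is
    # dominated by a systemic first-order degradation clearance rather than
    # organ blood flow. [default]
    renal_cl: 300.0                # L/h
    pathways:
      - {enzyme: CES1, site: liver, clint: 5.0, product: "", cv: 0.4}  # [default] minor hydrolytic route

physiology:
  chinese:
    q_hepatic_total: 90.0          # L/h [literature]
    q_portal: 67.5                 # L/h [literature]
    q_hepatic_arterial: 22.5       # L/h [literature]
    q_gut: 14.0                    # L/h villous ("Qgut"-style) flow [literature]
    liver_weight: 1500.0           # g [literature]
    mppgl: 40.0                    # mg microsomal-equivalent protein / g liver [literature]
    gut_protein: 3000.0            # mg intestinal enzyme-bearing protein [default]
    v_portal: 1.0                  # L [default]
    v_liver: 1.6                   # L [default]
  caucasian:
    q_hepatic_total: 90.0
    q_portal: 67.5
    q_hepatic_arterial: 22.5
    q_gut: 14.0
    liver_weight: 1650.0           # g [literature]
    mppgl: 40.0
    gut_protein: 3000.0
    v_portal: 1.0
    v_liver: 1.8

pd:
  kin: 0.0124        # pool-units/h; equals kout so baseline pool = 1 [anchor]
  kout: 0.0124       # 1/h; ln(8)/kout ~ 168 h gives the ~7-day recovery [anchor]
  kirre: 55.0        # 1/(uM.h); calibrated so maintenance-dose mean IPA ~ 80% [anchor]
  mpa0: 60.0         # % baseline maximal platelet aggregation (20 uM ADP) [literature]
  cv_kin: 0.2
  cv_kout: 0.2
  cv_kirre: 0.2
  cv_mpa0: 0.2

populations:
  chinese:
    ethnicity: chinese
    phenotype_frequencies: {EM: 0.42, IM: 0.45, PM: 0.13}   # CYP2C19, East-Asian [literature]
    genotype_settings: {}
    n_subjects: 100
    n_trials: 10
    seed: 20201208
  caucasian:
    ethnicity: caucasian
    phenotype_frequencies: {EM: 0.73, IM: 0.25, PM: 0.02}   # [literature]
    genotype_settings: {}
    n_subjects: 100
    n_trials: 10
    seed: 20201208

# Per-compound inter-individual CVs for non-pathway parameters. [default]
iiv:
  cv_ka: 0.3
  cv_v_sys: 0.3

perpetrators:
  omeprazole:
    molecular_weight: 345.42       # g/mol [literature]
    dose: 80.0                     # mg [printed regimen]
    ka: 2.0                        # 1/h [default]
    fa: 0.6                        # oral bioavailability into the 1-cpt model [literature]
    v: 20.0                        # L [literature]
    cl: 30.0                       # L/h [literature]
    fu_plasma: 0.05                # [literature]
    inhibition:
      mbi:
        CYP2C19: {k_i_app: 1.7, k_inact: 2.5, k_deg: 0.02}  # uM, 1/h, 1/h [literature]
  simvastatin:
    molecular_weight: 418.57       # g/mol [literature]
    dose: 80.0                     # mg [printed regimen]
    ka: 1.5                        # 1/h [default]
    fa: 0.05                       # net oral bioavailability (heavy first pass) [literature]
    v: 60.0                        # L [default]
    cl: 30.0                       # L/h [default]
    fu_plasma: 0.06                # [literature]
    inhibition:
      ki:
        CES1: 0.11                 # uM [printed]
        CES2: 0.67                 # uM [printed]
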