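# Antiretroviral (ARV) regimen dependency chain.
#
# If a patient is recorded as on ARV medication but reports no change in
# regimen, every downstream stop/change reason is logically "no" even
# when the field was left blank.  The first rule fills the gating
# "change in regimen" field; the remaining rules chain off it (a "no"
# filled by the first rule satisfies their second antecedent).
rules:
  - target: arv_regimen_change
    fill: "no"
    when:
      - {var: on_arv, is: "yes"}
  - target: arv_stop_completed_pmtct
    fill: "no"
    when:
      - {var: on_arv, is: "yes"}
      - {var: arv_regimen_change, is: no_or_filled}
  - target: arv_stop_regimen_failure
    fill: "no"
    when:
      - {var: on_arv, is: "yes"}
      - {var: arv_regimen_change, is: no_or_filled}
  - target: arv_stop_toxicity
    fill: "no"
    when:
      - {var: on_arv, is: "yes"}
      - {var: arv_regimen_change, is: no_or_filled}
  - target: arv_stop_weight_change
    fill: "no"
    when:
      - {var: on_arv, is: "yes"}
      - {var: arv_regimen_change, is: no_or_filled}
  - target: arv_stop_other
    fill: "no"
    when:
      - {var: on_arv, is: "yes"}
      - {var: arv_regimen_change, is: no_or_filled}
  - target: arv_stop_new_tb
    fill: "no"
    when:
      - {var: on_arv, is: "yes"}
      - {var: arv_regimen_change, is: no_or_filled}
  - target: arv_stop_nonadherence
    fill: "no"
    when:
      - {var: on_arv, is: "yes"}
      - {var: arv_regimen_change, is: no_or_filled}
  - target: arv_stop_out_of_stock
    fill: "no"
    when:
      - {var: on_arv, is: "yes"}
      - {var: arv_regimen_change, is: no_or_filled}
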