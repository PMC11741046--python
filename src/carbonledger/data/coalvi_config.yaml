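# System metadata for the packaged beef-farm consortium validation case.
# Flux amounts in the companion CSV are in thousands of tonnes of carbon
# per year, exactly as printed in the source table; the functional-unit
# quantities are therefore kept on the same 10^3 scale.
system_name: Coalvi beef-farm consortium
period: 1 year
canonical_unit: 10^3 t C
functional_units:
  - name: utilised agricultural area
    quantity: 70.632     # 10^3 ha, implied by the net-plant-exchange row ratio 357.4/5.06
    units: 10^3 ha
  - name: LW slaughtered
    quantity: 37.229     # 10^3 t live weight, implied by 357.4/9.60
    units: 10^3 t LW
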