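# GDD phenology calibration for the autochthonous Montenegrin variety Vranac.
# Thresholds are cumulative growing degree days (base 10 degC) from Jan 1.
variety: Vranac
base_temp: 10.0
stages:
  - {bbch: 7, gdd: 139.0}    # bud burst beginning
  - {bbch: 65, gdd: 492.0}   # full flowering (50% of flowers open)
  - {bbch: 81, gdd: 1203.0}  # beginning of ripening (veraison)
  - {bbch: 89, gdd: 2188.0}  # berries ripe for harvest
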