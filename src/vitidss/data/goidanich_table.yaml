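# Daily downy-mildew (Plasmopara viticola) development increments, %/day,
# by daily mean temperature and daily mean relative humidity.
#
# Curated transcription of the classical Goidanich incubation-rate
# convention (Goidanich, G., 1964. Manuale di patologia vegetale):
# at high humidity the daily increment is 100 / incubation-days for the
# temperature class; at moderate humidity (60-75%) development proceeds at
# roughly half rate; below 60% RH it is treated as halted. Values are an
# editable operational default, not a verbatim reproduction of the
# original table.
#
# Bins are left-closed, right-open: temp bin i covers
# [temp_edges[i], temp_edges[i+1]), likewise for RH.
temp_edges: [10, 12, 14, 16, 18, 20, 22, 24, 26, 28, 30]
rh_edges: [60, 75, 101]
increments:
  # [RH 60-75, RH 75-101]
  - [2.8, 5.6]    # 10-12 degC  (~18 d incubation)
  - [3.6, 7.1]    # 12-14 degC  (~14 d)
  - [4.5, 9.1]    # 14-16 degC  (~11 d)
  - [5.6, 11.1]   # 16-18 degC  (~9 d)
  - [7.1, 14.3]   # 18-20 degC  (~7 d)
  - [8.3, 16.7]   # 20-22 degC  (~6 d)
  - [10.0, 20.0]  # 22-24 degC  (~5 d)
  - [11.1, 22.2]  # 24-26 degC  (~4.5 d)
  - [10.0, 20.0]  # 26-28 degC  (~5 d)
  - [8.3, 16.7]   # 28-30 degC  (~6 d)
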