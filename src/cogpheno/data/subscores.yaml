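# Sub-score registry: names, scoring direction, domain membership and
# derived-score definitions for the extended BRB-N battery.
# Directions are fixed here by test construct, never inferred from data,
# so that an oriented Z < -1.5 uniformly means impairment.
version: 1
domains: [ips, memory, efwm, attention]
subscores:
  sdmt:                {domain: ips,       direction: higher_is_better}
  srt_lts:             {domain: memory,    direction: higher_is_better}
  srt_ltr:             {domain: memory,    direction: higher_is_better}
  srt_cltr:            {domain: memory,    direction: higher_is_better}
  srt_delayed:         {domain: memory,    direction: higher_is_better}
  spart_direct:        {domain: memory,    direction: higher_is_better}
  spart_delayed:       {domain: memory,    direction: higher_is_better}
  stroop_interference: {domain: efwm,      direction: lower_is_better,  efwm_facet: inhibition}
  cst_shifting:        {domain: efwm,      direction: lower_is_better,  efwm_facet: flexibility}
  wlg_total:           {domain: efwm,      direction: higher_is_better, efwm_facet: fluency}
  mct_slope:           {domain: efwm,      direction: lower_is_better,  efwm_facet: working_memory}
  stroop_card1:        {domain: attention, direction: lower_is_better}
  stroop_card2:        {domain: attention, direction: lower_is_better}
  cst_numbers:         {domain: attention, direction: lower_is_better}
  cst_letters:         {domain: attention, direction: lower_is_better}
  # informational composite, not part of any domain average
  srt_average:         {domain: null,      direction: higher_is_better}
# raw trial-level inputs that exist only to build derived scores
raw_inputs: [stroop_card3, wlg_animals, wlg_professions, wlg_m_words,
             mct_1letter, mct_4letter]
derived:
  stroop_interference: {op: interference, args: [stroop_card3, stroop_card1, stroop_card2]}
  mct_slope:           {op: difference,   args: [mct_4letter, mct_1letter]}
  wlg_total:           {op: sum,          args: [wlg_animals, wlg_professions, wlg_m_words]}
  srt_average:         {op: mean,         args: [srt_lts, srt_ltr, srt_cltr, srt_delayed]}
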