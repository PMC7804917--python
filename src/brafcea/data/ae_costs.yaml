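# Grade 3/4 adverse-event management costs, applied once at the start of each
# treatment line as an expected cost: sum over events of incidence x cost.
#
# PLACEHOLDER schedule (synthetic): incidences are loose readings of the
# source trials' toxicity tables and management costs are round figures from
# published colorectal-cancer cost-effectiveness analyses.  The exact
# event-level schedule used upstream is not reproduced here; edit this file
# to substitute your own.  The base-case contribution is small relative to
# drug costs (on the order of $1,000-$3,000 per line).

doublet:
  - {event: anemia, incidence: 0.034, cost: 12453.00}
  - {event: diarrhea, incidence: 0.029, cost: 9398.00}
  - {event: fatigue, incidence: 0.041, cost: 7302.00}
standard:
  - {event: neutropenia, incidence: 0.093, cost: 14282.00}
  - {event: diarrhea, incidence: 0.101, cost: 9398.00}
  - {event: anemia, incidence: 0.054, cost: 12453.00}
nivo_ipi:
  - {event: hepatotoxicity, incidence: 0.110, cost: 14280.00}
  - {event: diarrhea, incidence: 0.022, cost: 9398.00}
regorafenib:
  - {event: hand_foot_skin_reaction, incidence: 0.166, cost: 1596.00}
  - {event: hypertension, incidence: 0.073, cost: 4530.00}
  - {event: fatigue, incidence: 0.094, cost: 7302.00}
bsc: []
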