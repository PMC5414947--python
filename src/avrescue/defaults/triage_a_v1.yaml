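# Resuscitation success ceiling `a` as a function of the initial burial
# time of the extricated pulseless patient, version 1.
#
# `a` is the asymptotic fraction of patients in whom CPR can achieve
# return of spontaneous circulation; it decays with burial time because
# longer hypoxia makes the arrest less recoverable.  Beyond 35 min of
# burial the ceiling is zero.
name: triage-ceiling
version: v1
units: {burial_time: min, a: probability}
entries:
  - [12, 0.62]
  - [20, 0.25]
  - [35, 0.0]
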