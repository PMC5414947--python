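# Canonical digitization of the Swiss avalanche survival curve, version 1.
#
# Survival probability of a completely buried subject as a function of
# burial time in minutes.  This is an APPROXIMATE piecewise-linear
# digitization of the published Swiss curve shape (high plateau in the
# first ~10 min while air reserves last, steep asphyxia-driven decline to
# ~35 min, then a long shallow tail); the underlying figure is published
# graphically only, so users with their own digitization can substitute it
# via this file's format.
name: swiss-survival-curve
version: v1
units: {time: min, survival: probability}
knots:
  - [0, 0.92]
  - [10, 0.92]
  - [15, 0.88]
  - [20, 0.76]
  - [25, 0.60]
  - [30, 0.45]
  - [35, 0.33]
  - [45, 0.27]
  - [60, 0.24]
  - [90, 0.19]
  - [130, 0.07]
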