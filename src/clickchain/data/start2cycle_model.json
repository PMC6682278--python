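{
 "pages": [
  "Trophies",
  "Bug report",
  "Coach",
  "Competition",
  "Personal",
  "Route",
  "Routes",
  "Team",
  "Track"
 ],
 "exit_label": "Exit",
 "P": [
  [
   0,
   0,
   0.24,
   0.11,
   0.04,
   0,
   0.08,
   0.12,
   0.08,
   0.32
  ],
  [
   0,
   0,
   0.12,
   0.09,
   0.29,
   0,
   0.05,
   0.12,
   0.22,
   0.1
  ],
  [
   0.03,
   0,
   0,
   0.23,
   0.09,
   0.0,
   0.04,
   0.2,
   0.2,
   0.22
  ],
  [
   0.05,
   0,
   0.31,
   0,
   0.05,
   0.01,
   0.09,
   0.24,
   0.05,
   0.21
  ],
  [
   0,
   0.21,
   0.28,
   0.04,
   0,
   0.0,
   0.08,
   0.13,
   0.09,
   0.17
  ],
  [
   0,
   0,
   0.13,
   0,
   0.04,
   0,
   0.52,
   0.01,
   0.19,
   0.11
  ],
  [
   0.06,
   0,
   0.07,
   0.03,
   0.03,
   0.66,
   0,
   0.05,
   0.04,
   0.07
  ],
  [
   0.04,
   0,
   0.11,
   0.38,
   0.08,
   0.0,
   0.11,
   0,
   0.06,
   0.22
  ],
  [
   0.01,
   0,
   0.13,
   0.03,
   0.05,
   0.3,
   0.07,
   0.12,
   0,
   0.29
  ],
  [
   0,
   0,
   0,
   0,
   0,
   0,
   0,
   0,
   0,
   0
  ]
 ],
 "pi": [
  0.0,
  0.0,
  0.769,
  0.081,
  0.0,
  0.0,
  0.0,
  0.0,
  0.15,
  0.0
 ],
 "metadata": {
  "n_sessions": 824,
  "note": "Published Start2Cycle transition matrix at printed 2-decimal precision; absent transitions stored as 0. Initial distribution: 0.769 Coach as reported; remainder split Track 0.15 / Competition 0.081 as an emulation choice."
 }
}
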