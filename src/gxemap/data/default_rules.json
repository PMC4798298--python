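[
 {
  "name": "HS-a",
  "requirements": {"FLO8": "3S", "IRA2": "MUT", "MSS11": "BY"},
  "temperatures": [21]
 },
 {
  "name": "HS-b",
  "requirements": {"XII": "3S", "END3": "BY", "FLO8": "3S", "IRA2": "MUT", "MGA1": "BY", "MSS11": "3S", "SFL1": "BY"},
  "temperatures": [21]
 },
 {
  "name": "MS-a",
  "requirements": {"END3": "BY", "FLO8": "3S", "IRA2": "MUT", "MSS11": "BY", "TRR1": "3S"},
  "temperatures": [21, 30]
 },
 {
  "name": "MS-b",
  "requirements": {"END3": "3S", "FLO8": "3S", "IRA2": "MUT", "MGA1": "BY", "MSS11": "BY", "SFL1": "BY"},
  "temperatures": [21, 30]
 },
 {
  "name": "NS",
  "requirements": {"END3": "BY", "FLO8": "3S", "FLO11": "3S", "IRA2": "MUT", "MGA1": "BY", "MSS11": "BY", "SFL1": "BY", "TRR1": "3S"},
  "temperatures": [21, 30, 37]
 }
]
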