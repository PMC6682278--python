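,Trophies,Bug report,Coach,Competition,Personal,Route,Routes,Team,Track,Exit
Trophies,0.00,0.00,0.24,0.11,0.04,0.00,0.08,0.12,0.08,0.32
Bug report,0.00,0.00,0.12,0.09,0.29,0.00,0.05,0.12,0.22,0.10
Coach,0.03,0.00,0.00,0.23,0.09,0.00,0.04,0.20,0.20,0.22
Competition,0.05,0.00,0.31,0.00,0.05,0.01,0.09,0.24,0.05,0.21
Personal,0.00,0.21,0.28,0.04,0.00,0.00,0.08,0.13,0.09,0.17
Route,0.00,0.00,0.13,0.00,0.04,0.00,0.52,0.01,0.19,0.11
Routes,0.06,0.00,0.07,0.03,0.03,0.66,0.00,0.05,0.04,0.07
Team,0.04,0.00,0.11,0.38,0.08,0.00,0.11,0.00,0.06,0.22
Track,0.01,0.00,0.13,0.03,0.05,0.30,0.07,0.12,0.00,0.29
Exit,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
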