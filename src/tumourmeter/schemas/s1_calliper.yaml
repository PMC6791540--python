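# Schema map for the calliper statistical-review dataset (supplementary CSV).
# Edit the right-hand column names to match the file's actual headers on
# first use; units are multiplicative factors into mm / mm^2 / g.
columns:
  study_id: StudyID
  mouse_id: MouseID
  day: Date
  operator_id: OperatorID
  length: Length
  width: Width
units:
  length: 1.0
  width: 1.0
constants:
  instrument: calliper
date_format: null
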