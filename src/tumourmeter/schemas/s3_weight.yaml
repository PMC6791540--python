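# Schema map for the volume / excised-weight comparison dataset
# (supplementary CSV).  Weight is the excised tumour weight in grams.
columns:
  study_id: StudyID
  mouse_id: MouseID
  day: Date
  operator_id: OperatorID
  instrument: Instrument
  length: Length
  width: Width
  height: Height
  weight: Weight
units:
  length: 1.0
  width: 1.0
  height: 1.0
  weight: 1.0
date_format: null
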