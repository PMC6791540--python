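# Schema map for the calliper / scan comparison dataset (supplementary CSV).
# The Instrument column distinguishes calliper rows from scan rows; scan rows
# additionally carry height and footprint area.
columns:
  study_id: StudyID
  mouse_id: MouseID
  day: Date
  operator_id: OperatorID
  instrument: Instrument
  length: Length
  width: Width
  height: Height
  area: Area
  excluded: Excluded
units:
  length: 1.0
  width: 1.0
  height: 1.0
  area: 1.0
date_format: null
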