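# Default parameter file for the six culture configurations.
# Every scenario builds from this single file; field names mirror
# mivmsim.runner.ScenarioConfig.  Flow rates are in uL/min; omitted fields
# fall back to the study defaults (static well unperfused, 50 uL/min
# elsewhere, fixed per-scenario COC placement seeds).
scenarios:
  - scenario: static
  - scenario: native
  - scenario: ring
  - scenario: concave_ring
  - scenario: box
  - scenario: alginate
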