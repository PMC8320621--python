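# Default synonym table mapping raw clinical observations (as transcribed
# from study reports) onto the six standard respiratory-sign lexicon terms.
# Matching is case-insensitive; hyphens and repeated whitespace are ignored.
# Edit or replace this file to audit/extend the mapping; raw terms that match
# no entry are reported as "unmapped", never silently dropped.
irregular respiration:
  - irregular respiration
  - irregular breathing
  - respiration irregular
  - irregular breathing pattern
shallow respiration:
  - shallow respiration
  - shallow breathing
  - laboured shallow breathing
  - labored shallow breathing
  - hypopnoea
  - hypopnea
noisy respiration:
  - noisy respiration
  - noisy breathing
  - rales
  - audible respiration
  - wheezing
slow respiration:
  - slow respiration
  - slow breathing
  - bradypnoea
  - bradypnea
  - decreased respiratory rate
rapid/fast respiration:
  - rapid/fast respiration
  - rapid respiration
  - fast respiration
  - rapid breathing
  - tachypnoea
  - tachypnea
  - increased respiratory rate
  - hyperventilation
gasping:
  - gasping
  - gasps
  - agonal breathing
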