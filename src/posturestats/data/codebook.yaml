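# Body-part codebook: code -> term list (single tokens or contiguous
# phrases, matched case-insensitively against pre-tokenized transcripts).
# The terms are English translations of the original Japanese coding rules.
Foot:
  - plantar
  - sole
  - arch
  - toe
  - big toe
  - ball of foot
  - little toe
  - heel
  - foot
Lower limb (non-foot):
  - knee
  - thigh
  - calf
  - lower leg
  - lower body
  - hip joint
Shoulder:
  - shoulder
  - right shoulder
  - left shoulder
Lumbopelvic region:
  - lower back
  - lumbar
  - pelvis
  - sacrum
  - buttocks
  - gluteal
Trunk:
  - upper body
  - navel
  - trunk
  - core
  - spine
  - body
  - back
  - chest
  - abdomen
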