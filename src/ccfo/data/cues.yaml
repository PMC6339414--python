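# Contextual cue lexicons for qualifier, course and assertion resolution.
# Multi-word cues are matched on token n-grams. Windows are in tokens.
qualifier_window: 5
negation_window: 5
ability_cues:
  able: [able, can, independent, independently, unassisted]
  with-difficulty: [difficulty, assist, assisted, assists, needs help, with help, supervision]
  unable: [unable, cannot, dependent]
frequency_cues:
  high-frequency: [always, daily, often]
  mid-frequency: [sometimes, occasionally]
  absent: [never, denies, "no"]
course_cues:
  chronic: [chronic, longstanding]
  short-duration: [brief, transient]
  sudden-onset: [sudden, acute]
negation_cues: ["no", denies, without, not]
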