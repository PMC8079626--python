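# Default ethogram catalog: the coded behaviour vocabulary for
# shelter-dog walks, split into canine behaviours, human verbal cues and
# human body language.  Point events are counted; state events are timed.
canine:
  track: state
  sniff: state
  eliminate-mark: point
  shake: point
  pant: state
  gaze: point
  lip-lick: point
  tail wag: state
  tail high: state
human_verbal:
  sit: point
  command: point
  attention seeking: point
  high-pitched voice: point
  praise: point
  negative verbal cue: point
  communication: point
human_body:
  gestural: point
  physical contacts: point
  food reward: point
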