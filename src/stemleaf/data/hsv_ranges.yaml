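# HSV colour ranges (OpenCV convention: H on 0-180, S and V on 0-255).
# Achromatic colours are distinguished by S/V bands; red owns two hue
# intervals.  Editable: pass a modified copy via --hsv-table.
black:
  hue: [[0, 180]]
  sat: [0, 255]
  val: [0, 46]
gray:
  hue: [[0, 180]]
  sat: [0, 43]
  val: [46, 220]
white:
  hue: [[0, 180]]
  sat: [0, 30]
  val: [221, 255]
red:
  hue: [[0, 10], [156, 180]]
  sat: [43, 255]
  val: [46, 255]
orange:
  hue: [[11, 25]]
  sat: [43, 255]
  val: [46, 255]
yellow:
  hue: [[26, 34]]
  sat: [43, 255]
  val: [46, 255]
green:
  hue: [[35, 77]]
  sat: [43, 255]
  val: [46, 255]
cyan:
  hue: [[78, 99]]
  sat: [43, 255]
  val: [46, 255]
blue:
  hue: [[100, 124]]
  sat: [43, 255]
  val: [46, 255]
purple:
  hue: [[125, 155]]
  sat: [43, 255]
  val: [46, 255]
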