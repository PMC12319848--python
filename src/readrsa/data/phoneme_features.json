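{
  "_features": ["syllabic", "consonantal", "sonorant", "voiced", "nasal",
                "continuant", "labial", "coronal", "dorsal", "high"],
  "a":  [1, 0, 1, 1, 0, 1, 0, 0, 1, 0],
  "e":  [1, 0, 1, 1, 0, 1, 0, 0, 0, 0],
  "i":  [1, 0, 1, 1, 0, 1, 0, 0, 0, 1],
  "o":  [1, 0, 1, 1, 0, 1, 1, 0, 1, 0],
  "u":  [1, 0, 1, 1, 0, 1, 1, 0, 1, 1],
  "p":  [0, 1, 0, 0, 0, 0, 1, 0, 0, 0],
  "b":  [0, 1, 0, 1, 0, 0, 1, 0, 0, 0],
  "t":  [0, 1, 0, 0, 0, 0, 0, 1, 0, 0],
  "d":  [0, 1, 0, 1, 0, 0, 0, 1, 0, 0],
  "k":  [0, 1, 0, 0, 0, 0, 0, 0, 1, 1],
  "g":  [0, 1, 0, 1, 0, 0, 0, 0, 1, 1],
  "f":  [0, 1, 0, 0, 0, 1, 1, 0, 0, 0],
  "v":  [0, 1, 0, 1, 0, 1, 1, 0, 0, 0],
  "s":  [0, 1, 0, 0, 0, 1, 0, 1, 0, 0],
  "z":  [0, 1, 0, 1, 0, 1, 0, 1, 0, 0],
  "h":  [0, 1, 0, 0, 0, 1, 0, 0, 1, 0],
  "dZ": [0, 1, 0, 1, 0, 0, 0, 1, 0, 1],
  "m":  [0, 1, 1, 1, 1, 0, 1, 0, 0, 0],
  "n":  [0, 1, 1, 1, 1, 0, 0, 1, 0, 0],
  "l":  [0, 1, 1, 1, 0, 1, 0, 1, 0, 0],
  "r":  [0, 1, 1, 1, 0, 1, 0, 1, 0, 1],
  "w":  [0, 0, 1, 1, 0, 1, 1, 0, 1, 1],
  "j":  [0, 0, 1, 1, 0, 1, 0, 0, 1, 1]
}
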