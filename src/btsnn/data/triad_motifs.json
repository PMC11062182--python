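{
  "1":  [[0, 1, 1], [0, 0, 0], [0, 0, 0]],
  "2":  [[0, 0, 0], [1, 0, 0], [1, 0, 0]],
  "3":  [[0, 1, 0], [0, 0, 1], [0, 0, 0]],
  "4":  [[0, 1, 0], [1, 0, 0], [1, 0, 0]],
  "5":  [[0, 1, 1], [1, 0, 0], [0, 0, 0]],
  "6":  [[0, 1, 1], [0, 0, 1], [0, 0, 0]],
  "7":  [[0, 1, 0], [0, 0, 1], [1, 0, 0]],
  "8":  [[0, 1, 1], [1, 0, 0], [1, 0, 0]],
  "9":  [[0, 1, 0], [1, 0, 0], [1, 1, 0]],
  "10": [[0, 1, 1], [1, 0, 1], [0, 0, 0]],
  "11": [[0, 1, 1], [1, 0, 0], [0, 1, 0]],
  "12": [[0, 1, 1], [1, 0, 1], [1, 0, 0]],
  "13": [[0, 1, 1], [1, 0, 1], [1, 1, 0]]
}
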