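{
  "samples_collected": 386,
  "samples_analysable": 371,
  "printed_analysable_pct": 97.4,
  "label_counts": {
    "Cod": 179,
    "Cod|Atlantic": 57,
    "Cod|Pacific": 20,
    "Cod|NA": 102,
    "Haddock": 155,
    "Alaskan Pollack": 32,
    "Hake (M. capensis)": 4,
    "Whiting": 1
  },
  "processing_level_counts": {
    "1": 84,
    "2": 84,
    "3": 31,
    "4": 128,
    "5": 44
  },
  "processing_level_names": {
    "1": "fresh or frozen fillets",
    "2": "battered or breaded fillets",
    "3": "fish fingers",
    "4": "pre-cooked meals",
    "5": "fishcakes"
  },
  "discrepancy_flags": [
    "printed analysable percentage 97.4 disagrees with 371/386 = 96.1",
    "printed fish-finger rate 6.45% of n=31 implies 2 samples but the mislabelled table lists 1 fish-finger product",
    "printed pre-cooked-meal rate 5.47% of n=128 implies 7 samples but the mislabelled table lists 8 pre-cooked products"
  ]
}
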