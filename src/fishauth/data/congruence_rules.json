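{
  "comment": "Label + optional catch area -> acceptable genetic species groups. A rule with an explicit area beats a rule without one; generic cod (no area on the packaging) accepts either cod species.",
  "rules": [
    {"label": "Cod", "area": "Atlantic", "accept": ["morhua"]},
    {"label": "Cod", "area": "Pacific", "accept": ["macrocephalus-group"]},
    {"label": "Cod", "accept": ["morhua", "macrocephalus-group"]},
    {"label": "Haddock", "accept": ["aeglefinus"]},
    {"label": "Alaskan Pollack", "accept": ["chalcogramma-group"]},
    {"label": "Hake (M. capensis)", "accept": ["capensis"]},
    {"label": "Whiting", "accept": ["merlangus"]}
  ]
}
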