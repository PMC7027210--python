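{
  "core_funding": [
    "core funding",
    "core support",
    "core institutional funding",
    "institutional support",
    "operating grant"
  ],
  "training": [
    "training",
    "phd studentship",
    "doctoral training",
    "postgraduate",
    "studentship",
    "masters degree",
    "summer school"
  ],
  "capacity_strengthening": [
    "fellowship",
    "capacity strengthening",
    "capacity building",
    "career development award",
    "early career award",
    "prize"
  ],
  "meetings": [
    "conference",
    "workshop",
    "symposium",
    "scientific meeting",
    "congress"
  ],
  "networking": [
    "networking",
    "research network",
    "consortium",
    "partnership"
  ]
}
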