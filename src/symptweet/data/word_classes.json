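{
  "Infection": ["sick", "down", "ill", "infect", "caught", "recover"],
  "Possession": ["have", "contain", "contaminated", "my"],
  "Concern": ["awful", "worried", "scared", "afraid", "terrified", "fear", "sad", "unhappy", "feel"],
  "Humour": ["laugh", "ha", "haha", "hahaha", "lol", "lmao", "rofl", "funny", "hilarious", "amused"],
  "Symptomatic": ["runny nose", "cough", "spray", "shots", "wheezing", "mucus", "cold"]
}
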