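{
  "nns_keywords": [
    "acesulfam", "acesulfame", "advantam", "aspartam", "aspartame",
    "ciclamato", "cyclamate", "edulcorante", "eritritol",
    "glucosidos de esteviol", "neohesperidina", "neotam", "neotame",
    "sacarina", "saccharin", "stevia", "steviol", "sucralosa", "sucralose",
    "taumatina", "thaumatin",
    "e950", "e951", "e952", "e954", "e955", "e957", "e959", "e960", "e961", "e962", "e969",
    "e 950", "e 951", "e 952", "e 954", "e 955", "e 957", "e 959", "e 960", "e 961", "e 962", "e 969"
  ]
}
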