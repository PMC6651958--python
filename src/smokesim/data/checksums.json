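{
  "anchors.json": "71c8f9ddffb9581198c97fc3be6a08ff52146c5c4816279455a82cb059127051",
  "default_config.yaml": "a6d176ac32d93081ee133bfc095b3a2f7ed0da114b55c36bd051fedd52a1624a",
  "table4_deaths_2016_2025.csv": "836730edb46925ac1cccbedaa5fe7da3835921b69c73512061662a33ce250e84",
  "thai_cessation_2014.csv": "6a7414df08fb51a6e94683a529d88f1b34321c20d6c60d40b120fff9c284928a",
  "thai_initiation_2014.csv": "c846342965c8ed4d86ff40b85a864bd3042691f6e8bd6a32f69fc1e413814248",
  "thai_prevalence_2014.csv": "35ff77310af507e59c4042f67c940bd4c8feb91ccb0d3862f29b201429b89f8e"
}
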