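# Full pipeline: simulate -> clean -> learn -> evaluate -> sensitivity -> what-if.
seed: 7
simulate:
  fixture: survey11
  n: 11206
  missing: 0.05
  nonuser: 0.03
  dontknow: 0.02
preprocess:
  smartphone:
    column: Smartphone_Service
learn:
  class_var: Obesity_Level
  score: bdeu
  equivalent_sample_size: 1.0
  max_parents: 3
evaluate:
  models: [gbn, gbn-mb, nb]
  folds: 10
sensitivity:
  target: Obesity_Level
whatif:
  scenarios: [scenarios.yaml]
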