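[
  {
    "constraints": [
      {
        "feature": "TP53",
        "type": "FeatureContextConstraint"
      },
      {
        "location": {
          "end": 7687538,
          "sequenceId": "GRCh38:chr17",
          "start": 7668402
        },
        "matchMode": "OVERLAPS",
        "type": "DefiningLocationConstraint"
      },
      {
        "change": "LOSS",
        "type": "CopyChangeConstraint"
      }
    ],
    "declaredProfile": "CategoricalCNV",
    "id": "catvar-tp53-cnloss",
    "label": "TP53 CNLoss"
  }
]
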