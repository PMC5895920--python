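[
  {
    "name": "Alcohol",
    "role": "marker",
    "condition": "alcoholism"
  },
  {
    "name": "Alcohol abuse",
    "role": "marker",
    "condition": "alcoholism"
  },
  {
    "name": "Alcoholic beverages",
    "role": "marker",
    "condition": "alcoholism"
  },
  {
    "name": "Alcoholics anonymous",
    "role": "marker",
    "condition": "alcoholism"
  },
  {
    "name": "Alcoholism awareness",
    "role": "marker",
    "condition": "alcoholism"
  },
  {
    "name": "Bars",
    "role": "marker",
    "condition": "alcoholism"
  },
  {
    "name": "Sobriety",
    "role": "marker",
    "condition": "alcoholism"
  },
  {
    "name": "Twelve-step program",
    "role": "marker",
    "condition": "alcoholism"
  },
  {
    "name": "Bariatrics",
    "role": "marker",
    "condition": "obesity"
  },
  {
    "name": "Obesity awareness",
    "role": "marker",
    "condition": "obesity"
  },
  {
    "name": "Plus size",
    "role": "marker",
    "condition": "obesity"
  },
  {
    "name": "Plus-size clothing",
    "role": "marker",
    "condition": "obesity"
  },
  {
    "name": "Weight loss (fitness and wellness)",
    "role": "marker",
    "condition": "obesity"
  },
  {
    "name": "Dieting",
    "role": "marker",
    "condition": "obesity"
  },
  {
    "name": "Gestational diabetes",
    "role": "marker",
    "condition": "diabetes"
  },
  {
    "name": "Insulin index",
    "role": "marker",
    "condition": "diabetes"
  },
  {
    "name": "Insulin resistance awareness",
    "role": "marker",
    "condition": "diabetes"
  },
  {
    "name": "Diabetes mellitus awareness",
    "role": "marker",
    "condition": "diabetes"
  },
  {
    "name": "Diabetes mellitus type 1 awareness",
    "role": "marker",
    "condition": "diabetes"
  },
  {
    "name": "Diabetes mellitus type 2 awareness",
    "role": "marker",
    "condition": "diabetes"
  },
  {
    "name": "Diabetic diet",
    "role": "marker",
    "condition": "diabetes"
  },
  {
    "name": "Diabetic hypoglycemia",
    "role": "marker",
    "condition": "diabetes"
  },
  {
    "name": "Gluten sensitivity awareness",
    "role": "marker",
    "condition": "food sensitivities"
  },
  {
    "name": "Gluten-free diet",
    "role": "marker",
    "condition": "food sensitivities"
  },
  {
    "name": "Lactose intolerance",
    "role": "marker",
    "condition": "food sensitivities"
  },
  {
    "name": "Food allergy",
    "role": "marker",
    "condition": "food sensitivities"
  },
  {
    "name": "Food intolerance",
    "role": "marker",
    "condition": "food sensitivities"
  },
  {
    "name": "Peanut allergy",
    "role": "marker",
    "condition": "food sensitivities"
  },
  {
    "name": "Facebook",
    "role": "placebo"
  },
  {
    "name": "Reading",
    "role": "placebo"
  },
  {
    "name": "Entertainment",
    "role": "placebo"
  },
  {
    "name": "Music",
    "role": "placebo"
  },
  {
    "name": "Technology",
    "role": "placebo"
  },
  {
    "name": "Fitness and wellness",
    "role": "baseline"
  }
]
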