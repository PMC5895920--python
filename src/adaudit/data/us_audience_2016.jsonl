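{"granularity": 20, "timestamp": "2016-09"}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Alcohol"], "count": 13000000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Alcohol abuse"], "count": 610000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Alcoholic beverages"], "count": 74000000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Alcoholics anonymous"], "count": 670000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Alcoholism awareness"], "count": 4600000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Bars"], "count": 33000000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Sobriety"], "count": 3100000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Twelve-step program"], "count": 640000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Bariatrics"], "count": 710000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Obesity awareness"], "count": 7400000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Plus size"], "count": 430000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Plus-size clothing"], "count": 9100000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Weight loss (fitness and wellness)"], "count": 15000000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Dieting"], "count": 27000000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Gestational diabetes"], "count": 650000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Insulin index"], "count": 250000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Insulin resistance awareness"], "count": 500000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Diabetes mellitus awareness"], "count": 12000000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Diabetes mellitus type 1 awareness"], "count": 1200000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Diabetes mellitus type 2 awareness"], "count": 2100000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Diabetic diet"], "count": 2100000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Diabetic hypoglycemia"], "count": 230000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Gluten sensitivity awareness"], "count": 250000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Gluten-free diet"], "count": 10000000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Lactose intolerance"], "count": 240000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Food allergy"], "count": 690000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Food intolerance"], "count": 200000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Peanut allergy"], "count": 140000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Facebook"], "count": 83000000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Reading"], "count": 141000000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Entertainment"], "count": 171000000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Music"], "count": 152000000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Technology"], "count": 157000000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": ["Fitness and wellness"], "count": 110000000}
{"geography": "US", "gender": "any", "age": "any", "ethnicity": "any", "interests": [], "count": 194000000}
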