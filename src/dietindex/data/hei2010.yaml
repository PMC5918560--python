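# HEI-2010 component standards.
# Densities are per 1000 kcal except the fatty-acid ratio ((MUFA+PUFA)/SFA,
# unitless) and empty calories (% of total energy).  Editable: supply your
# own file to hei.HEIStandards.from_yaml to change thresholds without code
# changes.
components:
  - name: total_fruit
    kind: adequacy
    max_points: 5
    unit: cup-eq/1000 kcal
    numerator: total_fruit_cup
    full_threshold: 0.8
  - name: whole_fruit
    kind: adequacy
    max_points: 5
    unit: cup-eq/1000 kcal
    numerator: whole_fruit_cup
    full_threshold: 0.4
  - name: total_vegetables
    kind: adequacy
    max_points: 5
    unit: cup-eq/1000 kcal
    numerator: total_veg_cup
    full_threshold: 1.1
  - name: greens_and_beans
    kind: adequacy
    max_points: 5
    unit: cup-eq/1000 kcal
    numerator: greens_beans_cup
    full_threshold: 0.2
  - name: whole_grains
    kind: adequacy
    max_points: 10
    unit: oz-eq/1000 kcal
    numerator: whole_grains_oz
    full_threshold: 1.5
  - name: dairy
    kind: adequacy
    max_points: 10
    unit: cup-eq/1000 kcal
    numerator: dairy_cup
    full_threshold: 1.3
  - name: total_protein_foods
    kind: adequacy
    max_points: 5
    unit: oz-eq/1000 kcal
    numerator: total_protein_oz
    full_threshold: 2.5
  - name: seafood_and_plant_proteins
    kind: adequacy
    max_points: 5
    unit: oz-eq/1000 kcal
    numerator: seafood_plant_oz
    full_threshold: 0.8
  - name: fatty_acids
    kind: ratio
    max_points: 10
    unit: ratio
    numerator: fatty_acid_ratio
    full_threshold: 2.5
    zero_threshold: 1.2
  - name: refined_grains
    kind: moderation
    max_points: 10
    unit: oz-eq/1000 kcal
    numerator: refined_grains_oz
    full_threshold: 1.8
    zero_threshold: 4.3
  - name: sodium
    kind: moderation
    max_points: 10
    unit: g/1000 kcal
    numerator: sodium_g
    full_threshold: 1.1
    zero_threshold: 2.0
  - name: empty_calories
    kind: moderation
    max_points: 20
    unit: '% energy'
    numerator: empty_calories_pct
    full_threshold: 19.0
    zero_threshold: 50.0
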