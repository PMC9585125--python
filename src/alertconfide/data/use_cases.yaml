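# The five packaged use-case requirement profiles: the ideal minimum
# confidence level per criterion for each application of a structural alert.
# A cell with two levels (e.g. [high, moderate]) means either is the stated
# ideal; the default (permissive) reading takes the lower of the two as the
# acceptable minimum, a strict reading takes the higher.
scheme_version: 1
use_cases:
  - id: hazard_identification
    name: Hazard Identification Supporting Risk Assessment
    minima:
      structural_description: [high]
      property_domain: [high]
      toxicity_or_adversity: [high]
      species_specificity: [high]
      metabolic_domain: [high, moderate]
      purpose: [high]
      mechanistic_interpretation: [high]
      mechanistic_causality: [high]
      coverage: [high]
      performance: [high]
      corroborating_evidence: [high]
      supporting_evidence: [moderate]
  - id: mechanism_analogue_identification
    name: Mechanism-Based Analogue Identification
    minima:
      structural_description: [high]
      property_domain: [high]
      toxicity_or_adversity: [high]
      species_specificity: [high]
      metabolic_domain: [high, moderate]
      purpose: [high]
      mechanistic_interpretation: [high]
      mechanistic_causality: [high]
      coverage: [high]
      performance: [high]
      corroborating_evidence: [high]
      supporting_evidence: [moderate]
  - id: category_identification
    name: Category Identification (Chemical Class-Based Analogues)
    minima:
      structural_description: [high]
      property_domain: [high]
      toxicity_or_adversity: [high]
      species_specificity: [high]
      metabolic_domain: [high, moderate]
      purpose: [moderate]
      mechanistic_interpretation: [high]
      mechanistic_causality: [moderate, high]
      coverage: [low]
      performance: [moderate]
      corroborating_evidence: [moderate]
      supporting_evidence: [moderate, low]
  - id: classification_labelling
    name: Predictions Leading to Classification and Labelling
    minima:
      structural_description: [high]
      property_domain: [moderate]
      toxicity_or_adversity: [high]
      species_specificity: [high]
      metabolic_domain: [moderate]
      purpose: [moderate]
      mechanistic_interpretation: [high]
      mechanistic_causality: [moderate, high]
      coverage: [low]
      performance: [moderate]
      corroborating_evidence: [moderate]
      supporting_evidence: [low]
  - id: screening_prioritisation
    name: Screening and/or Prioritisation
    minima:
      structural_description: [high]
      property_domain: [moderate]
      toxicity_or_adversity: [high]
      species_specificity: [moderate]
      metabolic_domain: [moderate]
      purpose: [moderate]
      mechanistic_interpretation: [high]
      mechanistic_causality: [moderate, high]
      coverage: [low]
      performance: [moderate]
      corroborating_evidence: [moderate]
      supporting_evidence: [low]
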