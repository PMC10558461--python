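# Default category maps for the 77-covariate analysis.
#
# Comorbidities are flagged at the granularity of 16 ICD-10 chapters
# (ranges over the letter+2-digit code prefix).  Concomitant medications
# are flagged at the granularity of 60 ATC-style therapeutic categories;
# raw drug codes are resolved by their 5-character prefix.  The prefixes
# below are the synthetic codes the built-in claims generator emits; when
# running on other data, replace them with the real code lists while
# keeping the category names.
icd10_chapters:
  - key: infectious
    name: Certain infectious and parasitic diseases
    ranges: ["A00-B99"]
  - key: neoplasms
    name: Neoplasms
    ranges: ["C00-D48"]
  - key: blood
    name: Diseases of the blood and blood-forming organs and certain disorders involving the immune mechanism
    ranges: ["D50-D89"]
  - key: endocrine
    name: Endocrine, nutritional, and metabolic diseases
    ranges: ["E00-E90"]
  - key: mental
    name: Mental and behavioral disorders
    ranges: ["F00-F99"]
  - key: nervous
    name: Nervous system diseases
    ranges: ["G00-G99"]
  - key: eye
    name: Eye and adnexa diseases
    ranges: ["H00-H59"]
  - key: ear
    name: Ear and mastoid process diseases
    ranges: ["H60-H95"]
  - key: circulatory
    name: Diseases of the circulatory system
    ranges: ["I00-I99"]
  - key: respiratory
    name: Respiratory system diseases
    ranges: ["J00-J99"]
  - key: digestive
    name: Digestive system diseases
    ranges: ["K00-K93"]
  - key: skin
    name: Skin and subcutaneous tissue diseases
    ranges: ["L00-L99"]
  - key: musculoskeletal
    name: Musculoskeletal system and connective tissue diseases
    ranges: ["M00-M99"]
  - key: genitourinary
    name: Genitourinary system diseases
    ranges: ["N00-N99"]
  - key: symptoms
    name: Symptoms and signs and abnormal clinical and laboratory findings, not elsewhere classified
    ranges: ["R00-R99"]
  - key: injury
    name: Injury, poisoning, and certain other consequences of external causes
    ranges: ["S00-T98"]
medication_categories:
  - {prefix: ATC01, name: "Stomatologicals, mouth preparations, medicinal dentifrices"}
  - {prefix: ATC02, name: "Antacids, antiflatulents, and anti-ulcers"}
  - {prefix: ATC03, name: "Functional gastrointestinal disorder drugs"}
  - {prefix: ATC04, name: "Antiemetics and antinauseants"}
  - {prefix: ATC05, name: "Bile therapy and cholagogues"}
  - {prefix: ATC06, name: "Drugs for constipation"}
  - {prefix: ATC07, name: "Drugs for intestinal disorder"}
  - {prefix: ATC08, name: "Digestives system drug, including enzymes"}
  - {prefix: ATC09, name: "Antidiabetic drugs"}
  - {prefix: ATC10, name: "Vitamins"}
  - {prefix: ATC11, name: "Mineral supplements"}
  - {prefix: ATC12, name: "Anabolics, systemic"}
  - {prefix: ATC13, name: "Other alimentary tract and metabolism products"}
  - {prefix: ATC14, name: "Antithrombotic agents"}
  - {prefix: ATC15, name: "Antifibrinolytics"}
  - {prefix: ATC16, name: "Anti-anemic preparations"}
  - {prefix: ATC17, name: "Cardiac therapy"}
  - {prefix: ATC18, name: "Antihypertensives"}
  - {prefix: ATC19, name: "Diuretics"}
  - {prefix: ATC20, name: "Cerebral and peripheral vasotherapeutics"}
  - {prefix: ATC21, name: "Antivaricosis/anti-hemorrhoidal preparations"}
  - {prefix: ATC22, name: "Other cardiovascular products"}
  - {prefix: ATC23, name: "Beta-blockers"}
  - {prefix: ATC24, name: "Calcium antagonists"}
  - {prefix: ATC25, name: "Agents acting on the renin-angiotensin system"}
  - {prefix: ATC26, name: "Lipid-regulating/anti-atheroma preparations"}
  - {prefix: ATC27, name: "Cardiovascular multitherapy combination products"}
  - {prefix: ATC28, name: "Antipruritic, including topical antihistamine, anaesthetic"}
  - {prefix: ATC29, name: "Nonsteroidal product for inflammatory skin disorders"}
  - {prefix: ATC30, name: "Other dermatological preparations"}
  - {prefix: ATC31, name: "Gynecological anti-infective agents"}
  - {prefix: ATC32, name: "Sex hormones and products with similar desired effects, systemic action only"}
  - {prefix: ATC33, name: "Urologics"}
  - {prefix: ATC34, name: "Systemic corticosteroids"}
  - {prefix: ATC35, name: "Thyroid therapy"}
  - {prefix: ATC36, name: "Other types of hormones"}
  - {prefix: ATC37, name: "Systemic antibacterials"}
  - {prefix: ATC38, name: "Systemic agents for fungal infections"}
  - {prefix: ATC39, name: "Antimycobacterials"}
  - {prefix: ATC40, name: "Antivirals for systemic use"}
  - {prefix: ATC41, name: "Antineoplastics"}
  - {prefix: ATC42, name: "Cytostatic hormone therapy"}
  - {prefix: ATC43, name: "Immunostimulating agents"}
  - {prefix: ATC44, name: "Immunosuppressants"}
  - {prefix: ATC45, name: "Anti-inflammatory and anti-rheumatic agents"}
  - {prefix: ATC46, name: "Muscle relaxants"}
  - {prefix: ATC47, name: "Anti-gout preparations"}
  - {prefix: ATC48, name: "Other drugs for musculo-skeletal system disorders"}
  - {prefix: ATC49, name: "Anesthetics"}
  - {prefix: ATC50, name: "Analgesics"}
  - {prefix: ATC51, name: "Anti-epileptics"}
  - {prefix: ATC52, name: "Anti-Parkinson's drugs"}
  - {prefix: ATC53, name: "Psycholeptics"}
  - {prefix: ATC54, name: "Psychoanaleptics, excluding anti-obesity preparations"}
  - {prefix: ATC55, name: "Other Central Nervous System drugs"}
  - {prefix: ATC56, name: "Antiprotozoals and anthelmintics"}
  - {prefix: ATC57, name: "Anti-asthma and COPD products"}
  - {prefix: ATC58, name: "Cough and cold preparations"}
  - {prefix: ATC59, name: "Systemic antihistamines"}
  - {prefix: ATC60, name: "Other respiratory system products"}
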