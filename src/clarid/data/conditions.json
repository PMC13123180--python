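{
  "C22.0": "Liver cell carcinoma",
  "C92.0": "Acute myeloblastic leukemia",
  "J44.9": "Chronic obstructive pulmonary disease, unspecified",
  "A09": "Infectious gastroenteritis and colitis, unspecified",
  "B18.2": "Chronic viral hepatitis C",
  "C34.9": "Malignant neoplasm of bronchus or lung, unspecified",
  "C50.9": "Malignant neoplasm of breast, unspecified",
  "C61": "Malignant neoplasm of prostate",
  "E11.9": "Type 2 diabetes mellitus without complications",
  "F32.9": "Major depressive disorder, single episode, unspecified",
  "G30.9": "Alzheimer disease, unspecified",
  "I10": "Essential (primary) hypertension",
  "J45.9": "Asthma, unspecified",
  "K70.3": "Alcoholic cirrhosis of liver",
  "M54.5": "Low back pain",
  "N18.9": "Chronic kidney disease, unspecified"
}
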