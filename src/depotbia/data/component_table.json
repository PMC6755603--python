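{
  "n": 132,
  "scope": "sample_total",
  "arms": {
    "oral": {
      "productivity_loss": "57686.40",
      "ebm_services": "41496.84",
      "goa_services": "3780.70",
      "day_clinic_pia": "16000.00",
      "ebm_inpatient": "10344.07",
      "goa_inpatient": "616.66",
      "hospital_days": "746168.65",
      "emergency_services": "413.67",
      "emergency_physician": "1699.74",
      "non_drug_interventions": "49291.59",
      "depot_injections": "0.00",
      "medication": "323109.37",
      "comorbid_medication": "60861.86"
    },
    "depot": {
      "productivity_loss": "14220.00",
      "ebm_services": "37775.82",
      "goa_services": "1581.62",
      "day_clinic_pia": "8400.00",
      "ebm_inpatient": "3434.13",
      "goa_inpatient": "170.07",
      "hospital_days": "170021.33",
      "emergency_services": "80.22",
      "emergency_physician": "171.00",
      "non_drug_interventions": "13699.69",
      "depot_injections": "306975.32",
      "medication": "13642.75",
      "comorbid_medication": "31425.42"
    }
  }
}
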