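{
  "format": "mqrc-icsr-csv",
  "version": 1,
  "encoding": "utf-8",
  "columns": [
    "report_id",
    "report_date",
    "report_type",
    "trade_name",
    "api_names",
    "medicine_version",
    "therapeutic_class",
    "specific_product",
    "dosage_form",
    "route",
    "facility_sector",
    "facility_level",
    "reporter_profession",
    "county",
    "complaint_text",
    "patient_key",
    "is_test_entry"
  ],
  "date_format": "YYYY-MM-DD",
  "list_separator": ";",
  "vocabularies": {
    "report_type": [
      "sADR",
      "sPQM",
      "medication_error",
      "device_incident",
      "AEFI",
      "blood_product_reaction"
    ],
    "medicine_version": [
      "branded",
      "generic",
      "unstated"
    ],
    "therapeutic_class": [
      "antineoplastics",
      "antivirals",
      "antibacterials",
      "analgesics",
      "antihypertensives",
      "medical_devices",
      "antiprotozoals",
      "gynaecological",
      "antimycobacterial",
      "blood_perfusion_solutions",
      "anaesthetics",
      "minerals_vitamins",
      "diabetes_drugs",
      "vaccines",
      "other_therapeutic_products"
    ],
    "dosage_form": [
      "tablet",
      "injection",
      "oral_liquid",
      "medical_device",
      "capsule",
      "dermal_implant",
      "other"
    ],
    "route": [
      "oral",
      "parenteral",
      "topical",
      "other",
      "not_applicable"
    ],
    "facility_sector": [
      "government",
      "private_for_profit",
      "not_for_profit",
      "informal_unlicensed",
      "unknown"
    ],
    "facility_level": [
      "hospital",
      "dispensary_clinic_health_centre",
      "pharmacy_chemist",
      "importer_distributor_wholesaler",
      "individual",
      "research_institution",
      "unknown"
    ],
    "reporter_profession": [
      "pharmacist",
      "medical_doctor",
      "pharmaceutical_technician",
      "other_hcp",
      "not_stated"
    ],
    "county": [
      "Baringo",
      "Bomet",
      "Bungoma",
      "Busia",
      "Elgeyo-Marakwet",
      "Embu",
      "Garissa",
      "Homa Bay",
      "Isiolo",
      "Kajiado",
      "Kakamega",
      "Kericho",
      "Kiambu",
      "Kilifi",
      "Kirinyaga",
      "Kisii",
      "Kisumu",
      "Kitui",
      "Kwale",
      "Laikipia",
      "Lamu",
      "Machakos",
      "Makueni",
      "Mandera",
      "Marsabit",
      "Meru",
      "Migori",
      "Mombasa",
      "Murang'a",
      "Nairobi",
      "Nakuru",
      "Nandi",
      "Narok",
      "Nyamira",
      "Nyandarua",
      "Nyeri",
      "Samburu",
      "Siaya",
      "Taita-Taveta",
      "Tana River",
      "Tharaka-Nithi",
      "Trans-Nzoia",
      "Turkana",
      "Uasin Gishu",
      "Vihiga",
      "Wajir",
      "West Pokot",
      "Not Indicated"
    ]
  }
}
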