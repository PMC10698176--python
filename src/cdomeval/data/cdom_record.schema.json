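{
 "$defs": {
  "AdministrativeDetail": {
   "properties": {
    "sources": {
     "items": {
      "type": "string"
     },
     "title": "Sources",
     "type": "array"
    }
   },
   "title": "AdministrativeDetail",
   "type": "object"
  },
  "ClassificationCode": {
   "description": "One disease classification code with its system tag (e.g. ICD-10 I21).",
   "properties": {
    "system": {
     "description": "Classification system, e.g. 'ICD-10'",
     "minLength": 1,
     "title": "System",
     "type": "string"
    },
    "code": {
     "description": "The code itself, e.g. 'I21'",
     "minLength": 1,
     "title": "Code",
     "type": "string"
    }
   },
   "required": [
    "system",
    "code"
   ],
   "title": "ClassificationCode",
   "type": "object"
  },
  "CollectionMethod": {
   "enum": [
    "self_report",
    "study_examination",
    "administrative_database"
   ],
   "title": "CollectionMethod",
   "type": "string"
  },
  "ExaminationDetail": {
   "properties": {
    "procedures": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Procedures"
    },
    "thresholds": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Thresholds"
    }
   },
   "title": "ExaminationDetail",
   "type": "object"
  },
  "OutcomeGroup": {
   "description": "A chronic-disease outcome group examined by the included studies.",
   "properties": {
    "id": {
     "title": "Id",
     "type": "string"
    },
    "label": {
     "title": "Label",
     "type": "string"
    }
   },
   "required": [
    "id",
    "label"
   ],
   "title": "OutcomeGroup",
   "type": "object"
  },
  "OutcomeRole": {
   "enum": [
    "primary",
    "secondary"
   ],
   "title": "OutcomeRole",
   "type": "string"
  },
  "PrevalenceType": {
   "enum": [
    "prevalent",
    "incident",
    "both"
   ],
   "title": "PrevalenceType",
   "type": "string"
  },
  "SelfReportDetail": {
   "description": "Detail items for self-reported ascertainment (schema items 2a.i-2a.iv).\n\n``mode_device`` and ``reference_period`` are open-vocabulary strings: the\npublished lists are illustrative (\"e.g. ...\"), so canonical values such as\n``capi``, ``cati``, ``last_12_months`` are conventions, not a closed enum.",
   "properties": {
    "mode_device": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Mode Device"
    },
    "domains": {
     "items": {
      "type": "string"
     },
     "title": "Domains",
     "type": "array"
    },
    "reference_period": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Reference Period"
    },
    "verification_methods": {
     "items": {
      "type": "string"
     },
     "title": "Verification Methods",
     "type": "array"
    },
    "external_validation": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "External Validation"
    }
   },
   "title": "SelfReportDetail",
   "type": "object"
  }
 },
 "description": "Full structured metadata for one chronic-disease outcome in one study.",
 "properties": {
  "study_id": {
   "title": "Study Id",
   "type": "string"
  },
  "outcome_name": {
   "title": "Outcome Name",
   "type": "string"
  },
  "outcome_group": {
   "$ref": "#/$defs/OutcomeGroup"
  },
  "prevalence_type": {
   "$ref": "#/$defs/PrevalenceType"
  },
  "classification_codes": {
   "items": {
    "$ref": "#/$defs/ClassificationCode"
   },
   "title": "Classification Codes",
   "type": "array"
  },
  "outcome_role": {
   "$ref": "#/$defs/OutcomeRole"
  },
  "collection_methods": {
   "items": {
    "$ref": "#/$defs/CollectionMethod"
   },
   "minItems": 1,
   "title": "Collection Methods",
   "type": "array"
  },
  "self_report_detail": {
   "anyOf": [
    {
     "$ref": "#/$defs/SelfReportDetail"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "examination_detail": {
   "anyOf": [
    {
     "$ref": "#/$defs/ExaminationDetail"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "administrative_detail": {
   "anyOf": [
    {
     "$ref": "#/$defs/AdministrativeDetail"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  }
 },
 "required": [
  "study_id",
  "outcome_name",
  "outcome_group",
  "prevalence_type",
  "outcome_role",
  "collection_methods"
 ],
 "title": "CDOMRecord",
 "type": "object",
 "$id": "https://cdomeval.invalid/cdom_record/v1.0",
 "version": "1.0"
}
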