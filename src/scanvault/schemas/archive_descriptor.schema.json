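{
  "$defs": {
    "Assignment": {
      "description": "Project/individual/timepoint carried by a batch-created descriptor.",
      "properties": {
        "project": {
          "title": "Project",
          "type": "string"
        },
        "individual": {
          "title": "Individual",
          "type": "string"
        },
        "timepoint": {
          "title": "Timepoint",
          "type": "string"
        }
      },
      "required": [
        "project",
        "individual",
        "timepoint"
      ],
      "title": "Assignment",
      "type": "object"
    },
    "DicomFileRecord": {
      "properties": {
        "member_path": {
          "title": "Member Path",
          "type": "string"
        },
        "sop_instance_uid": {
          "title": "Sop Instance Uid",
          "type": "string"
        },
        "instance_number": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Instance Number"
        },
        "md5": {
          "pattern": "^[0-9a-f]{32}$",
          "title": "Md5",
          "type": "string"
        },
        "series_uid": {
          "title": "Series Uid",
          "type": "string"
        }
      },
      "required": [
        "member_path",
        "sop_instance_uid",
        "md5",
        "series_uid"
      ],
      "title": "DicomFileRecord",
      "type": "object"
    },
    "DicomSeriesRecord": {
      "properties": {
        "series_uid": {
          "title": "Series Uid",
          "type": "string"
        },
        "modality": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Modality"
        },
        "description": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Description"
        },
        "echo_time": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Echo Time"
        },
        "repetition_time": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Repetition Time"
        },
        "slice_thickness": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Slice Thickness"
        },
        "manufacturer": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Manufacturer"
        },
        "scanner_serial": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Scanner Serial"
        },
        "software_version": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Software Version"
        },
        "field_strength": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Field Strength"
        },
        "acquisition_date": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Acquisition Date"
        },
        "patient_id": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Patient Id"
        },
        "patient_birth_date": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Patient Birth Date"
        },
        "file_count": {
          "default": 0,
          "title": "File Count",
          "type": "integer"
        }
      },
      "required": [
        "series_uid"
      ],
      "title": "DicomSeriesRecord",
      "type": "object"
    }
  },
  "properties": {
    "archive_id": {
      "title": "Archive Id",
      "type": "string"
    },
    "archive_md5": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Archive Md5"
    },
    "format_version": {
      "default": "1.0",
      "title": "Format Version",
      "type": "string"
    },
    "created": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Created"
    },
    "anonymized_confirmed": {
      "default": false,
      "title": "Anonymized Confirmed",
      "type": "boolean"
    },
    "series": {
      "items": {
        "$ref": "#/$defs/DicomSeriesRecord"
      },
      "title": "Series",
      "type": "array"
    },
    "files": {
      "items": {
        "$ref": "#/$defs/DicomFileRecord"
      },
      "title": "Files",
      "type": "array"
    },
    "assignment": {
      "anyOf": [
        {
          "$ref": "#/$defs/Assignment"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "required": [
    "archive_id"
  ],
  "title": "DICOM archive descriptor",
  "type": "object",
  "$schema": "https://json-schema.org/draft/2020-12/schema"
}
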