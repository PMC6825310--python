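{
  "clones": [
    {
      "description": "unmutated cell, baseline microenvironment; no oncogenic fixings",
      "name": "healthy",
      "perturbations": []
    },
    {
      "description": "Myc-low tumor cell in a pure Myc-low tumor (hypoxic stroma)",
      "name": "myc_low",
      "perturbations": [
        {
          "level": 4,
          "mode": "force",
          "variable": "WntDrive"
        },
        {
          "level": 4,
          "mode": "force",
          "variable": "WntEnv"
        },
        {
          "level": 3,
          "mode": "force",
          "variable": "Hypoxia"
        },
        {
          "level": 1,
          "mode": "force",
          "variable": "Stress"
        }
      ]
    },
    {
      "description": "Myc-low tumor cell inside a biclonal tumor (normoxic stroma)",
      "name": "myc_low_mixed",
      "perturbations": [
        {
          "level": 4,
          "mode": "force",
          "variable": "WntDrive"
        },
        {
          "level": 4,
          "mode": "force",
          "variable": "WntEnv"
        },
        {
          "level": 1,
          "mode": "force",
          "variable": "Hypoxia"
        },
        {
          "level": 1,
          "mode": "force",
          "variable": "Stress"
        }
      ]
    },
    {
      "description": "Myc-high tumor cell in a pure Myc-high tumor (Wnt-starved)",
      "name": "myc_high_pure",
      "perturbations": [
        {
          "level": 4,
          "mode": "force",
          "variable": "Myc"
        },
        {
          "level": 4,
          "mode": "force",
          "variable": "WntDrive"
        },
        {
          "level": 0,
          "mode": "force",
          "variable": "WntEnv"
        },
        {
          "level": 1,
          "mode": "force",
          "variable": "Hypoxia"
        },
        {
          "level": 1,
          "mode": "force",
          "variable": "Stress"
        }
      ]
    },
    {
      "description": "Myc-high tumor cell rescued by paracrine Wnt from Myc-low neighbors",
      "name": "myc_high_mixed",
      "perturbations": [
        {
          "level": 4,
          "mode": "force",
          "variable": "Myc"
        },
        {
          "level": 4,
          "mode": "force",
          "variable": "WntDrive"
        },
        {
          "level": 4,
          "mode": "force",
          "variable": "WntEnv"
        },
        {
          "level": 1,
          "mode": "force",
          "variable": "Hypoxia"
        },
        {
          "level": 1,
          "mode": "force",
          "variable": "Stress"
        }
      ]
    }
  ]
}
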