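# Model file format

Models are stored as JSON in a dialect compatible with publicly documented
BioModelAnalyzer (BMA) model files.  `clonalqn.bma_io.parse_model`
validates a document and reports the JSON path (and, for formulas, the
character offset) of any violation.

## Document layout

```json
{
  "Model": {
    "Name": "breast_in_vivo",
    "Variables": [
      {"Id": 1, "Name": "EGF", "RangeFrom": 0, "RangeTo": 4, "Formula": ""}
    ],
    "Relationships": [
      {"Id": 1, "FromVariable": 1, "ToVariable": 2, "Type": "Activator"}
    ]
  },
  "Layout": { "...": "optional; ignored semantically, preserved on round-trip" },
  "Extensions": {
    "clonalqn": {
      "variables": {
        "1": {"pathway": "microenvironment", "druggable": false, "constitutive": 2}
      }
    }
  }
}
```

Rules:

* variable `Id`s and `Name`s are unique; `RangeFrom < RangeTo`;
* relationship endpoints must exist; `Type` is `Activator` or `Inhibitor`;
  `(from, to, type)` triples are unique;
* an empty `Formula` string selects the default target function
  (average of activators minus average of inhibitors; constitutive
  constant minus average inhibition when there are no activators);
* app-specific per-variable fields live under `Extensions.clonalqn.variables`,
  keyed by variable id as a string: `pathway` (string tag), `druggable`
  (bool), `constitutive` (number within the variable's range).  Files
  without the extension block are plain BMA documents and load fine;
  unknown top-level blocks are carried through serialization untouched.

## Formula grammar

```
expr    := term (("+" | "-") term)*
term    := factor (("*" | "/") factor)*
factor  := "-" factor | primary
primary := NUMBER | func "(" expr ("," expr)* ")" | var | "(" expr ")"
func    := "avg" | "min" | "max" | "ceil" | "floor"     (case-insensitive)
var     := "var" "(" NAME ")" | "var" "(" "\"" NAME "\"" ")" | "var" "(" ID ")"
```

Decimal literals are allowed (targets are real-valued).  Every `var()`
reference must name a variable that has a relationship into the formula's
owner.  `min`/`max` accept two or more arguments (folded left); `ceil`
and `floor` take exactly one.  The evaluated target is clamped to the
owner's range; division by zero is an error.

## Clone configuration files

```json
{
  "clones": [
    {
      "name": "myc_high_mixed",
      "description": "...",
      "perturbations": [
        {"variable": "Myc", "mode": "force", "level": 4},
        {"variable": "WntEnv", "mode": "force", "level": 4}
      ]
    }
  ]
}
```

`mode` is `force` (fix at `level`) or `inhibit` (fix at the variable's
range minimum; `level` is ignored and may be null).
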