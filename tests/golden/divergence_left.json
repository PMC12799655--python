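{
  "direction": "rightward",
  "diverging_poses": [
    "prone",
    "left_side_lying",
    "supine"
  ],
  "hypothetical": [
    {
      "events": [
        {
          "direction": "right_beat",
          "intensity": 1.0,
          "qualifier": "robust"
        }
      ],
      "gravity": 270.0,
      "outcome_set": [
        "right_beat"
      ],
      "pose": "right_side_lying"
    },
    {
      "events": [
        {
          "direction": "right_beat",
          "intensity": 1.0,
          "qualifier": "robust"
        }
      ],
      "gravity": 0.0,
      "outcome_set": [
        "right_beat"
      ],
      "pose": "prone"
    },
    {
      "events": [
        {
          "direction": "none",
          "intensity": 0.0,
          "qualifier": "none"
        }
      ],
      "gravity": 90.0,
      "outcome_set": [
        "none"
      ],
      "pose": "left_side_lying"
    },
    {
      "events": [
        {
          "direction": "none",
          "intensity": 0.0,
          "qualifier": "none"
        },
        {
          "direction": "left_beat",
          "intensity": 1.0,
          "qualifier": "robust"
        }
      ],
      "gravity": 180.0,
      "outcome_set": [
        "left_beat",
        "none"
      ],
      "pose": "supine"
    }
  ],
  "side": "left",
  "start_pose": "supine",
  "true": [
    {
      "events": [
        {
          "direction": "right_beat",
          "intensity": 1.0,
          "qualifier": "robust"
        }
      ],
      "gravity": 270.0,
      "outcome_set": [
        "right_beat"
      ],
      "pose": "right_side_lying"
    },
    {
      "events": [
        {
          "direction": "none",
          "intensity": 0.0,
          "qualifier": "none"
        }
      ],
      "gravity": 0.0,
      "outcome_set": [
        "none"
      ],
      "pose": "prone"
    },
    {
      "events": [
        {
          "direction": "none",
          "intensity": 0.0,
          "qualifier": "none"
        },
        {
          "direction": "left_beat",
          "intensity": 1.0,
          "qualifier": "robust"
        }
      ],
      "gravity": 90.0,
      "outcome_set": [
        "left_beat",
        "none"
      ],
      "pose": "left_side_lying"
    },
    {
      "events": [
        {
          "direction": "none",
          "intensity": 0.0,
          "qualifier": "none"
        },
        {
          "direction": "left_beat",
          "intensity": 0.6427876096865393,
          "qualifier": "robust"
        },
        {
          "direction": "right_beat",
          "intensity": 1.0,
          "qualifier": "robust"
        }
      ],
      "gravity": 180.0,
      "outcome_set": [
        "left_beat",
        "none",
        "right_beat"
      ],
      "pose": "supine"
    }
  ]
}
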