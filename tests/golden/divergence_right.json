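{
  "direction": "rightward",
  "diverging_poses": [
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
          "direction": "left_beat",
          "intensity": 1.0,
          "qualifier": "robust"
        }
      ],
      "gravity": 180.0,
      "outcome_set": [
        "left_beat"
      ],
      "pose": "supine"
    }
  ],
  "side": "right",
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
          "direction": "right_beat",
          "intensity": 1.0,
          "qualifier": "robust"
        }
      ],
      "gravity": 90.0,
      "outcome_set": [
        "right_beat"
      ],
      "pose": "left_side_lying"
    },
    {
      "events": [
        {
          "direction": "none",
          "intensity": 0.0,
          "qualifier": "none"
        }
      ],
      "gravity": 180.0,
      "outcome_set": [
        "none"
      ],
      "pose": "supine"
    }
  ]
}
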