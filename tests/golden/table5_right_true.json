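{
  "canal": {
    "ampulla_angle": 20.0,
    "lumen_orientation": "ccw",
    "opening_angle": 140.0,
    "side": "right",
    "variant": "true_posteromedial"
  },
  "initial": {
    "compartment": "in_lumen",
    "p": 180.0
  },
  "steps": [
    {
      "branches": [
        {
          "final": {
            "compartment": "in_lumen",
            "p": 270.0
          },
          "label": "deterministic",
          "nystagmus": {
            "direction": "right_beat",
            "intensity": 1.0,
            "qualifier": "robust"
          },
          "parent": -1,
          "segments": [
            {
              "end": 270.0,
              "in_lumen": true,
              "peak_force": 1.0,
              "rotation_sense": "cw",
              "start": 180.0
            }
          ]
        }
      ],
      "gravity": 270.0,
      "index": 0,
      "pose": "right_side_lying"
    },
    {
      "branches": [
        {
          "final": {
            "compartment": "in_lumen",
            "p": 0.0
          },
          "label": "deterministic",
          "nystagmus": {
            "direction": "right_beat",
            "intensity": 1.0,
            "qualifier": "robust"
          },
          "parent": 0,
          "segments": [
            {
              "end": 0.0,
              "in_lumen": true,
              "peak_force": 1.0,
              "rotation_sense": "cw",
              "start": 270.0
            }
          ]
        }
      ],
      "gravity": 0.0,
      "index": 1,
      "pose": "prone"
    },
    {
      "branches": [
        {
          "final": {
            "compartment": "in_lumen",
            "p": 20.0
          },
          "label": "deterministic",
          "nystagmus": {
            "direction": "right_beat",
            "intensity": 1.0,
            "qualifier": "robust"
          },
          "parent": 0,
          "segments": [
            {
              "end": 20.0,
              "in_lumen": true,
              "peak_force": 1.0,
              "rotation_sense": "cw",
              "start": 0.0
            }
          ]
        }
      ],
      "gravity": 90.0,
      "index": 2,
      "pose": "left_side_lying"
    },
    {
      "branches": [
        {
          "final": {
            "compartment": "in_lumen",
            "p": 20.0
          },
          "label": "deterministic",
          "nystagmus": {
            "direction": "none",
            "intensity": 0.0,
            "qualifier": "none"
          },
          "parent": 0,
          "segments": []
        }
      ],
      "gravity": 180.0,
      "index": 3,
      "pose": "supine"
    }
  ]
}
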