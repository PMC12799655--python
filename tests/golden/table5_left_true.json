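{
  "canal": {
    "ampulla_angle": 340.0,
    "lumen_orientation": "cw",
    "opening_angle": 220.0,
    "side": "left",
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
            "compartment": "in_utricle",
            "p": null
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
              "end": 220.0,
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
            "compartment": "in_utricle",
            "p": null
          },
          "label": "utricle_stay",
          "nystagmus": {
            "direction": "none",
            "intensity": 0.0,
            "qualifier": "none"
          },
          "parent": 0,
          "segments": []
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
            "compartment": "in_utricle",
            "p": null
          },
          "label": "utricle_stay",
          "nystagmus": {
            "direction": "none",
            "intensity": 0.0,
            "qualifier": "none"
          },
          "parent": 0,
          "segments": []
        },
        {
          "final": {
            "compartment": "in_lumen",
            "p": 90.0
          },
          "label": "utricle_reenter",
          "nystagmus": {
            "direction": "left_beat",
            "intensity": 1.0,
            "qualifier": "robust"
          },
          "parent": 0,
          "segments": [
            {
              "end": 90.0,
              "in_lumen": true,
              "peak_force": 1.0,
              "rotation_sense": "ccw",
              "start": 220.0
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
            "compartment": "in_utricle",
            "p": null
          },
          "label": "utricle_stay",
          "nystagmus": {
            "direction": "none",
            "intensity": 0.0,
            "qualifier": "none"
          },
          "parent": 0,
          "segments": []
        },
        {
          "final": {
            "compartment": "in_lumen",
            "p": 180.0
          },
          "label": "utricle_reenter",
          "nystagmus": {
            "direction": "left_beat",
            "intensity": 0.6427876096865393,
            "qualifier": "robust"
          },
          "parent": 0,
          "segments": [
            {
              "end": 180.0,
              "in_lumen": true,
              "peak_force": 0.6427876096865393,
              "rotation_sense": "ccw",
              "start": 220.0
            }
          ]
        },
        {
          "final": {
            "compartment": "in_lumen",
            "p": 180.0
          },
          "label": "deterministic",
          "nystagmus": {
            "direction": "right_beat",
            "intensity": 1.0,
            "qualifier": "robust"
          },
          "parent": 1,
          "segments": [
            {
              "end": 180.0,
              "in_lumen": true,
              "peak_force": 1.0,
              "rotation_sense": "cw",
              "start": 90.0
            }
          ]
        }
      ],
      "gravity": 180.0,
      "index": 3,
      "pose": "supine"
    }
  ]
}
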