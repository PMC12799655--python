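{
  "canal": {
    "ampulla_angle": 315.0,
    "lumen_orientation": "ccw",
    "opening_angle": 75.0,
    "side": "right",
    "variant": "hypothetical_anteromedial"
  },
  "canal_tilt": 30.0,
  "cases": [
    {
      "label": "A",
      "pitch": 0.0,
      "position": 270.0,
      "prediction": {
        "direction": "left_beat",
        "intensity": 0.49999999999999994,
        "qualifier": "modest"
      }
    },
    {
      "label": "B",
      "pitch": -60.0,
      "position": 270.0,
      "prediction": {
        "direction": "left_beat",
        "intensity": 1.0,
        "qualifier": "robust"
      }
    },
    {
      "label": "C",
      "pitch": 90.0,
      "position": 270.0,
      "prediction": {
        "direction": "right_beat",
        "intensity": 0.8660254037844386,
        "qualifier": "robust"
      }
    },
    {
      "label": "D",
      "pitch": 0.0,
      "position": 80.0,
      "prediction": {
        "direction": "right_beat",
        "intensity": 0.49240387650610395,
        "qualifier": "modest"
      }
    },
    {
      "label": "E",
      "pitch": -60.0,
      "position": 80.0,
      "prediction": {
        "direction": "right_beat",
        "intensity": 0.984807753012208,
        "qualifier": "robust"
      }
    },
    {
      "label": "F",
      "pitch": 90.0,
      "position": 80.0,
      "prediction": {
        "direction": "left_beat",
        "intensity": 0.8528685319524432,
        "qualifier": "robust"
      }
    }
  ]
}
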